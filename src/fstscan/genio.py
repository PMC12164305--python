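"""Genotype containers, VCF I/O and staged SNP quality control.

The central container is :class:`GenotypeMatrix`, a samples x SNPs matrix of
alternate-allele dosages (0/1/2, ``-1`` for missing) with per-variant and
per-sample metadata carried as pandas DataFrames. Quality control follows the
usual resequencing-panel recipe for a merged multi-breed panel: drop
multi-allelic sites, keep autosomes, drop high-missingness sites, drop low-MAF
sites, then drop sites out of Hardy-Weinberg equilibrium in any single breed.
Each stage's removals are recorded in an auditable :class:`QCReport` ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from sklearn.base import BaseEstimator, TransformerMixin

MISSING = -1

#: Pig autosomes; chromosome names follow the Ensembl/Sus scrofa convention.
PIG_AUTOSOMES = frozenset(str(i) for i in range(1, 19))


class VcfParseError(ValueError):
    """Malformed VCF content, annotated with the offending record number."""


class SampleMapError(KeyError):
    """A VCF sample is missing from the sample->population map."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosage matrix with metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_snps)
        Entries in {0, 1, 2} counting alternate alleles, ``-1`` for missing.
    variants : DataFrame with columns chrom, pos, ref, alt
        One row per SNP; ``pos`` is 1-based; ``alt`` is the comma-joined ALT
        list (multi-allelic records keep their full list so the biallelic
        filter can act on them).
    samples : DataFrame with columns id, population
        One row per sample, aligned with the dosage rows.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variants rows must match dosage columns")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("samples rows must match dosage rows")
        allowed = {0, 1, 2, MISSING}
        present = set(np.unique(self.dosages).tolist())
        if not present <= allowed:
            raise ValueError(f"dosage entries outside {allowed}: {present - allowed}")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        for _, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["population"]))

    def pop_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == label).to_numpy())
        if idx.size == 0:
            raise SampleMapError(f"population {label!r} not present")
        return idx

    def take_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[keep, :],
            variants=self.variants.copy(),
            samples=self.samples.iloc[keep].reset_index(drop=True),
        )


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the staged SNP filters.

    Defaults correspond to the common PLINK invocation on a merged breed panel:
    ``--geno 0.1 --maf 0.1 --hwe 0.01`` plus autosome-only and biallelic-only.
    """

    max_missing_rate: float = 0.10
    min_maf: float = 0.10
    hwe_alpha: float = 0.01
    autosomes: frozenset[str] = PIG_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")


@dataclass
class QCReport:
    """Ordered per-stage ledger of SNP removals."""

    n_input: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.stages.append((name, removed, remaining))

    @property
    def n_final(self) -> int:
        return self.stages[-1][2] if self.stages else self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "removed", "remaining"])

    def check_conservation(self) -> bool:
        return self.n_final == self.n_input - sum(r for _, r, _ in self.stages)


# ---------------------------------------------------------------------------
# VCF / sample-map I/O


def read_sample_map(path) -> dict[str, str]:
    """Read a two-column TSV of sample_id -> population label."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{i}: expected sample_id<TAB>population")
        out[parts[0]] = parts[1]
    return out


def write_sample_map(panel: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for _, row in panel.samples.iterrows():
            fh.write(f"{row['id']}\t{row['population']}\n")


def read_vcf(path, sample_map: Mapping[str, str] | str | Path) -> GenotypeMatrix:
    """Load a VCF (v4.x, GT field) into a :class:`GenotypeMatrix`.

    Genotype coding: 0/0 -> 0; 0/1, 1/0 -> 1; 1/1 -> 2; any genotype containing
    a missing allele (``./.`` or half calls such as ``./1``) -> missing.
    Phased separators are accepted. Multi-allelic records are retained with
    their full ALT list (non-reference alleles all count toward the dosage);
    the biallelic QC stage removes them.

    Parameters
    ----------
    sample_map : mapping or path
        sample id -> population label; every VCF sample must be present.
    """
    if not isinstance(sample_map, Mapping):
        sample_map = read_sample_map(sample_map)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sample_map]
    if missing:
        raise SampleMapError(f"samples absent from sample map: {missing}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    for i, v in enumerate(vcf, start=1):
        try:
            gt = np.asarray(v.genotype.array())  # (n_samples, ploidy+1); last col phasing
        except Exception as exc:  # pragma: no cover - cyvcf2 internal failure
            raise VcfParseError(f"{path}: record {i}: {exc}") from exc
        alleles = gt[:, :2]
        dos = np.where(
            (alleles < 0).any(axis=1), MISSING, (alleles > 0).sum(axis=1)
        ).astype(np.int8)
        cols.append(dos)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
    dosages = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    sdf = pd.DataFrame({"id": samples, "population": [sample_map[s] for s in samples]})
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=sdf)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    chrom_order = list(dict.fromkeys(panel.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fstscan\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["id"])
            + "\n"
        )
        variants = panel.variants
        for j in range(panel.n_snps):
            row = variants.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(d)] for d in panel.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@lru_cache(maxsize=None)
def _hwe_weights(n: int, n_a: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Integer weights of the conditional heterozygote-count distribution.

    Given ``n`` diploids and ``n_a`` copies of allele A (0 <= n_a <= 2n), the
    heterozygote count h has conditional probability proportional to
    ``n! / (n_AA! h! n_aa!) * 2**h`` (Levene/Haldane). Exact integers avoid
    float ties when summing the tail.
    """
    n_b = 2 * n - n_a
    hs = []
    ws = []
    fact_n = math.factorial(n)
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        w = fact_n // (math.factorial(a) * math.factorial(h) * math.factorial(b)) * (1 << h)
        hs.append(h)
        ws.append(w)
    return tuple(hs), tuple(ws)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Sums the conditional probabilities (given sample size and allele count)
    of every heterozygote count whose probability does not exceed that of the
    observed count. Monomorphic or empty sites return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_AA + n_Aa
    hs, ws = _hwe_weights(n, n_a)
    w_obs = ws[hs.index(n_Aa)]
    num = sum(w for w in ws if w <= w_obs)
    return float(Fraction(num, sum(ws)))


# ---------------------------------------------------------------------------
# Staged QC


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP counts of hom-ref / het / hom-alt over non-missing entries."""
    return (
        (dosages == 0).sum(axis=0),
        (dosages == 1).sum(axis=0),
        (dosages == 2).sum(axis=0),
    )


def _hwe_p_per_snp(dosages: np.ndarray) -> np.ndarray:
    n0, n1, n2 = _genotype_counts(dosages)
    return np.array(
        [hwe_exact_p(int(a), int(h), int(b)) for a, h, b in zip(n0, n1, n2)]
    )


def apply_qc(
    panel: GenotypeMatrix,
    cfg: QCConfig | None = None,
    populations: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the five staged SNP filters, returning the filtered panel and ledger.

    Stages, in order: (1) drop multi-allelic sites; (2) keep autosomes only;
    (3) drop sites with missing rate strictly greater than ``max_missing_rate``;
    (4) drop sites with MAF below ``min_maf`` (computed jointly over all samples
    on non-missing allele counts; sites at exactly the threshold are kept);
    (5) drop sites whose HWE exact p-value falls below ``hwe_alpha`` in any one
    population.
    """
    cfg = cfg or QCConfig()
    if populations is None:
        populations = panel.populations
    report = QCReport(n_input=panel.n_snps)
    cur = panel

    def _stage(name: str, keep: np.ndarray) -> None:
        nonlocal cur
        removed = int((~keep).sum())
        cur = cur.take_variants(keep)
        report.add(name, removed, cur.n_snps)

    alt = cur.variants["alt"].astype(str)
    _stage("biallelic", (~alt.str.contains(",")).to_numpy())
    _stage("autosomes", cur.variants["chrom"].isin(cfg.autosomes).to_numpy())

    miss = (cur.dosages == MISSING).mean(axis=0) if cur.n_samples else np.zeros(cur.n_snps)
    _stage("missing_rate", miss <= cfg.max_missing_rate)

    called = (cur.dosages != MISSING).sum(axis=0)
    alt_count = np.where(cur.dosages == MISSING, 0, cur.dosages).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(called > 0, alt_count / (2.0 * called), 0.0)
    maf = np.minimum(f, 1.0 - f)
    _stage("maf", maf >= cfg.min_maf)

    keep_hwe = np.ones(cur.n_snps, dtype=bool)
    for pop in populations:
        idx = cur.pop_indices(pop)
        keep_hwe &= _hwe_p_per_snp(cur.dosages[idx]) >= cfg.hwe_alpha
    _stage("hwe", keep_hwe)

    if cur.n_snps == 0:
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    assert report.check_conservation()
    return cur, report


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Staged SNP quality-control filter as a transformer.

    ``fit`` computes the per-stage keep masks and the removal ledger on a
    :class:`GenotypeMatrix`; ``transform`` returns the filtered panel.

    Attributes
    ----------
    report_ : QCReport
        Per-stage (name, removed, remaining) ledger.
    n_snps_in_ : int
    n_snps_out_ : int
    """

    def __init__(
        self,
        max_missing_rate: float = 0.10,
        min_maf: float = 0.10,
        hwe_alpha: float = 0.01,
        autosomes: frozenset[str] = PIG_AUTOSOMES,
    ):
        self.max_missing_rate = max_missing_rate
        self.min_maf = min_maf
        self.hwe_alpha = hwe_alpha
        self.autosomes = autosomes

    def _config(self) -> QCConfig:
        return QCConfig(
            max_missing_rate=self.max_missing_rate,
            min_maf=self.min_maf,
            hwe_alpha=self.hwe_alpha,
            autosomes=frozenset(self.autosomes),
        )

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypeQC":
        filtered, report = apply_qc(X, self._config())
        self.report_ = report
        self.n_snps_in_ = X.n_snps
        self.n_snps_out_ = filtered.n_snps
        self._filtered = filtered
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "report_"):
            raise RuntimeError("GenotypeQC is not fitted")
        filtered, _ = apply_qc(X, self._config())
        return filtered

    def fit_transform(self, X: GenotypeMatrix, y=None) -> GenotypeMatrix:
        self.fit(X)
        return self._filtered
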