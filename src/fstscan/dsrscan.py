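"""Differential-selection-region (DSR) scanning between breed pairs.

For each SNP the scan computes (i) a drift-model differentiation statistic —
the moment form of the Nicholson model, ``FST = Var(p1, p2) / (pbar (1-pbar))``
with the population-count denominator, bounded in [0, 1] — and (ii) an allelic
Fisher's exact test on the 2x2 ref/alt allele-count table, Bonferroni-corrected
over the SNPs entering the scan. SNPs are then classified by a two-tier rule:
the top 0.01% of FST values with corrected p < 0.05 are "extreme", the top 0.5%
with corrected p < 0.05 are "significant". Regions grow from every extreme SNP
in both directions along the marker order until two consecutive nonsignificant
SNPs are met; in addition any uninterrupted stretch holding more than five
significant SNPs forms a region without an extreme seed. Overlapping regions
are merged and numbered genome-wide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator

from .genio import MISSING, GenotypeMatrix

NONSIG = "nonsignificant"
SIG = "significant"
EXTREME = "extreme"

#: Relative tolerance of the two-sided point-probability rule: tables whose
#: hypergeometric probability is within this factor of the observed one count
#: as "at most as probable" (guards float round-off on exact ties).
_FISHER_RELTOL = 1 + 1e-7


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the two-tier scan.

    ``q_extreme``/``q_sig`` are upper-tail quantile fractions of the genome-wide
    per-SNP FST distribution (0.0001 = top 0.01%, 0.005 = top 0.5%); ``alpha``
    gates on the Bonferroni-corrected Fisher p; ``break_len`` consecutive
    nonsignificant SNPs end region extension; a seedless stretch needs at least
    ``min_run`` significant SNPs ("more than five").
    """

    q_extreme: float = 0.0001
    q_sig: float = 0.005
    alpha: float = 0.05
    break_len: int = 2
    min_run: int = 6

    def __post_init__(self) -> None:
        if not self.q_extreme < self.q_sig:
            raise ValueError("q_extreme must be smaller than q_sig")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.break_len < 1 or self.min_run < 1:
            raise ValueError("break_len and min_run must be >= 1")


@dataclass
class DSRegion:
    """A detected differentially selected region (1-based inclusive ends at the
    outermost significant-or-extreme SNPs)."""

    id: int
    chrom: str
    start: int
    end: int
    n_snps_spanned: int
    n_significant: int
    n_extreme: int

    @property
    def name(self) -> str:
        return f"DSR{self.id}"


# ---------------------------------------------------------------------------
# Per-SNP statistics


def pop_allele_counts(
    panel: GenotypeMatrix, pops: tuple[str, ...] | list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-population (ref_count, alt_count) allele tallies per SNP.

    Alt counts sum dosages over non-missing samples; ref = 2*called - alt.
    """
    out = {}
    for pop in pops:
        g = panel.dosages[panel.pop_indices(pop)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        ref = 2 * called.sum(axis=0) - alt
        out[pop] = (ref.astype(np.int64), alt.astype(np.int64))
    return out


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact test p-value of a 2x2 count table.

    Point-probability method (sum of hypergeometric probabilities of tables at
    most as probable as the observed one). A zero margin leaves only one
    possible table: p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


def fisher_two_sided_batch(
    ref_a: np.ndarray, alt_a: np.ndarray, ref_b: np.ndarray, alt_b: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher's exact test over many 2x2 tables.

    Enumerates the full hypergeometric support of every table (log-space
    probabilities via ``gammaln``) and sums the probabilities at most
    ``observed * (1 + 1e-7)``, the same point-probability rule as the scalar
    test. Zero-margin tables get p = 1.
    """
    ref_a = np.asarray(ref_a, dtype=np.int64)
    alt_a = np.asarray(alt_a, dtype=np.int64)
    ref_b = np.asarray(ref_b, dtype=np.int64)
    alt_b = np.asarray(alt_b, dtype=np.int64)
    n1 = ref_a + alt_a  # row margins
    n2 = ref_b + alt_b
    k = ref_a + ref_b  # first-column margin
    n = n1 + n2
    out = np.ones(ref_a.shape, dtype=float)
    ok = (n1 > 0) & (n2 > 0) & (k > 0) & (k < n)
    if not ok.any():
        return out
    idx = np.flatnonzero(ok)
    lo = np.maximum(0, k[idx] - n2[idx])
    hi = np.minimum(k[idx], n1[idx])
    width = int((hi - lo).max()) + 1
    x = lo[:, None] + np.arange(width)[None, :]
    valid = x <= hi[:, None]
    xc = np.where(valid, x, lo[:, None])  # clamp to keep gammaln args sane
    n1_, n2_, k_, n_ = (v[idx][:, None] for v in (n1, n2, k, n))
    logp = (
        gammaln(n1_ + 1)
        - gammaln(xc + 1)
        - gammaln(n1_ - xc + 1)
        + gammaln(n2_ + 1)
        - gammaln(k_ - xc + 1)
        - gammaln(n2_ - k_ + xc + 1)
        + gammaln(k_ + 1)
        + gammaln(n_ - k_ + 1)
        - gammaln(n_ + 1)
    )
    p = np.where(valid, np.exp(logp), 0.0)
    obs = np.take_along_axis(p, (ref_a[idx] - lo)[:, None], axis=1)
    out[idx] = np.minimum((p * (p <= obs * _FISHER_RELTOL)).sum(axis=1), 1.0)
    return out


def bonferroni_adjust(p, m: int):
    """Bonferroni correction: min(1, p*m) for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) else min(
        1.0, float(p) * m
    )


def snp_fst(p1, p2):
    """Per-SNP drift-model FST from two sample allele frequencies.

    ``pbar = (p1+p2)/2``; ``FST = ((p1-pbar)^2 + (p2-pbar)^2) / 2 / (pbar(1-pbar))``.
    Undefined (NaN) when the pooled frequency is 0 or 1. Accepts scalars or
    arrays; bounded in [0, 1].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2
    var = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where((pbar > 0) & (pbar < 1), var / (pbar * (1 - pbar)), np.nan)
    return float(fst) if fst.ndim == 0 else fst


# ---------------------------------------------------------------------------
# Classification and region detection


def rank_thresholds(fst: np.ndarray, cfg: ScanConfig) -> tuple[float, float]:
    """Realized FST cut values for the extreme and significant tiers.

    The tier-q threshold is the ``ceil(q*m)``-th largest defined FST value
    (ties at the cut are included downstream by >= comparison).
    """
    vals = np.sort(fst[np.isfinite(fst)])[::-1]
    m = vals.size
    if m == 0:
        return np.inf, np.inf
    if m < 1 / cfg.q_extreme:
        warnings.warn(
            f"only {m} SNPs with defined FST; extreme threshold degenerates to the maximum",
            stacklevel=2,
        )
    k_ext = min(max(math.ceil(cfg.q_extreme * m), 1), m)
    k_sig = min(max(math.ceil(cfg.q_sig * m), 1), m)
    return float(vals[k_ext - 1]), float(vals[k_sig - 1])


def classify_snps(stats: pd.DataFrame, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Attach the two-tier label to per-SNP statistics.

    ``stats`` needs columns fst (NaN allowed) and p_bonf. A SNP is extreme when
    its FST reaches the top-``q_extreme`` rank threshold and the corrected
    Fisher p is below ``alpha``; significant when it reaches the top-``q_sig``
    threshold under the same p gate (every extreme SNP also satisfies the
    significant tier); everything else — including undefined FST — is
    nonsignificant.
    """
    cfg = cfg or ScanConfig()
    t_ext, t_sig = rank_thresholds(stats["fst"].to_numpy(), cfg)
    out = stats.copy()
    fst = out["fst"].to_numpy()
    gate = out["p_bonf"].to_numpy() < cfg.alpha
    defined = np.isfinite(fst)
    label = np.full(len(out), NONSIG, dtype=object)
    label[defined & gate & (fst >= t_sig)] = SIG
    label[defined & gate & (fst >= t_ext)] = EXTREME
    out["label"] = label
    out.attrs["threshold_extreme"] = t_ext
    out.attrs["threshold_significant"] = t_sig
    return out


def _segments(is_nonsig: np.ndarray, break_len: int) -> list[tuple[int, int]]:
    """Maximal index spans free of any ``break_len``-long nonsignificant run."""
    n = is_nonsig.size
    segs = []
    run = 0
    start = 0
    i = 0
    while i < n:
        if is_nonsig[i]:
            run += 1
            if run == break_len:
                end = i - break_len  # last index before the breaking run
                if end >= start:
                    segs.append((start, end))
                start = i + 1
                run = 0
                # a new run may begin immediately after
        else:
            run = 0
        i += 1
    if start <= n - 1:
        segs.append((start, n - 1))
    return segs


def detect_dsrs(stats: pd.DataFrame, cfg: ScanConfig | None = None) -> list[DSRegion]:
    """Seed-and-extend region detection on labeled per-SNP statistics.

    ``stats`` needs columns chrom, pos, label, sorted by position within each
    chromosome. Within a chromosome the SNP sequence splits at every run of
    ``break_len`` consecutive nonsignificant SNPs; a split segment, trimmed to
    its outermost significant-or-extreme SNPs, is reported when it contains an
    extreme seed or at least ``min_run`` significant SNPs. This is exactly the
    union of (a) bidirectional extension from every extreme SNP until a
    ``break_len`` nonsignificant run and (b) the seedless uninterrupted-run
    rule, with overlaps merged. Regions are numbered genome-wide in
    (chromosome, position) order of the input.
    """
    cfg = cfg or ScanConfig()
    regions: list[DSRegion] = []
    next_id = 1
    for chrom, sub in stats.groupby("chrom", sort=False):
        labels = sub["label"].to_numpy()
        pos = sub["pos"].to_numpy()
        is_nonsig = labels == NONSIG
        for s, e in _segments(is_nonsig, cfg.break_len):
            sig_idx = np.flatnonzero(~is_nonsig[s : e + 1]) + s
            if sig_idx.size == 0:
                continue
            i, j = int(sig_idx[0]), int(sig_idx[-1])
            n_ext = int((labels[i : j + 1] == EXTREME).sum())
            n_sig = int(sig_idx.size)
            if n_ext == 0 and n_sig < cfg.min_run:
                continue
            regions.append(
                DSRegion(
                    id=next_id,
                    chrom=str(chrom),
                    start=int(pos[i]),
                    end=int(pos[j]),
                    n_snps_spanned=j - i + 1,
                    n_significant=n_sig,
                    n_extreme=n_ext,
                )
            )
            next_id += 1
    return regions


def regions_to_frame(regions: list[DSRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.name,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps_spanned": r.n_snps_spanned,
                "n_significant": r.n_significant,
                "n_extreme": r.n_extreme,
            }
            for r in regions
        ],
        columns=[
            "id",
            "chrom",
            "start",
            "end",
            "n_snps_spanned",
            "n_significant",
            "n_extreme",
        ],
    )


# ---------------------------------------------------------------------------
# Full pair scan


def run_pair_scan(
    panel: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    cfg: ScanConfig | None = None,
) -> tuple[pd.DataFrame, list[DSRegion]]:
    """Complete DSR scan between two populations of a QC'd panel.

    Composes allele counting, the allelic Fisher test (Bonferroni m = number of
    SNPs entering the scan), the per-SNP drift-model FST, two-tier
    classification and seed-and-extend detection. Deterministic.
    """
    cfg = cfg or ScanConfig()
    counts = pop_allele_counts(panel, (pop_a, pop_b))
    ref_a, alt_a = counts[pop_a]
    ref_b, alt_b = counts[pop_b]
    m = panel.n_snps
    fisher_p = fisher_two_sided_batch(ref_a, alt_a, ref_b, alt_b)
    p_bonf = bonferroni_adjust(fisher_p, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(ref_a + alt_a > 0, alt_a / (ref_a + alt_a), np.nan)
        p2 = np.where(ref_b + alt_b > 0, alt_b / (ref_b + alt_b), np.nan)
    fst = snp_fst(np.nan_to_num(p1, nan=0.0), np.nan_to_num(p2, nan=0.0))
    fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, fst)
    stats = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "fst": fst,
            "fisher_p": fisher_p,
            "p_bonf": p_bonf,
        }
    )
    stats = classify_snps(stats, cfg)
    regions = detect_dsrs(stats, cfg)
    return stats, regions


class DSRScanner(BaseEstimator):
    """Two-tier FST + Fisher selection scan between one breed pair.

    Parameters mirror :class:`ScanConfig`. ``fit(panel)`` runs the scan for
    ``(pop_a, pop_b)``.

    Attributes
    ----------
    snp_stats_ : DataFrame
        chrom, pos, fst, fisher_p, p_bonf, label per SNP.
    regions_ : list[DSRegion]
    thresholds_ : dict with the realized extreme/significant FST cut values.
    """

    def __init__(
        self,
        pop_a: str | None = None,
        pop_b: str | None = None,
        q_extreme: float = 0.0001,
        q_sig: float = 0.005,
        alpha: float = 0.05,
        break_len: int = 2,
        min_run: int = 6,
    ):
        self.pop_a = pop_a
        self.pop_b = pop_b
        self.q_extreme = q_extreme
        self.q_sig = q_sig
        self.alpha = alpha
        self.break_len = break_len
        self.min_run = min_run

    def _config(self) -> ScanConfig:
        return ScanConfig(
            q_extreme=self.q_extreme,
            q_sig=self.q_sig,
            alpha=self.alpha,
            break_len=self.break_len,
            min_run=self.min_run,
        )

    def fit(self, X: GenotypeMatrix, y=None):
        if self.pop_a is None or self.pop_b is None:
            raise ValueError("pop_a and pop_b must be set")
        stats, regions = run_pair_scan(X, self.pop_a, self.pop_b, self._config())
        self.snp_stats_ = stats
        self.regions_ = regions
        self.thresholds_ = {
            "extreme": stats.attrs["threshold_extreme"],
            "significant": stats.attrs["threshold_significant"],
        }
        return self
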