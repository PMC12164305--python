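"""Synthetic multi-population genotype panels under the Balding-Nichols model.

Population allele frequencies are dispersed around an ancestral frequency
``pi`` with a per-branch drift coefficient ``c``: ``p ~ Beta(pi(1-c)/c,
(1-pi)(1-c)/c)``, which has mean ``pi`` and variance ``c*pi*(1-pi)`` — the
Beta analogue of Nicholson's truncated-Gaussian drift model. Populations may
be related through a nested drift tree (two-level in the default breed panel),
and designated SNP windows can be "planted" with an elevated drift ``c_sel``
on a leaf branch to mimic divergent selection. Genotypes are drawn
Binomial(2, p) within each population (HWE within breeds).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, write_sample_map, write_vcf

_FREQ_CLAMP = 1e-9  # Beta draws may hit numerical 0/1; keep count tables defined


class ConfigurationError(ValueError):
    """Invalid simulation configuration (drift out of range, bad regions...)."""


@dataclass(frozen=True)
class DriftNode:
    """Node of a population drift tree.

    ``drift`` is the Balding-Nichols coefficient on the branch from the parent
    (the root uses ``drift=0`` meaning "ancestral frequency unchanged"). A leaf
    carries the population name it generates.
    """

    drift: float = 0.0
    pop: str | None = None
    children: tuple["DriftNode", ...] = ()

    def leaves(self) -> list[str]:
        if self.pop is not None:
            return [self.pop]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass(frozen=True)
class PlantedRegion:
    """A window of SNPs simulated with elevated leaf drift ``c_sel``.

    ``start``/``stop`` are 0-based half-open SNP indices within the chromosome's
    marker order; ``pops`` names the diverging population(s).
    """

    chrom: str
    start: int
    stop: int
    c_sel: float
    pops: tuple[str, ...]


@dataclass(frozen=True)
class Chromosome:
    name: str
    n_snps: int
    length: int


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic panel; deterministic given ``seed``."""

    pop_names: tuple[str, ...]
    pop_sizes: tuple[int, ...]
    drift: tuple[float, ...] | DriftNode
    chromosomes: tuple[Chromosome, ...]
    planted_regions: tuple[PlantedRegion, ...] = ()
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def n_snps(self) -> int:
        return sum(c.n_snps for c in self.chromosomes)

    def tree(self) -> DriftNode:
        """The drift tree; a flat drift vector means a star phylogeny."""
        if isinstance(self.drift, DriftNode):
            return self.drift
        children = tuple(
            DriftNode(drift=c, pop=name) for c, name in zip(self.drift, self.pop_names)
        )
        return DriftNode(drift=0.0, children=children)

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != len(self.pop_names):
            raise ConfigurationError("pop_sizes must match pop_names")
        if any(n < 2 for n in self.pop_sizes):
            raise ConfigurationError("each population needs >= 2 diploid samples")
        drifts = _branch_drifts(self.tree())
        if not drifts:
            raise ConfigurationError("drift tree has no branches")
        if any(not 0 < c < 1 for c in drifts):
            raise ConfigurationError("drift coefficients must lie in (0,1)")
        if sorted(self.tree().leaves()) != sorted(self.pop_names):
            raise ConfigurationError("drift tree leaves must match pop_names")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo < hi < 1:
            raise ConfigurationError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0,1)")
        chrom_names = {c.name for c in self.chromosomes}
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.planted_regions:
            if r.chrom not in chrom_names:
                raise ConfigurationError(f"planted region on unknown chromosome {r.chrom}")
            n = next(c.n_snps for c in self.chromosomes if c.name == r.chrom)
            if not 0 <= r.start < r.stop <= n:
                raise ConfigurationError(f"planted region {r} outside chromosome bounds")
            if r.c_sel <= max(drifts):
                raise ConfigurationError("c_sel must exceed every background drift")
            if not set(r.pops) <= set(self.pop_names):
                raise ConfigurationError(f"unknown diverging population in {r}")
            by_chrom.setdefault(r.chrom, []).append(r)
        for regions in by_chrom.values():
            regions = sorted(regions, key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if b.start < a.stop:
                    raise ConfigurationError("planted regions overlap")
        for c in self.chromosomes:
            if c.n_snps > c.length:
                raise ConfigurationError(f"chromosome {c.name}: more SNPs than positions")


@dataclass
class TruthSet:
    """Ground truth of a simulated panel.

    ``pop_freqs`` is pops x SNPs (row order = ``config.pop_names``);
    ``positions`` aligns 1-based bp positions with SNP columns;
    ``planted_intervals`` are (chrom, start_bp, end_bp), 1-based inclusive;
    ``pairwise_target_fst`` holds the analytic drift-based differentiation
    targets (composite drift to the most recent common ancestor, averaged).
    """

    pop_freqs: np.ndarray
    ancestral_freqs: np.ndarray
    positions: pd.DataFrame
    planted_intervals: list[tuple[str, int, int]]
    pairwise_target_fst: pd.DataFrame


def _branch_drifts(node: DriftNode, *, _root: bool = True) -> list[float]:
    out = [] if _root else [node.drift]
    for ch in node.children:
        out.extend(_branch_drifts(ch, _root=False))
    return out


def _collect_paths(node: DriftNode):
    """Return {pop: [(node_id, drift), ...] root->leaf} with unique node ids."""
    paths: dict[str, list[tuple[int, float]]] = {}
    counter = [0]

    def walk(n: DriftNode, acc: list[tuple[int, float]]):
        nid = counter[0]
        counter[0] += 1
        acc = acc + [(nid, n.drift)]
        if n.pop is not None:
            paths[n.pop] = acc
        for ch in n.children:
            walk(ch, acc)

    walk(node, [])
    return paths


def pairwise_target_fst(config: SimulationConfig) -> pd.DataFrame:
    """Analytic differentiation targets implied by the drift tree.

    Composite drift from the MRCA to leaf j is ``C_j = 1 - prod(1 - c)`` over
    the branches below the MRCA; the pairwise target is ``(C_a + C_b) / 2``,
    which the weighted Weir-Cockerham estimate tracks closely at these depths.
    """
    paths = _collect_paths(config.tree())
    names = list(config.pop_names)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, pb = paths[a], paths[b]
            shared = 0
            for (na, _), (nb, _) in zip(pa, pb):
                if na != nb:
                    break
                shared += 1
            ca = 1.0 - np.prod([1 - c for _, c in pa[shared:]])
            cb = 1.0 - np.prod([1 - c for _, c in pb[shared:]])
            out.loc[a, b] = out.loc[b, a] = (ca + cb) / 2
    return out


def _bn_draw(rng: np.random.Generator, base: np.ndarray, c: float) -> np.ndarray:
    p = rng.beta(base * (1 - c) / c, (1 - base) * (1 - c) / c)
    return np.clip(p, _FREQ_CLAMP, 1 - _FREQ_CLAMP)


def simulate_frequencies(config: SimulationConfig) -> TruthSet:
    """Draw ancestral and population allele frequencies plus marker positions.

    Per chromosome (independent sub-streams of the global seed):
    ``pi ~ Uniform(lo, hi)`` per SNP; frequencies propagate down the drift tree
    with one Beta draw per branch; inside planted regions the leaf-branch draw
    of each designated population uses ``c_sel`` instead of the leaf drift.
    """
    ss = np.random.SeedSequence(config.seed)
    freq_root, _ = ss.spawn(2)
    chrom_streams = freq_root.spawn(len(config.chromosomes))

    pop_order = {name: i for i, name in enumerate(config.pop_names)}
    pop_freqs = np.empty((config.n_pops, config.n_snps))
    anc = np.empty(config.n_snps)
    chroms_col: list[str] = []
    pos_col: list[int] = []
    planted: list[tuple[str, int, int]] = []
    lo, hi = config.ancestral_freq_range

    offset = 0
    for chrom, stream in zip(config.chromosomes, chrom_streams):
        rng = np.random.default_rng(stream)
        m = chrom.n_snps
        pi = rng.uniform(lo, hi, m)
        anc[offset : offset + m] = pi
        pos = np.sort(rng.choice(chrom.length, size=m, replace=False)) + 1
        chroms_col.extend([chrom.name] * m)
        pos_col.extend(int(p) for p in pos)
        regions = [r for r in config.planted_regions if r.chrom == chrom.name]

        def walk(node: DriftNode, base: np.ndarray) -> None:
            for ch in node.children:
                q = _bn_draw(rng, base, ch.drift) if ch.drift > 0 else base.copy()
                if ch.pop is not None:
                    for r in regions:
                        if ch.pop in r.pops:
                            q[r.start : r.stop] = _bn_draw(
                                rng, base[r.start : r.stop], r.c_sel
                            )
                    pop_freqs[pop_order[ch.pop], offset : offset + m] = q
                else:
                    walk(ch, q)

        root = config.tree()
        base = _bn_draw(rng, pi, root.drift) if root.drift > 0 else pi
        walk(root, base)
        for r in sorted(regions, key=lambda r: r.start):
            planted.append((chrom.name, int(pos[r.start]), int(pos[r.stop - 1])))
        offset += m

    positions = pd.DataFrame({"chrom": chroms_col, "pos": pos_col})
    return TruthSet(
        pop_freqs=pop_freqs,
        ancestral_freqs=anc,
        positions=positions,
        planted_intervals=planted,
        pairwise_target_fst=pairwise_target_fst(config),
    )


def simulate_genotypes(truth: TruthSet, config: SimulationConfig) -> GenotypeMatrix:
    """Sample diploid genotypes Binomial(2, p) with i.i.d. missingness."""
    if truth.pop_freqs.shape != (config.n_pops, config.n_snps):
        raise ConfigurationError("truth does not match config dimensions")
    ss = np.random.SeedSequence(config.seed)
    _, geno_stream = ss.spawn(2)
    rng = np.random.default_rng(geno_stream)

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    for j, (name, size) in enumerate(zip(config.pop_names, config.pop_sizes)):
        g = rng.binomial(2, truth.pop_freqs[j], size=(size, config.n_snps)).astype(np.int8)
        blocks.append(g)
        ids.extend(f"{name}_{k + 1:03d}" for k in range(size))
        labels.extend([name] * size)
    dosages = np.concatenate(blocks, axis=0)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    variants = truth.positions.copy()
    variants["ref"] = "A"
    variants["alt"] = "C"
    samples = pd.DataFrame({"id": ids, "population": labels})
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthSet]:
    truth = simulate_frequencies(config)
    return simulate_genotypes(truth, config), truth


def write_fixture(
    panel: GenotypeMatrix, prefix, truth: TruthSet | None = None
) -> dict[str, Path]:
    """Write VCF + sample map (+ truth-region BED), returning the paths.

    The BED uses 0-based half-open coordinates; the VCF round-trips losslessly
    through :func:`fstscan.genio.read_vcf`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": prefix.with_suffix(".vcf"),
        "sample_map": prefix.parent / (prefix.name + ".samples.tsv"),
    }
    write_vcf(panel, paths["vcf"])
    write_sample_map(panel, paths["sample_map"])
    if truth is not None:
        bed = prefix.parent / (prefix.name + ".truth_regions.bed")
        with open(bed, "w") as fh:
            for chrom, start, end in truth.planted_intervals:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")
        paths["truth_bed"] = bed
    return paths


# ---------------------------------------------------------------------------
# Ready-made study configurations


def two_pop_config(
    c: float,
    n1: int = 25,
    n2: int = 17,
    n_snps: int = 50_000,
    seed: int = 0,
    missing_rate: float = 0.0,
    planted_regions: tuple[PlantedRegion, ...] = (),
    pop_names: tuple[str, str] = ("P1", "P2"),
    drift: tuple[float, float] | None = None,
) -> SimulationConfig:
    """Two populations at symmetric drift ``c`` on one chromosome."""
    return SimulationConfig(
        pop_names=pop_names,
        pop_sizes=(n1, n2),
        drift=drift or (c, c),
        chromosomes=(Chromosome("1", n_snps, max(10 * n_snps, 1_000_000)),),
        planted_regions=planted_regions,
        missing_rate=missing_rate,
        seed=seed,
    )


#: Branch drifts of the default breed panel, calibrated so the weighted
#: Weir-Cockerham estimates land near 0.09 (DT-WZS) and 0.17 (DT-WC, WC-WZS).
THREE_BREED_TREE = DriftNode(
    children=(
        DriftNode(
            drift=0.05,
            children=(DriftNode(0.09, pop="DT"), DriftNode(0.09, pop="WZS")),
        ),
        DriftNode(0.205, pop="WC"),
        DriftNode(0.5, pop="OUT"),
    )
)


def three_breed_config(
    n_snps_per_chrom: int = 1500,
    n_chromosomes: int = 18,
    planted: bool = True,
    region_len: int = 50,
    c_sel: float = 0.6,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> SimulationConfig:
    """Default study panel: three breeds (DT 25, WZS 17, WC 23) plus a
    six-sample diverged outgroup on 18 autosomes.

    With ``planted=True``, six 50-SNP windows (two per breed, alternating
    chromosomes) are simulated under elevated drift ``c_sel`` to mimic
    divergent selection.
    """
    chroms = tuple(
        Chromosome(str(i), n_snps_per_chrom, 60_000_000) for i in range(1, n_chromosomes + 1)
    )
    regions: tuple[PlantedRegion, ...] = ()
    if planted:
        if n_snps_per_chrom < 2 * region_len:
            raise ConfigurationError("chromosomes too short for planted regions")
        mid = n_snps_per_chrom // 2
        assignments = [("1", "DT"), ("3", "WZS"), ("5", "WC"), ("7", "DT"), ("9", "WZS"), ("11", "WC")]
        regions = tuple(
            PlantedRegion(chrom, mid, mid + region_len, c_sel, (pop,))
            for chrom, pop in assignments
            if int(chrom) <= n_chromosomes
        )
    return SimulationConfig(
        pop_names=("DT", "WZS", "WC", "OUT"),
        pop_sizes=(25, 17, 23, 6),
        drift=THREE_BREED_TREE,
        chromosomes=chroms,
        planted_regions=regions,
        missing_rate=missing_rate,
        seed=seed,
    )
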