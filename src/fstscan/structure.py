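"""Population structure: IBS distances, neighbor-joining, MDS, pairwise FST.

Individual-level relationships are summarised by identity-by-state allele
sharing: for a sample pair, ``Dst = (IBS2 + 0.5 * IBS1) / N`` over the N sites
called in both individuals, and the genetic distance is ``1 - Dst``. The
distance matrix feeds a neighbor-joining tree (Saitou-Nei, via scikit-bio) and
classical multidimensional scaling (the cmdscale double-centering solution).
Population-level differentiation uses the Weir & Cockerham (1984) variance
components a/b/c with the weighted (ratio-of-sums) estimator
``theta = sum(a) / sum(a + b + c)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from sklearn.base import BaseEstimator, TransformerMixin

from .genio import MISSING, GenotypeMatrix


class UndefinedDistanceError(ValueError):
    """No jointly called site between a pair of samples."""


@dataclass
class MdsResult:
    """Classical MDS embedding: samples x k coordinates and the (non-increasing)
    eigenvalues of the double-centered matrix that produced them."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"C{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "id", self.labels)
        return df


# ---------------------------------------------------------------------------
# IBS distances


def ibs_pair(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Allele-sharing proportion and distance for one sample pair.

    Over sites where both dosage vectors are non-missing: IBS2 counts identical
    dosages, IBS1 counts dosages differing by one allele, and
    ``Dst = (IBS2 + 0.5*IBS1) / N``. Returns ``(Dst, 1 - Dst)``.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    both = (g1 != MISSING) & (g2 != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedDistanceError("no site called in both samples")
    diff = np.abs(g1[both].astype(np.int16) - g2[both].astype(np.int16))
    ibs2 = int((diff == 0).sum())
    ibs1 = int((diff == 1).sum())
    dst = (ibs2 + 0.5 * ibs1) / n
    return dst, 1.0 - dst


def distance_matrix(panel: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs 1-Dst matrix (symmetric, zero diagonal) as a labelled
    :class:`skbio.DistanceMatrix`."""
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    g = panel.dosages.astype(np.int16)
    called = g != MISSING
    n = panel.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        diff = np.abs(g[i] - g[i + 1 :])
        npair = both.sum(axis=1)
        if (npair == 0).any():
            raise UndefinedDistanceError("a sample pair shares no called site")
        ibs2 = ((diff == 0) & both).sum(axis=1)
        ibs1 = ((diff == 1) & both).sum(axis=1)
        d = 1.0 - (ibs2 + 0.5 * ibs1) / npair
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return DistanceMatrix(out, ids=list(panel.samples["id"]))


# ---------------------------------------------------------------------------
# Trees and ordination


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance
    matrix. Negative branch lengths are kept as computed unless
    ``clamp_negative`` is set."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor-joining needs at least three taxa")
    return nj(dm, neg_as_zero=clamp_negative)


def classical_mds(dm: DistanceMatrix | np.ndarray, k: int = 2) -> MdsResult:
    """Classical (metric) MDS of a distance matrix.

    Double-centers the squared distances, ``B = -0.5 * J D2 J``, and embeds on
    the top-k positive eigenvalues; coordinates are eigenvectors scaled by the
    square roots of their eigenvalues. If fewer than k positive eigenvalues
    exist the embedding is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        labels = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12 * max(vals[0], 1.0)
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating embedding to {k_eff}",
            stacklevel=2,
        )
    if k_eff == 0:
        return MdsResult(np.zeros((n, k)), np.zeros(k), labels)
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    return MdsResult(coords, vals[:k_eff], labels)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST


def wc_fst_components(
    panel: GenotypeMatrix, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-SNP Weir & Cockerham (1984) variance components for two populations.

    Returns a DataFrame with columns a, b, c and a boolean ``defined`` flag.
    A SNP is undefined (excluded from the weighted sum) if either population
    has no called genotype, if fewer than two genotypes are called overall in
    a population pair making ``n_bar <= 1``, or if the SNP is monomorphic
    across both populations.
    """
    ga = panel.dosages[panel.pop_indices(pop_a)]
    gb = panel.dosages[panel.pop_indices(pop_b)]
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValueError("both populations need >= 2 samples")

    def _summarise(g: np.ndarray):
        called = g != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, (g == 1).sum(axis=0) / n, np.nan)
        return n, p, h

    n1, p1, h1 = _summarise(ga)
    n2, p2, h2 = _summarise(gb)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    defined = (
        (n1 > 0)
        & (n2 > 0)
        & (nbar > 1)
        & (nc > 0)
        & np.isfinite(pbar)
        & (pbar > 0)
        & (pbar < 1)
    )
    out = pd.DataFrame({"a": a, "b": b, "c": c, "defined": defined})
    out.loc[~defined, ["a", "b", "c"]] = np.nan
    return out


def wc_weighted_fst(
    panel: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[float, pd.DataFrame]:
    """Weighted (ratio-of-sums) Weir-Cockerham theta over all defined SNPs."""
    comp = wc_fst_components(panel, pop_a, pop_b)
    d = comp[comp["defined"]]
    denom = (d["a"] + d["b"] + d["c"]).sum()
    if denom == 0:
        return float("nan"), comp
    return float(d["a"].sum() / denom), comp


# ---------------------------------------------------------------------------
# Estimator wrappers


class IBSDistance(BaseEstimator, TransformerMixin):
    """Transformer computing the all-pairs 1-Dst IBS distance matrix."""

    def fit(self, X: GenotypeMatrix, y=None):
        return self

    def transform(self, X: GenotypeMatrix) -> DistanceMatrix:
        return distance_matrix(X)


class NeighborJoining(BaseEstimator):
    """Neighbor-joining tree builder.

    Attributes
    ----------
    tree_ : skbio.TreeNode
    newick_ : str
    """

    def __init__(self, clamp_negative: bool = False):
        self.clamp_negative = clamp_negative

    def fit(self, X: DistanceMatrix, y=None):
        self.tree_ = nj_tree(X, clamp_negative=self.clamp_negative)
        self.newick_ = str(self.tree_).strip()
        return self


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical multidimensional scaling (cmdscale) on a distance matrix.

    Attributes
    ----------
    eigenvalues_ : ndarray, non-increasing, length <= n_components
    embedding_ : ndarray of shape (n_samples, n_components)
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        res = classical_mds(X, k=self.n_components)
        self.result_ = res
        self.embedding_ = res.coordinates
        self.eigenvalues_ = res.eigenvalues
        return self

    def transform(self, X) -> np.ndarray:
        return self.fit(X).embedding_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


class PairwiseFst(BaseEstimator):
    """Weighted Weir-Cockerham FST for a list of population pairs.

    Attributes
    ----------
    thetas_ : dict[(pop_a, pop_b), float]
    components_ : dict[(pop_a, pop_b), DataFrame]
    """

    def __init__(self, pairs: list[tuple[str, str]] | None = None):
        self.pairs = pairs

    def fit(self, X: GenotypeMatrix, y=None):
        pops = X.populations
        pairs = self.pairs or [
            (a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]
        ]
        self.thetas_ = {}
        self.components_ = {}
        for a, b in pairs:
            theta, comp = wc_weighted_fst(X, a, b)
            self.thetas_[(a, b)] = theta
            self.components_[(a, b)] = comp
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pop_a": a, "pop_b": b, "weighted_fst": t}
            for (a, b), t in self.thetas_.items()
        ]
        return pd.DataFrame(rows)
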