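"""Per-SNP statistics, two-tier classification and region detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_panel
from oracles import brute_force_regions, fisher_enum
from fstscan.dsrscan import (
    EXTREME,
    NONSIG,
    SIG,
    DSRScanner,
    ScanConfig,
    bonferroni_adjust,
    classify_snps,
    detect_dsrs,
    fisher_two_sided,
    fisher_two_sided_batch,
    pop_allele_counts,
    run_pair_scan,
    snp_fst,
)
from fstscan.genio import MISSING
from fstscan.simdata import PlantedRegion, simulate_panel, two_pop_config

# ---------------------------------------------------------------------------
# Allele counts


def test_pop_allele_counts_direct_tallies():
    dosages = np.array([[0], [1], [2], [MISSING], [2], [2]])
    panel = make_panel(dosages, populations=["A"] * 3 + ["B"] * 3)
    counts = pop_allele_counts(panel, ("A", "B"))
    assert counts["A"][0][0] == 3 and counts["A"][1][0] == 3  # (0,1,2) -> ref 3, alt 3
    assert counts["B"][0][0] == 0 and counts["B"][1][0] == 4  # missing + two hom-alt


def test_pop_allele_counts_all_missing_population():
    dosages = np.array([[MISSING], [MISSING], [0], [1]])
    panel = make_panel(dosages, populations=["A", "A", "B", "B"])
    counts = pop_allele_counts(panel, ("A", "B"))
    assert counts["A"][0][0] == 0 and counts["A"][1][0] == 0


# ---------------------------------------------------------------------------
# Fisher's exact test


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[10, 0], [0, 10]], 2 / 184756),
        ([[5, 5], [5, 5]], 1.0),
        ([[0, 0], [3, 4]], 1.0),  # zero margin convention
    ],
)
def test_fisher_two_sided_known_values(table, expected):
    assert fisher_two_sided(table) == pytest.approx(expected, rel=1e-9)


def test_fisher_two_sided_matches_enumeration_oracle():
    assert fisher_two_sided([[3, 7], [7, 3]]) == pytest.approx(
        float(fisher_enum(3, 7, 7, 3)), rel=1e-10
    )


def test_fisher_batch_matches_scalar_on_random_tables():
    rng = np.random.default_rng(0)
    t = rng.integers(0, 80, (400, 4))
    batch = fisher_two_sided_batch(t[:, 0], t[:, 1], t[:, 2], t[:, 3])
    scalar = np.array([fisher_two_sided([[a, b], [c, d]]) for a, b, c, d in t])
    assert np.abs(batch - scalar).max() < 1e-10


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_two_sided([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# Bonferroni and per-SNP FST


def test_bonferroni_adjust():
    assert bonferroni_adjust(0.001, 100) == pytest.approx(0.1)
    assert bonferroni_adjust(0.5, 10) == 1.0
    assert bonferroni_adjust(1e-8, 13_614_302) == pytest.approx(0.13614302)
    assert np.allclose(bonferroni_adjust(np.array([0.001, 0.5]), 100), [0.1, 1.0])


@pytest.mark.parametrize(
    "p1,p2,expected",
    [
        (0.3, 0.3, 0.0),
        (1.0, 0.0, 1.0),
        (0.8, 0.2, 0.36),  # Var = 0.09, pbar(1-pbar) = 0.25
    ],
)
def test_snp_fst_formula(p1, p2, expected):
    assert snp_fst(p1, p2) == pytest.approx(expected, abs=1e-12)


def test_snp_fst_undefined_at_pooled_fixation():
    assert np.isnan(snp_fst(0.0, 0.0))
    assert np.isnan(snp_fst(1.0, 1.0))
    arr = snp_fst(np.array([0.0, 0.5]), np.array([0.0, 0.5]))
    assert np.isnan(arr[0]) and arr[1] == 0.0


# ---------------------------------------------------------------------------
# Classification


def _stats_frame(fst, p_bonf, chrom=None, pos=None):
    n = len(fst)
    return pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * n,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 10,
            "fst": fst,
            "p_bonf": p_bonf,
        }
    )


def test_classify_top_ranks_by_sorting_oracle():
    rng = np.random.default_rng(1)
    m = 20_000
    fst = rng.uniform(0, 1, m)
    stats = classify_snps(_stats_frame(fst, np.zeros(m)), ScanConfig())
    # top ceil(1e-4 * m) = 2 by sorted order are extreme; top 100 significant
    order = np.argsort(fst)[::-1]
    labels = stats["label"].to_numpy()
    assert set(labels[order[:2]]) == {EXTREME}
    assert (labels[order[2:100]] == SIG).all()
    assert (labels[order[100:]] == NONSIG).all()
    assert stats.attrs["threshold_extreme"] == pytest.approx(np.sort(fst)[-2])


def test_classify_ties_at_threshold_included():
    fst = np.array([0.9, 0.9, 0.9, 0.5] + [0.1] * 96)
    cfg = ScanConfig(q_extreme=0.01, q_sig=0.03)
    stats = classify_snps(_stats_frame(fst, np.zeros(100)), cfg)
    labels = stats["label"].to_numpy()
    assert (labels[:3] == EXTREME).all()  # all tied at the cut value


def test_classify_corrected_p_gate_dominates():
    fst = np.linspace(0, 1, 50)
    stats = classify_snps(_stats_frame(fst, np.ones(50)), ScanConfig())
    assert (stats["label"] == NONSIG).all()


def test_classify_undefined_fst_is_nonsignificant():
    fst = np.array([np.nan, 0.99, 0.5])
    stats = classify_snps(
        _stats_frame(fst, np.zeros(3)), ScanConfig(q_extreme=0.3, q_sig=0.6)
    )
    assert stats["label"][0] == NONSIG


def test_label_monotonicity_in_alpha_and_qsig():
    rng = np.random.default_rng(4)
    fst = rng.uniform(0, 1, 500)
    p = rng.uniform(0, 0.2, 500)
    base = ScanConfig(q_extreme=0.002, q_sig=0.02, alpha=0.05)
    wider = ScanConfig(q_extreme=0.002, q_sig=0.08, alpha=0.20)
    s1 = classify_snps(_stats_frame(fst, p), base)["label"] != NONSIG
    s2 = classify_snps(_stats_frame(fst, p), wider)["label"] != NONSIG
    assert (s2 | ~s1).all()  # significant set only grows


def test_every_extreme_snp_satisfies_significant_tier():
    rng = np.random.default_rng(5)
    fst = rng.uniform(0, 1, 2000)
    p = rng.uniform(0, 0.1, 2000)
    stats = classify_snps(_stats_frame(fst, p), ScanConfig(q_extreme=0.005, q_sig=0.05))
    ext = stats["label"] == EXTREME
    t_sig = stats.attrs["threshold_significant"]
    assert (stats.loc[ext, "fst"] >= t_sig).all()
    assert (stats.loc[ext, "p_bonf"] < 0.05).all()


# ---------------------------------------------------------------------------
# Region detection


def _detect_from_string(s, cfg=None):
    labels = {"E": EXTREME, "S": SIG, "N": NONSIG}
    stats = pd.DataFrame(
        {
            "chrom": ["1"] * len(s),
            "pos": np.arange(1, len(s) + 1),
            "label": [labels[ch] for ch in s],
        }
    )
    return detect_dsrs(stats, cfg or ScanConfig())


def test_detect_spec_walkthrough():
    regions = _detect_from_string("NSESNNSS")
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (2, 4)
    assert regions[0].n_extreme == 1 and regions[0].n_significant == 3


def test_detect_all_nonsignificant_yields_nothing():
    assert _detect_from_string("N" * 50) == []


def test_detect_min_run_boundary():
    assert _detect_from_string("N N S S S S S N N".replace(" ", "")) == []  # 5 S
    regions = _detect_from_string("NNSSSSSSNN")  # 6 S
    assert len(regions) == 1 and regions[0].n_significant == 6


def test_detect_lone_extreme_forms_single_snp_region():
    (r,) = _detect_from_string("NNNENNN")
    assert r.start == r.end == 4
    assert r.n_snps_spanned == 1 and r.n_extreme == 1


@given(
    st.text(alphabet="ESN", min_size=1, max_size=120),
    st.integers(1, 3),
    st.integers(1, 8),
)
@settings(max_examples=200)
def test_detect_matches_brute_force_oracle(s, break_len, min_run):
    cfg = ScanConfig(break_len=break_len, min_run=min_run)
    regions = _detect_from_string(s, cfg)
    got = [(r.start - 1, r.end - 1) for r in regions]  # back to 0-based indices
    assert got == brute_force_regions(s, break_len=break_len, min_run=min_run)


def test_detect_respects_chromosome_boundaries():
    stats = pd.DataFrame(
        {
            "chrom": ["1"] * 3 + ["2"] * 3,
            "pos": [1, 2, 3, 1, 2, 3],
            "label": [NONSIG, SIG, EXTREME, EXTREME, SIG, NONSIG],
        }
    )
    regions = detect_dsrs(stats, ScanConfig())
    assert [(r.chrom, r.start, r.end) for r in regions] == [("1", 2, 3), ("2", 1, 2)]
    assert [r.id for r in regions] == [1, 2]


def test_reported_regions_satisfy_membership_invariant():
    rng = np.random.default_rng(6)
    s = "".join(rng.choice(list("ESNNN"), 500))
    for r in _detect_from_string(s):
        assert r.n_extreme >= 1 or r.n_significant >= ScanConfig().min_run


# ---------------------------------------------------------------------------
# Full pair scan


def test_run_pair_scan_recovers_planted_region():
    region = PlantedRegion("1", 2400, 2450, c_sel=0.6, pops=("P1",))
    cfg = two_pop_config(c=0.05, n_snps=5000, seed=2, planted_regions=(region,))
    panel, truth = simulate_panel(cfg)
    stats, regions = run_pair_scan(panel, "P1", "P2")
    chrom, start, end = truth.planted_intervals[0]
    assert any(
        r.chrom == chrom and r.start <= end and start <= r.end for r in regions
    )


def test_run_pair_scan_identical_populations_yield_no_regions():
    rng = np.random.default_rng(7)
    block = rng.integers(0, 3, (10, 800))
    panel = make_panel(
        np.vstack([block, block]), populations=["A"] * 10 + ["B"] * 10
    )
    stats, regions = run_pair_scan(panel, "A", "B")
    assert regions == []
    assert (stats["fst"].dropna() == 0).all()


def test_run_pair_scan_deterministic_and_scanner_wrapper():
    cfg = two_pop_config(c=0.1, n_snps=1500, seed=8, missing_rate=0.02)
    panel, _ = simulate_panel(cfg)
    s1, r1 = run_pair_scan(panel, "P1", "P2")
    s2, r2 = run_pair_scan(panel, "P1", "P2")
    pd.testing.assert_frame_equal(s1, s2)
    assert [(r.start, r.end) for r in r1] == [(r.start, r.end) for r in r2]
    scanner = DSRScanner(pop_a="P1", pop_b="P2").fit(panel)
    pd.testing.assert_frame_equal(scanner.snp_stats_, s1)
    assert scanner.thresholds_["significant"] <= scanner.thresholds_["extreme"]


def test_scanconfig_validation():
    with pytest.raises(ValueError):
        ScanConfig(q_extreme=0.01, q_sig=0.005)
    with pytest.raises(ValueError):
        ScanConfig(alpha=0.0)
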