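# Methods

## Scope and data model

`fstscan` operates strictly downstream of variant calling: its input is a
multi-sample VCF (GT field) of biallelic-candidate SNPs plus a two-column
sample→population TSV. The in-memory container is a samples × SNPs matrix of
alternate-allele dosages (0/1/2, −1 missing) with variant and sample metadata
as DataFrames. Coordinates are 1-based inclusive throughout (VCF convention);
BED exports are 0-based half-open. Half-called genotypes (`./1`) are treated
as missing; multi-allelic records are never split — they are carried through
parsing so the biallelic QC stage can remove and count them.

## Quality control

Stages run in a fixed order — (1) multi-allelic, (2) non-autosomal
(pig autosomes "1".."18" by default), (3) missing rate, (4) MAF, (5) HWE —
and each SNP is charged to the first stage that rejects it, giving a
conservation identity (input = final + Σ removed) that the ledger asserts.
Boundary conventions: missing rate must *exceed* 0.10 to remove; MAF exactly
at 0.10 is kept. MAF is computed on non-missing allele counts jointly across
all samples, because the filters are meant for a merged multi-breed panel.
The HWE exact test (Levene/Haldane conditional distribution of heterozygote
counts given the allele count) is applied within each population separately
and a SNP is removed if it fails in any one of them. The conditional weights
`n!/(n_AA! n_Aa! n_aa!)·2^n_Aa` are computed as exact integers and the
two-sided p (sum of outcomes no more probable than the observed one) as an
exact rational before conversion to float, so there are no floating-point
tie artifacts; per-(n, allele count) distributions are cached, making the
per-SNP cost a table lookup.

## Structure statistics

IBS sharing counts only sites called in *both* samples of a pair; with
missing data the shared-allele counts are otherwise undefined. This
both-called convention matches the behavior of the standard `--distance
1-ibs` implementation. Neighbor-joining is delegated to scikit-bio's
Saitou–Nei implementation; negative branch lengths are retained by default
(an optional clamp flag sets them to zero) so that additive matrices are
recovered exactly — the suite verifies exact recovery on random 10-taxon
additive trees. Classical MDS is the cmdscale algorithm (double-centering +
`eigh`); since scikit-learn's MDS is the SMACOF iteration, not the classical
solution, the 20-line eigendecomposition is implemented directly. MDS
coordinates are defined only up to sign/rotation, so all tests compare
reconstructed distances, never raw coordinates.

The Weir & Cockerham (1984) variance components a/b/c are computed per SNP
with per-SNP sample sizes (missingness-aware) and observed heterozygosities,
and combined as the weighted ratio-of-sums θ̂ = Σa/Σ(a+b+c) — not the
average of per-SNP ratios — because the weighted form is the standard
genome-wide summary. SNPs monomorphic across the pair, or with an
uncalled population, are excluded from both sums. A hand-derived
exact-fraction evaluation of the 1984 formulas on a 4+4-sample table
(a=1/32, b=1/16, c=3/16) anchors the implementation in the tests.

## Selection scan

Per-SNP differentiation uses the moment estimator
`F_ST = Var(p₁,p₂)/(p̄(1−p̄))` with the population-count denominator (r=2),
the desk-scale form of the Nicholson drift model: it is 0 at equal
frequencies, 1 at a fixed difference, and undefined (hence nonsignificant)
when the pooled frequency is 0 or 1. The allelic association test is
Fisher's exact test on the 2×2 ref/alt allele-count table; two-sided by the
point-probability rule with a 1+1e−7 relative tolerance. The scalar path
delegates to `scipy.stats.fisher_exact`; genome scans use an in-package
vectorized enumeration of the hypergeometric support (log-space via
`gammaln`), which agrees with the scalar path to <1e−10 and is ~100× faster
over 10⁵ tables. Bonferroni m is the number of SNPs entering the pair scan
after QC, not a genome-wide constant.

Tier thresholds are rank-based over all defined-F<sub>ST</sub> SNPs of the
scan: the tier-q cut is the ⌈q·m⌉-th largest value, ties at the cut
included, gated by corrected p < α. When m < 1/q the threshold degenerates
to the maximum and a warning is emitted (expected on small panels).

Region detection is implemented as a segment decomposition: each
chromosome's marker sequence splits at every run of `break_len` (default 2)
consecutive nonsignificant SNPs; a segment trimmed to its outermost
significant-or-extreme SNPs is reported iff it contains an extreme seed or
at least `min_run` significant SNPs. This is provably the union of the two
stated rules — bidirectional extension from every extreme seed, plus the
seedless uninterrupted-run rule — with overlapping regions merged; the test
suite checks identity against a literal brute-force implementation of the
two rules on random label sequences. "More than five significant SNPs" is
read as min_run = 6; the parameter is configurable because the phrasing
admits ≥5. A lone extreme SNP forms a valid 1-SNP region. Extension operates
in marker order, not bp distance, and stops at chromosome ends.

Gene mapping assigns a gene to a region iff their intervals share ≥1 bp
(both 1-based inclusive), strand ignored — a gene partially covered by a
region counts. Interval queries use an interval tree; tests compare against
a quadratic brute-force check.

## Synthetic panels

Population allele frequencies follow the Balding–Nichols parameterization:
`p ~ Beta(π(1−c)/c, (1−π)(1−c)/c)` with mean π and variance c·π(1−π) — the
Beta analogue of Nicholson's truncated-Gaussian model, chosen because it
matches the variance structure the per-SNP estimator assumes while staying
in [0,1]. Ancestral frequencies are Uniform(0.1, 0.9) so the MAF filter does
not annihilate the panel; Beta draws are clamped to [1e−9, 1−1e−9] to keep
count tables well-defined. Genotypes are Binomial(2, p) within populations
(HWE within breeds holds by construction, so the HWE filter removes only
sampling-noise outliers), with i.i.d. missingness (default 2% in the breed
panel). All randomness flows from one seed through per-chromosome
`SeedSequence` sub-streams, making every output byte-reproducible.

The default study panel mirrors the three-breed design: DT (n=25), WZS
(n=17), WC (n=23) and a six-sample diverged outgroup on 18 autosomes.
Populations are related by a two-level drift tree — outgroup (c=0.5) and WC
(c=0.205) branch from the root, DT and WZS (c=0.09 each) from an internal
node at c=0.05. The branch values were calibrated empirically (50k-SNP
two-population runs) so the weighted Weir–Cockerham estimates land at
≈0.09 for the close pair and ≈0.17 for both distant pairs; at these depths
θ̂ tracks the leaf drift coefficient to ~0.003. Planted selected windows
re-draw the leaf-branch frequency of designated populations with an elevated
drift c_sel (default 0.6 over 50 SNPs, two windows per breed).

**What the simulator does not emulate.** Sites are independent: there is no
linkage disequilibrium, recombination map, allele-frequency spectrum from a
mutation model, or genotype-calling error structure. Two consequences
matter for interpreting results. First, because the extreme/significant
tiers are genome-wide quantiles, the number of possible seed SNPs scales
with panel size — a 27,000-SNP panel admits only ⌈0.0001·m⌉ ≈ 3 extreme
SNPs per scan, so with six planted windows most windows cannot seed a
region and the reported planted-window recovery on the default panel is
intentionally partial (~25–50%). Second, without LD the SNPs inside a
selected window are only individually (not jointly) elevated, so the
run-based extension rules recover less of each window than they would on
real, locally correlated data. The dedicated recovery benchmark in the test
suite therefore uses the single-window configuration (5,000 SNPs, one
50-SNP window, c=0.05 background, c_sel=0.6), where ≥80% of panels yield an
overlapping region with ≤1 false region per panel on average.

## Problem sizes and numerical choices

Default/validation sizes were chosen as the smallest that make the
statistics stable: 50,000 SNPs for FST calibration (MC error ≪ the ±0.02
band), 27,000 SNPs (1,500 × 18 autosomes) for the end-to-end panel, 5,000
SNPs × 20 replicates for sweep recovery. The headline counts of the original
resequencing study (13.6M post-QC SNPs, thousands of DSRs per pair) arise
from whole-genome variant calling upstream of this package's scope and are
not desk-scale reproducible; the package reproduces the *pattern* —
differentiation 0.09/0.17/0.17, four-cluster tree, two-tier scan mechanics —
not those counts.

Degenerate inputs: an all-missing SNP passes HWE (undefined → pass), is
skipped by FST (excluded from both sums), and gets Fisher p=1 (zero
margin). A sample pair with no jointly called site raises an explicit
undefined-distance error. Empty post-QC panels warn rather than raise.

## Design decisions that were genuinely open

- The removal ordering of the QC ledger follows the narrative order
  (multi-allelic → sex chromosomes → missing → MAF → HWE); tool invocation
  order is not otherwise documented.
- FST rank thresholds are computed over all defined-FST SNPs before the
  corrected-p gate is applied (the gate then filters labels, not ranks).
- Region merging is overlap-only; adjacent but disjoint regions keep
  separate ids.
- The CLI is flag-based (`simulate`, `qc`, `structure`, `scan`, `annotate`,
  `all`) with every threshold surfaced and defaulting to the standard values
  (0.1 missing, 0.1 MAF, 0.01 HWE, 0.0001/0.005 quantiles, 0.05 alpha).
- ADMIXTURE-style model-based clustering is deliberately not reimplemented;
  structure claims rest on the tree, MDS and FST, which this package
  computes itself.
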