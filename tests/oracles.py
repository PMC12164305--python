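"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exact rational
arithmetic, exhaustive enumeration, literal rule-following) and share no code
with the package implementation.
"""

from fractions import Fraction
from math import comb

#: Same relative tolerance the two-sided point-probability rule states, as an
#: exact rational so the oracle has no float round-off of its own.
FISHER_RELTOL = Fraction(10_000_001, 10_000_000)


def fisher_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p of [[a,b],[c,d]] by full hypergeometric enumeration."""
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or k == n:
        return Fraction(1)
    total = comb(n, k)
    probs = {}
    for x in range(max(0, k - n2), min(k, n1) + 1):
        probs[x] = Fraction(comb(n1, x) * comb(n2, k - x), total)
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * FISHER_RELTOL)


def hwe_enum(n_aa_hom: int, n_het: int, n_bb_hom: int) -> Fraction:
    """Exact HWE p by enumerating the conditional heterozygote distribution."""
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        return Fraction(1)
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n - n_a
    probs = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        a = (n_a - h) // 2
        bb = (n_b - h) // 2
        # multinomial coefficient times 2**h, all exact
        w = Fraction(
            comb(n, a) * comb(n - a, h) * 2**h
        )
        probs[h] = w
    total = sum(probs.values())
    obs = probs[n_het]
    return sum(w for w in probs.values() if w <= obs) / total


def brute_force_regions(labels, break_len: int = 2, min_run: int = 6):
    """Literal seed-and-extend + seedless-run region finder on a label string.

    ``labels`` is a sequence over {"E", "S", "N"}. Returns a sorted list of
    merged (start_index, end_index) inclusive intervals, trimmed to the
    outermost non-N SNPs.
    """
    n = len(labels)

    def has_break(i, j):
        run = 0
        for k in range(i, j + 1):
            run = run + 1 if labels[k] == "N" else 0
            if run >= break_len:
                return True
        return False

    raw = set()
    # rule (a): extend from every extreme seed in both directions
    for s in range(n):
        if labels[s] != "E":
            continue
        i = s
        while i > 0 and not has_break(i - 1, s):
            i -= 1
        j = s
        while j < n - 1 and not has_break(s, j + 1):
            j += 1
        while labels[i] == "N":
            i += 1
        while labels[j] == "N":
            j -= 1
        raw.add((i, j))
    # rule (b): any maximal break-free stretch with >= min_run significant SNPs
    for i in range(n):
        if has_break(i, i):
            continue
        j = i
        while j < n - 1 and not has_break(i, j + 1):
            j += 1
        if i > 0 and not has_break(i - 1, j):
            continue  # not maximal
        lo, hi = i, j
        while lo <= hi and labels[lo] == "N":
            lo += 1
        while hi >= lo and labels[hi] == "N":
            hi -= 1
        if lo > hi:
            continue
        n_sig = sum(1 for k in range(lo, hi + 1) if labels[k] in "ES")
        if n_sig >= min_run:
            raw.add((lo, hi))
    # merge overlapping intervals
    merged = []
    for s, e in sorted(raw):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def brute_force_overlaps(regions, genes):
    """Quadratic any-bp interval intersection between regions and genes.

    ``regions``: iterable of (rid, chrom, start, end); ``genes``: iterable of
    (gid, chrom, start, end); 1-based inclusive. Returns {rid: sorted gene ids}.
    """
    out = {}
    for rid, rchrom, rstart, rend in regions:
        hits = [
            gid
            for gid, gchrom, gstart, gend in genes
            if gchrom == rchrom and rstart <= gend and gstart <= rend
        ]
        out[rid] = sorted(hits)
    return out
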