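"""Independent reference implementations used only to check the package.

These deliberately use different algorithms and libraries than the
implementation under test: exhaustive enumeration for inverted-repeat
pairs, direct combinatorics for the hypergeometric tail, and Biopython's
PairwiseAligner for alignment identity.
"""

from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": None}


def brute_force_ir_pairs(seq, min_repeat, max_repeat, min_spacer, max_spacer, max_mm):
    """Enumerate all maximal IR pairs by scanning every (i, j, L) triple."""
    n = len(seq)

    def mismatches(i, j, L):
        m = 0
        for t in range(L):
            a, b = seq[i + t], seq[j + L - 1 - t]
            if _COMP[a] is None or _COMP[a] != b:
                m += 1
        return m

    def valid(i, j, L):
        if i < 0 or j + L > n or not (min_repeat <= L <= max_repeat):
            return False
        spacer = j - (i + L)
        if not (min_spacer <= spacer <= max_spacer):
            return False
        return mismatches(i, j, L) <= max_mm

    out = []
    for i in range(n):
        for L in range(min_repeat, max_repeat + 1):
            for j in range(i + L + min_spacer, min(n - L, i + L + max_spacer) + 1):
                if not valid(i, j, L):
                    continue
                # suppress pairs growable by one base on both repeats:
                # inward (spacer shrinks by 2) or outward (spacer kept)
                if valid(i, j - 1, L + 1) or valid(i - 1, j, L + 1):
                    continue
                out.append((i, i + L, j, j + L, L, mismatches(i, j, L)))
    out.sort(key=lambda p: (p[0], -p[4]))
    return out


def hypergeom_upper_tail(k, N, K, n):
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by direct summation."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def alignment_identity(a, b):
    """Global-alignment identity (matches / columns) via Biopython."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    matches = columns = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        columns += a1 - a0
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    # count gap columns
    aligned_a = sum(a1 - a0 for a0, a1 in aln.aligned[0])
    aligned_b = sum(b1 - b0 for b0, b1 in aln.aligned[1])
    gaps = (len(a) - aligned_a) + (len(b) - aligned_b)
    return matches / (columns + gaps)


def welch_from_formula(a, b):
    """Welch t, Satterthwaite df and two-sided p from the textbook formulas."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2**0.5
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p
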