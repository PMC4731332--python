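"""Independent brute-force oracles used to verify the production algorithms.

Each oracle is deliberately naive (exhaustive enumeration or full dynamic
programming without heuristics) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def pairable(a: str, b: str, allow_gu: bool = True) -> bool:
    s = frozenset((a, b))
    ok = s == frozenset("AT") or s == frozenset("GC")
    if allow_gu:
        ok = ok or s == frozenset("GT")
    return ok


def max_pairs_exhaustive(seq: str, min_hairpin: int = 3, allow_gu: bool = True) -> int:
    """Maximum number of nested pairs by exhaustive recursion (no memo)."""

    def rec(i: int, j: int) -> int:
        if j - i <= min_hairpin:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            if pairable(seq[i], seq[k], allow_gu):
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def max_sum_substring(gains: list[float]) -> tuple[float, int, int]:
    """Best (sum, start, end) over all substrings: max sum, then longest,
    then leftmost; computed from the same prefix sums the implementation
    uses so exact float ties are shared."""
    n = len(gains)
    S = [0.0] * (n + 1)
    for i, g in enumerate(gains):
        S[i + 1] = S[i] + g
    best = (0.0, 0, 0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            cand = S[j] - S[i]
            s, bi, bj = best
            if cand > s or (cand == s and s > 0 and (j - i) > (bj - bi)):
                best = (cand, i, j)
    return best


def smith_waterman_gotoh(
    a: str, b: str, match: int = 1, mismatch: int = 4,
    gap_open: int = 6, gap_extend: int = 1,
) -> int:
    """Full local affine-gap alignment score; a k-gap costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0
    for i in range(1, n + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - gap_open - gap_extend, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hi1[j] - gap_open - gap_extend, Fi1[j] - gap_extend)
            diag = Hi1[j - 1] + (match if ai == b[j - 1] else -mismatch)
            h = max(0, diag, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def iupac_scan_naive(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Plus-strand and minus-strand matches by position-by-position checking;
    returns (start, strand) in plus coordinates."""
    m = len(pattern)
    sets = [IUPAC_SETS[p] for p in pattern.upper()]
    out = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + k] in sets[k] for k in range(m)):
            out.append((i, "+"))
        window_rc = "".join(_COMP[c] for c in reversed(seq[i : i + m]))
        if all(window_rc[k] in sets[k] for k in range(m)):
            out.append((i, "-"))
    return sorted(out)


def duplex_helices_naive(s1: str, s2: str, min_len: int = 2, allow_gu: bool = True):
    """All maximal (i, j, L) with s1[i+k] pairing s2[j-1-k], by brute force."""
    n1, n2 = len(s1), len(s2)

    def helix_ok(i, j, L):
        if i < 0 or j - L < 0 or i + L > n1 or j > n2:
            return False
        return all(pairable(s1[i + k], s2[j - 1 - k], allow_gu) for k in range(L))

    out = []
    for i in range(n1):
        for j in range(1, n2 + 1):
            for L in range(min_len, min(n1 - i, j) + 1):
                if not helix_ok(i, j, L):
                    continue
                left_ext = helix_ok(i - 1, j + 1, 1)
                right_ext = helix_ok(i + L, j - L, 1)
                if not left_ext and not right_ext:
                    out.append((i, j, L))
    return sorted(out)
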