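"""Minimal RNA secondary-structure machinery.

Folding potential is assessed by maximum base pairing (Nussinov dynamic
programming) rather than a thermodynamic model: it is parameter-free,
deterministic, and exhaustively verifiable on small sequences. An energy
backend could be substituted behind the same FoldResult contract.

Pairing rules: Watson-Crick (A-U/A-T, G-C) plus, by default, the G-U wobble
pair, since structure-preserving G-C -> G-U substitutions are a hallmark of
the RNA family this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .formats import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_HAIRPIN = 3


def _pair_matrix(allow_gu: bool) -> np.ndarray:
    m = np.zeros((5, 5), dtype=np.bool_)
    pairs = [(0, 3), (2, 1)]  # A-T/U, G-C
    if allow_gu:
        pairs.append((2, 3))  # G-U/T
    for a, b in pairs:
        m[a, b] = m[b, a] = True
    return m


_PAIR_WC = _pair_matrix(allow_gu=False)
_PAIR_GU = _pair_matrix(allow_gu=True)


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """True iff nucleotides a and b can form a base pair (wobble optional)."""
    m = _PAIR_GU if allow_gu else _PAIR_WC
    try:
        return bool(m[_CODE[a.upper()], _CODE[b.upper()]])
    except KeyError:
        return False


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


@dataclass
class FoldResult:
    dotbracket: str
    n_pairs: int
    pairs: list[tuple[int, int]]


@njit(cache=True)
def _nussinov_fill(codes, pair_mat, min_hairpin):  # pragma: no cover - numba
    n = codes.shape[0]
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            # i paired with some k in (i+min_hairpin, j]
            for k in range(i + min_hairpin + 1, j + 1):
                if pair_mat[codes[i], codes[k]]:
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = left + right + 1
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


def nussinov_fold(seq: str, min_hairpin: int = MIN_HAIRPIN, allow_gu: bool = True) -> FoldResult:
    """Maximum base-pairing fold.

    Deterministic traceback, outermost-first: on ties the pair (i, j) is
    preferred over leaving i unpaired, which is preferred over pairing i with
    an interior k (scanned from the outside in).
    """
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    codes = encode(seq)
    pm = _PAIR_GU if allow_gu else _PAIR_WC
    if n <= min_hairpin + 1:
        return FoldResult("." * n, 0, [])
    N = _nussinov_fill(codes, pm, min_hairpin)

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_hairpin or N[i, j] == 0:
            continue
        # prefer closing pair (i, j)
        inner = N[i + 1, j - 1] if j - 1 >= i + 1 else 0
        if pm[codes[i], codes[j]] and inner + 1 == N[i, j]:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if N[i + 1, j] == N[i, j]:
            stack.append((i + 1, j))
            continue
        found = False
        for k in range(j - 1, i + min_hairpin, -1):
            if pm[codes[i], codes[k]]:
                left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1, j]
                if left + right + 1 == N[i, j]:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    found = True
                    break
        if not found:  # defensive: DP and traceback disagree
            raise AssertionError("nussinov traceback failed")

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult("".join(db), int(N[0, n - 1]), pairs)


def pairing_fraction(seq: str, min_hairpin: int = MIN_HAIRPIN, allow_gu: bool = True) -> float:
    """Fraction of bases paired in the maximum-pairing fold: 2*n_pairs/len."""
    if len(seq) < 2:
        raise ValueError("need at least 2 nucleotides")
    return 2.0 * nussinov_fold(seq, min_hairpin, allow_gu).n_pairs / len(seq)


def enumerate_duplex_helices(
    s1: str, s2: str, min_len: int = 2, allow_gu: bool = True
) -> list[tuple[int, int, int]]:
    """All maximal antiparallel helices between two strands.

    A helix (i, j, L) pairs s1[i+k] with s2[j-1-k] for k in [0, L); i.e.
    s1[i:i+L] against s2[j-L:j] read 3'->5'. Maximal means extendable in
    neither direction. Helices lie on anti-diagonals x + y = const of the
    pairability matrix, so each maximal run along a diagonal is one helix.
    """
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        raise ValueError("strands must be non-empty")
    pm = _PAIR_GU if allow_gu else _PAIR_WC
    c1, c2 = encode(s1), encode(s2)
    out: list[tuple[int, int, int]] = []
    for s in range(0, n1 + n2 - 1):  # s = x + y, x on s1, y on s2
        x_lo = max(0, s - (n2 - 1))
        x_hi = min(n1 - 1, s)
        run = 0
        for x in range(x_lo, x_hi + 2):
            ok = x <= x_hi and pm[c1[x], c2[s - x]]
            if ok:
                run += 1
            else:
                if run >= min_len:
                    i = x - run
                    j = s - i + 1  # s2 end (exclusive): pairs s2[j-run:j]
                    out.append((i, j, run))
                run = 0
    out.sort()
    return out
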