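"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: alignment is scored by
exhaustive enumeration of alignment move sequences, AUC by the all-pairs
Mann-Whitney count, the TM mask by a naive window loop.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 10
GAP_EXTEND = 1


def _score_alignment(cols: list[tuple[str, str]]) -> float:
    """Affine-gap score of one explicit alignment; gap of length L costs
    GAP_OPEN + (L-1)*GAP_EXTEND, terminal gaps included."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in cols:
        if x == "-":
            score -= GAP_EXTEND if in_gap_a else GAP_OPEN
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= GAP_EXTEND if in_gap_b else GAP_OPEN
            in_gap_b, in_gap_a = True, False
        else:
            score += _BLOSUM62[x, y]
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a list of columns."""
    if not a and not b:
        yield []
        return
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def brute_force_alignment(a: str, b: str) -> tuple[float, set[float]]:
    """(optimal score, set of identities achievable at the optimal score).

    Identity = identical aligned pairs / alignment columns. Exponential;
    only usable for len <= ~7.
    """
    best_score = None
    identities: set[float] = set()
    for cols in enumerate_alignments(a, b):
        s = _score_alignment(cols)
        if best_score is None or s > best_score + 1e-9:
            best_score = s
            identities = set()
        if abs(s - best_score) <= 1e-9:
            ident = sum(1 for x, y in cols if x == y and x != "-") / len(cols)
            identities.add(ident)
    return best_score, identities


def in_identity_set(value: float, identities: set[float], tol: float = 1e-9) -> bool:
    return any(abs(value - i) <= tol for i in identities)


def mann_whitney_auc(scores, labels) -> float:
    """All-pairs AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_tm_mask(seq: str, window: int = 19, threshold: float = 1.6):
    """Naive sliding-window TM mask (no running sum), Kyte-Doolittle scale."""
    kd = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
          "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
          "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
          "Y": -1.3, "V": 4.2}
    n = len(seq)
    mask = [False] * n
    for start in range(max(0, n - window + 1)):
        win = seq[start : start + window]
        if len(win) == window and sum(kd[aa] for aa in win) / window >= threshold:
            for i in range(start, start + window):
                mask[i] = True
    return mask
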