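"""Pluggable per-residue sequence annotators.

External predictors (transmembrane topology, backbone flexibility, secondary
structure, disorder) enter the feature pipeline only through the small
callable contracts defined here, so any tool that can produce a per-residue
mask or score can be plugged in. A self-contained hydropathy-window
transmembrane annotator is provided as the default; the flexibility /
secondary-structure / disorder slots default to ``None`` (their features are
sentinel-filled and excluded from model selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

TM_WINDOW = 19
TM_THRESHOLD = 1.6


def hydropathy_window_tm_mask(
    seq: str, window: int = TM_WINDOW, threshold: float = TM_THRESHOLD
) -> list[bool]:
    """Per-residue transmembrane mask from a sliding hydropathy window.

    A residue is marked transmembrane if it lies in any window of length
    ``window`` whose mean Kyte-Doolittle hydropathy is >= ``threshold``.
    Overlapping qualifying windows merge into single helices downstream.
    Sequences shorter than the window yield an all-False mask.
    """
    n = len(seq)
    mask = [False] * n
    if n < window:
        return mask
    scores = [KYTE_DOOLITTLE[aa] for aa in seq]
    running = sum(scores[:window])
    cutoff = threshold * window
    for start in range(n - window + 1):
        if start > 0:
            running += scores[start + window - 1] - scores[start - 1]
        if running >= cutoff:
            for i in range(start, start + window):
                mask[i] = True
    return mask


def count_helices(mask: Sequence[bool]) -> int:
    """Number of maximal runs of True in a per-residue mask."""
    count = 0
    prev = False
    for flag in mask:
        if flag and not prev:
            count += 1
        prev = flag
    return count


# Contracts: tm -> per-residue bool mask; flexibility/disorder -> per-residue
# float scores; secondary_structure -> per-residue labels over {H, E, C}.
TMAnnotator = Callable[[str], Sequence[bool]]
ScoreAnnotator = Callable[[str], Sequence[float]]
SSAnnotator = Callable[[str], Sequence[str]]


@dataclass
class AnnotatorSet:
    """The set of per-residue annotators available to the feature extractor."""

    tm: TMAnnotator = field(default=hydropathy_window_tm_mask)
    flexibility: Optional[ScoreAnnotator] = None
    secondary_structure: Optional[SSAnnotator] = None
    disorder: Optional[ScoreAnnotator] = None


DEFAULT_ANNOTATORS = AnnotatorSet()
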