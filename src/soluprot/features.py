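"""The 251-dimensional sequence feature vector and its standardization.

Features fall into eight fixed-order groups:

(i)    single amino-acid content, 20 features;
(ii)   amino-acid dimer content as unordered pairs, 210 features;
(iii)  physicochemical descriptors, 12 features;
(iv)   average backbone flexibility (plugin), 1 feature;
(v)    secondary-structure content (plugin), 3 features;
(vi)   average disorder (plugin), 1 feature;
(vii)  predicted transmembrane-helix content, 3 features;
(viii) maximum global identity to a soluble reference set, 1 feature.

Groups (iv)-(vi) require external per-residue predictors; when no annotator is
plugged in they are filled with a 0.0 sentinel and flagged so they can never
silently enter feature selection. Standardization (zero mean, unit variance,
statistics from the training set only) is provided by :class:`Standardizer`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import annotators as _ann
from .annotators import AnnotatorSet, DEFAULT_ANNOTATORS, count_helices
from .identity import max_identity
from .seqio import STANDARD_AA, ProteinRecord, validate_sequence

# ---------------------------------------------------------------------------
# feature name registry (stable, versioned by FEATURE_SCHEMA_VERSION)

FEATURE_SCHEMA_VERSION = 1

COMPOSITION_NAMES = [f"comp_{aa}" for aa in STANDARD_AA]

DIMER_PAIRS = [
    (a, b) for a, b in itertools.combinations_with_replacement(STANDARD_AA, 2)
]
DIMER_NAMES = [f"dimer_{a}{b}" for a, b in DIMER_PAIRS]

PHYSCHEM_NAMES = [
    "length",
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "aromaticity",
    "aliphatic_index",
    "instability_index",
    "frac_positive_kr",
    "frac_negative_de",
    "net_charge_ph7",
    "abs_charge_per_residue",
    "frac_small_agstc",
]

FLEXIBILITY_NAMES = ["avg_flexibility"]
SS_NAMES = ["ss_helix_frac", "ss_sheet_frac", "ss_coil_frac"]
DISORDER_NAMES = ["avg_disorder"]
TM_NAMES = ["tm_residues_total", "tm_residues_first60", "tm_helix_count"]
IDENTITY_NAMES = ["max_identity_reference"]

GROUP_NAMES = {
    "composition": COMPOSITION_NAMES,
    "dimer": DIMER_NAMES,
    "physchem": PHYSCHEM_NAMES,
    "flexibility": FLEXIBILITY_NAMES,
    "secondary_structure": SS_NAMES,
    "disorder": DISORDER_NAMES,
    "transmembrane": TM_NAMES,
    "max_identity": IDENTITY_NAMES,
}

# groups only computable via an external plugin annotator
PLUGIN_GROUPS = ("flexibility", "secondary_structure", "disorder")


def feature_names() -> list[str]:
    """The full ordered 251-name feature list."""
    names: list[str] = []
    for group in (
        "composition",
        "dimer",
        "physchem",
        "flexibility",
        "secondary_structure",
        "disorder",
        "transmembrane",
        "max_identity",
    ):
        names.extend(GROUP_NAMES[group])
    return names

FEATURE_NAMES = feature_names()
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered feature values for one sequence.

    ``excluded`` lists features that were sentinel-filled because the
    corresponding plugin annotator was absent; they must not enter selection.
    """

    names: tuple[str, ...]
    values: tuple[float, ...]
    excluded: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


# ---------------------------------------------------------------------------
# group (i) and (ii): composition

def aa_composition(seq: str) -> list[float]:
    """Single amino-acid content: count of each residue / length (20 values)."""
    n = len(seq)
    return [seq.count(aa) / n for aa in STANDARD_AA]


def dimer_composition(seq: str) -> list[float]:
    """Unordered amino-acid dimer content (210 values).

    Overlapping dimers are counted, pooling XY with YX into one feature per
    unordered pair; counts are divided by (length - 1). A sequence shorter
    than 2 residues yields the all-zero vector.
    """
    if len(seq) < 2:
        return [0.0] * len(DIMER_PAIRS)
    counts: dict[tuple[str, str], int] = {}
    for x, y in zip(seq, seq[1:]):
        key = (x, y) if x <= y else (y, x)
        counts[key] = counts.get(key, 0) + 1
    denom = len(seq) - 1
    return [counts.get(pair, 0) / denom for pair in DIMER_PAIRS]


# ---------------------------------------------------------------------------
# group (iii): physicochemical descriptors

# EMBOSS pKa values for ionizable groups
PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of the sequence at a given pH."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA["Cterm"] - ph))
    for aa in _POSITIVE:
        k = seq.count(aa)
        if k:
            charge += k / (1.0 + 10 ** (ph - PKA[aa]))
    for aa in _NEGATIVE:
        k = seq.count(aa)
        if k:
            charge -= k / (1.0 + 10 ** (PKA[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pI by bisection on the net-charge function, to ``tol`` pH units.

    Net charge is strictly decreasing in pH, so the root in [0, 14] is unique.
    If the charge does not change sign on [0, 14] the nearer endpoint is
    returned (pathological compositions only).
    """
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) < 0:
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def aliphatic_index(seq: str) -> float:
    """Relative volume of aliphatic side chains: 100*(fA + 2.9 fV + 3.9 (fI+fL))."""
    n = len(seq)
    return 100.0 * (
        seq.count("A") / n
        + 2.9 * seq.count("V") / n
        + 3.9 * (seq.count("I") + seq.count("L")) / n
    )


def physchem_features(seq: str) -> list[float]:
    """The 12 physicochemical descriptors, in :data:`PHYSCHEM_NAMES` order."""
    n = len(seq)
    pa = ProteinAnalysis(seq)
    charge7 = net_charge(seq, 7.0)
    return [
        float(n),
        pa.molecular_weight(),
        isoelectric_point(seq),
        pa.gravy(),
        pa.aromaticity(),
        aliphatic_index(seq),
        pa.instability_index(),
        (seq.count("K") + seq.count("R")) / n,
        (seq.count("D") + seq.count("E")) / n,
        charge7,
        abs(charge7) / n,
        sum(seq.count(aa) for aa in "AGSTC") / n,
    ]


# ---------------------------------------------------------------------------
# groups (iv)-(vii): annotator-backed features

def tm_features(seq: str, annotator=None) -> list[float]:
    """Transmembrane-helix content from a per-residue TM mask (3 values).

    Returns (a) TM residues over the whole sequence, (b) TM residues within
    the first 60 residues, (c) number of predicted helices. Always (b) <= (a).
    """
    annotator = annotator or _ann.hydropathy_window_tm_mask
    try:
        mask = list(annotator(seq))
    except Exception as exc:  # pragma: no cover - plugin failure path
        raise RuntimeError(f"TM annotator failed on sequence of length {len(seq)}") from exc
    if len(mask) != len(seq):
        raise ValueError("TM annotator returned a mask of the wrong length")
    total = float(sum(mask))
    first60 = float(sum(mask[:60]))
    return [total, first60, float(count_helices(mask))]


def _plugin_features(seq: str, plugins: AnnotatorSet) -> tuple[list[float], list[str]]:
    """Groups (iv)-(vi); sentinel 0.0 + exclusion flags where no plugin is set."""
    values: list[float] = []
    excluded: list[str] = []
    if plugins.flexibility is not None:
        values.append(float(np.mean(list(plugins.flexibility(seq)))))
    else:
        values.append(0.0)
        excluded.extend(FLEXIBILITY_NAMES)
    if plugins.secondary_structure is not None:
        labels = list(plugins.secondary_structure(seq))
        n = len(labels)
        values.extend(
            [labels.count("H") / n, labels.count("E") / n, labels.count("C") / n]
        )
    else:
        values.extend([0.0, 0.0, 0.0])
        excluded.extend(SS_NAMES)
    if plugins.disorder is not None:
        values.append(float(np.mean(list(plugins.disorder(seq)))))
    else:
        values.append(0.0)
        excluded.extend(DISORDER_NAMES)
    return values, excluded


# ---------------------------------------------------------------------------
# full vector / matrix

def compute_feature_vector(
    seq: str,
    reference: Sequence[ProteinRecord] = (),
    plugins: Optional[AnnotatorSet] = None,
    exclude_exact: Optional[set[str]] = None,
) -> FeatureVector:
    """Compute the full 251-feature vector for one sequence.

    ``reference`` is the soluble reference set for the max-identity feature
    (empty reference gives 0.0); ``exclude_exact`` removes verbatim sequences
    from it, used to keep held-out sequences out of the reference.
    """
    seq = validate_sequence(seq)
    plugins = plugins or DEFAULT_ANNOTATORS
    values: list[float] = []
    values.extend(aa_composition(seq))
    values.extend(dimer_composition(seq))
    values.extend(physchem_features(seq))
    plugin_vals, excluded = _plugin_features(seq, plugins)
    values.extend(plugin_vals)
    values.extend(tm_features(seq, plugins.tm))
    values.append(max_identity(seq, reference, exclude_exact))
    return FeatureVector(
        names=tuple(FEATURE_NAMES), values=tuple(values), excluded=tuple(excluded)
    )


def compute_feature_matrix(
    records: Sequence[ProteinRecord],
    reference: Sequence[ProteinRecord] = (),
    plugins: Optional[AnnotatorSet] = None,
    exclude_exact: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix (rows = record ids, columns = feature names).

    Returns the matrix and the list of sentinel-filled (excluded) features.
    """
    rows = []
    excluded: tuple[str, ...] = ()
    for rec in records:
        fv = compute_feature_vector(rec.sequence, reference, plugins, exclude_exact)
        rows.append(fv.values)
        excluded = fv.excluded
    matrix = pd.DataFrame(rows, index=[r.id for r in records], columns=FEATURE_NAMES)
    return matrix, list(excluded)


# ---------------------------------------------------------------------------
# standardization

@dataclass(frozen=True)
class Standardizer:
    """Per-feature centering/scaling statistics, fitted on training data only.

    ``scales`` holds the population standard deviation of each training
    column; zero-variance columns get scale 1 so they standardize to zero.
    """

    names: tuple[str, ...]
    means: np.ndarray
    scales: np.ndarray


def fit_standardizer(matrix: pd.DataFrame) -> Standardizer:
    if matrix.empty:
        raise ValueError("cannot fit a standardizer on an empty matrix")
    means = matrix.mean(axis=0).to_numpy()
    scales = matrix.std(axis=0, ddof=0).to_numpy().copy()
    scales[scales == 0.0] = 1.0
    return Standardizer(tuple(matrix.columns), means, scales)


def apply_standardizer(std: Standardizer, matrix: pd.DataFrame) -> pd.DataFrame:
    if tuple(matrix.columns) != std.names:
        missing = set(std.names) - set(matrix.columns)
        raise ValueError(
            f"feature columns do not match the fitted standardizer"
            f" (missing: {sorted(missing)[:5]}...)" if missing
            else "feature columns do not match the fitted standardizer (order differs)"
        )
    return (matrix - std.means) / std.scales
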