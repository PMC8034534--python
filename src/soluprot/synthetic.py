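"""Synthetic data with a planted, tunable solubility signal.

Two generators make every pipeline stage testable without external
downloads:

* :func:`gen_sequences` draws random protein sequences (configurable residue
  background), optionally inserts a hydrophobic 21-mer that the
  transmembrane annotator will detect, and samples binary solubility labels
  from a logistic model on a named subset of realized sequence features. By
  default the signal is carried by positive-residue content (K+R, positive
  weight), predicted TM-segment presence (negative weight) and isoelectric
  point — the same kinds of features the real predictor leans on.

* :func:`gen_curation_records` emits experiment-tracking records from a
  scenario mixture (soluble path, insoluble stop, unknown outcome, non-coli
  host, transmembrane, PDB-rescuable), so curation attrition has closed-form
  expectations.

Effect weights are per standard deviation of the realized feature within the
generated batch, so their magnitudes are comparable across features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotators import hydropathy_window_tm_mask
from .curation import CurationRecord
from .features import isoelectric_point
from .seqio import INSOLUBLE, SOLUBLE, STANDARD_AA, ProteinRecord

# Approximate Swiss-Prot residue frequencies (realism preset).
SWISSPROT_FREQS = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0591, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0472, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

HYDROPHOBIC_CORE = "LIVFAM"
TM_SEGMENT_LENGTH = 21

DEFAULT_EFFECT_WEIGHTS = {
    "frac_positive_kr": 1.5,
    "tm_presence": -1.2,
    "isoelectric_point": 0.6,
}


@dataclass(frozen=True)
class PlantedModel:
    """Generative model for labeled sequences with a planted signal."""

    n: int = 2000
    length_range: tuple[int, int] = (60, 300)
    effect_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_WEIGHTS)
    )
    noise_sd: float = 0.5
    prevalence: float = 0.5
    tm_insert_prob: float = 0.30
    background: Optional[dict] = None  # residue -> frequency; None = uniform
    seed: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def _realized_features(seq: str) -> dict[str, float]:
    n = len(seq)
    mask = hydropathy_window_tm_mask(seq)
    return {
        "frac_positive_kr": (seq.count("K") + seq.count("R")) / n,
        "tm_presence": 1.0 if any(mask) else 0.0,
        "isoelectric_point": isoelectric_point(seq),
        "gravy": sum(
            {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
             "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
             "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
             "Y": -1.3, "V": 4.2}[aa] for aa in seq
        ) / n,
        "length": float(n),
    }


def gen_sequences(model: PlantedModel) -> list[ProteinRecord]:
    """Generate labeled sequences under the planted logistic model.

    Residues are drawn i.i.d. from the background distribution; with
    probability ``tm_insert_prob`` a hydrophobic 21-mer is spliced in at a
    random position. Labels are Bernoulli draws from
    ``sigmoid(b0 + sum_j w_j z_j + eps)`` where z_j are batch-z-scored
    realized features, eps ~ N(0, noise_sd) and b0 sets the target
    prevalence. Fully deterministic per seed.
    """
    rng = np.random.default_rng(model.seed)
    alphabet = list(STANDARD_AA)
    if model.background is None:
        probs = np.full(20, 0.05)
    else:
        probs = np.array([model.background[aa] for aa in alphabet], dtype=float)
        probs = probs / probs.sum()
    lo, hi = model.length_range

    sequences: list[str] = []
    for _ in range(model.n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        if length >= TM_SEGMENT_LENGTH and rng.random() < model.tm_insert_prob:
            segment = "".join(
                rng.choice(list(HYDROPHOBIC_CORE), size=TM_SEGMENT_LENGTH)
            )
            pos = int(rng.integers(0, length - TM_SEGMENT_LENGTH + 1))
            seq = seq[:pos] + segment + seq[pos + TM_SEGMENT_LENGTH:]
        sequences.append(seq)

    weight_names = sorted(model.effect_weights)
    unknown = [w for w in weight_names if w not in _realized_features("A" * 25)]
    if unknown:
        raise ValueError(f"unknown effect feature(s): {unknown}")

    eta = np.full(model.n, math.log(model.prevalence / (1 - model.prevalence)))
    if weight_names:
        realized = np.array(
            [[_realized_features(s)[w] for w in weight_names] for s in sequences]
        )
        mu = realized.mean(axis=0)
        sd = realized.std(axis=0)
        sd[sd == 0.0] = 1.0
        z = (realized - mu) / sd
        weights = np.array([model.effect_weights[w] for w in weight_names])
        eta = eta + z @ weights
    if model.noise_sd > 0:
        eta = eta + rng.normal(0.0, model.noise_sd, size=model.n)
    p_soluble = 1.0 / (1.0 + np.exp(-eta))
    labels = rng.random(model.n) < p_soluble

    return [
        ProteinRecord(
            id=f"syn{i:05d}",
            sequence=seq,
            label=SOLUBLE if lab else INSOLUBLE,
        )
        for i, (seq, lab) in enumerate(zip(sequences, labels))
    ]


# ---------------------------------------------------------------------------
# synthetic experiment-tracking records

SCENARIOS = (
    "soluble-path",
    "insoluble-stop",
    "unknown",
    "non-coli-host",
    "transmembrane",
    "pdb-rescuable",
)

ECOLI_PROTOCOL = "Expressed in Escherichia coli BL21(DE3), IPTG induction at 18C"
OTHER_PROTOCOL = "Baculovirus-driven insect cell expression (Sf9), 27C"


@dataclass
class SyntheticCurationSet:
    """Records plus the matching soluble structural reference and truth tags."""

    records: list[CurationRecord]
    pdb_subset: list[ProteinRecord]
    scenarios: list[str]

    def scenario_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SCENARIOS}
        for s in self.scenarios:
            counts[s] += 1
        return counts


def _random_sequence(rng: np.random.Generator, lo: int = 60, hi: int = 200) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def gen_curation_records(
    n: int,
    seed: int = 1,
    scenario_mix: Optional[dict[str, float]] = None,
) -> SyntheticCurationSet:
    """Generate experiment-tracking records from a scenario mixture.

    ``scenario_mix`` maps scenario names to probabilities summing to 1;
    default is an even split of the first three scenarios. Sequences for the
    'pdb-rescuable' scenario are also placed in the returned soluble
    structural reference so the rescue filter can find them.
    """
    mix = scenario_mix or {"soluble-path": 0.4, "insoluble-stop": 0.4, "unknown": 0.2}
    bad = set(mix) - set(SCENARIOS)
    if bad:
        raise ValueError(f"unknown scenarios: {sorted(bad)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"scenario mix sums to {total}, expected 1")
    names = sorted(mix)
    probs = np.array([mix[s] for s in names])
    rng = np.random.default_rng(seed)

    records: list[CurationRecord] = []
    pdb_subset: list[ProteinRecord] = []
    scenarios: list[str] = []
    for i in range(n):
        scenario = names[int(rng.choice(len(names), p=probs))]
        seq = _random_sequence(rng)
        tid = f"tgt{i:05d}"
        statuses: tuple[str, ...]
        stop = None
        protocol = ECOLI_PROTOCOL
        tm_flag = False
        if scenario == "soluble-path":
            statuses = ("cloned", "expressed", "soluble", "purified")
        elif scenario == "insoluble-stop":
            statuses = ("cloned", "expressed")
            stop = "work stopped: expression failed, target insoluble"
        elif scenario == "unknown":
            statuses = ("cloned", "expressed")
        elif scenario == "non-coli-host":
            statuses = ("cloned", "expressed", "soluble", "purified")
            protocol = OTHER_PROTOCOL
        elif scenario == "transmembrane":
            statuses = ("cloned", "expressed", "soluble", "purified")
            tm_flag = True
        else:  # pdb-rescuable
            statuses = ("cloned", "expressed")
            stop = "work stopped: purification failed"
            pdb_subset.append(ProteinRecord(id=f"pdb_{tid}", sequence=seq))
        records.append(
            CurationRecord(
                target_id=tid,
                sequence=seq,
                status_history=statuses,
                stop_status=stop,
                protocol_text=protocol,
                direct_tm_annotation=tm_flag,
            )
        )
        scenarios.append(scenario)
    return SyntheticCurationSet(records, pdb_subset, scenarios)
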