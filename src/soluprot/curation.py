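"""Training/test dataset construction from experiment-tracking records.

Implements the curation pipeline that turns noisy crystallization-pipeline
records (status histories, free-text stop statuses and protocols) into a
balanced, redundancy-reduced binary solubility dataset:

1. solubility labeling from status history and stop status,
2. expression-host filtering (E. coli only),
3. transmembrane-protein removal,
4. "PDB rescue" — drop insoluble-labeled sequences that are verbatim present
   in a soluble structural reference set,
5. sequence validity filters (length >= 20, defined residues only),
6. redundancy reduction by identity clustering (separately per class),
7. class and length-distribution balancing,
8. train/test independence filtering at an identity threshold.

Every step reports its in/out counts so the attrition of the pipeline
reconciles exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .identity import cluster_reduce, global_identity
from .seqio import (
    INSOLUBLE,
    MIN_LENGTH,
    SOLUBLE,
    ProteinRecord,
    classify_sequence,
)

UNKNOWN = "unknown"


@dataclass(frozen=True)
class CurationRecord:
    """One experiment-tracking record for a protein target."""

    target_id: str
    sequence: str
    status_history: tuple[str, ...] = ()
    stop_status: Optional[str] = None
    protocol_text: Optional[str] = None
    direct_tm_annotation: bool = False


# Default vocabularies; explicit config, not hard-coded policy. The soluble
# states are ordered: reaching any of them (or any later one) implies soluble
# expression upstream.
DEFAULT_SOLUBLE_STATES = (
    "soluble",
    "purified",
    "crystallized",
    "diffraction",
    "nmr assigned",
    "structure deposited",
)
DEFAULT_INSOLUBLE_KEYWORDS = (
    "expression failed",
    "insoluble",
    "purification failed",
    "no expression",
)
DEFAULT_HOST_KEYWORDS = ("e.coli", "e. coli", "escherichia coli")


@dataclass(frozen=True)
class LabelRules:
    """Keyword rules for labeling and host filtering (case-insensitive)."""

    soluble_states: tuple[str, ...] = DEFAULT_SOLUBLE_STATES
    insoluble_stop_keywords: tuple[str, ...] = DEFAULT_INSOLUBLE_KEYWORDS
    host_keywords: tuple[str, ...] = DEFAULT_HOST_KEYWORDS
    confirmed_protocols: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.soluble_states or not self.insoluble_stop_keywords:
            raise ValueError("label rule vocabularies must be nonempty")
        if not self.host_keywords:
            raise ValueError("host keyword set must be nonempty")


DEFAULT_RULES = LabelRules()


def label_record(rec: CurationRecord, rules: LabelRules = DEFAULT_RULES) -> str:
    """Label one record 'soluble', 'insoluble' or 'unknown'.

    Soluble takes precedence: a record that reached any soluble state is
    soluble regardless of its stop status. Insoluble requires an *explicit*
    stop status matching an insolubility keyword; records with neither are
    unknown and excluded downstream.
    """
    soluble_states = {s.lower() for s in rules.soluble_states}
    for status in rec.status_history:
        if status.lower().strip() in soluble_states:
            return SOLUBLE
    if rec.stop_status:
        stop = rec.stop_status.lower()
        if any(kw.lower() in stop for kw in rules.insoluble_stop_keywords):
            return INSOLUBLE
    return UNKNOWN


def filter_host(
    records: Sequence[CurationRecord], rules: LabelRules = DEFAULT_RULES
) -> list[CurationRecord]:
    """Keep records expressed in E. coli: protocol keyword match or allow-list."""
    kept = []
    for rec in records:
        if rec.target_id in rules.confirmed_protocols:
            kept.append(rec)
            continue
        if rec.protocol_text and any(
            kw.lower() in rec.protocol_text.lower() for kw in rules.host_keywords
        ):
            kept.append(rec)
    return kept


def filter_transmembrane(
    records: Sequence[ProteinRecord], tm_calls: Sequence[bool]
) -> list[ProteinRecord]:
    """Remove records flagged transmembrane (direct annotation or prediction)."""
    if len(records) != len(tm_calls):
        raise ValueError("tm_calls length does not match records")
    return [rec for rec, tm in zip(records, tm_calls) if not tm]


def pdb_rescue(
    records: Sequence[ProteinRecord], pdb_subset: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Drop insoluble-labeled records whose sequence is verbatim in the
    soluble structural reference; soluble records pass through untouched."""
    soluble_seqs = {rec.sequence for rec in pdb_subset}
    return [
        rec
        for rec in records
        if not (rec.label == INSOLUBLE and rec.sequence in soluble_seqs)
    ]


def filter_valid_sequences(
    records: Sequence[ProteinRecord], min_length: int = MIN_LENGTH
) -> tuple[list[ProteinRecord], int, int]:
    """Apply the length/undefined-residue rules; returns (kept, n_short, n_undef)."""
    kept: list[ProteinRecord] = []
    n_short = n_undef = 0
    for rec in records:
        kind = classify_sequence(rec.sequence, min_length)
        if kind == "ok":
            kept.append(rec)
        elif kind == "short":
            n_short += 1
        else:
            n_undef += 1
    return kept, n_short, n_undef


def binarize_solubility(level: int, threshold: int = 1) -> str:
    """Binary class from a 0-5 solubility level: soluble iff level >= threshold."""
    if not 0 <= level <= 5:
        raise ValueError(f"solubility level {level} outside 0..5")
    return SOLUBLE if level >= threshold else INSOLUBLE


def _length_bin(length: int, bin_width: int) -> int:
    return length // bin_width


def balance_dataset(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    bin_width: int = 25,
    seed: int = 42,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Equalize class sizes per sequence-length bin.

    Within each length bin the over-represented class is downsampled
    uniformly at random (seeded); bins present in only one class are dropped
    entirely. The result has equal class counts overall and per bin, so
    sequence length alone cannot drive the classifier.
    """
    if not pos or not neg:
        raise ValueError("both classes must be nonempty")
    rng = random.Random(seed)
    by_bin_pos: dict[int, list[ProteinRecord]] = {}
    by_bin_neg: dict[int, list[ProteinRecord]] = {}
    for rec in pos:
        by_bin_pos.setdefault(_length_bin(len(rec.sequence), bin_width), []).append(rec)
    for rec in neg:
        by_bin_neg.setdefault(_length_bin(len(rec.sequence), bin_width), []).append(rec)
    out_pos: list[ProteinRecord] = []
    out_neg: list[ProteinRecord] = []
    for b in sorted(set(by_bin_pos) & set(by_bin_neg)):
        p, q = by_bin_pos[b], by_bin_neg[b]
        k = min(len(p), len(q))
        out_pos.extend(p if len(p) == k else rng.sample(p, k))
        out_neg.extend(q if len(q) == k else rng.sample(q, k))
    return out_pos, out_neg


def enforce_independence(
    test: Sequence[ProteinRecord],
    train: Sequence[ProteinRecord],
    threshold: float = 0.25,
) -> list[ProteinRecord]:
    """Drop test records with global identity above ``threshold`` to any
    training sequence, so the evaluation cannot exploit homology leakage."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    train_seqs = {rec.sequence for rec in train}
    kept = []
    for rec in test:
        if rec.sequence in train_seqs:
            continue
        if any(
            global_identity(rec.sequence, t.sequence) > threshold for t in train
        ):
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# end-to-end pipeline with attrition bookkeeping

@dataclass
class AttritionReport:
    """Counts in/out per curation step, in execution order."""

    steps: list = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append({"step": name, "in": n_in, "out": n_out})

    def to_json(self) -> str:
        return json.dumps({"steps": self.steps}, indent=2)


def curate(
    records: Sequence[CurationRecord],
    rules: LabelRules = DEFAULT_RULES,
    pdb_subset: Sequence[ProteinRecord] = (),
    identity_threshold: float = 0.25,
    bin_width: int = 25,
    seed: int = 42,
    cluster: bool = True,
) -> tuple[list[ProteinRecord], list[ProteinRecord], AttritionReport]:
    """Run the full curation pipeline; returns (soluble, insoluble, report).

    Clustering is the expensive step (all-pairs global alignment); it can be
    switched off for large synthetic runs where redundancy is absent by
    construction.
    """
    report = AttritionReport()

    hosted = filter_host(records, rules)
    report.add("host_filter", len(records), len(hosted))

    labeled: list[ProteinRecord] = []
    tm_by_id: dict[str, bool] = {}
    for rec in hosted:
        lab = label_record(rec, rules)
        if lab != UNKNOWN:
            labeled.append(ProteinRecord(rec.target_id, rec.sequence.upper(), lab))
            tm_by_id[rec.target_id] = rec.direct_tm_annotation
    report.add("labeling", len(hosted), len(labeled))

    tm_calls = [tm_by_id[rec.id] for rec in labeled]
    no_tm = filter_transmembrane(labeled, tm_calls)
    report.add("transmembrane_filter", len(labeled), len(no_tm))

    valid, n_short, n_undef = filter_valid_sequences(no_tm)
    report.add("sequence_validity", len(no_tm), len(valid))

    rescued = pdb_rescue(valid, pdb_subset)
    report.add("pdb_rescue", len(valid), len(rescued))

    pos = [r for r in rescued if r.label == SOLUBLE]
    neg = [r for r in rescued if r.label == INSOLUBLE]

    if cluster:
        pos = cluster_reduce(pos, identity_threshold)
        neg = cluster_reduce(neg, identity_threshold)
    report.add("redundancy_reduction", len(rescued), len(pos) + len(neg))

    pos, neg = balance_dataset(pos, neg, bin_width=bin_width, seed=seed)
    report.add("balancing", report.steps[-1]["out"], len(pos) + len(neg))

    return pos, neg, report


# ---------------------------------------------------------------------------
# record I/O (JSON-lines)

def write_curation_records(records: Iterable[CurationRecord], path) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(
                json.dumps(
                    {
                        "target_id": rec.target_id,
                        "sequence": rec.sequence,
                        "status_history": list(rec.status_history),
                        "stop_status": rec.stop_status,
                        "protocol_text": rec.protocol_text,
                        "tm_flag": rec.direct_tm_annotation,
                    }
                )
                + "\n"
            )


def read_curation_records(path) -> list[CurationRecord]:
    path = Path(path)
    records = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            d = json.loads(line)
            records.append(
                CurationRecord(
                    target_id=d["target_id"],
                    sequence=d["sequence"],
                    status_history=tuple(d.get("status_history", ())),
                    stop_status=d.get("stop_status"),
                    protocol_text=d.get("protocol_text"),
                    direct_tm_annotation=bool(d.get("tm_flag", False)),
                )
            )
    return records
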