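"""Sequence and prediction-table I/O.

Reads protein FASTA into validated :class:`ProteinRecord` objects, applying the
dataset validity rules used throughout the pipeline: sequences must be at least
20 residues long and contain only the 20 standard amino-acid letters (no
X/B/Z/U/*). Writes prediction score tables as TSV.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Optional

from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

MIN_LENGTH = 20

SOLUBLE = "soluble"
INSOLUBLE = "insoluble"


class SequenceError(ValueError):
    """Raised for invalid sequences or malformed sequence files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional binary solubility label.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited token of a FASTA header).
    sequence : str
        Amino-acid sequence over the 20 standard letters, uppercase.
    label : str, optional
        ``"soluble"`` or ``"insoluble"``; ``None`` for unlabeled records.
    """

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (None, SOLUBLE, INSOLUBLE):
            raise ValueError(f"invalid label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: Optional[str]) -> "ProteinRecord":
        return replace(self, label=label)


@dataclass
class ReadReport:
    """Per-file filtering report: every FASTA entry lands in exactly one bucket."""

    kept: int = 0
    filtered_short: int = 0
    filtered_undefined: int = 0
    renamed_duplicates: int = 0
    dropped_ids: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.kept + self.filtered_short + self.filtered_undefined


def validate_sequence(seq: str, min_length: int = MIN_LENGTH) -> str:
    """Uppercase and validate a sequence; raise :class:`SequenceError` if invalid."""
    seq = seq.upper()
    if len(seq) < min_length:
        raise SequenceError(f"sequence shorter than {min_length} residues (length {len(seq)})")
    bad = set(seq) - _AA_SET
    if bad:
        raise SequenceError(f"undefined residues {sorted(bad)} in sequence")
    return seq


def classify_sequence(seq: str, min_length: int = MIN_LENGTH) -> str:
    """Return 'ok', 'short' or 'undefined' for a raw sequence string.

    A too-short sequence is reported as 'short' even if it also contains
    undefined residues (the length rule is checked first).
    """
    seq = seq.upper()
    if len(seq) < min_length:
        return "short"
    if set(seq) - _AA_SET:
        return "undefined"
    return "ok"


def _open_maybe_gzip(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path,
    strict: bool = False,
    min_length: int = MIN_LENGTH,
) -> tuple[list[ProteinRecord], ReadReport]:
    """Read a protein FASTA file into validated records.

    With ``strict=True`` any invalid entry (too short, undefined residues,
    duplicate id) raises :class:`SequenceError`. With ``strict=False`` invalid
    entries are dropped and counted in the returned report, and duplicate ids
    get a deterministic numeric suffix (``id.2``, ``id.3``, ...).

    Returns
    -------
    (records, report)
        The valid records in file order, and the filtering report. The report
        satisfies ``kept + filtered_short + filtered_undefined == total``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ReadReport()
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with _open_maybe_gzip(path) as handle:
        entries = list(SeqIO.parse(handle, "fasta"))
    if not entries:
        raise SequenceError(f"no FASTA entries in {path}")
    for entry in entries:
        rid = entry.id
        raw = str(entry.seq)
        kind = classify_sequence(raw, min_length)
        if kind != "ok":
            if strict:
                raise SequenceError(f"invalid entry {rid!r}: {kind}")
            if kind == "short":
                report.filtered_short += 1
            else:
                report.filtered_undefined += 1
            report.dropped_ids.append(rid)
            continue
        if rid in seen:
            if strict:
                raise SequenceError(f"duplicate id {rid!r}")
            seen[rid] += 1
            report.renamed_duplicates += 1
            rid = f"{rid}.{seen[entry.id]}"
        else:
            seen[rid] = 1
        records.append(ProteinRecord(id=rid, sequence=raw.upper()))
        report.kept += 1
    return records, report


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as multi-line FASTA (wrap at ``width`` columns)."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def write_predictions(scored: Iterable[tuple[str, float]], path) -> None:
    """Write (id, score) pairs as a TSV with header ``id\tsoluprot_score``.

    Scores must lie in [0, 1] and are printed with 6 decimals; row order
    follows input order.
    """
    rows = list(scored)
    for rid, score in rows:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score for {rid!r} outside [0, 1]: {score}")
    path = Path(path)
    with open(path, "w") as out:
        out.write("id\tsoluprot_score\n")
        for rid, score in rows:
            out.write(f"{rid}\t{score:.6f}\n")


def read_predictions(path) -> list[tuple[str, float]]:
    """Read a prediction TSV written by :func:`write_predictions`."""
    path = Path(path)
    rows: list[tuple[str, float]] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise SequenceError(f"malformed prediction header in {path}")
        for line in handle:
            if not line.strip():
                continue
            rid, score = line.rstrip("\n").split("\t")[:2]
            rows.append((rid, float(score)))
    return rows


def write_labels(records: Iterable[ProteinRecord], path) -> None:
    """Write ``id\tlabel`` TSV with labels encoded 1 (soluble) / 0 (insoluble)."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("id\tlabel\n")
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} is unlabeled")
            out.write(f"{rec.id}\t{1 if rec.label == SOLUBLE else 0}\n")


def read_labels(path) -> dict[str, int]:
    """Read an ``id\tlabel`` TSV into a dict of 0/1 labels."""
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as handle:
        handle.readline()
        for line in handle:
            if not line.strip():
                continue
            rid, lab = line.rstrip("\n").split("\t")[:2]
            labels[rid] = int(lab)
    return labels
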