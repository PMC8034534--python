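"""Global sequence identity and greedy identity-threshold clustering.

Pairwise identity is computed from a Needleman–Wunsch global alignment
(BLOSUM62, affine gaps: open 10, extend 1) as the number of identical aligned
residue pairs divided by the number of alignment columns — the definition
USEARCH reports by default. Identity drives three pipeline steps: the
max-identity-to-reference feature, redundancy reduction of the training set,
and train/test independence filtering.

Exact dynamic programming stands in for the heuristic engines (USEARCH,
MMseqs2) used at database scale: at desk scale exactness beats heuristic
fidelity, and those tools only serve as identity engines here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

GAP_OPEN = 10
GAP_EXTEND = 1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND
    aligner.open_gap_score = -float(GAP_OPEN)
    aligner.extend_gap_score = -float(GAP_EXTEND)
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class IdentityResult:
    query_id: str
    target_id: str
    identity: float


def global_identity(a: str, b: str) -> float:
    """Fraction of identical aligned pairs over alignment columns, in [0, 1].

    Uses the first optimal global alignment under the fixed scoring scheme;
    Biopython's traceback order makes this deterministic, and the pair is
    put in lexicographic order first so identity(a, b) == identity(b, a)
    even when co-optimal alignments differ in identity count.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    alignment = _ALIGNER.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score under the module's scoring scheme."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _ALIGNER.score(a, b)


def max_identity(
    query: str,
    reference: Sequence[ProteinRecord],
    exclude_exact: Optional[set[str]] = None,
) -> float:
    """Maximum global identity of ``query`` to any eligible reference member.

    Members whose sequence appears in ``exclude_exact`` are skipped (used to
    purge verbatim test-set sequences from the soluble reference before the
    max-identity feature is computed). Returns 0.0 when no member is eligible.
    """
    exclude_exact = exclude_exact or set()
    best = 0.0
    for rec in reference:
        if rec.sequence in exclude_exact:
            continue
        if rec.sequence == query:  # exact-match fast path
            return 1.0
        best = max(best, global_identity(query, rec.sequence))
    return best


@dataclass(frozen=True)
class ClusterAssignment:
    member_id: str
    centroid_id: str
    identity: float


def cluster_assign(
    records: Sequence[ProteinRecord], threshold: float
) -> tuple[list[ProteinRecord], list[ClusterAssignment]]:
    """Greedy centroid clustering at an identity threshold.

    Records are visited in order of decreasing length (ties broken by id);
    each joins the first existing centroid with identity >= threshold, else
    founds a new cluster. The sort makes the result independent of input
    order. Returns (centroids, per-member assignments).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    centroids: list[ProteinRecord] = []
    assignments: list[ClusterAssignment] = []
    for rec in ordered:
        placed = False
        for centroid in centroids:
            ident = (
                1.0
                if rec.sequence == centroid.sequence
                else global_identity(rec.sequence, centroid.sequence)
            )
            if ident >= threshold:
                assignments.append(ClusterAssignment(rec.id, centroid.id, ident))
                placed = True
                break
        if not placed:
            centroids.append(rec)
            assignments.append(ClusterAssignment(rec.id, rec.id, 1.0))
    return centroids, assignments


def cluster_reduce(records: Sequence[ProteinRecord], threshold: float) -> list[ProteinRecord]:
    """Redundancy reduction: keep one representative per identity cluster."""
    centroids, _ = cluster_assign(records, threshold)
    return centroids


def write_cluster_tsv(assignments: Iterable[ClusterAssignment], path) -> None:
    path = Path(path)
    with open(path, "w") as out:
        out.write("member_id\tcentroid_id\tidentity\n")
        for a in assignments:
            out.write(f"{a.member_id}\t{a.centroid_id}\t{a.identity:.4f}\n")
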