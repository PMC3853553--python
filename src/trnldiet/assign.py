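"""Taxonomic assignment of amplicon clusters against a haplotype-group
reference, with ties resolved to the lowest common taxonomic level.

Each retained cluster centroid is aligned against every reference
haplotype group (semi-global alignment: overhangs of the reference beyond
the query are free).  Hits must clear an identity and an aligned-length
threshold; among passing hits, all groups attaining the maximal alignment
score are kept.  A unique best hit inherits the group's own label; an
exact score tie is lifted to the lowest taxonomic rank containing every
member species of every tied group, and a tie spanning two families is
reported as unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from ._utils import DNA_LETTERS
from .reads import AlignmentScoring, SequenceCluster
from .reference import HaplotypeGroup
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)


class AssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonAssignment:
    sample_id: str
    cluster_id: str
    assigned_label: str
    assigned_rank: str  # species | genus | family | above_family-> "unassigned"
    read_count: int
    best_identity: float
    tied_groups: tuple[str, ...]


from functools import lru_cache


@lru_cache(maxsize=8)
def _semiglobal_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free end gaps in the query: reference overhang costs nothing
    try:
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older Bio.Align attribute names
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def score_pair(
    query: str, ref: str, scoring: AlignmentScoring = AlignmentScoring()
) -> tuple[float, float, int]:
    """Align a cluster centroid to one reference haplotype.

    Returns ``(score, identity, aligned_length)``.  The alignment is global
    with free end gaps on the query, so a query that is a sub-fragment of
    the reference aligns without penalty; identity is computed as matches
    over alignment columns *excluding* the free end-gap columns, and
    ``aligned_length`` is that column count.
    """
    query = query.upper()
    ref = ref.upper()
    if query == ref and "N" not in query:
        return float(len(query) * scoring.match), 1.0, len(query)
    aln = _semiglobal_aligner(scoring).align(ref, query)[0]
    t, q = str(aln[0]), str(aln[1])
    start = 0
    end = len(q)
    while start < end and q[start] == "-":
        start += 1
    while end > start and q[end - 1] == "-":
        end -= 1
    cols = end - start
    if cols == 0:
        return float(aln.score), 0.0, 0
    ident = sum(
        1 for x, y in zip(t[start:end], q[start:end]) if x == y and x in DNA_LETTERS
    )
    return float(aln.score), ident / cols, cols


def best_hits(
    query: str,
    groups: list[HaplotypeGroup],
    min_identity: float = 0.95,
    min_aligned: int = 40,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[list[HaplotypeGroup], float]:
    """All reference groups attaining the maximal alignment score.

    Only hits with identity >= ``min_identity`` over >= ``min_aligned``
    columns are considered; ties are exact score equality (scores are
    integer-valued under unit costs).  Returns the tied groups and the best
    identity among them (0.0 when nothing passes).
    """
    if not groups:
        raise AssignmentError("no reference loaded")
    best: list[HaplotypeGroup] = []
    best_score = None
    best_identity = 0.0
    for g in groups:
        score, identity, cols = score_pair(query, g.p6_seq, scoring)
        if identity < min_identity or cols < min_aligned:
            continue
        if best_score is None or score > best_score:
            best_score = score
            best = [g]
            best_identity = identity
        elif score == best_score:
            best.append(g)
            best_identity = max(best_identity, identity)
    return best, best_identity


def lca_label(groups: list[HaplotypeGroup], tax: Taxonomy) -> tuple[str, str]:
    """Label for a set of tied groups.

    A single group keeps its own label and rank; several tied groups are
    lifted to the lowest rank whose single taxon contains every member
    species of every group.  A tie spanning families is unresolvable at a
    useful rank and maps to ``("unassigned", "unassigned")``.
    """
    if not groups:
        return "unassigned", "unassigned"
    if len(groups) == 1:
        return groups[0].label, groups[0].label_rank
    all_members = {s for g in groups for s in g.members}
    taxon, rank = tax.lca(all_members)
    if rank == "above_family":
        return "unassigned", "unassigned"
    return taxon, rank


def assign_all(
    clusters: list[SequenceCluster],
    groups: list[HaplotypeGroup],
    tax: Taxonomy,
    min_identity: float = 0.95,
    min_aligned: int = 40,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[list[TaxonAssignment], int]:
    """Assign every retained cluster; tally reads that found no hit.

    Returns one :class:`TaxonAssignment` per cluster (rank ``unassigned``
    when no hit passed the thresholds or the tie rose above family) and the
    total read count of clusters with no passing hit at all.
    """
    assignments: list[TaxonAssignment] = []
    unassigned_reads = 0
    for cl in clusters:
        # exact shortcut: under unit costs with free reference overhangs, the
        # maximal attainable score is len(query), reached exactly by the
        # groups containing the query as a substring
        substr_hits = [g for g in groups if cl.centroid_seq in g.p6_seq]
        if substr_hits and len(cl.centroid_seq) >= min_aligned:
            tied, identity = substr_hits, 1.0
        else:
            tied, identity = best_hits(cl.centroid_seq, groups, min_identity, min_aligned, scoring)
        if not tied:
            unassigned_reads += cl.read_count
        label, rank = lca_label(tied, tax)
        assignments.append(
            TaxonAssignment(
                sample_id=cl.sample_id,
                cluster_id=cl.cluster_id,
                assigned_label=label,
                assigned_rank=rank,
                read_count=cl.read_count,
                best_identity=identity,
                tied_groups=tuple(g.group_id for g in tied),
            )
        )
    n_assigned = sum(a.read_count for a in assignments if a.assigned_rank != "unassigned")
    logger.info(
        "assigned %d clusters (%d reads); %d reads without a passing hit",
        len(assignments), n_assigned, unassigned_reads,
    )
    return assignments, unassigned_reads
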