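"""Amplicon read processing: MID demultiplexing, primer trimming,
dereplication, 98%-identity clustering, and length/abundance filtering.

Pooled pyrosequencing runs label each sample's amplicons with a short MID
(multiplex identifier) tag prepended to the forward primer.  Processing is
strictly per sample: reads are routed by MID prefix, primer-trimmed,
dereplicated, clustered greedily at a global-alignment identity threshold
(default 98%), and finally filtered by centroid length (>= 40 bp) and
cluster read count (>= 4), the thresholds conventionally used to remove
sequencing noise from short-amplicon 454 data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

try:
    import edlib as _edlib
except ImportError:  # pragma: no cover - edlib is an optional accelerator
    _edlib = None

from ._utils import DNA_LETTERS, mismatches
from .reference import PRIMER_G, PRIMER_H, extract_p6

logger = logging.getLogger(__name__)


class ReadProcessingError(ValueError):
    pass


@dataclass
class RawRead:
    """A single sequencer read (quality string optional and unused)."""

    read_id: str
    seq: str
    qual: str | None = None

    def __post_init__(self):
        if not self.seq:
            raise ReadProcessingError(f"{self.read_id}: empty sequence")
        self.seq = self.seq.upper()


class MIDMap:
    """MID tag -> sample id mapping; tags must be prefix-unique."""

    def __init__(self, tag_to_sample: dict[str, str]):
        tags = [t.upper() for t in tag_to_sample]
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                if a.startswith(b) or b.startswith(a):
                    raise ReadProcessingError(f"MID tags not prefix-unique: {a!r} / {b!r}")
        samples = list(tag_to_sample.values())
        if len(set(samples)) != len(samples):
            raise ReadProcessingError("one MID tag per sample required")
        self._map = {t.upper(): s for t, s in tag_to_sample.items()}

    def items(self):
        return self._map.items()

    @property
    def samples(self) -> list[str]:
        return list(self._map.values())

    def __len__(self):
        return len(self._map)


@dataclass
class SequenceCluster:
    """Per-sample cluster of near-identical amplicons.

    The centroid is the most abundant member sequence (the cluster founder,
    since candidates are processed in decreasing-abundance order).
    """

    sample_id: str
    cluster_id: str
    centroid_seq: str
    members: dict[str, int] = field(default_factory=dict)

    @property
    def read_count(self) -> int:
        return sum(self.members.values())


# ----------------------------------------------------------------------
# demultiplexing and trimming
# ----------------------------------------------------------------------

def demultiplex(
    reads: list[RawRead], mids: MIDMap, max_mid_mismatch: int = 0
) -> tuple[dict[str, list[RawRead]], list[RawRead]]:
    """Route reads to samples by MID prefix; strip the tag from routed reads.

    A read is routed to the unique sample whose tag matches the read prefix
    within ``max_mid_mismatch`` substitutions.  Reads matching no tag, or
    more than one tag at the same (minimal) mismatch count, go to the
    unassigned bin unchanged.
    """
    if max_mid_mismatch < 0:
        raise ReadProcessingError("max_mid_mismatch must be >= 0")
    bins: dict[str, list[RawRead]] = {s: [] for s in mids.samples}
    unassigned: list[RawRead] = []
    tag_items = list(mids.items())
    for read in reads:
        best: list[tuple[str, str]] = []
        best_d = max_mid_mismatch + 1
        for tag, sample in tag_items:
            if len(read.seq) < len(tag):
                continue
            d = mismatches(read.seq[: len(tag)], tag)
            if d < best_d:
                best_d = d
                best = [(tag, sample)]
            elif d == best_d:
                best.append((tag, sample))
        if best_d <= max_mid_mismatch and len(best) == 1:
            tag, sample = best[0]
            bins[sample].append(RawRead(read.read_id, read.seq[len(tag) :], read.qual))
        else:
            unassigned.append(read)
    return bins, unassigned


def trim_primers(
    seq: str,
    primer_fwd: str = PRIMER_G,
    primer_rev: str = PRIMER_H,
    max_mismatch: int = 0,
    pass_through: bool = False,
) -> str | None:
    """Cut the insert between the primer sites of an amplicon read.

    Same contract as :func:`trnldiet.reference.extract_p6`.  With
    ``pass_through`` set, a read lacking primer sites is returned unchanged
    (for inputs that were trimmed upstream).
    """
    insert = extract_p6(seq, primer_fwd, primer_rev, max_mismatch)
    if insert is None and pass_through:
        return seq.upper()
    return insert


def prefilter_read(seq: str, min_length: int | None = None, max_n_fraction: float = 0.10) -> str | None:
    """Reject reads that are too short to contain a primer or too N-rich.

    Returns the reason string when rejected, else None.
    """
    if min_length is None:
        min_length = len(PRIMER_G)
    if len(seq) < min_length:
        return f"shorter than {min_length} bp"
    n_frac = sum(1 for c in seq if c not in DNA_LETTERS) / len(seq)
    if n_frac > max_n_fraction:
        return f"more than {max_n_fraction:.0%} ambiguous bases"
    return None


# ----------------------------------------------------------------------
# dereplication and clustering
# ----------------------------------------------------------------------

def dereplicate(seqs: list[str]) -> list[tuple[str, int]]:
    """Collapse identical sequences; sort by decreasing count, then sequence."""
    counts = Counter(s.upper() for s in seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class AlignmentScoring:
    """Unit-match global-alignment scoring used for identity computation."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


from functools import lru_cache


@lru_cache(maxsize=8)
def _global_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_identity(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Global-alignment identity: matches / alignment columns (end gaps count).

    N matches nothing in the identity numerator.
    """
    a = a.upper()
    b = b.upper()
    if a == b and "N" not in a:
        return 1.0
    aln = _global_aligner(scoring).align(a, b)[0]
    if "N" in a or "N" in b:
        s1, s2 = str(aln[0]), str(aln[1])
        ident = sum(1 for x, y in zip(s1, s2) if x == y and x in DNA_LETTERS)
    else:
        ident = aln.counts().identities
    return ident / aln.length


def cluster_reads(
    uniques: list[tuple[str, int]],
    identity_threshold: float = 0.98,
    scoring: AlignmentScoring = AlignmentScoring(),
    sample_id: str = "",
) -> list[SequenceCluster]:
    """Greedy centroid clustering of dereplicated sequences.

    Sequences are scanned in the deterministic order produced by
    :func:`dereplicate`; each joins the first existing cluster whose
    centroid it matches at >= ``identity_threshold`` global identity,
    otherwise it founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ReadProcessingError("identity_threshold must be in (0, 1]")
    clusters: list[SequenceCluster] = []
    for seq, count in uniques:
        placed = False
        for cl in clusters:
            la, lb = len(seq), len(cl.centroid_seq)
            # identity <= min_len / max_len, so a large length gap cannot pass
            if min(la, lb) / max(la, lb) < identity_threshold:
                continue
            # equal-length fast accept: the ungapped alignment is one global
            # alignment candidate, so clearing the threshold without gaps
            # means the optimal alignment clears it too
            if la == lb and (la - mismatches(seq, cl.centroid_seq)) / la >= identity_threshold:
                cl.members[seq] = cl.members.get(seq, 0) + count
                placed = True
                break
            # exact reject: every global alignment has >= edit-distance
            # non-match columns, so identity <= Lmin / (Lmin + ed)
            if _edlib is not None:
                ed = _edlib.align(seq, cl.centroid_seq, mode="NW", task="distance")["editDistance"]
                lmin = min(la, lb)
                if lmin / (lmin + ed) < identity_threshold:
                    continue
            if global_identity(seq, cl.centroid_seq, scoring) >= identity_threshold:
                cl.members[seq] = cl.members.get(seq, 0) + count
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    sample_id=sample_id,
                    cluster_id=f"{sample_id}_c{len(clusters) + 1}" if sample_id else f"c{len(clusters) + 1}",
                    centroid_seq=seq,
                    members={seq: count},
                )
            )
    return clusters


def filter_clusters(
    clusters: list[SequenceCluster], min_length: int = 40, min_reads: int = 4
) -> tuple[list[SequenceCluster], list[dict]]:
    """Drop short-centroid and low-count clusters.

    Retains clusters with centroid length >= ``min_length`` AND read count
    >= ``min_reads`` (i.e. "less than 40 bp" and "fewer than four reads"
    are excluded; both boundaries are kept).  Returns retained clusters and
    a discard log recording the reason for every dropped cluster.
    """
    kept: list[SequenceCluster] = []
    discarded: list[dict] = []
    for cl in clusters:
        reasons = []
        if len(cl.centroid_seq) < min_length:
            reasons.append(f"centroid shorter than {min_length} bp")
        if cl.read_count < min_reads:
            reasons.append(f"fewer than {min_reads} reads")
        if reasons:
            discarded.append(
                {
                    "sample_id": cl.sample_id,
                    "cluster_id": cl.cluster_id,
                    "read_count": cl.read_count,
                    "centroid_length": len(cl.centroid_seq),
                    "reason": "; ".join(reasons),
                }
            )
        else:
            kept.append(cl)
    return kept, discarded


# ----------------------------------------------------------------------
# per-sample orchestration
# ----------------------------------------------------------------------

@dataclass
class SampleProcessingResult:
    sample_id: str
    clusters: list[SequenceCluster]
    discarded_clusters: list[dict]
    rejected_reads: list[dict]  # pre-clustering rejects (primer / N / length)
    n_reads_in: int

    @property
    def n_reads_clustered(self) -> int:
        return sum(c.read_count for c in self.clusters)


def process_sample(
    sample_id: str,
    reads: list[RawRead],
    identity_threshold: float = 0.98,
    min_length: int = 40,
    min_reads: int = 4,
    primer_fwd: str = PRIMER_G,
    primer_rev: str = PRIMER_H,
    max_primer_mismatch: int = 0,
    primer_pass_through: bool = False,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> SampleProcessingResult:
    """Trim, dereplicate, cluster and filter one sample's demultiplexed reads."""
    inserts: list[str] = []
    rejected: list[dict] = []
    for read in reads:
        reason = prefilter_read(read.seq)
        if reason is not None:
            rejected.append({"sample_id": sample_id, "read_id": read.read_id, "reason": reason})
            continue
        insert = trim_primers(
            read.seq, primer_fwd, primer_rev, max_primer_mismatch, primer_pass_through
        )
        if insert is None or not insert:
            rejected.append(
                {"sample_id": sample_id, "read_id": read.read_id, "reason": "primer site not found"}
            )
            continue
        inserts.append(insert)
    uniques = dereplicate(inserts)
    clusters = cluster_reads(uniques, identity_threshold, scoring, sample_id=sample_id)
    kept, discarded = filter_clusters(clusters, min_length, min_reads)
    logger.info(
        "%s: %d reads -> %d clustered, %d clusters kept, %d discarded, %d reads rejected",
        sample_id, len(reads), sum(c.read_count for c in clusters), len(kept),
        len(discarded), len(rejected),
    )
    return SampleProcessingResult(
        sample_id=sample_id,
        clusters=kept,
        discarded_clusters=discarded,
        rejected_reads=rejected,
        n_reads_in=len(reads),
    )
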