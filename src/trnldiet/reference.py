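"""P6-loop reference database: primer-site extraction, haplotype grouping,
and taxonomic discrimination statistics.

The P6 loop of the chloroplast trnL (UAA) intron is a short hypervariable
fragment flanked by the universal plant primers g and h.  A local reference
database stores, for each candidate food-plant species, the P6 insert cut
out of its full intron sequence.  Because the fragment is short, different
species frequently share an identical haplotype; such species are collapsed
into a *haplotype group* labelled at the lowest taxonomic rank containing
all of its members (e.g. ``"Gr. Lauraceae1"`` for an unresolved set of
Lauraceae species).  How much resolution the marker retains is summarised
by discrimination rates at the species (Rs), genus (Rg) and within-family
(Rf) levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._utils import mismatches, revcomp, round_half_up
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

#: universal trnL P6-loop primer g (forward)
PRIMER_G = "GGGCAATCCTGAGCCAA"
#: universal trnL P6-loop primer h (reverse, given 5'->3' on the opposite strand)
PRIMER_H = "CCATTGAGTCTCTGCACCTATC"

#: plausible P6 insert length range used when building a database
DEFAULT_LENGTH_RANGE = (50, 200)


class ReferenceError(ValueError):
    """Raised for invalid reference-database inputs."""


class AmbiguousPrimerSiteError(ReferenceError):
    """A sequence contains several non-overlapping forward-primer sites."""

    def __init__(self, positions: list[int]):
        self.positions = positions
        super().__init__(f"ambiguous primer site at positions {positions}")


@dataclass
class ReferenceSequence:
    """One reference species' trnL intron and (once extracted) its P6 insert."""

    species_id: str
    intron_seq: str
    p6_seq: str | None = None


@dataclass(frozen=True)
class HaplotypeGroup:
    """Set of species sharing one exact P6 haplotype.

    ``label`` is the species name for singletons, or ``"Gr. <taxon><k>"``
    for multi-species groups, where ``<taxon>`` is the lowest-rank taxon
    containing every member and ``k`` numbers groups sharing that taxon.
    """

    group_id: str
    p6_seq: str
    members: frozenset[str]
    label: str
    label_rank: str  # species | genus | family | above_family


@dataclass
class DiscriminationReport:
    """Taxonomic discrimination statistics of a reference database.

    Rates are integer percentages (ties rounded half-up), matching the way
    such tables are conventionally printed.
    """

    Rs: int
    Rg: int
    Rf_by_family: dict[str, int]
    n_species: int
    n_genera: int
    n_families: int
    n_distinct_sequences: int
    per_family_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-family table: family, n_species, n_sequences, Rf_percent."""
        rows = [
            {
                "family": fam,
                "n_species": self.per_family_counts[fam][0],
                "n_sequences": self.per_family_counts[fam][1],
                "Rf_percent": self.Rf_by_family[fam],
            }
            for fam in sorted(self.Rf_by_family)
        ]
        return pd.DataFrame(rows, columns=["family", "n_species", "n_sequences", "Rf_percent"])


# ----------------------------------------------------------------------
# primer-site extraction
# ----------------------------------------------------------------------

def _find_sites(seq: str, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where ``primer`` matches ``seq`` within max_mismatch
    substitutions (no indels; N matches nothing)."""
    k = len(primer)
    hits = []
    if max_mismatch == 0:
        start = 0
        while True:
            i = seq.find(primer, start)
            if i == -1:
                break
            hits.append(i)
            start = i + 1
        # a primer containing N can never match exactly
        return hits if set(primer) <= {"A", "C", "G", "T"} else []
    for i in range(len(seq) - k + 1):
        if mismatches(seq[i : i + k], primer) <= max_mismatch:
            hits.append(i)
    return hits


def extract_p6(
    intron: str,
    primer_fwd: str = PRIMER_G,
    primer_rev: str = PRIMER_H,
    max_mismatch: int = 0,
) -> str | None:
    """Cut the P6 insert out of a trnL intron (or amplicon) sequence.

    The insert is the subsequence strictly between the 3' end of the
    forward-primer site and the 5' end of the reverse-primer site; the
    primers themselves are excluded.  The reverse primer is matched as its
    reverse complement on the given strand.  Returns ``None`` when either
    site is absent within ``max_mismatch`` substitutions.

    Raises
    ------
    AmbiguousPrimerSiteError
        If two or more non-overlapping forward-primer sites are found.
    """
    if not primer_fwd or not primer_rev:
        raise ReferenceError("primers must be non-empty")
    if max_mismatch < 0:
        raise ReferenceError("max_mismatch must be >= 0")

    seq = intron.upper()
    fwd = primer_fwd.upper()
    rev_site = revcomp(primer_rev.upper())

    fwd_hits = _find_sites(seq, fwd, max_mismatch)
    if not fwd_hits:
        return None
    # several overlapping hits collapse to the leftmost; non-overlapping
    # hits mean the primer site is genuinely ambiguous
    separated = [fwd_hits[0]]
    for pos in fwd_hits[1:]:
        if pos - separated[-1] >= len(fwd):
            separated.append(pos)
    if len(separated) > 1:
        raise AmbiguousPrimerSiteError(separated)

    insert_start = fwd_hits[0] + len(fwd)
    tail = seq[insert_start:]
    rev_hits = _find_sites(tail, rev_site, max_mismatch)
    if not rev_hits:
        return None
    return tail[: rev_hits[0]]


def extract_all(
    refs: list[ReferenceSequence],
    primer_fwd: str = PRIMER_G,
    primer_rev: str = PRIMER_H,
    max_mismatch: int = 0,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> tuple[list[ReferenceSequence], list[dict]]:
    """Extract P6 inserts for a whole reference set.

    Returns the references whose insert was found and lies inside
    ``length_range``, plus a per-failure log (species_id + reason).
    """
    lo, hi = length_range
    kept: list[ReferenceSequence] = []
    failures: list[dict] = []
    for ref in refs:
        try:
            p6 = extract_p6(ref.intron_seq, primer_fwd, primer_rev, max_mismatch)
        except AmbiguousPrimerSiteError as exc:
            failures.append({"species_id": ref.species_id, "reason": str(exc)})
            continue
        if p6 is None:
            failures.append({"species_id": ref.species_id, "reason": "primer site not found"})
        elif not lo <= len(p6) <= hi:
            failures.append(
                {"species_id": ref.species_id, "reason": f"insert length {len(p6)} outside {lo}-{hi}"}
            )
        else:
            kept.append(ReferenceSequence(ref.species_id, ref.intron_seq, p6))
    if failures:
        logger.warning("P6 extraction failed for %d of %d references", len(failures), len(refs))
    return kept, failures


# ----------------------------------------------------------------------
# haplotype grouping
# ----------------------------------------------------------------------

def build_haplotype_groups(
    refs: list[ReferenceSequence], tax: Taxonomy
) -> list[HaplotypeGroup]:
    """Partition references by exact P6 identity and label each group.

    Sequence comparison is case-insensitive and exact (the database is
    Sanger-derived, so no alignment-based merging is done).  Singleton
    groups take the species name; multi-species groups take
    ``"Gr. <LCA taxon><k>"`` with ``k`` numbering groups that share the
    same LCA taxon in order of first appearance.
    """
    seen: set[str] = set()
    order: list[str] = []
    members: dict[str, list[str]] = {}
    for ref in refs:
        if ref.p6_seq is None:
            raise ReferenceError(f"{ref.species_id}: p6_seq missing; run extract first")
        if ref.species_id in seen:
            raise ReferenceError(f"duplicate species_id: {ref.species_id}")
        seen.add(ref.species_id)
        key = ref.p6_seq.upper()
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(ref.species_id)

    groups: list[HaplotypeGroup] = []
    per_taxon_counter: dict[str, int] = {}
    for idx, seq in enumerate(order):
        spp = members[seq]
        taxon, rank = tax.lca(spp)
        if len(spp) == 1:
            label = spp[0]
        else:
            per_taxon_counter[taxon] = per_taxon_counter.get(taxon, 0) + 1
            label = f"Gr. {taxon}{per_taxon_counter[taxon]}"
        groups.append(
            HaplotypeGroup(
                group_id=f"H{idx + 1:04d}",
                p6_seq=seq,
                members=frozenset(spp),
                label=label,
                label_rank=rank,
            )
        )
    return groups


def groups_to_frame(groups: list[HaplotypeGroup]) -> pd.DataFrame:
    """Tabular view of haplotype groups (one row per group)."""
    rows = [
        {
            "group_id": g.group_id,
            "label": g.label,
            "label_rank": g.label_rank,
            "n_members": len(g.members),
            "members": ";".join(sorted(g.members)),
            "p6_seq": g.p6_seq,
        }
        for g in groups
    ]
    return pd.DataFrame(
        rows, columns=["group_id", "label", "label_rank", "n_members", "members", "p6_seq"]
    )


# ----------------------------------------------------------------------
# discrimination statistics
# ----------------------------------------------------------------------

def discrimination_rates(groups: list[HaplotypeGroup], tax: Taxonomy) -> DiscriminationReport:
    """Species/genus/family discrimination rates of a reference database.

    * Rs = 100 x (distinct haplotypes) / (species with a sequence).
    * Rf(family) = 100 x (distinct haplotypes among that family's species)
      / (species in the family).
    * Rg = 100 x (genera possessing at least one genus-exclusive haplotype,
      i.e. a haplotype found in no other genus) / (total genera).

    All rates are rounded half-up to integer percent.
    """
    if not groups:
        raise ReferenceError("empty database")

    species = sorted({s for g in groups for s in g.members})
    genera = sorted({tax.genus_of(s) for s in species})
    families = sorted({tax.family_of(s) for s in species})

    n_species = len(species)
    n_distinct = len(groups)
    rs = round_half_up(100.0 * n_distinct / n_species)

    rf: dict[str, int] = {}
    counts: dict[str, tuple[int, int]] = {}
    for fam in families:
        fam_species = [s for s in species if tax.family_of(s) == fam]
        fam_seqs = {g.p6_seq for g in groups if any(s in g.members for s in fam_species)}
        rf[fam] = round_half_up(100.0 * len(fam_seqs) / len(fam_species))
        counts[fam] = (len(fam_species), len(fam_seqs))

    resolved_genera = set()
    for g in groups:
        member_genera = {tax.genus_of(s) for s in g.members}
        if len(member_genera) == 1:
            resolved_genera.add(next(iter(member_genera)))
    rg = round_half_up(100.0 * len(resolved_genera) / len(genera))

    return DiscriminationReport(
        Rs=rs,
        Rg=rg,
        Rf_by_family=rf,
        n_species=n_species,
        n_genera=len(genera),
        n_families=len(families),
        n_distinct_sequences=n_distinct,
        per_family_counts=counts,
    )
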