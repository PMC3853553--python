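"""Synthetic taxonomies, reference databases, diets, and MID-tagged reads
with known ground truth, so every pipeline stage is testable end to end.

The generator mirrors the statistical shape of a local-flora P6-loop diet
study: a reference database of 222 species in 175 genera and 76 families
collapsing to 167 distinct haplotypes of 66-148 bp; 48 fecal samples split
over two islands with per-sample read depths around 743 +/- 338; strongly
skewed multi-taxon diets with one dominant shared food item; and reads
built as MID tag + forward primer + haplotype copy (with i.i.d.
substitution errors) + reverse-complemented reverse primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import revcomp
from .reads import MIDMap, RawRead
from .reference import (
    PRIMER_G,
    PRIMER_H,
    DiscriminationReport,
    HaplotypeGroup,
    ReferenceSequence,
    build_haplotype_groups,
    discrimination_rates,
)
from .taxonomy import Taxonomy

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the shape of
    a two-island fecal metabarcoding survey (see module docstring)."""

    seed: int = 0
    # reference database shape
    n_families: int = 76
    n_genera: int = 175
    n_species: int = 222
    n_distinct: int = 167  # realized number of distinct haplotypes
    p6_length_range: tuple[int, int] = (66, 148)
    flank_length: int = 40
    p_introduced: float = 0.3
    p_within_genus_collapse: float = 0.5  # collapse partner drawn within genus when possible
    # sampling design
    islands: tuple[str, ...] = ("Chichijima", "Hahajima")
    samples_per_island: int = 24
    months: tuple[str, ...] = (
        "2010-09", "2010-10", "2010-11", "2010-12", "2011-01",
        "2011-02", "2011-03", "2011-04", "2011-05",
    )
    # diet structure
    taxa_pool_size: int = 20
    island_disjoint_fraction: float = 0.3
    richness_mean: float = 6.7
    richness_sd: float = 2.7
    diet_alpha: float = 0.3
    dominant_taxon: bool = True
    dominant_min_fraction: float = 0.35
    # sequencing
    depth_mean: float = 743.0
    depth_sd: float = 338.0
    depth_min: int = 50
    error_rate: float = 0.01
    indel_rate: float = 0.0
    efficiency_bias: dict[str, float] | None = None
    mid_length: int = 10

    def __post_init__(self):
        lo, hi = self.p6_length_range
        if not (50 <= lo <= hi <= 200):
            raise SimulationError("p6_length_range must lie within [50, 200]")
        for p in (self.p_introduced, self.error_rate, self.indel_rate,
                  self.island_disjoint_fraction, self.p_within_genus_collapse):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_min <= 0:
            raise SimulationError("depths must be positive")
        if not self.n_families <= self.n_genera <= self.n_species:
            raise SimulationError("need n_families <= n_genera <= n_species")
        if not 1 <= self.n_distinct <= self.n_species:
            raise SimulationError("n_distinct must lie in [1, n_species]")


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery checks."""

    diet_proportions: dict[str, dict[str, float]]  # sample -> label -> intended proportion
    read_counts: dict[str, dict[str, int]]  # sample -> label -> realized multinomial count
    read_sources: dict[str, str]  # read_id -> true haplotype-group label
    haplotype_species: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, cfg.seed])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ----------------------------------------------------------------------
# reference database
# ----------------------------------------------------------------------

def _partition(total: int, bins: int, rng: np.random.Generator) -> np.ndarray:
    """Random sizes >= 1 per bin summing to total."""
    extra = rng.multinomial(total - bins, np.full(bins, 1.0 / bins))
    return extra + 1


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[Taxonomy, list[ReferenceSequence], DiscriminationReport]:
    """Random taxonomy + reference set with a controlled haplotype collapse.

    Exactly ``cfg.n_distinct`` distinct P6 haplotypes are realized:
    starting from one unique haplotype per species, species are repeatedly
    merged onto the haplotype of another member of their family (within
    the genus with probability ``p_within_genus_collapse`` when possible)
    until the target count is reached.  The returned report is the
    database's own discrimination statistics, the construction's ground
    truth.
    """
    rng = _rng(cfg, 1)

    genera_per_family = _partition(cfg.n_genera, cfg.n_families, rng)
    species_per_genus = _partition(cfg.n_species, cfg.n_genera, rng)

    rows = []
    g_idx = 0
    for f in range(cfg.n_families):
        family = f"Family{f + 1:03d}"
        for _ in range(genera_per_family[f]):
            genus = f"Genus{g_idx + 1:03d}"
            for s in range(species_per_genus[g_idx]):
                rows.append(
                    {
                        "species_id": f"{genus}_sp{s + 1}",
                        "genus": genus,
                        "family": family,
                        "origin": "introduced" if rng.random() < cfg.p_introduced else "native",
                    }
                )
            g_idx += 1
    tax_table = pd.DataFrame(rows)
    tax = Taxonomy(tax_table)

    lo, hi = cfg.p6_length_range
    species = list(tax_table["species_id"])
    haplo: dict[str, str] = {}
    used: set[str] = set()
    for sp in species:
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        while seq in used:
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        used.add(seq)
        haplo[sp] = seq

    family_of = dict(zip(tax_table["species_id"], tax_table["family"]))
    genus_of = dict(zip(tax_table["species_id"], tax_table["genus"]))
    by_family: dict[str, list[str]] = {}
    for sp in species:
        by_family.setdefault(family_of[sp], []).append(sp)

    n_merge = cfg.n_species - cfg.n_distinct
    for _ in range(n_merge):
        counts: dict[str, int] = {}
        for seq in haplo.values():
            counts[seq] = counts.get(seq, 0) + 1
        candidates = [
            sp
            for sp in species
            if counts[haplo[sp]] == 1 and len(by_family[family_of[sp]]) > 1
        ]
        if not candidates:
            raise SimulationError("cannot reach requested n_distinct with this taxonomy shape")
        target = candidates[int(rng.integers(len(candidates)))]
        congeners = [
            sp for sp in by_family[family_of[target]]
            if sp != target and genus_of[sp] == genus_of[target]
        ]
        relatives = [sp for sp in by_family[family_of[target]] if sp != target]
        pool = congeners if congeners and rng.random() < cfg.p_within_genus_collapse else relatives
        donor = pool[int(rng.integers(len(pool)))]
        haplo[target] = haplo[donor]

    refs = []
    for sp in species:
        intron = (
            _random_seq(rng, cfg.flank_length)
            + PRIMER_G
            + haplo[sp]
            + revcomp(PRIMER_H)
            + _random_seq(rng, cfg.flank_length)
        )
        refs.append(ReferenceSequence(species_id=sp, intron_seq=intron, p6_seq=haplo[sp]))

    report = discrimination_rates(build_haplotype_groups(refs, tax), tax)
    return tax, refs, report


def reference_from_structure(
    structure: list[tuple[str, int, int]], cfg: SimulationConfig | None = None
) -> tuple[Taxonomy, list[ReferenceSequence]]:
    """Reference set with an exact per-family (n_species, n_haplotypes) layout.

    ``structure`` lists ``(family, n_species, n_haplotypes)`` rows, e.g. the
    printed per-family discrimination table of a published database.  Each
    family's species are split over exactly ``n_haplotypes`` shared
    haplotypes (the first haplotype takes the remainder); every species is
    placed in its own genus, so the layout pins Rs and Rf only.
    """
    cfg = cfg or SimulationConfig()
    rng = _rng(cfg, 7)
    lo, hi = cfg.p6_length_range
    rows = []
    refs = []
    used: set[str] = set()
    g = 0
    for family, n_species, n_haplotypes in structure:
        if not 1 <= n_haplotypes <= n_species:
            raise SimulationError(f"{family}: need 1 <= n_haplotypes <= n_species")
        seqs = []
        for _ in range(n_haplotypes):
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            while seq in used:
                seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            used.add(seq)
            seqs.append(seq)
        for s in range(n_species):
            g += 1
            genus = f"Genus{g:03d}"
            sp = f"{genus}_sp1"
            rows.append({"species_id": sp, "genus": genus, "family": family, "origin": "native"})
            # species i >= n_haplotypes all reuse the first haplotype
            seq = seqs[s] if s < n_haplotypes else seqs[0]
            intron = PRIMER_G + seq + revcomp(PRIMER_H)
            refs.append(ReferenceSequence(species_id=sp, intron_seq=intron, p6_seq=seq))
    return Taxonomy(pd.DataFrame(rows)), refs


# ----------------------------------------------------------------------
# diets and metadata
# ----------------------------------------------------------------------

def simulate_diet(
    cfg: SimulationConfig, groups: list[HaplotypeGroup]
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Per-sample diet proportions over haplotype groups, plus metadata.

    Each island draws a taxon pool of ``taxa_pool_size`` groups, of which a
    fraction ``island_disjoint_fraction`` is exclusive to the island.  Each
    sample picks a richness ~ N(richness_mean, richness_sd) subset of its
    island pool and Dirichlet(diet_alpha) proportions; in dominant-taxon
    mode one shared group is present everywhere at >= dominant_min_fraction
    of the diet, mimicking a single heavily amplified food item.
    """
    rng = _rng(cfg, 2)
    labels = [g.label for g in groups]
    n_excl = int(round(cfg.taxa_pool_size * cfg.island_disjoint_fraction))
    n_shared = cfg.taxa_pool_size - n_excl
    need = n_shared + n_excl * len(cfg.islands)
    if need > len(labels):
        raise SimulationError(f"need at least {need} haplotype groups for the island pools")
    chosen = list(rng.choice(len(labels), size=need, replace=False))
    shared = [labels[i] for i in chosen[:n_shared]]
    pools = {}
    for k, island in enumerate(cfg.islands):
        excl = [labels[i] for i in chosen[n_shared + k * n_excl : n_shared + (k + 1) * n_excl]]
        pools[island] = shared + excl
    dominant = shared[0] if (cfg.dominant_taxon and shared) else None

    diets: dict[str, dict[str, float]] = {}
    meta_rows = []
    sample_no = 0
    for island in cfg.islands:
        for _ in range(cfg.samples_per_island):
            sample_no += 1
            sid = f"S{sample_no:03d}"
            pool = pools[island]
            richness = int(np.clip(round(rng.normal(cfg.richness_mean, cfg.richness_sd)), 1, len(pool)))
            others = [t for t in pool if t != dominant]
            picked = list(rng.choice(len(others), size=min(richness, len(others)), replace=False))
            taxa = [others[i] for i in picked]
            props: dict[str, float] = {}
            if dominant is not None:
                p_dom = float(rng.uniform(cfg.dominant_min_fraction, 0.6))
                rest = rng.dirichlet(np.full(len(taxa), cfg.diet_alpha)) * (1 - p_dom)
                props[dominant] = p_dom
                for t, p in zip(taxa, rest):
                    props[t] = float(p)
            else:
                rest = rng.dirichlet(np.full(len(taxa), cfg.diet_alpha))
                for t, p in zip(taxa, rest):
                    props[t] = float(p)
            diets[sid] = props
            month = cfg.months[(sample_no - 1) % len(cfg.months)]
            meta_rows.append(
                {
                    "sample_id": sid,
                    "island": island,
                    "collection_date": f"{month}-15",
                    "collection_mode": "observed" if rng.random() < 35 / 48 else "nest_roost",
                    "host_confirmed": True,
                    "method": "barcoding",
                }
            )
    meta = pd.DataFrame(meta_rows)
    return diets, meta


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, sub_rate: float) -> str:
    if sub_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(
    cfg: SimulationConfig,
    diets: dict[str, dict[str, float]],
    groups: list[HaplotypeGroup],
) -> tuple[list[RawRead], MIDMap, GroundTruth]:
    """MID-tagged error-bearing amplicon reads drawn from per-sample diets.

    Depth per sample is truncated-normal (resampled until >= depth_min);
    reads are multinomial over diet proportions times the per-taxon
    efficiency bias (renormalized).  Each read is
    ``MID + primer_g + haplotype-with-substitutions + revcomp(primer_h)``.
    """
    rng = _rng(cfg, 3)
    seq_by_label = {g.label: g.p6_seq for g in groups}
    members_by_label = {g.label: tuple(sorted(g.members)) for g in groups}

    mids: dict[str, str] = {}
    used_tags: set[str] = set()
    for sid in diets:
        tag = _random_seq(rng, cfg.mid_length)
        while tag in used_tags:
            tag = _random_seq(rng, cfg.mid_length)
        used_tags.add(tag)
        mids[tag] = sid
    midmap = MIDMap(mids)
    tag_of = {s: t for t, s in mids.items()}

    reads: list[RawRead] = []
    truth = GroundTruth(
        diet_proportions={s: dict(p) for s, p in diets.items()},
        read_counts={},
        read_sources={},
        haplotype_species={g.label: members_by_label[g.label] for g in groups},
    )
    rev_tail = revcomp(PRIMER_H)
    for sid, props in diets.items():
        depth = 0
        while depth < cfg.depth_min:
            depth = int(round(rng.normal(cfg.depth_mean, cfg.depth_sd)))
        labels = list(props)
        weights = np.array([props[t] for t in labels], dtype=float)
        if cfg.efficiency_bias:
            weights = weights * np.array([cfg.efficiency_bias.get(t, 1.0) for t in labels])
        weights = weights / weights.sum()
        counts = rng.multinomial(depth, weights)
        truth.read_counts[sid] = {t: int(c) for t, c in zip(labels, counts)}
        r = 0
        for label, count in zip(labels, counts):
            template = seq_by_label[label]
            for _ in range(count):
                r += 1
                rid = f"{sid}_r{r:05d}"
                insert = _mutate(template, rng, cfg.error_rate)
                reads.append(RawRead(rid, tag_of[sid] + PRIMER_G + insert + rev_tail))
                truth.read_sources[rid] = label
    return reads, midmap, truth


def simulate_study(
    cfg: SimulationConfig,
) -> dict:
    """Full synthetic study bundle: reference, diets, reads, and truth."""
    tax, refs, report = simulate_reference(cfg)
    groups = build_haplotype_groups(refs, tax)
    diets, meta = simulate_diet(cfg, groups)
    reads, midmap, truth = simulate_reads(cfg, diets, groups)
    return {
        "config": cfg,
        "taxonomy": tax,
        "references": refs,
        "groups": groups,
        "expected_discrimination": report,
        "diets": diets,
        "metadata": meta,
        "reads": reads,
        "midmap": midmap,
        "truth": truth,
    }
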