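"""Reference database: P6 extraction, haplotype grouping, discrimination."""

import numpy as np
import pandas as pd
import pytest

from trnldiet._utils import mismatches, revcomp, round_half_up
from trnldiet.reference import (
    PRIMER_G,
    PRIMER_H,
    AmbiguousPrimerSiteError,
    ReferenceError,
    build_haplotype_groups,
    discrimination_rates,
    extract_p6,
)
from trnldiet.taxonomy import Taxonomy

from conftest import make_refs


def brute_force_extract(intron, fwd, rev, max_mm):
    """Independent oracle: scan all windows counting substitutions."""
    seq = intron.upper()
    rev_site = revcomp(rev)
    fwd_hits = [
        i
        for i in range(len(seq) - len(fwd) + 1)
        if sum(a != b for a, b in zip(seq[i : i + len(fwd)], fwd)) <= max_mm
    ]
    if not fwd_hits:
        return None
    start = fwd_hits[0] + len(fwd)
    rev_hits = [
        j
        for j in range(start, len(seq) - len(rev_site) + 1)
        if sum(a != b for a, b in zip(seq[j : j + len(rev_site)], rev_site)) <= max_mm
    ]
    if not rev_hits:
        return None
    return seq[start : rev_hits[0]]


class TestExtractP6:
    def test_exact_site_construction(self):
        intron = PRIMER_G + "ACGTACGT" + revcomp(PRIMER_H)
        assert extract_p6(intron, max_mismatch=0) == "ACGTACGT"

    def test_flanked_insert(self):
        intron = "TTTT" + PRIMER_G + "ACGTACGTGG" + revcomp(PRIMER_H) + "AAAA"
        assert extract_p6(intron) == "ACGTACGTGG"

    def test_no_primer_site(self):
        assert extract_p6("ACGT" * 30) is None

    def test_one_mismatch_tolerance(self):
        insert = "ACGTACGTCCGGTTAA"
        fwd_mut = "C" + PRIMER_G[1:]  # one substitution in the forward site
        intron = fwd_mut + insert + revcomp(PRIMER_H)
        assert extract_p6(intron, max_mismatch=0) is None
        got = extract_p6(intron, max_mismatch=1)
        assert got == insert
        assert got == brute_force_extract(intron, PRIMER_G, PRIMER_H, 1)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            insert = "".join(rng.choice(bases, size=rng.integers(10, 60)))
            flank = "".join(rng.choice(bases, size=20))
            intron = flank + PRIMER_G + insert + revcomp(PRIMER_H) + flank
            for mm in (0, 1, 2):
                assert extract_p6(intron, max_mismatch=mm) == brute_force_extract(
                    intron, PRIMER_G, PRIMER_H, mm
                )

    def test_ambiguous_forward_site_raises_with_positions(self):
        intron = PRIMER_G + "AAAA" + PRIMER_G + "CCCC" + revcomp(PRIMER_H)
        with pytest.raises(AmbiguousPrimerSiteError) as exc:
            extract_p6(intron)
        assert exc.value.positions == [0, len(PRIMER_G) + 4]

    def test_case_insensitive(self):
        intron = (PRIMER_G + "acgtacgt" + revcomp(PRIMER_H)).lower()
        assert extract_p6(intron) == "ACGTACGT"

    def test_n_matches_nothing_in_primer_site(self):
        intron = PRIMER_G[:-1] + "N" + "ACGTACGT" + revcomp(PRIMER_H)
        assert extract_p6(intron, max_mismatch=0) is None
        assert extract_p6(intron, max_mismatch=1) == "ACGTACGT"


class TestHaplotypeGroups:
    def test_all_distinct_yields_species_groups(self, small_taxonomy):
        refs = make_refs(
            {
                "Morus_australis": "ACGT" * 12,
                "Machilus_kobu": "TTGG" * 12,
                "Carex_hattoriana": "CCAA" * 12,
            }
        )
        groups = build_haplotype_groups(refs, small_taxonomy)
        assert len(groups) == 3
        assert all(g.label_rank == "species" for g in groups)
        assert {g.label for g in groups} == {
            "Morus_australis",
            "Machilus_kobu",
            "Carex_hattoriana",
        }

    def test_family_collapse_label(self):
        """Seven congener-free species sharing one haplotype group to the family."""
        rows = [(f"Sp{i}", f"Genus{i}", "Lauraceae", "native") for i in range(7)]
        tax = Taxonomy(pd.DataFrame(rows, columns=["species_id", "genus", "family", "origin"]))
        refs = make_refs({f"Sp{i}": "ACGTTGCA" * 9 for i in range(7)})
        groups = build_haplotype_groups(refs, tax)
        assert len(groups) == 1
        assert groups[0].label == "Gr. Lauraceae1"
        assert groups[0].label_rank == "family"
        assert groups[0].members == frozenset(f"Sp{i}" for i in range(7))

    def test_genus_level_collapse(self, small_taxonomy):
        refs = make_refs(
            {
                "Ficus_microcarpa": "AAGG" * 15,
                "Ficus_boninsimae": "AAGG" * 15,
                "Carex_hattoriana": "CCTT" * 15,
            }
        )
        groups = build_haplotype_groups(refs, small_taxonomy)
        by_label = {g.label: g for g in groups}
        assert len(groups) == 2
        assert by_label["Gr. Ficus1"].label_rank == "genus"
        assert by_label["Carex_hattoriana"].label_rank == "species"

    def test_group_numbering_by_first_appearance(self):
        rows = [(f"Sp{i}", f"G{i}", "Lauraceae", "native") for i in range(4)]
        tax = Taxonomy(pd.DataFrame(rows, columns=["species_id", "genus", "family", "origin"]))
        refs = make_refs(
            {"Sp0": "A" * 50, "Sp1": "A" * 50, "Sp2": "C" * 50, "Sp3": "C" * 50}
        )
        labels = [g.label for g in build_haplotype_groups(refs, tax)]
        assert labels == ["Gr. Lauraceae1", "Gr. Lauraceae2"]

    def test_duplicate_species_is_an_error(self, small_taxonomy):
        refs = make_refs({"Morus_australis": "ACGT" * 12})
        refs.append(refs[0])
        with pytest.raises(ReferenceError, match="duplicate"):
            build_haplotype_groups(refs, small_taxonomy)

    def test_singleton_iff_species_rank(self, default_study):
        for g in default_study["groups"]:
            assert (len(g.members) == 1) == (g.label_rank == "species")


class TestDiscriminationRates:
    def test_study_scale_species_rate(self):
        # 222 species collapsing to 167 distinct haplotypes -> Rs = 75
        assert round_half_up(100 * 167 / 222) == 75

    def test_every_species_distinct_gives_all_100(self, small_taxonomy):
        seqs = {sp: f"{'ACGT' * 12}{'AACC GGTT'.replace(' ', '')[i:i+2]}" for i, sp in enumerate(small_taxonomy.species)}
        groups = build_haplotype_groups(make_refs(seqs), small_taxonomy)
        rep = discrimination_rates(groups, small_taxonomy)
        assert rep.Rs == 100
        assert rep.Rg == 100
        assert all(v == 100 for v in rep.Rf_by_family.values())

    def test_seven_species_one_sequence_family_rf(self):
        rows = [(f"Sp{i}", f"G{i}", "Lauraceae", "native") for i in range(7)]
        tax = Taxonomy(pd.DataFrame(rows, columns=["species_id", "genus", "family", "origin"]))
        groups = build_haplotype_groups(make_refs({f"Sp{i}": "ACGT" * 20 for i in range(7)}), tax)
        rep = discrimination_rates(groups, tax)
        assert rep.Rf_by_family["Lauraceae"] == 14

    def test_rs_invariant_under_species_permutation(self, small_taxonomy, small_reference):
        refs, _ = small_reference
        rep_fwd = discrimination_rates(
            build_haplotype_groups(refs, small_taxonomy), small_taxonomy
        )
        rep_rev = discrimination_rates(
            build_haplotype_groups(refs[::-1], small_taxonomy), small_taxonomy
        )
        assert rep_fwd.Rs == rep_rev.Rs
        assert rep_fwd.Rf_by_family == rep_rev.Rf_by_family
        assert rep_fwd.Rg == rep_rev.Rg

    def test_merging_haplotypes_never_increases_rates(self, small_taxonomy):
        seqs = {
            "Morus_australis": "ACGT" * 12,
            "Ficus_microcarpa": "TTGG" * 12,
            "Ficus_boninsimae": "CCAA" * 12,
            "Machilus_kobu": "GGTT" * 12,
            "Neolitsea_aurata": "AATT" * 12,
            "Carex_hattoriana": "GGCC" * 12,
        }
        before = discrimination_rates(
            build_haplotype_groups(make_refs(seqs), small_taxonomy), small_taxonomy
        )
        merged = dict(seqs)
        merged["Ficus_boninsimae"] = merged["Ficus_microcarpa"]
        after = discrimination_rates(
            build_haplotype_groups(make_refs(merged), small_taxonomy), small_taxonomy
        )
        assert after.Rs <= before.Rs
        for fam in before.Rf_by_family:
            assert after.Rf_by_family[fam] <= before.Rf_by_family[fam]

    def test_empty_database_signals(self, small_taxonomy):
        with pytest.raises(ReferenceError, match="empty"):
            discrimination_rates([], small_taxonomy)

    def test_genus_exclusive_reading_of_rg(self, small_taxonomy):
        # the two Lauraceae genera share their only haplotype -> neither
        # resolved; Ficus species share within the genus -> still resolved
        seqs = {
            "Morus_australis": "ACGT" * 12,
            "Ficus_microcarpa": "TTGG" * 12,
            "Ficus_boninsimae": "TTGG" * 12,
            "Machilus_kobu": "GGCC" * 12,
            "Neolitsea_aurata": "GGCC" * 12,
            "Carex_hattoriana": "AACC" * 12,
        }
        rep = discrimination_rates(
            build_haplotype_groups(make_refs(seqs), small_taxonomy), small_taxonomy
        )
        # genera: Morus, Ficus, Machilus, Neolitsea, Carex -> 3 of 5 resolved
        assert rep.Rg == 60
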