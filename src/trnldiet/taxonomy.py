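"""Rank-tree taxonomy (species -> genus -> family -> root) with origin annotation.

The taxonomy underlying a local plant barcode database is a shallow tree:
every species belongs to exactly one genus, every genus to exactly one
family, and all families hang off an implicit above-family root.  Each
species additionally carries an *origin* flag recording whether it is
native to the study area or introduced.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

#: ordered ranks, lowest first
RANKS = ("species", "genus", "family", "above_family")

#: label used for the implicit root above the family rank
ROOT_LABEL = "Plantae"

ORIGINS = frozenset({"native", "introduced", "both"})


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomy tables."""


class Taxonomy:
    """Immutable species -> genus -> family lookup with origin annotation.

    Parameters
    ----------
    table:
        DataFrame with columns ``species_id``, ``genus``, ``family`` and
        ``origin`` (one row per species).

    Raises
    ------
    TaxonomyError
        If species ids are duplicated, a genus is claimed by two families,
        or an origin value is not one of ``native``/``introduced``/``both``.
    """

    def __init__(self, table: pd.DataFrame):
        required = ["species_id", "genus", "family", "origin"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise TaxonomyError(f"taxonomy table lacks columns: {missing}")
        table = table[required].astype(str).reset_index(drop=True)

        dup = table["species_id"][table["species_id"].duplicated()]
        if len(dup):
            raise TaxonomyError(f"duplicate species_id: {sorted(set(dup))}")

        fam_per_genus = table.groupby("genus")["family"].nunique()
        bad = fam_per_genus[fam_per_genus > 1]
        if len(bad):
            raise TaxonomyError(f"genus in multiple families: {list(bad.index)}")

        bad_origin = set(table["origin"]) - ORIGINS
        if bad_origin:
            raise TaxonomyError(f"unknown origin values: {sorted(bad_origin)}")

        self._table = table
        self._genus = dict(zip(table["species_id"], table["genus"]))
        self._family = dict(zip(table["species_id"], table["family"]))
        self._origin = dict(zip(table["species_id"], table["origin"]))

    # ------------------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def species(self) -> list[str]:
        return list(self._table["species_id"])

    @property
    def genera(self) -> list[str]:
        return sorted(set(self._table["genus"]))

    @property
    def families(self) -> list[str]:
        return sorted(set(self._table["family"]))

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._genus

    def __len__(self) -> int:
        return len(self._table)

    def genus_of(self, species_id: str) -> str:
        return self._genus[species_id]

    def family_of(self, species_id: str) -> str:
        return self._family[species_id]

    def origin_of(self, species_id: str) -> str:
        return self._origin[species_id]

    # ------------------------------------------------------------------
    def lca(self, species_ids: Iterable[str]) -> tuple[str, str]:
        """Lowest single taxon containing every listed species.

        Returns ``(label, rank)`` where rank is one of :data:`RANKS`.
        A single species gives ``(species_id, "species")``; species spanning
        two or more families give ``(ROOT_LABEL, "above_family")``.
        """
        ids = sorted(set(species_ids))
        if not ids:
            raise TaxonomyError("lca of an empty species set")
        unknown = [s for s in ids if s not in self._genus]
        if unknown:
            raise TaxonomyError(f"species not in taxonomy: {unknown}")
        if len(ids) == 1:
            return ids[0], "species"
        genera = {self._genus[s] for s in ids}
        if len(genera) == 1:
            return next(iter(genera)), "genus"
        families = {self._family[s] for s in ids}
        if len(families) == 1:
            return next(iter(families)), "family"
        return ROOT_LABEL, "above_family"

    def species_in(self, taxon: str, rank: str) -> set[str]:
        """All species contained in a named taxon at the given rank."""
        if rank == "species":
            if taxon not in self._genus:
                raise TaxonomyError(f"unknown species: {taxon}")
            return {taxon}
        if rank == "genus":
            return set(self._table.loc[self._table["genus"] == taxon, "species_id"])
        if rank == "family":
            return set(self._table.loc[self._table["family"] == taxon, "species_id"])
        if rank == "above_family":
            return set(self._table["species_id"])
        raise TaxonomyError(f"unknown rank: {rank}")

    def combined_origin(self, species_ids: Iterable[str]) -> str:
        """Origin of a species set: native / introduced / both."""
        origins = {self._origin[s] for s in species_ids}
        if "both" in origins or len(origins) > 1:
            return "both"
        return next(iter(origins))

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self._table.to_csv(path, sep="\t", index=False)
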