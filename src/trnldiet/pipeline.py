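"""End-to-end orchestration: demultiplex -> trim -> dereplicate -> cluster
-> filter -> assign -> diet metrics -> community statistics.

Every stage logs its input/output read counts, and the bundle's stage log
satisfies conservation at each boundary (reads in = reads routed +
rejected).  Identical configuration and inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import assign as _assign
from . import community, diet
from . import io as _io
from .config import RunConfig
from .reads import AlignmentScoring, demultiplex, process_sample
from .reference import build_haplotype_groups, discrimination_rates, extract_all, groups_to_frame

logger = logging.getLogger(__name__)


def build_reference_db(cfg: RunConfig):
    """Load the intron FASTA + taxonomy, extract P6 inserts, group, report."""
    refs = _io.read_reference_fasta(cfg.reference_fasta)
    tax = _io.read_taxonomy(cfg.taxonomy_tsv)
    extracted, failures = extract_all(
        refs,
        cfg.primer_fwd,
        cfg.primer_rev,
        cfg.max_primer_mismatch,
        (cfg.p6_length_min, cfg.p6_length_max),
    )
    groups = build_haplotype_groups(extracted, tax)
    report = discrimination_rates(groups, tax)
    return tax, extracted, groups, report, failures


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline described by ``cfg``; write all outputs.

    Returns the result bundle (tables, stats, logs) as a dict; everything
    is also written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tax, refs, groups, disc_report, ref_failures = build_reference_db(cfg)
    _io.write_tsv(groups_to_frame(groups), out / "haplotype_groups.tsv")
    _io.write_tsv(disc_report.to_frame(), out / "discrimination_report.tsv")

    reads = _io.read_sequences(cfg.reads_path)
    mids = _io.read_midmap(cfg.mids_tsv)
    meta = _io.read_metadata(cfg.metadata_tsv)
    if len(reads) == 0:
        logger.warning("zero reads in input; producing empty outputs")

    bins, unrouted = demultiplex(reads, mids, cfg.max_mid_mismatch)

    scoring = AlignmentScoring()
    all_clusters = []
    discard_log: list[dict] = []
    reject_log: list[dict] = []
    stage_counts = {
        "reads_in": len(reads),
        "reads_routed": sum(len(v) for v in bins.values()),
        "reads_unassigned_mid": len(unrouted),
    }
    for sample_id, sample_reads in bins.items():
        res = process_sample(
            sample_id,
            sample_reads,
            identity_threshold=cfg.identity_threshold,
            min_length=cfg.min_cluster_length,
            min_reads=cfg.min_cluster_reads,
            primer_fwd=cfg.primer_fwd,
            primer_rev=cfg.primer_rev,
            max_primer_mismatch=cfg.max_primer_mismatch,
            primer_pass_through=cfg.primer_pass_through,
            scoring=scoring,
        )
        all_clusters.extend(res.clusters)
        discard_log.extend(res.discarded_clusters)
        reject_log.extend(res.rejected_reads)
    stage_counts["reads_rejected_preclustering"] = len(reject_log)
    stage_counts["reads_in_discarded_clusters"] = sum(d["read_count"] for d in discard_log)
    stage_counts["reads_in_retained_clusters"] = sum(c.read_count for c in all_clusters)

    _io.write_cluster_fasta(all_clusters, out / "clusters.fasta")
    _io.write_tsv(pd.DataFrame(discard_log), out / "discarded_clusters.tsv")
    _io.write_tsv(pd.DataFrame(reject_log), out / "rejected_reads.tsv")

    assignments, no_hit_reads = _assign.assign_all(
        all_clusters, groups, tax, cfg.min_identity, cfg.min_aligned, scoring
    )
    stage_counts["reads_without_hit"] = no_hit_reads
    assign_df = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "cluster_id": a.cluster_id,
                "label": a.assigned_label,
                "rank": a.assigned_rank,
                "reads": a.read_count,
                "best_identity": a.best_identity,
            }
            for a in assignments
        ]
    )
    _io.write_tsv(assign_df, out / "assignments.tsv")

    m = diet.build_diet_matrix(assignments)
    stats: dict = {"discrimination": {"Rs": disc_report.Rs, "Rg": disc_report.Rg}}
    if len(m) > 0:
        _io.write_tsv(m.reset_index(), out / "diet_matrix.tsv")

        micro = None
        if cfg.microhistology_tsv:
            micro = _io.read_presence_table(cfg.microhistology_tsv)
        report = diet.diet_report(m, tax, groups, micro)
        _io.write_tsv(report, out / "diet_report.tsv")

        monthly = diet.monthly_relative_frequency(m, meta, cfg.major_threshold)
        if len(monthly) > 0:
            _io.write_tsv(monthly.reset_index(), out / "monthly_frequency.tsv")

        richness, mean_rich, sd_rich = diet.taxa_per_sample(m)
        stats["taxa_per_sample"] = {"mean": mean_rich, "sd": sd_rich}

        meta_idx = meta.set_index("sample_id")
        if "island" in meta_idx.columns and len(m) >= 4:
            island = meta_idx.loc[m.index, "island"]
            if island.nunique() >= 2:
                stats["island_comparison"] = compare_islands(m, island, cfg)
                _io.write_tsv(
                    pd.DataFrame(
                        stats["island_comparison"]["ordination"]["coordinates"]
                    ).reset_index(names="sample_id"),
                    out / "nmds_coordinates.tsv",
                )

    with open(out / "stats.json", "w") as fh:
        json.dump(_jsonable({"stages": stage_counts, **stats}), fh, indent=2, sort_keys=True)

    return {
        "taxonomy": tax,
        "groups": groups,
        "discrimination": disc_report,
        "clusters": all_clusters,
        "assignments": assignments,
        "diet_matrix": m,
        "metadata": meta,
        "stats": {"stages": stage_counts, **stats},
        "reference_failures": ref_failures,
    }


def compare_islands(m: pd.DataFrame, island: pd.Series, cfg: RunConfig) -> dict:
    """Island contrast: pooled chi-square, Chao/Jaccard NMDS + ANOSIM."""
    pooled = m.groupby(island.values).sum().T  # labels x islands
    if cfg.chisq_mode == "presence":
        pres = (m > 0).astype(int)
        pooled = pres.groupby(island.values).sum().T
    x2, df, p_chi = community.pearson_chisq(pooled)

    grouping = dict(zip(m.index, island.values))
    result: dict = {"chisq": {"X2": x2, "df": df, "p": p_chi, "mode": cfg.chisq_mode}}
    for mode, metric in (("reads", "chao"), ("presence", "jaccard")):
        D = community.dissimilarity_matrix(m, metric=metric)
        ord_res = community.nmds(
            D, cfg.nmds_k, cfg.nmds_starts, cfg.nmds_max_iter, cfg.nmds_tol, seed=cfg.seed
        )
        an = community.anosim(D, grouping, cfg.anosim_permutations, seed=cfg.seed)
        result[mode] = {
            "metric": metric,
            "stress": ord_res.stress,
            "anosim_R": an.R,
            "anosim_p": an.p,
        }
        if mode == "presence":
            result["ordination"] = {
                "coordinates": ord_res.coordinates.to_dict(),
                "stress": ord_res.stress,
            }
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
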