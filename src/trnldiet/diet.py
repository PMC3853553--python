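"""Diet summaries from taxon assignments: read/presence frequencies,
per-sample richness, method comparison, and monthly composition.

Two complementary frequency measures are standard in metabarcoding diet
work.  The frequency of reads F_R of a food item is its read count over
all assigned reads (read proportions are PCR-biased, so F_R is treated as
semi-quantitative); the frequency of presence F_P is the fraction of
samples containing the item, which is robust to amplification bias.  Both
are reported as percentages rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up
from .assign import TaxonAssignment
from .reference import HaplotypeGroup
from .taxonomy import Taxonomy


class DietError(ValueError):
    pass


# ----------------------------------------------------------------------
# matrix construction
# ----------------------------------------------------------------------

def build_diet_matrix(assignments: list[TaxonAssignment]) -> pd.DataFrame:
    """Samples x labels read-count matrix from per-cluster assignments.

    Clusters of the same sample assigned to the same label are summed into
    one cell.  Unassigned clusters are excluded (their reads are tallied
    separately by the assignment stage).
    """
    rows = [
        {"sample_id": a.sample_id, "label": a.assigned_label, "reads": a.read_count}
        for a in assignments
        if a.assigned_rank != "unassigned"
    ]
    if not rows:
        return pd.DataFrame(dtype=int)
    df = pd.DataFrame(rows)
    m = df.pivot_table(index="sample_id", columns="label", values="reads", aggfunc="sum", fill_value=0)
    m.columns.name = None
    m.index.name = "sample_id"
    return m.astype(int)


def presence_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """0/1 presence view of a read-count matrix."""
    return (m > 0).astype(int)


# ----------------------------------------------------------------------
# frequencies
# ----------------------------------------------------------------------

def frequency_of_reads(m: pd.DataFrame) -> pd.Series:
    """F_R percent per label: reads of the label over all assigned reads.

    The denominator is the sum of assigned reads only.  Values are rounded
    half-up to 2 decimals and sorted by decreasing frequency.
    """
    totals = m.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise DietError("no assigned reads")
    fr = totals.astype(float) / float(grand) * 100.0
    fr = fr.map(lambda v: round_half_up(v, 2))
    return fr.sort_values(ascending=False, kind="stable")


def frequency_of_presence(m: pd.DataFrame, denominator: int) -> pd.Series:
    """F_P percent per label: samples containing the label over ``denominator``.

    The denominator is explicit because different detection methods may
    have analysed different numbers of samples from the same collection.
    """
    if denominator <= 0:
        raise DietError("denominator must be positive")
    present = (m > 0).sum(axis=0)
    fp = present.astype(float) / float(denominator) * 100.0
    return fp.map(lambda v: round_half_up(v, 2)).sort_values(ascending=False, kind="stable")


# ----------------------------------------------------------------------
# richness and method comparison
# ----------------------------------------------------------------------

def taxa_per_sample(m: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Per-sample count of detected food items, with mean and sample SD (n-1)."""
    richness = (m > 0).sum(axis=1)
    mean = float(richness.mean())
    sd = float(richness.std(ddof=1)) if len(richness) > 1 else float("nan")
    return richness, mean, sd


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_ttest(a, b) -> WelchResult:
    """Two-sided Welch unequal-variance t-test between richness vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DietError("need at least two observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def mean_reads_per_sample(depths) -> tuple[float, float]:
    """Mean and sample SD of per-sample read depths (sequencing bookkeeping)."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise DietError("no samples")
    sd = float(depths.std(ddof=1)) if depths.size > 1 else float("nan")
    return float(depths.mean()), sd


# ----------------------------------------------------------------------
# monthly composition
# ----------------------------------------------------------------------

def monthly_relative_frequency(
    m: pd.DataFrame, meta: pd.DataFrame, major_threshold: float = 0.10
) -> pd.DataFrame:
    """Month x label table of relative presence frequency for major items.

    Major food items are labels present in more than ``major_threshold``
    (fraction) of all samples in ``m``.  Per month, the relative frequency
    of a major label is its presence count over the summed presence counts
    of all major labels that month; month rows therefore sum to 1.  Months
    with no samples (or no major-label detections) are omitted.  Months are
    taken as the calendar year-month of ``collection_date`` (ISO dates), so
    the same month of different years stays distinct.
    """
    if "collection_date" not in meta.columns:
        raise DietError("metadata lacks collection_date")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    present = (m > 0).astype(int)
    overall = present.sum(axis=0) / len(m)
    major = overall.index[overall > major_threshold]
    if len(major) == 0:
        return pd.DataFrame()
    months = meta.loc[m.index, "collection_date"].astype(str).str[:7]
    counts = present[major].groupby(months.values).sum()
    counts = counts.loc[counts.sum(axis=1) > 0]
    rel = counts.div(counts.sum(axis=1), axis=0)
    rel.index.name = "month"
    return rel.sort_index()


# ----------------------------------------------------------------------
# origin annotation and Table-style report
# ----------------------------------------------------------------------

def annotate_origin(
    labels, tax: Taxonomy, groups: list[HaplotypeGroup] | None = None
) -> pd.Series:
    """Origin (native / introduced / both) per assigned label.

    A species-level label maps to its own origin; a haplotype-group label
    ("Gr. ...") to the combined origin of its member species; a plain genus
    or family label (from tie lifting) to the combined origin of every
    database species in that taxon.
    """
    by_label = {g.label: g for g in groups} if groups else {}
    out = {}
    for label in labels:
        if label in tax:
            out[label] = tax.origin_of(label)
        elif label in by_label:
            out[label] = tax.combined_origin(by_label[label].members)
        else:
            for rank in ("genus", "family"):
                spp = tax.species_in(label, rank)
                if spp:
                    out[label] = tax.combined_origin(spp)
                    break
            else:
                out[label] = "both"
    return pd.Series(out, name="origin")


def diet_report(
    m: pd.DataFrame,
    tax: Taxonomy,
    groups: list[HaplotypeGroup] | None = None,
    micro_presence: pd.DataFrame | None = None,
    micro_denominator: int | None = None,
) -> pd.DataFrame:
    """Per-food-item summary: origin, read count, F_R, and F_P per method.

    ``micro_presence`` is an externally supplied samples x labels presence
    table from microhistological examination of the same collection; its
    own sample count (or an explicit ``micro_denominator``) is used for its
    presence frequencies, since the two methods may cover different sample
    subsets.
    """
    n_reads = m.sum(axis=0)
    fr = frequency_of_reads(m)
    fp = frequency_of_presence(m, len(m))
    origin = annotate_origin(fr.index, tax, groups)
    report = pd.DataFrame(
        {
            "label": fr.index,
            "origin": origin.loc[fr.index].values,
            "n_reads": n_reads.loc[fr.index].values,
            "F_R": fr.values,
            "F_P_barcoding": fp.loc[fr.index].values,
        }
    )
    if micro_presence is not None:
        denom = micro_denominator if micro_denominator is not None else len(micro_presence)
        fp_micro = frequency_of_presence(micro_presence, denom)
        report["F_P_microhistology"] = [
            fp_micro.get(label, 0.0) for label in report["label"]
        ]
    return report.reset_index(drop=True)
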