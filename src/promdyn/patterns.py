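"""The eight-category taxonomy of paired major/minor promoter dynamics.

Within one organ, every (major, minor) promoter pair of a gene is
assigned one of eight categories from the trend directions of the two
promoters — Up_Up, Up_Flat, Flat_Up, Down_Down, Down_Flat, Flat_Down,
Up_Down, Down_Up — or Unclassified when neither promoter is dynamic.
The gene-level trend (from the same regression machinery applied to
total gene expression) is carried along for reporting: in the idealized
taxonomy Up_* pairs belong to upregulated genes, Down_* to downregulated
ones and Up_Down/Down_Up to genes with stable overall expression, but
observed combinations are only flagged, never reassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import PromoterCatalog

__all__ = [
    "PAIR_CATEGORIES",
    "classify_pair",
    "trend_direction",
    "build_pattern_calls",
    "aggregate_categories",
    "relative_usage_trajectory",
    "coding_fraction",
]

PAIR_CATEGORIES = [
    "Up_Up", "Up_Flat", "Flat_Up",
    "Down_Down", "Down_Flat", "Flat_Down",
    "Up_Down", "Down_Up", "Unclassified",
]

_PAIR_MAP = {
    ("Up", "Up"): "Up_Up",
    ("Up", "Flat"): "Up_Flat",
    ("Flat", "Up"): "Flat_Up",
    ("Down", "Down"): "Down_Down",
    ("Down", "Flat"): "Down_Flat",
    ("Flat", "Down"): "Flat_Down",
    ("Up", "Down"): "Up_Down",
    ("Down", "Up"): "Down_Up",
    ("Flat", "Flat"): "Unclassified",
}

# which gene-level trend each category is expected to accompany
_EXPECTED_GENE_TREND = {
    "Up_Up": "Up", "Up_Flat": "Up", "Flat_Up": "Up",
    "Down_Down": "Down", "Down_Flat": "Down", "Flat_Down": "Down",
    "Up_Down": "Flat", "Down_Up": "Flat",
}


def classify_pair(major_trend: str, minor_trend: str) -> str:
    """Map a (major, minor) trend pair to its category."""
    try:
        return _PAIR_MAP[(major_trend, minor_trend)]
    except KeyError:
        raise ValueError(
            f"trends must be Up/Down/Flat, got ({major_trend!r}, {minor_trend!r})"
        ) from None


def trend_direction(fit_row: pd.Series) -> str:
    """Up / Down / Flat from a fit-result row (needs is_ddp, delta_fit)."""
    if not bool(fit_row["is_ddp"]):
        return "Flat"
    delta = fit_row["delta_fit"]
    if delta > 0:
        return "Up"
    if delta < 0:
        return "Down"
    return "Flat"


def build_pattern_calls(
    labels: pd.DataFrame,
    promoter_results: pd.DataFrame,
    gene_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One call per (major, minor) promoter pair of each gene.

    Parameters
    ----------
    labels : classification table from :func:`promdyn.activity.classify_promoters`.
    promoter_results : per-promoter fit table with is_ddp/direction
        (``DynamicPromoterDetector.results_``).
    gene_results : optional per-gene fit table (same layout, indexed by
        gene_id) supplying the gene-level trend.

    Pairs are formed between the gene's major promoter and every
    non-inactive minor promoter. ``consistent`` flags whether the
    observed gene trend matches the category's expected gene trend.
    """
    rows = []
    majors = labels[labels["label"] == "major"]
    minors = labels[labels["label"] == "minor"]
    gene_dir = (
        gene_results["direction"] if gene_results is not None else pd.Series(dtype=object)
    )
    for major_pid, major_row in majors.iterrows():
        gene_id = major_row["gene_id"]
        if major_pid not in promoter_results.index:
            continue
        major_trend = promoter_results.loc[major_pid, "direction"]
        g_trend = gene_dir.get(gene_id, np.nan)
        for minor_pid, minor_row in minors[minors["gene_id"] == gene_id].iterrows():
            if minor_pid not in promoter_results.index:
                continue
            minor_trend = promoter_results.loc[minor_pid, "direction"]
            category = classify_pair(major_trend, minor_trend)
            expected = _EXPECTED_GENE_TREND.get(category)
            consistent = (
                bool(g_trend == expected) if expected is not None and isinstance(g_trend, str)
                else np.nan
            )
            rows.append(
                {
                    "gene_id": gene_id,
                    "major_promoter_id": major_pid,
                    "minor_promoter_id": minor_pid,
                    "gene_trend": g_trend,
                    "major_trend": major_trend,
                    "minor_trend": minor_trend,
                    "category": category,
                    "consistent": consistent,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "major_promoter_id", "minor_promoter_id",
            "gene_trend", "major_trend", "minor_trend", "category", "consistent",
        ],
    )


def aggregate_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-category pair counts and gene counts.

    Pair count: number of (major, minor) pairs in the category. Gene
    count: number of distinct genes with at least one pair in the
    category — a gene with several minors can contribute to several
    categories.
    """
    pair_counts = {c: 0 for c in PAIR_CATEGORIES}
    gene_counts = {c: 0 for c in PAIR_CATEGORIES}
    if len(calls):
        pc = calls.groupby("category").size()
        gc = calls.groupby("category")["gene_id"].nunique()
        for c in PAIR_CATEGORIES:
            pair_counts[c] = int(pc.get(c, 0))
            gene_counts[c] = int(gc.get(c, 0))
    out = pd.DataFrame(
        {"n_pairs": pair_counts, "n_genes": gene_counts},
    )
    out.index.name = "category"
    return out


def relative_usage_trajectory(
    relative: pd.DataFrame,
    labels: pd.DataFrame,
    design: pd.DataFrame,
    genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-stage mean relative usage of major vs minor promoters.

    Genes are restricted to those with a major and at least one other
    quantifiable promoter (optionally further restricted to ``genes``).
    For each such gene and sample, the major fraction is the major
    promoter's relative activity and the minor fraction the sum over the
    remaining quantifiable promoters; the two sum to 1 whenever the gene
    is expressed. Stage means average over genes and replicate samples.
    """
    majors = labels[labels["label"] == "major"]
    gene_sizes = labels.groupby("gene_id").size()
    eligible = set(gene_sizes[gene_sizes >= 2].index) & set(majors["gene_id"])
    if genes is not None:
        eligible &= set(genes)
    if not eligible:
        return pd.DataFrame(columns=["major", "minor", "n_genes"])

    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    stage_of = design["time_ordinal"]
    major_rows = []
    minor_rows = []
    for gene_id in sorted(eligible):
        pids = labels.index[labels["gene_id"] == gene_id]
        major_pid = majors.index[majors["gene_id"] == gene_id][0]
        rel_g = relative.reindex(pids)
        major_frac = rel_g.loc[major_pid]
        minor_frac = rel_g.drop(index=major_pid).sum(min_count=1)
        # only samples where the gene is expressed (fractions defined)
        ok = major_frac.notna()
        major_rows.append(major_frac.where(ok).rename(gene_id))
        minor_rows.append(minor_frac.where(ok).rename(gene_id))
    major_df = pd.DataFrame(major_rows)
    minor_df = pd.DataFrame(minor_rows).fillna(0.0).where(major_df.notna())
    times = stage_of.reindex(major_df.columns).to_numpy()
    out = pd.DataFrame(
        {
            "major": major_df.T.groupby(times).mean().mean(axis=1),
            "minor": minor_df.T.groupby(times).mean().mean(axis=1),
            "n_genes": (major_df.T.groupby(times).count() > 0).sum(axis=1),
        }
    )
    out.index.name = "time_ordinal"
    return out.sort_index()


def coding_fraction(
    catalog: PromoterCatalog, calls: pd.DataFrame
) -> pd.Series:
    """Per category, the fraction of minor-promoter member transcripts
    whose biotype is protein_coding; NaN for categories with no
    transcripts."""
    biotypes = catalog.transcript_biotypes()
    promoter_tids = {p.promoter_id: p.transcript_ids for p in catalog}
    fracs = {}
    for cat in PAIR_CATEGORIES:
        sub = calls[calls["category"] == cat]
        tids: list[str] = []
        for pid in sub["minor_promoter_id"]:
            tids.extend(promoter_tids.get(pid, ()))
        if not tids:
            fracs[cat] = np.nan
            continue
        b = biotypes.reindex(tids)
        fracs[cat] = float((b == "protein_coding").mean())
    out = pd.Series(fracs, name="coding_fraction")
    out.index.name = "category"
    return out
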