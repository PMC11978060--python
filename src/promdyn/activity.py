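"""Normalization, promoter activity, and major/minor/inactive classification.

Absolute promoter activity is the log2 of depth-normalized unique
junction read counts, ``log2(count / size_factor + 1)``; size factors
are DESeq2-style median-of-ratios computed on the promoter count matrix.
Gene expression is the log2 of the summed normalized linear counts over
the gene's quantifiable promoters, and relative activity is each
promoter's fraction of that linear total.

Classification: the promoter with the highest mean absolute activity
across all samples is the gene's *major* promoter (provided that mean is
at least the inactivity threshold, default 0.25 on the log2 scale);
promoters with mean activity below the threshold are *inactive*; the
rest are *minor/alternative*. Ties at the maximum break toward the
5'-most promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation import PromoterCatalog

__all__ = [
    "ActivityNormalizer",
    "ActivityMatrix",
    "size_factors",
    "absolute_activity",
    "gene_expression",
    "relative_activity",
    "compute_activity",
    "classify_promoters",
    "multi_active_genes",
    "top_variance_promoters",
]

INACTIVE_THRESHOLD = 0.25
CONTRIBUTION_THRESHOLD = 0.10


@dataclass
class ActivityMatrix:
    """Absolute (log2) and relative (fractional) promoter activity plus
    gene-level expression and the per-sample size factors used."""

    absolute: pd.DataFrame
    relative: pd.DataFrame
    gene_expression: pd.DataFrame
    size_factors: pd.Series

    def to_dir(self, outdir: str | Path, prefix: str = "") -> None:
        outdir = Path(outdir)
        fmt = "%.10g"
        self.absolute.to_csv(
            outdir / f"{prefix}absolute_activity.tsv", sep="\t",
            index_label="promoter_id", float_format=fmt,
        )
        self.relative.to_csv(
            outdir / f"{prefix}relative_activity.tsv", sep="\t",
            index_label="promoter_id", float_format=fmt,
        )
        self.gene_expression.to_csv(
            outdir / f"{prefix}gene_expression.tsv", sep="\t",
            index_label="gene_id", float_format=fmt,
        )
        self.size_factors.rename("size_factor").to_csv(
            outdir / f"{prefix}size_factors.tsv", sep="\t",
            index_label="sample_id", float_format=fmt,
        )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2-style median-of-ratios size factors.

    The reference is the per-promoter geometric mean across samples;
    promoters with any zero or missing count are excluded from the
    reference set. Each sample's factor is the median over reference
    promoters of count/reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    complete = counts.dropna()
    positive = complete[(complete > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no promoter has positive counts in every sample; consider a "
            "pseudo-reference fallback (not enabled)"
        )
    log_ref = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_ref, axis=0)
    return pd.Series(
        np.exp(ratios.median(axis=0)), index=counts.columns, name="size_factor"
    )


def absolute_activity(
    counts: pd.DataFrame, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount); missing counts stay missing."""
    return np.log2(counts.div(factors, axis=1) + pseudocount)


def _linear_normalized(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts.div(factors, axis=1)


def gene_expression(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene_map: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per gene-sample: log2(pseudocount + sum of normalized linear counts
    over the gene's quantifiable promoters). Genes with no quantifiable
    promoter are absent."""
    lin = _linear_normalized(counts, factors)
    lin = lin.loc[lin.notna().any(axis=1)]
    if lin.empty:
        return pd.DataFrame(columns=counts.columns)
    totals = lin.groupby(gene_map.reindex(lin.index)).sum(min_count=1)
    totals.index.name = "gene_id"
    return np.log2(totals + pseudocount)


def relative_activity(
    counts: pd.DataFrame, factors: pd.Series, gene_map: pd.Series
) -> pd.DataFrame:
    """Each promoter's fraction of its gene's summed normalized linear
    counts; missing when the gene total is 0 or the promoter is
    non-quantifiable."""
    lin = _linear_normalized(counts, factors)
    genes = gene_map.reindex(lin.index)
    totals = lin.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = lin / totals.where(totals > 0)
    return rel


class ActivityNormalizer(BaseEstimator, TransformerMixin):
    """Depth normalization and log2 activity as a scikit-learn transformer.

    Parameters
    ----------
    gene_map : pandas.Series or None
        promoter_id -> gene_id mapping (e.g. ``catalog.gene_map()``).
        Required for :meth:`gene_expression_` computations and
        :meth:`relative_activity`.
    pseudocount : float, default 1.0
        Added inside the log2 so zero counts map to zero activity.

    Attributes
    ----------
    size_factors_ : pandas.Series
        Median-of-ratios per-sample factors estimated by :meth:`fit`.
    """

    def __init__(self, gene_map: pd.Series | None = None, pseudocount: float = 1.0):
        self.gene_map = gene_map
        self.pseudocount = pseudocount

    @classmethod
    def from_catalog(cls, catalog: PromoterCatalog, **kwargs) -> "ActivityNormalizer":
        return cls(gene_map=catalog.gene_map(), **kwargs)

    def fit(self, X: pd.DataFrame, y=None) -> "ActivityNormalizer":
        """Estimate per-sample size factors from the raw count table."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a promoters x samples DataFrame of counts")
        if (X.fillna(0) < 0).any().any():
            raise ValueError("counts must be non-negative")
        self.size_factors_ = size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Absolute (log2-scale) promoter activity."""
        self._check_fitted()
        return absolute_activity(X, self.size_factors_, self.pseudocount)

    def relative(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        self._need_gene_map()
        return relative_activity(X, self.size_factors_, self.gene_map)

    def gene_expression(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        self._need_gene_map()
        return gene_expression(X, self.size_factors_, self.gene_map, self.pseudocount)

    def activity_matrix(self, X: pd.DataFrame) -> ActivityMatrix:
        """All activity views at once."""
        return ActivityMatrix(
            absolute=self.transform(X),
            relative=self.relative(X),
            gene_expression=self.gene_expression(X),
            size_factors=self.size_factors_.copy(),
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "size_factors_"):
            raise RuntimeError("ActivityNormalizer is not fitted; call fit() first")

    def _need_gene_map(self) -> None:
        if self.gene_map is None:
            raise ValueError("this operation requires gene_map")


def compute_activity(
    counts: pd.DataFrame, gene_map: pd.Series, pseudocount: float = 1.0
) -> ActivityMatrix:
    """Fit an :class:`ActivityNormalizer` on ``counts`` and return all
    activity views."""
    norm = ActivityNormalizer(gene_map=gene_map, pseudocount=pseudocount)
    return norm.fit(counts).activity_matrix(counts)


def classify_promoters(
    absolute: pd.DataFrame,
    catalog: PromoterCatalog,
    inactive_threshold: float = INACTIVE_THRESHOLD,
) -> pd.DataFrame:
    """Label every quantifiable promoter major / minor / inactive.

    Returns a DataFrame indexed by promoter_id with columns gene_id,
    tss_rank, mean_activity, label. A gene has a major promoter iff its
    maximal mean activity is >= the threshold; the mean is taken over all
    samples, skipping missing values.
    """
    means = absolute.mean(axis=1, skipna=True)
    meta = catalog.to_frame().set_index("promoter_id")
    rows = []
    for gene_id, plist in catalog.by_gene().items():
        quantified = [
            p for p in plist if p.promoter_id in means.index
            and not np.isnan(means[p.promoter_id])
        ]
        if not quantified:
            continue
        best = max(
            quantified, key=lambda p: (means[p.promoter_id], -p.tss_rank)
        )
        major_id = best.promoter_id if means[best.promoter_id] >= inactive_threshold else None
        for p in quantified:
            m = means[p.promoter_id]
            if p.promoter_id == major_id:
                label = "major"
            elif m < inactive_threshold:
                label = "inactive"
            else:
                label = "minor"
            rows.append(
                {
                    "promoter_id": p.promoter_id,
                    "gene_id": gene_id,
                    "tss_rank": meta.loc[p.promoter_id, "tss_rank"],
                    "mean_activity": m,
                    "label": label,
                }
            )
    out = pd.DataFrame(
        rows, columns=["promoter_id", "gene_id", "tss_rank", "mean_activity", "label"]
    )
    return out.set_index("promoter_id")


def multi_active_genes(
    labels: pd.DataFrame,
    relative: pd.DataFrame,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD,
) -> set[str]:
    """Genes with >= 2 active (non-inactive) promoters each contributing
    more than ``contribution_threshold`` of the gene's expression on
    average."""
    rel_means = relative.mean(axis=1, skipna=True)
    active = labels[labels["label"] != "inactive"]
    qualifying = active[rel_means.reindex(active.index) > contribution_threshold]
    counts = qualifying.groupby("gene_id").size()
    return set(counts[counts >= 2].index)


def top_variance_promoters(absolute: pd.DataFrame, n: int) -> list[str]:
    """Promoters ranked by descending across-sample variance of absolute
    activity; the top ``n`` are returned (all, with a warning, if ``n``
    exceeds the promoter count)."""
    if absolute.shape[1] < 2:
        raise ValueError("variance ranking needs at least 2 samples")
    variances = absolute.var(axis=1, skipna=True).dropna()
    order = variances.sort_values(ascending=False, kind="stable")
    if n > len(order):
        warnings.warn(
            f"requested top {n} promoters but only {len(order)} available"
        )
        n = len(order)
    return list(order.index[:n])
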