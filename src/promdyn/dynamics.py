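"""Developmentally dynamic promoter (DDP) detection.

Each promoter's absolute activity is regressed on developmental time
with a cubic polynomial (ordinary least squares on standardized ordinal
time). Significance comes from the F-test of the full cubic against the
intercept-only model; Benjamini-Hochberg FDR is applied across all
fitted promoters of an organ. A promoter is a DDP iff its q-value is at
most ``alpha`` AND its goodness of fit R² is at least ``r2_min``
(default 0.3). Non-DDPs are "flat". The trend direction of a DDP is the
sign of the fitted activity difference between the last and first time
points.

This is a reduction of the maSigPro two-step procedure to the full-model
F-test plus the R² acceptance cutoff; stepwise term selection is
deliberately not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DynamicPromoterDetector",
    "fit_timecourse",
    "call_ddps",
    "bootstrap_trajectory",
    "stage_mean_profiles",
    "compare_ddp_vs_flat",
]

R2_MIN = 0.3
ALPHA = 0.05
DEGREE = 3

RESULT_COLUMNS = [
    "beta0", "beta1", "beta2", "beta3",
    "r_squared", "p_value", "n_obs", "delta_fit", "skip_reason",
]


def _standardize(t: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(t))
    sd = float(np.std(t))
    if sd == 0:
        sd = 1.0
    return (t - mu) / sd, mu, sd


def fit_timecourse(
    times: np.ndarray, activities: np.ndarray, degree: int = DEGREE
) -> dict:
    """OLS polynomial fit of activity on standardized time.

    Returns a dict with the coefficients (beta0..beta<degree>, in the
    standardized-time basis), R², the F-test p-value against the
    intercept-only model, n_obs, and ``delta_fit`` = fitted(t_last) -
    fitted(t_first). Missing activities are dropped pairwise.

    Raises ValueError when fewer than ``degree + 1`` distinct time points
    remain.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(activities, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(t)
    t, y = t[keep], y[keep]
    n = len(y)
    n_params = degree + 1
    if len(np.unique(t)) < n_params:
        raise ValueError(
            f"cubic fit needs at least {n_params} distinct time points, "
            f"got {len(np.unique(t))}"
        )
    z, _, _ = _standardize(t)
    X = np.vander(z, N=n_params, increasing=True)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    if tss <= 0:
        # constant response: no variance to explain
        r2, pval = 0.0, 1.0
        beta = np.r_[np.mean(y), np.zeros(degree)]
        fitted = X @ beta
    else:
        r2 = 1.0 - rss / tss
        df_model, df_resid = degree, n - n_params
        if df_resid <= 0:
            pval = np.nan
        elif rss <= 1e-300:
            pval = 0.0
        else:
            f_stat = ((tss - rss) / df_model) / (rss / df_resid)
            pval = float(stats.f.sf(f_stat, df_model, df_resid))
    i_first, i_last = int(np.argmin(t)), int(np.argmax(t))
    delta = float(fitted[i_last] - fitted[i_first])
    out = {f"beta{i}": float(beta[i]) for i in range(n_params)}
    out.update(
        r_squared=float(r2), p_value=float(pval), n_obs=int(n), delta_fit=delta
    )
    return out


def call_ddps(
    fits: pd.DataFrame, alpha: float = ALPHA, r2_min: float = R2_MIN
) -> pd.DataFrame:
    """Benjamini-Hochberg over all fitted promoters; annotate is_ddp and
    direction.

    ``fits`` must have columns p_value, r_squared, delta_fit (rows with
    missing p_value — skipped promoters — are labelled flat and excluded
    from FDR correction).
    """
    out = fits.copy()
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.any():
        _, q, _, _ = multipletests(
            out.loc[tested, "p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        out.loc[tested, "q_value"] = q
    out["is_ddp"] = (
        tested & (out["q_value"] <= alpha) & (out["r_squared"] >= r2_min)
    )
    direction = np.where(
        ~out["is_ddp"], "Flat",
        np.where(out["delta_fit"] > 0, "Up",
                 np.where(out["delta_fit"] < 0, "Down", "Flat")),
    )
    out["direction"] = direction
    return out


class DynamicPromoterDetector(BaseEstimator):
    """Cubic time-course regression screen as a scikit-learn estimator.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree of the time trend.
    alpha : float, default 0.05
        FDR level for the Benjamini-Hochberg-adjusted F-test p-values.
    r2_min : float, default 0.3
        Minimum goodness of fit for a promoter to be called dynamic.
    min_fraction_present : float, default 0.7
        Promoters observed in fewer than this fraction of the organ's
        samples are skipped (reason recorded), not fitted.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per input promoter: coefficients, r_squared, p_value,
        q_value, n_obs, delta_fit, is_ddp, direction, skip_reason.
    ddp_ids_ : list of str
        Promoters called dynamic.
    """

    def __init__(
        self,
        degree: int = DEGREE,
        alpha: float = ALPHA,
        r2_min: float = R2_MIN,
        min_fraction_present: float = 0.7,
    ):
        self.degree = degree
        self.alpha = alpha
        self.r2_min = r2_min
        self.min_fraction_present = min_fraction_present

    def fit(self, X: pd.DataFrame, times) -> "DynamicPromoterDetector":
        """Fit every promoter's time course.

        Parameters
        ----------
        X : DataFrame, promoters x samples (one organ's samples).
        times : array-like of ordinal developmental time per sample
            (aligned with ``X.columns``).
        """
        t = np.asarray(times, dtype=float)
        if len(t) != X.shape[1]:
            raise ValueError("times must align with the sample columns of X")
        if len(np.unique(t)) < self.degree + 1:
            raise ValueError(
                f"need at least {self.degree + 1} distinct time points"
            )
        n_samples = X.shape[1]
        rows = []
        for pid, y in X.iterrows():
            yv = y.to_numpy(dtype=float)
            present = int(np.sum(~np.isnan(yv)))
            row: dict = {c: np.nan for c in RESULT_COLUMNS}
            row["skip_reason"] = ""
            if present < self.min_fraction_present * n_samples:
                row["skip_reason"] = (
                    f"only {present}/{n_samples} samples present"
                )
            else:
                try:
                    row.update(
                        fit_timecourse(t, yv, degree=self.degree)
                    )
                except ValueError as exc:
                    row["skip_reason"] = str(exc)
            rows.append(pd.Series(row, name=pid))
        fits = pd.DataFrame(rows)
        fits.index.name = "promoter_id"
        self.results_ = call_ddps(fits, alpha=self.alpha, r2_min=self.r2_min)
        self.ddp_ids_ = list(self.results_.index[self.results_["is_ddp"]])
        return self

    def predict(self, promoter_ids=None) -> pd.Series:
        """Trend direction per promoter (Up / Down / Flat)."""
        if not hasattr(self, "results_"):
            raise RuntimeError("call fit() first")
        d = self.results_["direction"]
        return d if promoter_ids is None else d.reindex(promoter_ids)


def stage_mean_profiles(
    activity: pd.DataFrame, stage_by_sample: pd.Series
) -> pd.DataFrame:
    """Average replicate samples per stage: promoters x stages (stages in
    ascending order of their ordinal value)."""
    stages = stage_by_sample.reindex(activity.columns)
    prof = activity.T.groupby(stages.to_numpy()).mean().T
    return prof[sorted(prof.columns)]


def bootstrap_trajectory(
    profiles: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Mean trajectory of a promoter group with a bootstrap band.

    Promoters (rows of ``profiles``, a promoters x stages matrix) are
    resampled with replacement ``n_boot`` times; the band is the
    2.5-97.5 percentile range of the resampled per-stage means.
    """
    if profiles.shape[0] == 0:
        raise ValueError("empty promoter group")
    rng = np.random.default_rng(seed)
    vals = profiles.to_numpy(dtype=float)
    point = np.nanmean(vals, axis=0)
    idx = rng.integers(0, vals.shape[0], size=(n_boot, vals.shape[0]))
    boot_means = np.nanmean(vals[idx, :], axis=1)  # n_boot x stages
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    lo = np.percentile(boot_means, lo_q, axis=0)
    hi = np.percentile(boot_means, hi_q, axis=0)
    return pd.DataFrame(
        {"mean": point, "lower": lo, "upper": hi}, index=profiles.columns
    )


def compare_ddp_vs_flat(
    profiles: pd.DataFrame, is_ddp: pd.Series
) -> pd.DataFrame:
    """Compare DDP vs flat promoters on per-promoter summary activity.

    For each promoter the max, mean and median of its per-stage activity
    profile are computed; the two groups are compared per metric with a
    two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns a DataFrame indexed by metric with columns statistic, p_value,
    n_ddp, n_flat, median_ddp, median_flat; all-NaN (with a warning) when
    either group is empty.
    """
    is_ddp = is_ddp.reindex(profiles.index).fillna(False).astype(bool)
    summaries = pd.DataFrame(
        {
            "max": profiles.max(axis=1),
            "mean": profiles.mean(axis=1),
            "median": profiles.median(axis=1),
        }
    )
    rows = {}
    for metric in summaries.columns:
        a = summaries.loc[is_ddp, metric].dropna()
        b = summaries.loc[~is_ddp, metric].dropna()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(
                f"DDP-vs-flat comparison for {metric!r}: a group is empty"
            )
            rows[metric] = dict(
                statistic=np.nan, p_value=np.nan, n_ddp=len(a), n_flat=len(b),
                median_ddp=np.nan, median_flat=np.nan,
            )
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows[metric] = dict(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_ddp=len(a),
            n_flat=len(b),
            median_ddp=float(a.median()),
            median_flat=float(b.median()),
        )
    out = pd.DataFrame(rows).T
    out.index.name = "metric"
    return out
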