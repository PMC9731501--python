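"""ROI metric extraction and test-retest reliability statistics.

Implements the reliability framework used to screen tracts: per-subject
coefficient of variation across visits, two-way mixed single-measure
consistency ICC(3,1) with parametric and two-level bootstrap confidence
intervals, pairwise Pearson correlation across visits, Tukey's
one-degree-of-freedom non-additivity test, and the >5%-COV-in-either-erosion
exclusion rule.

COV uses the sample (n-1) standard deviation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image import BinaryMask, GeometryError, Volume

__all__ = [
    "ROIMetrics",
    "roi_stats",
    "cov_percent",
    "cov_table",
    "icc_consistency",
    "bootstrap_icc",
    "pairwise_visit_correlation",
    "tukey_nonadditivity",
    "exclude_tracts",
]

HIST_BIN_WIDTH = 0.02  # default FA histogram bin width over [0, 1]
COV_CUTOFF = 5.0       # percent; exclusion rule threshold


@dataclass
class ROIMetrics:
    """Per-tract summary of an FA map inside a binary mask."""

    subject: str
    visit: str
    tract: str
    mean_fa: float
    sd_fa: float
    n_voxels: int
    volume_mm3: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    undefined: bool = False  # empty mask: statistics undefined, not NaN-poison

    def as_row(self) -> dict:
        return {
            "subject": self.subject,
            "visit": self.visit,
            "tract": self.tract,
            "mean_fa": self.mean_fa,
            "sd_fa": self.sd_fa,
            "n_voxels": self.n_voxels,
            "volume_mm3": self.volume_mm3,
            "undefined": self.undefined,
        }

    def hist_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tract": self.tract,
                "bin_left": self.hist_edges[:-1],
                "bin_right": self.hist_edges[1:],
                "count": self.hist_counts,
            }
        )


def roi_stats(
    fa: Volume,
    mask: BinaryMask,
    bin_width: float = HIST_BIN_WIDTH,
    subject: str = "",
    visit: str = "",
    tract: str = "",
) -> ROIMetrics:
    """Mean/SD FA, voxel count, physical volume and FA histogram over a mask.

    An empty mask yields count 0 with the ``undefined`` flag set (mean/SD
    are NaN but clearly marked, so downstream tables can drop them cleanly).
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    if not mask.same_grid(fa):
        raise GeometryError("FA map and mask are not on the same grid")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    vals = fa.data[mask.data]
    n = vals.size
    if n == 0:
        return ROIMetrics(
            subject, visit, tract, float("nan"), float("nan"), 0, 0.0,
            edges, np.zeros(len(edges) - 1, dtype=int), undefined=True,
        )
    counts, _ = np.histogram(vals, bins=edges)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return ROIMetrics(
        subject, visit, tract,
        float(vals.mean()), sd, int(n), float(n * mask.voxel_volume),
        edges, counts,
    )


def cov_percent(values) -> float:
    """Coefficient of variation (sample SD / mean) * 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("COV needs at least 2 values")
    m = v.mean()
    if abs(m) < 1e-300:
        raise ValueError("COV undefined for zero mean")
    return float(np.std(v, ddof=1) / m * 100.0)


def cov_table(
    metrics: pd.DataFrame, per: str = "fa", min_visits: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Per-tract COV summary of a tidy subject x visit x tract table.

    For each subject a COV is computed for every tract across its visits
    (one measure per subject per tract); tract-level values are the mean of
    these subject COVs, and the grand mean +/- SD across tracts is reported.
    Subjects with fewer than ``min_visits`` visits for a tract are dropped
    for that tract (logged in the returned summary dict).

    Parameters
    ----------
    metrics : DataFrame with columns subject, visit, tract and the value
        column (``mean_fa`` for per="fa", ``n_voxels`` for per="voxels").
    """
    col = {"fa": "mean_fa", "voxels": "n_voxels"}[per]
    df = metrics.copy()
    if "undefined" in df.columns:
        df = df[~df["undefined"].astype(bool)]
    dropped = []
    rows = []
    for (tract, subject), grp in df.groupby(["tract", "subject"], sort=True):
        vals = grp[col].to_numpy(dtype=float)
        if len(vals) < min_visits or abs(vals.mean()) < 1e-300:
            dropped.append((tract, subject))
            continue
        rows.append(
            {"tract": tract, "subject": subject, "cov": cov_percent(vals)}
        )
    per_subject = pd.DataFrame(rows)
    per_tract = (
        per_subject.groupby("tract", sort=True)["cov"]
        .agg(mean_cov="mean", n_subjects="count")
        .reset_index()
    )
    summary = {
        "grand_mean_cov": float(per_tract["mean_cov"].mean()),
        "grand_sd_cov": float(per_tract["mean_cov"].std(ddof=1))
        if len(per_tract) > 1
        else 0.0,
        "dropped": dropped,
        "per_subject": per_subject,
    }
    return per_tract, summary


# ---------------------------------------------------------------------------
# ICC(3,1): two-way mixed, single measure, consistency
# ---------------------------------------------------------------------------

def _two_way_ms(table: np.ndarray):
    """Row/error mean squares from a two-way ANOVA without interaction."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - gm) ** 2).sum()
    ssc = n * ((col_means - gm) ** 2).sum()
    sst = ((x - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, mse, n, k


def icc_consistency(table, alpha: float = 0.05):
    """ICC(3,1) with F statistic and parametric confidence interval.

    ``table`` is targets x raters (complete, rectangular).  Consistency form:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE); additive rater shifts are ignored.
    When the error variance is exactly zero the ICC is 1 with a degenerate
    CI, flagged in the returned dict.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a rectangular table with >=2 targets and >=2 raters")
    if not np.isfinite(x).all():
        raise ValueError("table must be complete (no missing cells)")
    msr, mse, n, k = _two_way_ms(x)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse <= 1e-12 * max(msr, 1e-30):  # zero error variance up to rounding
        return {
            "icc": 1.0, "F": float("inf"), "ci": (1.0, 1.0),
            "df": (df1, df2), "p": 0.0, "degenerate": True,
        }
    icc = (msr - mse) / (msr + (k - 1) * mse)
    F = msr / mse
    p = float(stats.f.sf(F, df1, df2))
    fu = stats.f.ppf(1 - alpha / 2, df1, df2)
    fl_q = stats.f.ppf(1 - alpha / 2, df2, df1)
    f_lower = F / fu
    f_upper = F * fl_q
    ci = (
        float((f_lower - 1) / (f_lower + k - 1)),
        float((f_upper - 1) / (f_upper + k - 1)),
    )
    return {
        "icc": float(icc), "F": float(F), "ci": ci,
        "df": (df1, df2), "p": p, "degenerate": False,
    }


def bootstrap_icc(
    table, n_boot: int = 10000, seed: int | None = None, alpha: float = 0.05
):
    """Two-level bootstrap percentile CI for ICC(3,1).

    Each replicate resamples targets (level 1) with replacement and then
    raters within the resampled table (level 2) with replacement; the ICC is
    recomputed per replicate and the (alpha/2, 1-alpha/2) percentiles form
    the CI.  A degenerate resample with a single distinct target is redrawn
    (counted in the result).  ``seed`` is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("seed is mandatory for bootstrap_icc")
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    rng = np.random.default_rng(seed)
    iccs = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            rows = rng.integers(0, n, size=n)
            if len(np.unique(rows)) >= 2:
                break
            redraws += 1
        cols = rng.integers(0, k, size=k)
        sub = x[np.ix_(rows, cols)]
        msr, mse, _, _ = _two_way_ms(sub)
        if mse <= 1e-12 * max(msr, 1e-30):
            iccs[i] = 1.0
        else:
            iccs[i] = (msr - mse) / (msr + (k - 1) * mse)
    lo, hi = np.percentile(iccs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {
        "ci": (float(lo), float(hi)),
        "n_boot": int(n_boot),
        "redraws": int(redraws),
        "icc_samples_mean": float(iccs.mean()),
    }


def pairwise_visit_correlation(
    metrics: pd.DataFrame, value_col: str = "mean_fa"
) -> pd.DataFrame:
    """Pearson r (with p) for every visit pair, pooled over tract x subject.

    Returns a tidy frame (visit_a, visit_b, r, p, n).  A visit with zero
    variance yields NaN r with a flag column set.
    """
    df = metrics.copy()
    if "undefined" in df.columns:
        df = df[~df["undefined"].astype(bool)]
    wide = df.pivot_table(
        index=["subject", "tract"], columns="visit", values=value_col
    )
    visits = list(wide.columns)
    rows = []
    for i, va in enumerate(visits):
        for vb in visits[i + 1:]:
            pair = wide[[va, vb]].dropna()
            a, b = pair[va].to_numpy(), pair[vb].to_numpy()
            if len(a) < 3:
                raise ValueError("need >=3 paired observations per visit pair")
            if a.std() < 1e-300 or b.std() < 1e-300:
                rows.append(
                    {"visit_a": va, "visit_b": vb, "r": float("nan"),
                     "p": float("nan"), "n": len(a), "degenerate": True}
                )
                continue
            r, p = stats.pearsonr(a, b)
            rows.append(
                {"visit_a": va, "visit_b": vb, "r": float(r), "p": float(p),
                 "n": len(a), "degenerate": False}
            )
    return pd.DataFrame(rows)


def tukey_nonadditivity(table):
    """Tukey's one-degree-of-freedom test for non-additivity.

    For a complete two-way layout with one replicate per cell, regresses the
    interaction residual on the product of row and column effects:
    SS_nonadd = (sum_ij x_ij a_i b_j)^2 / (sum a_i^2 * sum b_j^2) with
    a_i, b_j the centred row/column means; the F statistic has
    (1, (r-1)(c-1)-1) degrees of freedom.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("need >=3 rows and >=3 columns for non-additivity test")
    r, c = x.shape
    gm = x.mean()
    a = x.mean(axis=1) - gm
    b = x.mean(axis=0) - gm
    denom = (a**2).sum() * (b**2).sum()
    df2 = (r - 1) * (c - 1) - 1
    resid = x - gm - a[:, None] - b[None, :]
    ss_resid = (resid**2).sum()
    total_scale = ((x - gm) ** 2).sum() + 1e-300
    if denom < 1e-300 or ss_resid <= 1e-12 * total_scale:
        # exactly (or numerically) additive layout: no interaction to test
        return {"F": 0.0, "p": 1.0, "df": (1, df2)}
    num = (x * np.outer(a, b)).sum() ** 2 / denom
    ss_rem = ss_resid - num
    if ss_rem <= 1e-300:
        return {"F": float("inf"), "p": 0.0, "df": (1, df2)}
    F = num / (ss_rem / df2)
    return {"F": float(F), "p": float(stats.f.sf(F, 1, df2)), "df": (1, df2)}


def exclude_tracts(
    cov_by_tract: pd.DataFrame, cutoff: float = COV_CUTOFF
) -> tuple[list, list]:
    """Apply the reliability screen: exclude a tract iff its COV exceeds the
    cutoff (strict >) in *either* erosion condition.

    ``cov_by_tract`` has columns tract, cov_erode1, cov_erode2 (a missing
    condition column, or NaN entries, are evaluated on the available
    condition with a warning).  Returns (kept, excluded) tract name lists.
    """
    import warnings as _w

    df = cov_by_tract.copy()
    cond_cols = [c for c in ("cov_erode1", "cov_erode2") if c in df.columns]
    if not cond_cols:
        raise ValueError("need cov_erode1 and/or cov_erode2 columns")
    kept, excluded = [], []
    for _, row in df.iterrows():
        vals = [row[c] for c in cond_cols if np.isfinite(row[c])]
        if len(vals) < len(cond_cols) or len(cond_cols) < 2:
            _w.warn(
                f"tract {row['tract']}: only one erosion condition available",
                stacklevel=2,
            )
        if any(v > cutoff for v in vals):
            excluded.append(row["tract"])
        else:
            kept.append(row["tract"])
    return kept, excluded
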