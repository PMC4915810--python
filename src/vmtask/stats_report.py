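"""Non-parametric statistics, box-plot summaries and the group report.

All group comparisons use two-tailed Wilcoxon tests: the rank-sum
(Mann-Whitney) test for unpaired samples and the signed-rank test for
paired samples, switching from exact to normal-approximation p-values at
the documented thresholds. Box summaries report the median, quartiles
(linear interpolation) and Tukey whiskers (most extreme data within
1.5×IQR of the quartiles). Raw p-values are reported without
multiple-testing correction, matching common practice for this kind of
confirmatory within-design testing; the report footer says so.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Use the exact rank-sum null when n1*n2 is at most this and there are no ties.
EXACT_RANKSUM_MAX_PRODUCT = 400
#: Use the exact signed-rank null when n (after dropping zero diffs) <= this.
EXACT_SIGNED_RANK_MAX_N = 25

REPORT_FOOTER = (
    "Two-tailed Wilcoxon tests; raw p-values, no multiple-testing "
    "correction. Box stats: median, quartiles (linear interpolation), "
    "Tukey whiskers at 1.5 x IQR."
)


@dataclass
class BoxStats:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n: int


@dataclass
class ComparisonResult:
    """Outcome of a two-sample test.

    ``direction`` is the sign of (first sample median - second sample
    median); ``degenerate`` flags comparisons where the data admitted no
    test (all values identical / all differences zero), reported as p = 1.
    """

    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    direction: int
    degenerate: bool = False


def box_stats(values) -> BoxStats:
    """Median, quartiles and Tukey whiskers of a sample (n >= 1)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("box_stats needs at least one finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(in_fence.min()),
        whisker_hi=float(in_fence.max()),
        n=int(v.size),
    )


def _direction(x, y) -> int:
    return int(np.sign(np.median(x) - np.median(y)))


def rank_sum_test(x, y) -> ComparisonResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) test, unpaired.

    Exact null distribution when ``n1 * n2 <= 400`` and the pooled data
    have no ties; otherwise the normal approximation with tie and
    continuity corrections. Identical constant samples are degenerate
    (p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one value")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; rank-sum test degenerate",
                      stacklevel=2)
        return ComparisonResult("rank_sum", np.nan, 1.0, x.size, y.size, 0,
                                degenerate=True)
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= EXACT_RANKSUM_MAX_PRODUCT
                         and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return ComparisonResult(
        test="rank_sum",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
        direction=_direction(x, y),
    )


def signed_rank_test(x, y=None) -> ComparisonResult:
    """Two-tailed Wilcoxon signed-rank test for paired samples.

    With ``y`` given, tests the paired differences ``x - y``; zero
    differences are dropped first (Wilcoxon's rule) and at least two
    non-zero differences are required. Exact null when the remaining n is
    at most 25 and the absolute differences are untied; otherwise the
    normal approximation with continuity correction. All-zero differences
    are degenerate (p = 1).
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    n_pairs = d.size
    d_nz = d[d != 0]
    if d_nz.size == 0:
        warnings.warn("all paired differences are zero; test degenerate",
                      stacklevel=2)
        return ComparisonResult("signed_rank", np.nan, 1.0, n_pairs, n_pairs,
                                0, degenerate=True)
    if d_nz.size < 2:
        raise ValueError("need >= 2 non-zero paired differences")
    ties = np.unique(np.abs(d_nz)).size < d_nz.size
    method = "exact" if (d_nz.size <= EXACT_SIGNED_RANK_MAX_N and not ties) \
        else "approx"
    res = stats.wilcoxon(d_nz, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return ComparisonResult(
        test="signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=n_pairs,
        n2=n_pairs,
        direction=int(np.sign(np.median(d))),
    )


# ---------------------------------------------------------------------------
# Report assembly

ID_COLUMNS = ("cell_id", "mouse_id", "group", "projection_target")


def _metric_columns(cell_df: pd.DataFrame, metrics=None):
    if metrics is not None:
        return list(metrics)
    return [c for c in cell_df.columns
            if c not in ID_COLUMNS
            and pd.api.types.is_numeric_dtype(cell_df[c])]


def build_report(cell_df: pd.DataFrame, metrics=None) -> dict:
    """Descriptive and comparative tables for a recorded cohort.

    ``cell_df`` holds one row per cell with identifier columns
    (``cell_id``, ``mouse_id``, ``group``, ``projection_target``) and
    numeric metric columns; paired hit/miss metrics use matching
    ``<name>_hit`` / ``<name>_miss`` column pairs.

    Emitted comparisons, at both the cell and the mouse level:

    * S2-p vs M1-p within each training group (rank-sum), per metric;
    * good_performer vs naive within each projection target (rank-sum);
    * hit vs miss within each group x target (signed-rank), per pair.

    Missing groups skip their comparisons with a log entry. Returns
    ``{"descriptive": DataFrame, "comparisons": DataFrame, "footer": str}``.
    """
    from .evoked_analysis import aggregate_cells  # local: avoid cycle

    cols = _metric_columns(cell_df, metrics)
    paired = [(c, c[:-4] + "_miss") for c in cols
              if c.endswith("_hit") and c[:-4] + "_miss" in cols]

    desc_rows = []
    comp_rows = []
    levels = ("cell", "mouse")

    def mouse_means(df, value_cols):
        return df.groupby("mouse_id", as_index=False)[value_cols].mean()

    for (grp, tgt), sub in cell_df.groupby(["group", "projection_target"]):
        for level in levels:
            agg = aggregate_cells(sub, cols, level=level)
            agg["group"] = grp
            agg["projection_target"] = tgt
            desc_rows.append(agg)

    def add_unpaired(context, a_df, b_df, label_a, label_b):
        for level in levels:
            for col in cols:
                xa = (mouse_means(a_df, [col]) if level == "mouse" else a_df)
                xb = (mouse_means(b_df, [col]) if level == "mouse" else b_df)
                va = xa[col].dropna().to_numpy()
                vb = xb[col].dropna().to_numpy()
                if va.size < 1 or vb.size < 1:
                    logger.info("skipping %s %s at %s level: empty group",
                                context, col, level)
                    continue
                r = rank_sum_test(va, vb)
                comp_rows.append({
                    "comparison": context, "metric": col, "level": level,
                    "a": label_a, "b": label_b, "test": r.test,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "n1": r.n1, "n2": r.n2, "direction": r.direction,
                })

    for grp, sub in cell_df.groupby("group"):
        s2 = sub[sub["projection_target"] == "S2-p"]
        m1 = sub[sub["projection_target"] == "M1-p"]
        if len(s2) and len(m1):
            add_unpaired(f"S2-p vs M1-p ({grp})", s2, m1, "S2-p", "M1-p")
        else:
            logger.info("group %s lacks one projection target; skipped", grp)

    for tgt, sub in cell_df.groupby("projection_target"):
        gp = sub[sub["group"] == "good_performer"]
        nv = sub[sub["group"] == "naive"]
        if len(gp) and len(nv):
            add_unpaired(f"good_performer vs naive ({tgt})", gp, nv,
                         "good_performer", "naive")
        else:
            logger.info("target %s lacks one group; skipped", tgt)

    for (grp, tgt), sub in cell_df.groupby(["group", "projection_target"]):
        for hit_col, miss_col in paired:
            for level in levels:
                df = (mouse_means(sub, [hit_col, miss_col])
                      if level == "mouse" else sub)
                both = df[[hit_col, miss_col]].dropna()
                if len(both) < 2:
                    logger.info("hit/miss %s (%s %s, %s): too few pairs",
                                hit_col, grp, tgt, level)
                    continue
                r = signed_rank_test(both[hit_col].to_numpy(),
                                     both[miss_col].to_numpy())
                comp_rows.append({
                    "comparison": f"hit vs miss ({grp} {tgt})",
                    "metric": hit_col[:-4], "level": level,
                    "a": "hit", "b": "miss", "test": r.test,
                    "statistic": r.statistic, "p_value": r.p_value,
                    "n1": r.n1, "n2": r.n2, "direction": r.direction,
                })

    descriptive = (pd.concat(desc_rows, ignore_index=True)
                   if desc_rows else pd.DataFrame())
    comparisons = pd.DataFrame(comp_rows)
    return {"descriptive": descriptive, "comparisons": comparisons,
            "footer": REPORT_FOOTER}
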