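"""Cohort-level statistics for ERG metrics.

Per-eye b-wave (or FFF) metrics are aggregated into per-intensity
genotype-versus-wild-type comparisons: a two-tailed two-sample t-test (Student
pooled-variance by default, Welch available) and box-and-whisker summaries
with Tukey-hinge quartiles and whiskers at the data extremes.  Invalid
metrics (implicit times filtered outside 50–230 ms, failed extractions) are
excluded listwise and the exclusion counts reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateVarianceError(ValueError):
    """Both groups are constant: the t statistic is undefined."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary matching the study's box-and-whisker convention:
    Tukey-hinge quartiles, whiskers at the minimum and maximum (no fencing)."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int


def two_tailed_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "student",
) -> TTestResult:
    """Two-sided two-sample t-test; t is signed as mean(a) − mean(b).

    ``variant="student"`` pools the variances (classical equal-variance
    test); ``variant="welch"`` uses the Welch–Satterthwaite correction.
    Zero within-group variance raises instead of returning a meaningless p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va + vb == 0:
        raise DegenerateVarianceError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), variant=variant)


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    # medians of the lower/upper halves, each half including the middle
    # observation when n is odd
    n = sorted_values.size
    m = (n + 1) // 2
    return float(np.median(sorted_values[:m])), float(np.median(sorted_values[n - m:]))


def box_whisker_summary(values: Sequence[float]) -> BoxSummary:
    """Five-number summary with Tukey hinges and extreme whiskers."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("sample contains non-finite values")
    q1, q3 = _tukey_hinges(v)
    return BoxSummary(
        minimum=float(v[0]), q1=q1, median=float(np.median(v)), q3=q3,
        maximum=float(v[-1]), n=int(v.size),
    )


def summarize_cohort(
    metrics: pd.DataFrame,
    metric: str,
    reference: str = "WT",
    variant: str = "student",
    group_col: str = "genotype",
    intensity_col: str = "attenuation_log",
    valid_col: str = "valid",
) -> pd.DataFrame:
    """Per-intensity mutant-versus-reference comparison table.

    ``metrics`` is a tidy per-eye table (one row per recording) such as the
    output of :func:`ergkit.waveform.metrics_table`.  For each intensity step
    and each non-reference genotype the result holds group sizes, exclusion
    counts, means, mean difference and ratio, box summaries for both groups,
    and the two-tailed t-test.  Cells with fewer than two valid values on
    either side yield NaN test fields rather than an error.
    """
    if metric not in metrics.columns:
        raise ValueError(f"metric column {metric!r} not present")
    groups = list(dict.fromkeys(metrics[group_col]))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing from the data")
    others = [g for g in groups if g != reference]
    if not others:
        raise ValueError("at least one non-reference genotype is required")

    if valid_col in metrics.columns:
        ok = metrics[valid_col].astype(bool) & np.isfinite(metrics[metric])
    else:
        ok = np.isfinite(metrics[metric])

    rows = []
    for intensity, chunk in metrics.groupby(intensity_col, sort=True):
        ok_chunk = ok.loc[chunk.index]
        ref_all = chunk[chunk[group_col] == reference]
        ref_vals = ref_all.loc[ok_chunk.loc[ref_all.index], metric].to_numpy()
        for geno in others:
            mut_all = chunk[chunk[group_col] == geno]
            mut_vals = mut_all.loc[ok_chunk.loc[mut_all.index], metric].to_numpy()
            row: dict = {
                intensity_col: intensity,
                "comparison": f"{geno} vs {reference}",
                "genotype": geno,
                "reference": reference,
                "metric": metric,
                "n_ref": ref_vals.size,
                "n_mut": mut_vals.size,
                "n_excluded_ref": len(ref_all) - ref_vals.size,
                "n_excluded_mut": len(mut_all) - mut_vals.size,
                "mean_ref": float(np.mean(ref_vals)) if ref_vals.size else np.nan,
                "mean_mut": float(np.mean(mut_vals)) if mut_vals.size else np.nan,
            }
            row["mean_diff"] = row["mean_mut"] - row["mean_ref"]
            row["mean_ratio"] = (
                row["mean_mut"] / row["mean_ref"] if row["mean_ref"] else np.nan
            )
            if ref_vals.size >= 2 and mut_vals.size >= 2:
                try:
                    tt = two_tailed_t_test(mut_vals, ref_vals, variant)
                    row.update(t=tt.t, df=tt.df, p=tt.p, test_variant=tt.variant)
                except DegenerateVarianceError:
                    row.update(t=np.nan, df=np.nan, p=np.nan,
                               test_variant=f"{variant} (degenerate)")
            else:
                row.update(t=np.nan, df=np.nan, p=np.nan, test_variant="")
            for tag, vals in (("ref", ref_vals), ("mut", mut_vals)):
                if vals.size:
                    bx = box_whisker_summary(vals)
                    row.update({f"{tag}_min": bx.minimum, f"{tag}_q1": bx.q1,
                                f"{tag}_median": bx.median, f"{tag}_q3": bx.q3,
                                f"{tag}_max": bx.maximum})
                else:
                    row.update({f"{tag}_min": np.nan, f"{tag}_q1": np.nan,
                                f"{tag}_median": np.nan, f"{tag}_q3": np.nan,
                                f"{tag}_max": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)
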