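"""Segmentation metrics and truth-vs-predicted agreement statistics.

Covers the full evaluation protocol: per-class Dice / IoU / sensitivity /
specificity from confusion counts, RMSE / MAPE / Bland-Altman agreement,
two-sample Kolmogorov-Smirnov and Mann-Whitney U tests, a both-eyes
relative-error outlier filter, and a figure/table report bundle.

Conventions (documented because they matter for edge cases):

* Dice/IoU of two empty masks is 1 (perfect agreement); sensitivity of an
  empty reference is reported as NaN (undefined), likewise specificity of
  an all-foreground reference.
* Relative errors use the ground-truth value as denominator, matching the
  MAPE convention.
* All tests are two-sided; p-value methods are scipy's defaults (exact
  for small samples without ties, asymptotic otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClassMetrics:
    """Overlap metrics for one class; each in [0, 1] or NaN if undefined."""

    dice: float
    iou: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (math.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class AgreementStats:
    """Truth-vs-predicted agreement summary for one stratum."""

    n: int
    rmse: float
    mape: float          # fraction; NaN (flagged) if any truth value is 0
    mean_diff: float     # predicted - truth
    loa_lower: float     # mean_diff - 1.96 sd
    loa_upper: float     # mean_diff + 1.96 sd
    pearson_r: float
    mape_undefined: bool = False

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if not self.mape_undefined and self.mape < 0:
            raise ValueError("mape must be >= 0")
        if not (self.loa_lower <= self.mean_diff <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean difference")


@dataclass(frozen=True)
class DistributionTestResult:
    statistic: float
    p_value: float
    test: str  # "ks" | "mw"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def class_metrics(predicted: np.ndarray, truth: np.ndarray,
                  class_id: int) -> ClassMetrics:
    """Dice, IoU, sensitivity, specificity for one class from two label grids."""
    predicted, truth = np.asarray(predicted), np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {truth.shape}")
    p = predicted == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))

    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    iou = 1.0 if (tp + fp + fn) == 0 else tp / (tp + fp + fn)
    sens = float("nan") if (tp + fn) == 0 else tp / (tp + fn)
    spec = float("nan") if (tn + fp) == 0 else tn / (tn + fp)
    return ClassMetrics(dice=dice, iou=iou, sensitivity=sens, specificity=spec)


def agreement(truth: Sequence[float], predicted: Sequence[float]) -> AgreementStats:
    """RMSE, MAPE, Bland-Altman mean difference / limits, Pearson r."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and predicted must be 1D and paired")
    if t.size < 2:
        raise ValueError("agreement needs at least 2 pairs")
    d = p - t
    rmse = float(np.sqrt(np.mean(d ** 2)))
    mape_undef = bool(np.any(t == 0))
    if mape_undef:
        warnings.warn("truth contains zeros; MAPE undefined", stacklevel=2)
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(d) / np.abs(t)))
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(t, t[0]) or np.allclose(p, p[0]):
        r = float("nan")  # correlation undefined for constant input
    else:
        r = float(stats.pearsonr(t, p).statistic)
    return AgreementStats(n=t.size, rmse=rmse, mape=mape, mean_diff=mean_diff,
                          loa_lower=mean_diff - 1.96 * sd,
                          loa_upper=mean_diff + 1.96 * sd,
                          pearson_r=r, mape_undefined=mape_undef)


def ks_test(a: Sequence[float], b: Sequence[float]) -> DistributionTestResult:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    Statistic is the supremum ECDF discrepancy; the p-value uses scipy's
    default method (exact for small samples, asymptotic otherwise).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return DistributionTestResult(float(res.statistic), float(res.pvalue), "ks")


def mw_test(a: Sequence[float], b: Sequence[float]) -> DistributionTestResult:
    """Two-sample two-sided Mann-Whitney U test (midranks for ties).

    The reported U is for the first sample (so all-a-below-all-b gives
    U = 0); p-values are exact for small tie-free samples, otherwise the
    tie-corrected normal approximation (scipy default).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)  # report the smaller-orientation U
    return DistributionTestResult(u, float(res.pvalue), "mw")


# ---------------------------------------------------------------------------
# cohort tables


REQUIRED_COLUMNS = ("subject_id", "side", "truth", "predicted")


def filter_outliers(table: pd.DataFrame, threshold: float = 0.35) -> pd.DataFrame:
    """Flag subjects whose relative error exceeds the threshold in BOTH eyes.

    ``table`` needs columns subject_id / side / truth / predicted with one
    row per orbit.  A subject is excluded only when
    ``|predicted - truth| / truth > threshold`` for the right AND the left
    orbit; the returned copy carries ``relative_error`` and ``excluded``
    columns (the excluded=False subset is the "sorted" cohort).  Subjects
    missing a side are retained with a warning.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    out = table.copy()
    out["relative_error"] = (out["predicted"] - out["truth"]).abs() / out["truth"]
    out["excluded"] = False
    for sid, grp in out.groupby("subject_id"):
        sides = set(grp["side"])
        if not {"left", "right"} <= sides:
            warnings.warn(f"subject {sid} lacks both sides; skipped by the "
                          "outlier rule", stacklevel=2)
            continue
        if (grp.groupby("side")["relative_error"].max() > threshold).all():
            out.loc[out["subject_id"] == sid, "excluded"] = True
    return out


def stratum_summary(table: pd.DataFrame,
                    strata: Sequence[str] = ()) -> pd.DataFrame:
    """Per-stratum truth/predicted means, RMSE, MAPE and KS/MW p-values."""
    rows = []
    groups = table.groupby(list(strata)) if strata else [((), table)]
    for key, grp in groups:
        if len(grp) < 2:
            continue
        ag = agreement(grp["truth"], grp["predicted"])
        ks = ks_test(grp["truth"], grp["predicted"])
        mw = mw_test(grp["truth"], grp["predicted"])
        key = key if isinstance(key, tuple) else (key,)
        rows.append({
            **dict(zip(strata, key)),
            "n": len(grp),
            "truth_mean": grp["truth"].mean(), "truth_sd": grp["truth"].std(),
            "pred_mean": grp["predicted"].mean(), "pred_sd": grp["predicted"].std(),
            "rmse": ag.rmse, "mape": ag.mape,
            "ks_p": ks.p_value, "mw_p": mw.p_value,
        })
    return pd.DataFrame(rows)


def report(table: pd.DataFrame, out_dir: Path | str,
           strata: Sequence[str] = ("side",),
           value_label: str = "eyeball volume (cm3)",
           outlier_threshold: float = 0.35) -> dict:
    """Write the full agreement report: tables, QQ / Bland-Altman / KDE figures.

    Returns a dict with the summary DataFrames and figure paths.  Strata
    with fewer than two pairs are omitted with a notice.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flagged = filter_outliers(table, outlier_threshold)
    summary = stratum_summary(flagged, strata)
    sorted_summary = stratum_summary(flagged[~flagged["excluded"]], strata)
    summary.to_csv(out_dir / "summary.csv", index=False)
    sorted_summary.to_csv(out_dir / "summary_sorted.csv", index=False)

    t = flagged["truth"].to_numpy(float)
    p = flagged["predicted"].to_numpy(float)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    # QQ: quantiles of predicted against quantiles of truth
    qs = np.linspace(0.01, 0.99, min(len(t), 99))
    axes[0].plot(np.quantile(t, qs), np.quantile(p, qs), "o", ms=4)
    lim = [min(t.min(), p.min()), max(t.max(), p.max())]
    axes[0].plot(lim, lim, "k--", lw=1)
    axes[0].set_xlabel(f"truth quantiles, {value_label}")
    axes[0].set_ylabel("predicted quantiles")
    axes[0].set_title("QQ")
    # Bland-Altman
    mean_, diff = (t + p) / 2, p - t
    md, sd = diff.mean(), diff.std(ddof=1) if len(diff) > 1 else 0.0
    axes[1].plot(mean_, diff, "o", ms=4)
    for y, style in ((md, "-"), (md + 1.96 * sd, "--"), (md - 1.96 * sd, "--")):
        axes[1].axhline(y, color="k", ls=style, lw=1)
    axes[1].set_xlabel(f"mean of methods, {value_label}")
    axes[1].set_ylabel("predicted - truth")
    axes[1].set_title("Bland-Altman")
    # histogram + KDE
    kde_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arr, lab in ((t, "truth"), (p, "predicted")):
        axes[2].hist(arr, bins=12, alpha=0.35, density=True, label=lab)
        if np.std(arr) > 0:
            kde = stats.gaussian_kde(arr)
            span = arr.max() - arr.min()
            xs = np.linspace(arr.min() - span - 3, arr.max() + span + 3, 512)
            kde_curves[lab] = (xs, kde(xs))
            axes[2].plot(xs, kde(xs))
    axes[2].legend()
    axes[2].set_xlabel(value_label)
    axes[2].set_title("distribution + KDE")
    fig.tight_layout()
    fig_path = out_dir / "agreement.png"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)

    md_lines = [f"# Agreement report — {value_label}", "",
                f"{len(flagged)} orbit pairs; "
                f"{int(flagged['excluded'].sum())} rows excluded by the "
                f"both-eyes relative-error > {outlier_threshold} rule.", "",
                "## All data", summary.to_markdown(index=False), "",
                "## Sorted (outliers removed)",
                sorted_summary.to_markdown(index=False), ""]
    (out_dir / "report.md").write_text("\n".join(md_lines))
    return {"summary": summary, "sorted_summary": sorted_summary,
            "figure": fig_path, "table": flagged, "kde": kde_curves}
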