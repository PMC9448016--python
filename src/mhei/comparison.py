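"""Agreement analysis between two diet-quality indices on the same cohort.

Bland–Altman bias and 95% limits of agreement (bias ± 1.96 x SD of the
per-subject differences, sample SD with n-1 denominator), normal-theory
confidence intervals for the bias and both limits, Pearson correlation on
total scores, Spearman rank correlation per component, and Table-style
mean/SD/median/IQR summaries.

The difference direction is A - B with A the reference index; swapping the
inputs negates the bias and mirrors the limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedScores",
    "AgreementResult",
    "bland_altman",
    "correlations",
    "summarize",
    "bland_altman_plot",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class PairedScores:
    """Subject-aligned score vectors for two indices.

    ``a`` and ``b`` are total scores; ``components_a``/``components_b``
    optionally carry per-component score columns (same row order).
    """

    subject_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    components_a: pd.DataFrame | None = None
    components_b: pd.DataFrame | None = None
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.subject_ids) == len(self.a) == len(self.b)):
            raise ValueError("subject ids and score vectors must align")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return len(self.a)

    @classmethod
    def from_frames(
        cls,
        scores_a: pd.DataFrame,
        scores_b: pd.DataFrame,
        label_a: str = "A",
        label_b: str = "B",
    ) -> "PairedScores":
        """Pair two scores tables (scoring-module schema) on subject_id.

        Raises with the list of unmatched ids if the cohorts differ.
        """
        ia = scores_a.set_index("subject_id").sort_index()
        ib = scores_b.set_index("subject_id").sort_index()
        unmatched = sorted(set(ia.index) ^ set(ib.index))
        if unmatched:
            raise ValueError(f"unmatched subject ids: {unmatched}")
        comp_cols = [
            c for c in ia.columns if c not in ("total", "standards_id") and c in ib.columns
        ]
        return cls(
            subject_ids=list(ia.index),
            a=ia["total"].to_numpy(dtype=float),
            b=ib["total"].to_numpy(dtype=float),
            components_a=ia[comp_cols] if comp_cols else None,
            components_b=ib[comp_cols] if comp_cols else None,
            label_a=label_a,
            label_b=label_b,
        )


@dataclass
class AgreementResult:
    """Bland–Altman statistics and correlations for one paired score set."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    pearson_r: float | None = None
    spearman_rho: dict[str, float] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"statistic": "n", "value": self.n},
            {"statistic": "bias", "value": self.bias},
            {"statistic": "sd_diff", "value": self.sd_diff},
            {"statistic": "loa_low", "value": self.loa_low},
            {"statistic": "loa_high", "value": self.loa_high},
            {"statistic": "bias_ci_low", "value": self.bias_ci[0]},
            {"statistic": "bias_ci_high", "value": self.bias_ci[1]},
            {"statistic": "loa_low_ci_low", "value": self.loa_low_ci[0]},
            {"statistic": "loa_low_ci_high", "value": self.loa_low_ci[1]},
            {"statistic": "loa_high_ci_low", "value": self.loa_high_ci[0]},
            {"statistic": "loa_high_ci_high", "value": self.loa_high_ci[1]},
        ]
        if self.pearson_r is not None:
            rows.append({"statistic": "pearson_r_total", "value": self.pearson_r})
        for comp, rho in self.spearman_rho.items():
            rows.append({"statistic": f"spearman_rho_{comp}", "value": rho})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "bias_ci": list(self.bias_ci),
            "loa_low_ci": list(self.loa_low_ci),
            "loa_high_ci": list(self.loa_high_ci),
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
        }


def bland_altman(paired: PairedScores) -> AgreementResult:
    """Bias, 95% limits of agreement, and their confidence intervals.

    LOA use the literal 1.96 multiplier on the sample SD of the differences.
    CIs are normal-theory: bias ± t·SD/sqrt(n); each limit ± t·SD·sqrt(3/n),
    with t the 97.5th percentile of t(n-1).
    """
    n = paired.n
    if n < 2:
        raise InsufficientDataError("Bland–Altman requires at least 2 pairs")
    diff = paired.a - paired.b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    t = float(stats.t.ppf(0.975, n - 1))
    half_bias = t * sd / math.sqrt(n)
    half_loa = t * sd * math.sqrt(3.0 / n)
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_low_ci=(loa_low - half_loa, loa_low + half_loa),
        loa_high_ci=(loa_high - half_loa, loa_high + half_loa),
    )


def correlations(paired: PairedScores) -> AgreementResult:
    """Bland–Altman statistics plus Pearson r on totals and Spearman rho per
    component (average ranks for ties). Zero-variance vectors flag the
    correlation as ``nan`` rather than raising."""
    result = bland_altman(paired)
    if np.std(paired.a) == 0 or np.std(paired.b) == 0:
        result.pearson_r = math.nan
    else:
        result.pearson_r = float(stats.pearsonr(paired.a, paired.b).statistic)
    if paired.components_a is not None and paired.components_b is not None:
        for col in paired.components_a.columns:
            x = paired.components_a[col].to_numpy(dtype=float)
            y = paired.components_b[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                result.spearman_rho[col] = math.nan
            else:
                result.spearman_rho[col] = float(stats.spearmanr(x, y).statistic)
    return result


def summarize(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD and median (IQR) per component and total.

    Sample SD (n-1 denominator); IQR = Q3 - Q1 with linear-interpolation
    quantiles.
    """
    cols = [c for c in scores.columns if c not in ("subject_id", "standards_id")]
    rows = []
    for col in cols:
        x = scores[col].to_numpy(dtype=float)
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
        rows.append(
            {
                "component": col,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "median": float(np.median(x)),
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(
    paired: PairedScores,
    result: AgreementResult,
    path: str | Path,
    values_csv: str | Path | None = None,
) -> None:
    """Mean-vs-difference scatter with bias/LOA lines and marginal histograms.

    Purely presentational; all numbers come from :func:`bland_altman`. Also
    writes the plotted (mean, difference) values to ``values_csv`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if paired.n < 2:
        raise InsufficientDataError("nothing to plot: fewer than 2 pairs")
    mean = (paired.a + paired.b) / 2.0
    diff = paired.a - paired.b

    fig = plt.figure(figsize=(7, 6))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 5), hspace=0.05, wspace=0.05
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)

    ax.scatter(mean, diff, s=12, alpha=0.5, color="grey")
    ax.axhline(result.bias, color="tab:blue", label=f"bias {result.bias:.2f}")
    ax.axhline(result.loa_high, color="tab:green", linestyle="--",
               label=f"upper LOA {result.loa_high:.2f}")
    ax.axhline(result.loa_low, color="tab:red", linestyle="--",
               label=f"lower LOA {result.loa_low:.2f}")
    ax.set_xlabel(f"mean of {paired.label_a} and {paired.label_b}")
    ax.set_ylabel(f"{paired.label_a} − {paired.label_b}")
    ax.legend(loc="best", fontsize=8)
    ax_top.hist(mean, bins=30, color="grey")
    ax_top.axis("off")
    ax_right.hist(diff, bins=30, orientation="horizontal", color="grey")
    ax_right.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    if values_csv is not None:
        pd.DataFrame(
            {"subject_id": paired.subject_ids, "mean": mean, "difference": diff}
        ).to_csv(values_csv, index=False)
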