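"""Cohort-level results: descriptives, skewness, bootstrap CIs, frequency tables.

Per-patient cost is heavily right-skewed — a minority of patients (long
admissions, repeated opportunistic infections) consume a disproportionate
share of resources — so alongside mean/SD/min/max summaries the module
reports the adjusted Fisher-Pearson sample skewness and percentile-bootstrap
confidence intervals for arm mean costs, which stay valid without any
normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import COMPONENTS, CostBreakdown, round_half_up

__all__ = [
    "CohortSummary",
    "BootstrapResult",
    "OiFrequencyTable",
    "summarise",
    "summarise_cohort",
    "skewness",
    "bootstrap_mean_ci",
    "oi_frequency_table",
    "mortality_rate",
    "cost_ratio",
    "export_cost_histogram",
]


@dataclass(frozen=True)
class CohortSummary:
    """One descriptive row: mean, sample SD, min, max over n patients."""

    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    level: float
    seed: int


@dataclass(frozen=True)
class OiFrequencyTable:
    """Rows of (condition, count, percent of total count), in input order."""

    rows: tuple[tuple[str, float, float], ...]

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (cond, freq, round_half_up(pct, ndigits))
                for cond, freq, pct in self.rows
            ],
            columns=["condition", "frequency", "percent"],
        )

    def percent(self, condition: str) -> float:
        for cond, _, pct in self.rows:
            if cond == condition:
                return pct
        raise KeyError(condition)


def summarise(costs: Sequence[float]) -> CohortSummary:
    """Exact sample mean, SD (n-1 denominator), min and max of a cost list."""
    arr = np.asarray(list(costs), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty cost list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return CohortSummary(
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=int(arr.size),
    )


def summarise_cohort(
    cohort: Sequence[CostBreakdown], arm_label: str = ""
) -> pd.DataFrame:
    """Component x {mean, sd, min, max, n} table for one costed arm."""
    rows = []
    for comp in (*COMPONENTS, "total"):
        vals = [getattr(b, comp) for b in cohort]
        s = summarise(vals)
        rows.append(
            {
                "arm": arm_label,
                "component": comp,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.minimum,
                "max": s.maximum,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def skewness(costs: Sequence[float]) -> float:
    """Adjusted Fisher-Pearson sample skewness (the bias-corrected g1)."""
    arr = np.asarray(list(costs), dtype=float)
    if arr.size < 3:
        raise ValueError("skewness needs at least 3 observations")
    if arr.std(ddof=1) == 0:
        raise ValueError("skewness undefined for a constant sample")
    return float(stats.skew(arr, bias=False))


def bootstrap_mean_ci(
    costs: Sequence[float],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI for the mean cost; deterministic given the seed."""
    arr = np.asarray(list(costs), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty cost list")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_resamples, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return BootstrapResult(
        point_estimate=float(arr.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        level=level,
        seed=seed,
    )


def oi_frequency_table(
    causes: Iterable[str] | Mapping[str, float],
) -> OiFrequencyTable:
    """Tabulate condition counts and percents (percent_i = 100 f_i / sum f).

    Accepts either raw cause labels (counted in first-appearance order) or a
    precomputed condition -> count mapping (kept in its order).
    """
    if isinstance(causes, Mapping):
        counts = dict(causes)
    else:
        counts = {}
        for c in causes:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        raise ValueError("no conditions to tabulate")
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("total frequency must be positive")
    rows = tuple((cond, freq, 100.0 * freq / total) for cond, freq in counts.items())
    return OiFrequencyTable(rows=rows)


def mortality_rate(deaths: int, n: int) -> float:
    """Cumulative mortality as a percentage: 100 x deaths / n."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= deaths <= n:
        raise ValueError(f"deaths must lie in [0, {n}], got {deaths}")
    return 100.0 * deaths / n


def cost_ratio(summary_a: CohortSummary, summary_b: CohortSummary) -> float:
    """Ratio of mean costs between two summaries (a over b)."""
    if summary_b.mean == 0:
        raise ValueError("denominator mean cost is zero")
    return summary_a.mean / summary_b.mean


def export_cost_histogram(
    costs: Sequence[float], path, bins: int = 40, title: str = "Per-patient total cost"
) -> None:
    """Histogram of per-patient total cost (the cost-distribution figure analogue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(np.asarray(list(costs), dtype=float), bins=bins, color="#46658c")
    ax.set_xlabel("cost (US$)")
    ax.set_ylabel("patients")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
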