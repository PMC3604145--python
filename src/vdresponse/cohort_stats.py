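"""Cohort summaries, vitamin D status classification, and power analysis.

Serum 25-hydroxyvitamin D (25(OH)D, ng/ml) is the status marker:
deficiency is defined as a concentration strictly below 20 ng/ml.  The
power calculator uses the normal-approximation formula for a two-sided
two-sample comparison of means,

    N = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 * sigma^2 / delta^2 ),

with a floor of 2 subjects per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

DEFICIENCY_CUTOFF_NG_ML = 20.0

DEFICIENT = "deficient"
INSUFFICIENT_SUFFICIENT = "insufficient_sufficient"


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-group mean comparison.

    alpha : two-sided type-I error rate.
    power : 1 - beta.
    sd    : within-group standard deviation (log-expression units).
    delta : detectable difference in means, same units as ``sd``.
    """

    alpha: float = 0.05
    power: float = 0.80
    sd: float = 1.0
    delta: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0,1), got {self.power}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")


def classify_status(serum_25ohd: float) -> str:
    """Classify vitamin D status from baseline serum 25(OH)D (ng/ml).

    Deficient iff serum < 20 ng/ml (strict); exactly 20 is classified as
    insufficient/sufficient.
    """
    if serum_25ohd <= 0:
        raise ValueError(f"serum 25(OH)D must be positive, got {serum_25ohd}")
    if serum_25ohd < DEFICIENCY_CUTOFF_NG_ML:
        return DEFICIENT
    return INSUFFICIENT_SUFFICIENT


def serum_change(table1: pd.DataFrame) -> pd.Series:
    """Per-arm mean serum 25(OH)D change (after - before), ng/ml.

    Expects a demographics table with columns ``dose``,
    ``serum_before_mean`` and ``serum_after_mean`` (one row per arm).
    """
    for col in ("dose", "serum_before_mean", "serum_after_mean"):
        if col not in table1.columns:
            raise ValueError(f"missing column {col!r} in demographics table")
    change = table1["serum_after_mean"] - table1["serum_before_mean"]
    return pd.Series(change.to_numpy(), index=table1["dose"].to_numpy(), name="serum_change")


def weighted_group_mean(means, sizes) -> float:
    """Pooled mean of per-group means weighted by group size."""
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if means.shape != sizes.shape:
        raise ValueError(
            f"means and sizes differ in length ({means.size} vs {sizes.size})"
        )
    if np.any(sizes <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sum(means * sizes) / np.sum(sizes))


def sample_size(spec: PowerSpec) -> int:
    """Per-group N for a two-sided two-sample comparison of means.

    Normal-approximation formula with a floor of 2 per group.  An exact
    t-based iteration is available via :func:`sample_size_t`.
    """
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n = 2 * (z_a + z_b) ** 2 * spec.sd**2 / spec.delta**2
    return max(2, ceil(n))


def sample_size_t(spec: PowerSpec, max_iter: int = 100) -> int:
    """Per-group N using the noncentral-t power function (iterative)."""
    n = sample_size(spec)
    for _ in range(max_iter):
        df = 2 * (n - 1)
        ncp = spec.delta / (spec.sd * np.sqrt(2.0 / n))
        crit = stats.t.ppf(1 - spec.alpha / 2, df)
        achieved = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
        if achieved >= spec.power:
            return max(2, n)
        n += 1
    return max(2, n)


def delta_sweep(spec: PowerSpec, deltas) -> pd.DataFrame:
    """Per-group N over a range of detectable differences."""
    rows = [
        {"delta": float(d), "n_per_group": sample_size(
            PowerSpec(spec.alpha, spec.power, spec.sd, float(d)))}
        for d in deltas
    ]
    return pd.DataFrame(rows)


def cohort_summary(table1: pd.DataFrame) -> dict:
    """Headline cohort numbers pooled over dose arms."""
    sizes = table1["n"].to_numpy(dtype=float)
    out = {
        "n_total": int(sizes.sum()),
        "mean_age": weighted_group_mean(table1["age_mean"], sizes),
        "mean_serum_baseline": weighted_group_mean(
            table1["serum_before_mean"], sizes
        ),
    }
    change = serum_change(table1)
    for dose, val in change.items():
        out[f"serum_change_{int(dose)}"] = float(val)
    return out
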