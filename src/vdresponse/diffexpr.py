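"""Paired differential expression, subgroup contrasts, and qPCR concordance.

The supplementation contrast follows a split-plot two-way ANOVA: visit
(baseline vs follow-up) is a within-subject factor, dose arm (400 vs
2000 IU/day) a between-subject factor.  Visit and visit-by-dose effects
are assessed on within-subject differences, the dose main effect on
subject means, giving exact F(1, n_subjects - 2) tests.  Gene selection
combines a Benjamini-Hochberg FDR cut on the visit p-value with a
fold-change filter (|log2FC| >= log2(threshold), closed comparison).

The vitamin-D-status contrast compares baseline expression between
deficient and insufficient/sufficient subjects with a two-sample t-test
(equal variances by default, Welch optional) and the same fold-change
filter applied strictly (> threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# paired fold change
# ---------------------------------------------------------------------------

def paired_log2_fc(matrix: ExpressionMatrix) -> pd.Series:
    """Mean over subjects of (follow-up - baseline) log2 values, per gene."""
    _, base, follow = matrix.paired_columns()
    fc = (follow - base).mean(axis=1)
    return pd.Series(fc, index=matrix.gene_ids, name="log2fc")


# ---------------------------------------------------------------------------
# split-plot two-way ANOVA
# ---------------------------------------------------------------------------

def _ols_t_pvalues(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for every coefficient, gene-wise.

    Y is genes x subjects, X subjects x p.  Residual variance of zero is
    treated as a degenerate fit: p = 1 when the coefficient is also zero
    (no information), machine epsilon otherwise.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv  # genes x p
    resid = Y - B @ X.T
    dfres = n - p
    rss = np.sum(resid**2, axis=1)
    s2 = rss / dfres
    se = np.sqrt(np.maximum(s2[:, None], 0) * np.diag(xtx_inv)[None, :])
    pvals = np.empty_like(B)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B / se
    pvals = 2 * stats.t.sf(np.abs(t), dfres)
    degenerate = se <= np.sqrt(_EPS) * (1 + np.abs(B))
    zero_coef = np.abs(B) <= 1e-10 * (1 + np.abs(Y).max())
    pvals[degenerate & zero_coef] = 1.0
    pvals[degenerate & ~zero_coef] = _EPS
    return pvals


def anova2(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene visit, dose, and visit-by-dose p-values.

    Returns a DataFrame indexed by gene id with columns ``p_time``,
    ``p_dose`` and ``p_interaction``.  Both dose arms and both visits
    must be present.
    """
    subjects, base, follow = matrix.paired_columns()
    dose_by_subject = (
        matrix.meta.drop_duplicates("subject").set_index("subject")["dose"]
    )
    doses = dose_by_subject.loc[subjects].to_numpy()
    levels = np.unique(doses)
    if len(levels) != 2:
        raise ValueError(
            f"need exactly two dose arms with >=1 subject each, got {levels}"
        )
    for lv in levels:
        if np.sum(doses == lv) < 1:
            raise ValueError(f"dose arm {lv} has no subjects")
    g = np.where(doses == levels.max(), 0.5, -0.5)
    X = np.column_stack([np.ones(len(subjects)), g])

    diffs = follow - base
    means = (follow + base) / 2.0
    p_within = _ols_t_pvalues(diffs, X)
    p_between = _ols_t_pvalues(means, X)
    return pd.DataFrame(
        {
            "p_time": p_within[:, 0],
            "p_dose": p_between[:, 1],
            "p_interaction": p_within[:, 1],
        },
        index=matrix.gene_ids,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Exact zeros are floored at machine epsilon before adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, _EPS)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# responsive-gene selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Annotated DE table plus the up/down partition of selected genes."""

    table: pd.DataFrame
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.up) + len(self.down)


def de_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Combine paired fold changes with ANOVA p-values and BH-FDR."""
    fc = paired_log2_fc(matrix)
    pvals = anova2(matrix)
    out = pvals.copy()
    out.insert(0, "log2fc", fc)
    out.insert(1, "fold_change", 2.0 ** np.abs(fc))
    out.insert(2, "direction", np.where(fc < 0, "down", "up"))
    out["fdr"] = bh_adjust(out["p_time"].to_numpy())
    return out


def select_responsive(
    records: pd.DataFrame, fc_thresh: float = 1.5, fdr_thresh: float = 0.1
) -> SelectionResult:
    """Select genes with fold change >= threshold and FDR < threshold.

    ``records`` is a :func:`de_table` output.  The fold-change cut is
    closed (a gene at exactly the threshold passes, "at least" a 1.5
    fold change); the FDR cut is strict.
    """
    tbl = records.copy()
    tbl["selected"] = (tbl["fold_change"] >= fc_thresh) & (tbl["fdr"] < fdr_thresh)
    chosen = tbl[tbl["selected"]]
    return SelectionResult(
        table=tbl,
        up=list(chosen.index[chosen["direction"] == "up"]),
        down=list(chosen.index[chosen["direction"] == "down"]),
    )


# ---------------------------------------------------------------------------
# vitamin D status subgroup contrast
# ---------------------------------------------------------------------------

def baseline_status_diff(
    matrix: ExpressionMatrix,
    p_thresh: float = 0.01,
    fc_thresh: float = 1.5,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Baseline contrast of deficient vs insufficient/sufficient subjects.

    Per gene: two-sample t-test on baseline values between the two
    status groups, the baseline log2 fold change (deficient minus
    other), and within-group paired before/after p-values used later
    for the candidate-gene selection.  ``selected66`` flags genes with
    p < ``p_thresh`` and fold change strictly > ``fc_thresh``.
    """
    def group_cols(status, visit):
        return matrix.sample_ids_for(status=status, visit=visit)

    def_base = group_cols("deficient", "baseline")
    suf_base = group_cols("insufficient_sufficient", "baseline")
    if len(def_base) < 2 or len(suf_base) < 2:
        raise ValueError(
            "each status group needs >=2 baseline samples "
            f"(got {len(def_base)} deficient, {len(suf_base)} other)"
        )
    a = matrix.values[def_base].to_numpy(dtype=float)
    b = matrix.values[suf_base].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trigger scipy's catastrophic-cancellation
        # warning; their p-values are forced to 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    pval = np.where(np.isnan(pval), 1.0, pval)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    post = {}
    for status, col in (
        ("deficient", "post_p_deficient"),
        ("insufficient_sufficient", "post_p_sufficient"),
    ):
        sub = ExpressionMatrix(
            matrix.values[matrix.sample_ids_for(status=status)],
            matrix.meta.loc[matrix.sample_ids_for(status=status)],
        )
        _, base, follow = sub.paired_columns()
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_rel(follow, base, axis=1)
        post[col] = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0 ** np.abs(log2fc),
            "direction": np.where(log2fc < 0, "down", "up"),
            "p_baseline": pval,
            "post_p_deficient": post["post_p_deficient"],
            "post_p_sufficient": post["post_p_sufficient"],
        },
        index=matrix.gene_ids,
    )
    out["selected66"] = (out["p_baseline"] < p_thresh) & (out["fold_change"] > fc_thresh)
    return out


def select_vdre_candidates(
    subgroup: pd.DataFrame, p_thresh: float = 0.01
) -> pd.DataFrame:
    """Flag status-dependent genes also responsive within both groups.

    Adds a ``selected17`` column: genes from ``selected66`` whose paired
    before/after change is significant (p < ``p_thresh``) in the
    deficient AND the insufficient/sufficient group.  ``selected17``
    implies ``selected66`` by construction.
    """
    out = subgroup.copy()
    out["selected17"] = (
        out["selected66"]
        & (out["post_p_deficient"] < p_thresh)
        & (out["post_p_sufficient"] < p_thresh)
    )
    return out


# ---------------------------------------------------------------------------
# qPCR relative quantification and concordance
# ---------------------------------------------------------------------------

def ddct_relative_expression(
    qpcr: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``qpcr`` needs columns gene_id, sample_id, condition, ct_target and
    ct_control (the endogenous control, e.g. 18S rRNA).  Per record,
    delta Ct = ct_target - ct_control; the per-gene reference delta Ct
    is the mean over records in ``reference_condition`` and
    rq = 2^-(delta Ct - reference delta Ct).
    """
    required = {"gene_id", "sample_id", "condition", "ct_target", "ct_control"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if qpcr["ct_control"].isna().any():
        bad = qpcr.loc[qpcr["ct_control"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing endogenous-control Ct for samples: {bad}")
    out = qpcr.copy()
    out["dct"] = out["ct_target"] - out["ct_control"]
    ref = out[out["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"no records in reference condition {reference_condition!r}")
    ref_dct = ref.groupby("gene_id")["dct"].mean()
    out["ddct"] = out["dct"] - out["gene_id"].map(ref_dct)
    out["rq"] = 2.0 ** (-out["ddct"])
    return out


@dataclass
class ConcordanceFit:
    """OLS fit of qPCR on microarray log2 fold changes.

    ``pi_halfwidths`` are the half-widths of the t-based 95% prediction
    interval evaluated at the observed x values.
    """

    slope: float
    intercept: float
    r: float
    n: int
    resid_sd: float
    x_mean: float
    sxx: float
    pi_halfwidths: np.ndarray

    def halfwidth(self, x0: float, level: float = 0.95) -> float:
        """Prediction-interval half-width for a new observation at x0."""
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return float(
            tcrit
            * self.resid_sd
            * np.sqrt(1 + 1 / self.n + (x0 - self.x_mean) ** 2 / self.sxx)
        )

    def predict(self, x0: float) -> float:
        return self.intercept + self.slope * x0


def concordance_fit(x, y, level: float = 0.95) -> ConcordanceFit:
    """Least-squares concordance of microarray vs qPCR fold changes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need >=3 paired points, got {x.size}")
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise ValueError("x values are constant; slope undefined")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    syy = float(np.sum((y - ybar) ** 2))
    r = float(slope * np.sqrt(sxx / syy)) if syy > 0 else 1.0
    fit = ConcordanceFit(
        slope=slope,
        intercept=intercept,
        r=r,
        n=n,
        resid_sd=s,
        x_mean=float(xbar),
        sxx=sxx,
        pi_halfwidths=np.empty(0),
    )
    fit.pi_halfwidths = np.array([fit.halfwidth(xi, level) for xi in x])
    return fit
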