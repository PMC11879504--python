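"""Cohort statistics: MSS-B scoring, winsorization, correlations with FDR,
effect-size gating, and multiple/robust regression.

The analysis plan mirrors an exploratory individual-differences study:
questionnaire subscale scores are correlated with visual and oculomotor
outcomes (zero-order Pearson r with Fisher-z confidence intervals),
p-values are corrected per outcome family by Benjamini-Hochberg FDR, and
only medium-or-larger effects (|r| >= 0.30) are carried forward into
multiple OLS regression, confirmed by Huber M-estimation robust
regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


# -- MSS-B scoring ------------------------------------------------------------

MSSB_ITEM_COUNTS = {"positive": 13, "negative": 13, "disorganized": 12}
MSSB_N_ITEMS = 38


def default_item_map() -> dict[str, str]:
    """Items q1-q13 positive, q14-q26 negative, q27-q38 disorganized.

    A placeholder keying: the real instrument's item order is proprietary;
    supply your own map for real data.  Scoring depends only on the
    13/13/12 partition.
    """
    m = {}
    for i in range(1, 14):
        m[f"q{i}"] = "positive"
    for i in range(14, 27):
        m[f"q{i}"] = "negative"
    for i in range(27, 39):
        m[f"q{i}"] = "disorganized"
    return m


@dataclass(frozen=True)
class MssbScores:
    positive: int
    negative: int
    disorganized: int

    @property
    def overall(self) -> int:
        return self.positive + self.negative + self.disorganized


def score_mssb(item_responses: dict, item_map: dict | None = None) -> MssbScores:
    """Score 38 binary item responses into the three subscales.

    ``item_map`` must partition exactly 38 items into 13 positive, 13
    negative and 12 disorganized.  Missing or extra items raise; there is
    no silent imputation.
    """
    item_map = default_item_map() if item_map is None else item_map
    counts = {dim: 0 for dim in MSSB_ITEM_COUNTS}
    for item, dim in item_map.items():
        if dim not in counts:
            raise ValueError(f"item {item!r} mapped to unknown dimension {dim!r}")
        counts[dim] += 1
    if counts != MSSB_ITEM_COUNTS:
        raise ValueError(
            f"item map partition {counts} != required {MSSB_ITEM_COUNTS}"
        )

    missing = sorted(set(item_map) - set(item_responses))
    extra = sorted(set(item_responses) - set(item_map))
    if missing or extra:
        raise ValueError(
            f"item responses do not match the map (missing {missing[:5]}, extra {extra[:5]})"
        )

    scores = {dim: 0 for dim in MSSB_ITEM_COUNTS}
    for item, resp in item_responses.items():
        if resp not in (0, 1, True, False):
            raise ValueError(f"item {item!r} has non-binary response {resp!r}")
        scores[item_map[item]] += int(resp)
    return MssbScores(**scores)


# -- winsorization ------------------------------------------------------------


def detect_and_winsorize(values, fence_multiplier: float = 3.0):
    """Replace extreme outliers with the nearest non-extreme value.

    Extreme = strictly beyond Tukey's outer fences Q1 - k*IQR / Q3 + k*IQR
    (k = 3 by default), a formula stand-in for visual stem-and-leaf
    inspection.  Each flagged value becomes the most extreme non-flagged
    value on its side; order is preserved.
    Returns (winsorized array, n_replaced, outlier indices).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 values for outlier detection")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    out_lo = x < lo_fence
    out_hi = x > hi_fence
    outliers = np.flatnonzero(out_lo | out_hi)
    if outliers.size == 0 or outliers.size == len(x):
        return x.copy(), 0, np.array([], dtype=int)
    keep = x[~(out_lo | out_hi)]
    y = x.copy()
    y[out_lo] = keep.min()
    y[out_hi] = keep.max()
    return y, int(outliers.size), outliers


# -- correlations -------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    p_fdr: float | None = None
    passes_effect_gate: bool = False


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Zero-order Pearson r with Fisher-z 95% CI and two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length x, y with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    n = len(x)
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    res = CorrelationResult(float(r), float(lo), float(hi), float(p), n)
    res.passes_effect_gate = effect_gate(res.r)
    return res


def effect_gate(r: float, threshold: float = 0.30) -> bool:
    """Medium-or-larger effect: |r| >= 0.30."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    return abs(r) >= threshold


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    adjusted_i = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to
    the input order; flags are adjusted <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def correlation_table(
    cohort: pd.DataFrame,
    dimensions,
    outcomes,
    families: dict | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """All (dimension, outcome) Pearson correlations with per-family BH-FDR.

    ``families`` maps outcome name -> family label; FDR is applied within
    each family separately (one correction per outcome group), default one
    family for all outcomes.
    """
    rows = []
    for dim in dimensions:
        for out in outcomes:
            res = pearson_ci(cohort[dim], cohort[out])
            rows.append(
                dict(
                    dimension=dim,
                    outcome=out,
                    family=(families or {}).get(out, "all"),
                    r=res.r,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    p=res.p,
                    n=res.n,
                    gate=res.passes_effect_gate,
                )
            )
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    df["significant"] = False
    for _, idx in df.groupby("family").groups.items():
        adj, flags = bh_fdr(df.loc[idx, "p"].to_numpy(), q=q)
        df.loc[idx, "p_fdr"] = adj
        df.loc[idx, "significant"] = flags & df.loc[idx, "gate"]
    return df


# -- regression ---------------------------------------------------------------


@dataclass
class RegressionResult:
    betas: dict
    beta_p: dict
    f_stat: float
    df_model: int
    df_resid: int
    r_squared: float
    overall_p: float
    residual_qq_ok: bool
    method: str = "ols"


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _design(X):
    X = pd.DataFrame(X)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy(dtype=float)) < Xc.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    return Xc


def ols_fit(y, X) -> RegressionResult:
    """Multiple OLS regression with overall F-test and a residual-normality
    flag (Shapiro-Wilk at alpha .05, standing in for a Q-Q plot precheck;
    the flag never blocks the fit)."""
    y = np.asarray(y, dtype=float)
    Xc = _design(X)
    if len(y) <= Xc.shape[1]:
        raise ValueError("need n > number of predictors + 1")
    model = sm.OLS(y, Xc).fit()
    _, shapiro_p = sps.shapiro(model.resid)
    names = list(Xc.columns)
    return RegressionResult(
        betas={n: float(b) for n, b in zip(names, model.params)},
        beta_p={n: float(p) for n, p in zip(names, model.pvalues)},
        f_stat=float(model.fvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        r_squared=float(model.rsquared),
        overall_p=float(model.f_pvalue),
        residual_qq_ok=bool(shapiro_p > 0.05),
        method="ols",
    )


def robust_fit(y, X, tuning_constant: float = 1.345, maxiter: int = 200, tol: float = 1e-8) -> RegressionResult:
    """Huber M-estimation (IRLS) confirming the OLS pattern under outliers."""
    y = np.asarray(y, dtype=float)
    Xc = _design(X)
    model = sm.RLM(y, Xc, M=sm.robust.norms.HuberT(t=tuning_constant))
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs")
    n_iter = len(res.fit_history.get("params", [])) or res.fit_history.get("iteration", 0)
    if n_iter >= maxiter:
        raise RuntimeError(f"robust regression failed to converge in {maxiter} iterations")
    names = list(Xc.columns)
    return RegressionResult(
        betas={n: float(b) for n, b in zip(names, res.params)},
        beta_p={n: float(p) for n, p in zip(names, res.pvalues)},
        f_stat=float("nan"),
        df_model=int(Xc.shape[1] - 1),
        df_resid=int(len(y) - Xc.shape[1]),
        r_squared=float("nan"),
        overall_p=float("nan"),
        residual_qq_ok=True,
        method="huber",
    )


def qq_plot_residuals(y, X, path) -> None:
    """Export the residual Q-Q plot used as the regression precheck."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xc = _design(X)
    resid = sm.OLS(np.asarray(y, float), Xc).fit().resid
    fig, ax = plt.subplots(figsize=(4, 4))
    sm.ProbPlot(resid).qqplot(line="s", ax=ax)
    ax.set_title("Residual Q-Q")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def cronbach_alpha(items) -> float:
    """Internal-consistency utility for item-response matrices (rows =
    participants, columns = items)."""
    X = np.asarray(items, dtype=float)
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1 - item_vars / total_var))
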