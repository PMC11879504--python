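"""Chance-corrected Weibull psychometric fitting and ISL decomposition.

The probability of a correct 4AFC response as a function of stimulus
presentation time t is modeled as

    P(t) = gamma + (1 - gamma - lambda) * (1 - exp(-(t/alpha)^beta))

with guess rate gamma fixed at 0.25, lapse rate lambda small, Weibull
scale alpha (ms) and slope beta.  The integrated saccade latency (ISL) is
the presentation time at which P(t) reaches the 71% criterion; subtracting
the end of the saccade (T1 + T2) from the ISL yields the post-saccadic
visual processing time T3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import xlogy


class FitError(RuntimeError):
    pass


def weibull_p(t, alpha: float, beta: float, gamma: float = 0.25, lambda_: float = 0.0):
    t = np.asarray(t, dtype=float)
    p = gamma + (1.0 - gamma - lambda_) * (1.0 - np.exp(-((t / alpha) ** beta)))
    return p if p.ndim else float(p)


def chance_adjust(p_correct, gamma: float):
    """Map raw proportion correct to the [0, 1] above-chance scale.

    (p - gamma) / (1 - gamma), clamped below at zero; a 4AFC observer at
    pure chance maps to 0 and perfect performance to 1.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("guess rate gamma must be in [0, 1)")
    p = np.asarray(p_correct, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    adj = np.maximum((p - gamma) / (1.0 - gamma), 0.0)
    return adj if adj.ndim else float(adj)


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    lambda_: float
    isl_ms: float
    gof: float
    n_trials_used: int
    degenerate: bool = False
    neg_loglik: float = np.nan

    def predict(self, t):
        return weibull_p(t, self.alpha, self.beta, self.gamma, self.lambda_)


def _nll(params, durations, k, n, gamma, lam_fixed):
    if lam_fixed is None:
        alpha, beta, lam = params
    else:
        alpha, beta = params
        lam = lam_fixed
    p = np.clip(weibull_p(durations, alpha, beta, gamma, lam), 1e-12, 1 - 1e-12)
    return -float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def fit_weibull(
    durations,
    k_correct,
    n_total,
    gamma: float = 0.25,
    lapse_mode: str = "fixed",  # "fixed" | "free"
    lapse_fixed: float = 0.01,
    criterion: float = 0.71,
    criterion_scale: str = "raw",
    gof_method: str = "r2",
) -> PsychometricFit:
    """Maximum-likelihood chance-corrected Weibull fit to binomial counts.

    Deterministic: a fixed grid of (alpha, beta) starts is polished with
    L-BFGS-B and the best likelihood wins, ties broken by smaller alpha.
    All-correct or at/below-chance data yield a flagged degenerate fit.
    """
    durations = np.asarray(durations, dtype=float)
    k = np.asarray(k_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if len(np.unique(durations)) < 3:
        raise FitError("need at least 3 distinct durations")
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise FitError("invalid counts: need 0 <= k <= n, n >= 1")
    if n.sum() < 30:
        warnings.warn("fewer than 30 total trials; fit may be unstable", stacklevel=2)

    lam_fixed = lapse_fixed if lapse_mode == "fixed" else None
    obs = k / n
    degenerate = bool(np.all(k == n) or np.all(obs <= gamma + 1e-9))

    alpha_starts = np.quantile(durations, [0.25, 0.5, 0.75])
    beta_starts = [1.0, 2.0, 4.0, 8.0, 16.0]
    bounds = [(1e-3, 10 * durations.max()), (0.1, 50.0)]
    if lam_fixed is None:
        bounds.append((0.0, 0.06))

    best = None
    for a0 in alpha_starts:
        for b0 in beta_starts:
            x0 = [a0, b0] if lam_fixed is not None else [a0, b0, 0.01]
            res = minimize(
                _nll,
                x0,
                args=(durations, k, n, gamma, lam_fixed),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if not np.isfinite(res.fun):
                continue
            if (
                best is None
                or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0])
            ):
                best = res
    if best is None:
        raise FitError("no optimization start converged to a finite likelihood")

    alpha, beta = float(best.x[0]), float(best.x[1])
    lam = float(best.x[2]) if lam_fixed is None else float(lam_fixed)

    if degenerate:
        isl = np.nan
    else:
        isl = _invert(alpha, beta, gamma, lam, criterion, criterion_scale)
    gof = goodness_of_fit_arrays(durations, k, n, alpha, beta, gamma, lam, method=gof_method)
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        lambda_=lam,
        isl_ms=isl,
        gof=gof,
        n_trials_used=int(n.sum()),
        degenerate=degenerate,
        neg_loglik=float(best.fun),
    )


def _invert(alpha, beta, gamma, lam, criterion, scale):
    if scale == "adjusted":
        # criterion expressed on the chance-adjusted scale
        target = gamma + (1.0 - gamma) * criterion
    elif scale == "raw":
        target = criterion
    else:
        raise ValueError("criterion_scale must be 'raw' or 'adjusted'")
    if not gamma < target < 1.0 - lam:
        raise ValueError(
            f"criterion {target:.4f} outside the attainable range "
            f"({gamma}, {1 - lam}) of the fitted function"
        )
    hi = alpha
    while weibull_p(hi, alpha, beta, gamma, lam) < target:
        hi *= 2
    return float(brentq(lambda t: weibull_p(t, alpha, beta, gamma, lam) - target, 1e-9, hi, xtol=1e-9))


def isl_from_fit(fit: PsychometricFit, criterion: float = 0.71, criterion_scale: str = "raw") -> float:
    """Presentation time at which the fitted function reaches ``criterion``.

    For lambda = 0 the closed form alpha * (-ln(1 - (c-g)/(1-g)))^(1/beta)
    applies; the numerical inversion used here agrees with it to 1e-6 ms.
    """
    return _invert(fit.alpha, fit.beta, fit.gamma, fit.lambda_, criterion, criterion_scale)


def goodness_of_fit_arrays(
    durations, k, n, alpha, beta, gamma, lam, method: str = "r2"
) -> float:
    """GOF in [0, 1] for a fitted curve against binned binomial data.

    ``r2``: n-weighted coefficient of determination between observed and
    fitted chance-adjusted proportions, floored at 0 — the variability
    index: noisy observers scatter around the curve and score lower.
    ``deviance``: 1 - D/D0 with D the binomial deviance of the fit and D0
    that of the weighted-mean-only model, floored at 0.
    """
    durations = np.asarray(durations, float)
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    if len(durations) < 2:
        return np.nan
    obs = k / n
    pred = weibull_p(durations, alpha, beta, gamma, lam)
    if method == "r2":
        o = chance_adjust(obs, gamma)
        f = np.maximum((pred - gamma) / (1.0 - gamma), 0.0)
        w = n / n.sum()
        om = np.sum(w * o)
        ss_tot = np.sum(w * (o - om) ** 2)
        ss_res = np.sum(w * (o - f) ** 2)
        if ss_tot <= 0:
            return 1.0 if ss_res <= 1e-12 else 0.0
        return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    if method == "deviance":
        p = np.clip(pred, 1e-12, 1 - 1e-12)
        dev = 2 * np.sum(xlogy(k, obs / p) + xlogy(n - k, (1 - obs) / (1 - p)))
        pbar = np.clip(k.sum() / n.sum(), 1e-12, 1 - 1e-12)
        dev0 = 2 * np.sum(xlogy(k, obs / pbar) + xlogy(n - k, (1 - obs) / (1 - pbar)))
        if dev0 <= 0:
            return 1.0 if dev <= 1e-12 else 0.0
        return float(np.clip(1.0 - dev / dev0, 0.0, 1.0))
    raise ValueError("method must be 'r2' or 'deviance'")


def goodness_of_fit(fit: PsychometricFit, durations, k_correct, n_total, method="r2") -> float:
    return goodness_of_fit_arrays(
        durations, k_correct, n_total, fit.alpha, fit.beta, fit.gamma, fit.lambda_, method=method
    )


@dataclass(frozen=True)
class IslDecomposition:
    isl_ms: float
    t1_ms: float
    t2_ms: float

    @property
    def saccade_end_ms(self) -> float:
        return self.t1_ms + self.t2_ms

    @property
    def t3_ms(self) -> float:
        return self.isl_ms - self.saccade_end_ms

    @property
    def negative_t3(self) -> bool:
        """Response before the processing window closed, or estimation noise."""
        return self.t3_ms < 0


def decompose_isl(isl_ms: float, t1_ms: float, t2_ms: float) -> IslDecomposition:
    """Split the ISL into its oculomotor and processing components.

    T3 = ISL - (T1 + T2): the post-saccadic stimulus time available for
    processing.  Negative T3 is permitted but flagged.
    """
    if isl_ms <= 0 or t1_ms <= 0 or t2_ms <= 0:
        raise ValueError("isl_ms, t1_ms, t2_ms must all be positive")
    return IslDecomposition(isl_ms=float(isl_ms), t1_ms=float(t1_ms), t2_ms=float(t2_ms))


def bin_trials(presentation_ms, correct, excluded=None, bin_width_ms: float | None = None):
    """Group per-trial outcomes into (durations, k_correct, n_total) bins.

    Exact programmed durations by default; ``bin_width_ms`` (e.g. 2 ms for
    photodiode-measured times) buckets onto a rounded grid instead.
    """
    pres = np.asarray(presentation_ms, dtype=float)
    corr = np.asarray(correct, dtype=bool)
    if excluded is not None:
        keep = ~np.asarray(excluded, dtype=bool)
        pres, corr = pres[keep], corr[keep]
    if bin_width_ms:
        pres = np.round(pres / bin_width_ms) * bin_width_ms
    durations = np.unique(pres)
    k = np.array([corr[pres == d].sum() for d in durations], dtype=float)
    n = np.array([(pres == d).sum() for d in durations], dtype=float)
    return durations, k, n
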