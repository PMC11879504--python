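"""Simulated observers, gaze traces and cohorts for integrated-saccade-latency testing.

The generative model mirrors the measurement model of the EMAIL test
(Eye Movement and Integrated Saccade Latency): a peripheral Landolt-C
target at 8 deg eccentricity triggers a visually guided saccade with
latency T1, the eye is in flight for T2, and a correct report of the gap
orientation requires a further post-saccadic processing time drawn from a
right-skewed distribution.  If the stimulus outlasts T1 + T2 + required
processing time the observer answers correctly (up to lapses); otherwise
the observer guesses among the four gap orientations.

Cohorts are generated with a Gaussian copula so that planted correlations
between schizotypy dimension scores and visual/oculomotor outcomes can be
recovered by the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import integrate, stats

GAP_DIRECTIONS = ("NE", "SE", "SW", "NW")

_PRESETS = {
    # Population values follow typical adult cohort means:
    # T1 123.4 (12.64) ms, T2 40.4 ms at 8 deg, realized T3 ~52 (12.5) ms.
    "typical": dict(
        latency_mean=123.4,
        latency_sd=12.64,
        duration_intercept=21.0,
        duration_slope=2.425,
        t3_median=52.0,
        t3_spread=0.24,
        lapse_rate=0.02,
        blink_rate=0.05,
        anticipatory_rate=0.02,
    ),
    # A slower observer: longer latencies and processing times.
    "slow": dict(
        latency_mean=160.0,
        latency_sd=20.0,
        duration_intercept=24.0,
        duration_slope=2.6,
        t3_median=75.0,
        t3_spread=0.30,
        lapse_rate=0.03,
        blink_rate=0.08,
        anticipatory_rate=0.03,
    ),
}


@dataclass(frozen=True)
class ObserverModel:
    """Generative truth for one simulated participant.

    Times are in milliseconds, angles in degrees of visual angle.
    ``guess_rate`` is fixed at 0.25: all tasks are 4AFC.
    """

    latency_mean: float = 123.4
    latency_sd: float = 12.64
    duration_intercept: float = 21.0
    duration_slope: float = 2.425  # ms per degree of amplitude
    t3_median: float = 52.0
    t3_spread: float = 0.24  # log-normal shape (sigma of log)
    lapse_rate: float = 0.02
    guess_rate: float = 0.25
    blink_rate: float = 0.05
    anticipatory_rate: float = 0.02
    latency_family: str = "truncnorm"  # or "shifted_gamma"

    def __post_init__(self) -> None:
        checks = [
            ("latency_mean", self.latency_mean > 60.0, "> 60 ms"),
            ("latency_sd", self.latency_sd > 0, "> 0"),
            ("duration_intercept", self.duration_intercept >= 0, ">= 0"),
            ("duration_slope", self.duration_slope >= 0, ">= 0"),
            ("t3_median", self.t3_median > 0, "> 0"),
            ("t3_spread", self.t3_spread > 0, "> 0"),
            ("lapse_rate", 0 <= self.lapse_rate <= 0.06, "in [0, 0.06]"),
            ("guess_rate", self.guess_rate == 0.25, "= 0.25 (4AFC)"),
            ("blink_rate", 0 <= self.blink_rate <= 0.2, "in [0, 0.2]"),
            ("anticipatory_rate", 0 <= self.anticipatory_rate <= 0.1, "in [0, 0.1]"),
            (
                "latency_family",
                self.latency_family in ("truncnorm", "shifted_gamma"),
                "one of truncnorm/shifted_gamma",
            ),
        ]
        for name, ok, constraint in checks:
            if not ok:
                raise ValueError(
                    f"ObserverModel.{name} = {getattr(self, name)!r} violates {constraint}"
                )

    # -- latency distribution -------------------------------------------------

    @cached_property
    def _latency_dist(self):
        if self.latency_family == "truncnorm":
            a = (0.0 - self.latency_mean) / self.latency_sd
            return stats.truncnorm(a, np.inf, loc=self.latency_mean, scale=self.latency_sd)
        # shifted gamma with 60 ms shift matched to mean/sd
        shift = 60.0
        theta = self.latency_sd**2 / (self.latency_mean - shift)
        k = ((self.latency_mean - shift) / self.latency_sd) ** 2
        return stats.gamma(k, loc=shift, scale=theta)

    @cached_property
    def _t3_dist(self):
        return stats.lognorm(self.t3_spread, scale=self.t3_median)

    def saccade_duration(self, amplitude_deg: float) -> float:
        return self.duration_intercept + self.duration_slope * amplitude_deg

    # -- closed-form performance ----------------------------------------------

    def p_correct(self, presentation_ms, eccentricity_deg: float = 8.0):
        """Trial-level P(correct | presentation time) by numerical integration.

        Marginalizes over the latency distribution (including the anticipatory
        mixture component) and the required-processing-time distribution.
        """
        t2 = self.saccade_duration(eccentricity_deg)
        lat = self._latency_dist
        t3 = self._t3_dist

        def q_seen(t):
            # P(T1 + T2 + t3req <= t), integrating over T1
            def integrand(u):
                return lat.pdf(u) * t3.cdf(t - u - t2)

            hi = max(t - t2, 0.0)
            if hi <= 0:
                main = 0.0
            else:
                main, _ = integrate.quad(integrand, 0.0, hi, limit=200)
            if self.anticipatory_rate > 0:
                g = integrate.quad(
                    lambda u: (1.0 / 40.0) * t3.cdf(t - u - t2), 20.0, min(60.0, hi)
                )[0] if hi > 20.0 else 0.0
                main = (1 - self.anticipatory_rate) * main + self.anticipatory_rate * g
            return main

        scalar = np.isscalar(presentation_ms)
        ts = np.atleast_1d(np.asarray(presentation_ms, dtype=float))
        qs = np.array([q_seen(t) for t in ts])
        p = qs * (1.0 - self.lapse_rate) + (1.0 - qs) * self.guess_rate
        return float(p[0]) if scalar else p

    def true_isl(self, criterion: float = 0.71, eccentricity_deg: float = 8.0) -> float:
        """Presentation time at which P(correct) reaches ``criterion``."""
        from scipy.optimize import brentq

        lo, hi = 1.0, 2000.0
        if not self.p_correct(lo) < criterion < self.p_correct(hi):
            raise ValueError(f"criterion {criterion} not attainable by this observer")
        return brentq(lambda t: self.p_correct(t) - criterion, lo, hi, xtol=1e-6)


def make_observer(config: str | dict = "typical", seed: int = 0, **overrides) -> ObserverModel:
    """Build an :class:`ObserverModel` from a preset name or parameter dict.

    Deterministic for a given (config, seed): presets define fixed population
    parameters; ``seed`` only matters when ``jitter`` is supplied in overrides,
    which perturbs latency/processing parameters for between-subject variation.
    """
    if isinstance(config, str):
        try:
            params = dict(_PRESETS[config])
        except KeyError:
            raise ValueError(f"unknown observer preset {config!r}") from None
    else:
        params = dict(config)
    jitter = overrides.pop("jitter", params.pop("jitter", 0.0))
    params.update(overrides)
    if jitter:
        rng = np.random.default_rng(seed)
        for name in ("latency_mean", "latency_sd", "t3_median"):
            params[name] = params[name] * float(rng.normal(1.0, jitter))
    return ObserverModel(**params)


# -- gaze traces and trials ---------------------------------------------------


@dataclass(frozen=True)
class GazeTrace:
    """Uniformly sampled gaze for one trial; t = 0 is stimulus onset."""

    t: np.ndarray  # ms
    x: np.ndarray  # deg, rightward positive
    y: np.ndarray  # deg, upward positive
    valid: np.ndarray  # bool; False during blinks
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("GazeTrace arrays must have equal length")
        step = 1000.0 / self.sample_rate
        if n > 1 and not np.allclose(np.diff(self.t), step, atol=1e-9):
            raise ValueError("GazeTrace timestamps must be uniform at 1000/sample_rate ms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t, "x_deg": self.x, "y_deg": self.y, "valid": self.valid.astype(int)}
        )


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    target_side: int  # -1 left, +1 right
    eccentricity: float  # deg
    gap_direction: str  # one of GAP_DIRECTIONS
    presentation_ms: float
    response: str | None
    correct: bool
    stimulus_contrast: float = 75.0

    def __post_init__(self) -> None:
        if self.target_side not in (-1, 1):
            raise ValueError("target_side must be -1 or +1")
        if self.presentation_ms <= 0 or self.eccentricity <= 0:
            raise ValueError("presentation_ms and eccentricity must be positive")
        if self.gap_direction not in GAP_DIRECTIONS:
            raise ValueError(f"gap_direction must be one of {GAP_DIRECTIONS}")
        if self.response is not None and self.response not in GAP_DIRECTIONS:
            raise ValueError(f"response must be one of {GAP_DIRECTIONS} or None")


def _min_jerk(frac: np.ndarray) -> np.ndarray:
    s = np.clip(frac, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def simulate_email_trial(
    observer: ObserverModel,
    presentation_ms: float,
    rng: np.random.Generator,
    trial_id: int = 0,
    eccentricity_deg: float = 8.0,
    noise_sd_deg: float = 0.05,
    sample_rate: float = 1000.0,
) -> tuple[TrialRecord, GazeTrace]:
    """Simulate one EMAIL trial: response outcome plus the gaze trace.

    The trace embeds fixation at the origin, a minimum-jerk displacement of
    ``eccentricity_deg`` toward the target side starting at the sampled
    latency, optional blink dropouts (validity False, positions NaN, as a
    video tracker would report), and Gaussian position noise.
    """
    if presentation_ms <= 0:
        raise ValueError("presentation_ms must be positive")

    target_side = int(rng.choice((-1, 1)))
    gap_dir = str(rng.choice(GAP_DIRECTIONS))

    if rng.random() < observer.anticipatory_rate:
        latency = float(rng.uniform(20.0, 60.0))
    else:
        latency = float(observer._latency_dist.rvs(random_state=rng))
    t2 = observer.saccade_duration(eccentricity_deg)
    t3_required = float(observer._t3_dist.rvs(random_state=rng))

    seen = presentation_ms >= latency + t2 + t3_required
    if seen:
        if rng.random() < 1.0 - observer.lapse_rate:
            response = gap_dir
        else:
            others = [d for d in GAP_DIRECTIONS if d != gap_dir]
            response = str(rng.choice(others))
    else:
        response = str(rng.choice(GAP_DIRECTIONS))
    correct = response == gap_dir

    trial = TrialRecord(
        trial_id=trial_id,
        target_side=target_side,
        eccentricity=eccentricity_deg,
        gap_direction=gap_dir,
        presentation_ms=float(presentation_ms),
        response=response,
        correct=bool(correct),
    )

    step = 1000.0 / sample_rate
    trace_ms = max(600.0, presentation_ms + 300.0, latency + t2 + 200.0)
    t = np.arange(0.0, trace_ms, step)
    frac = (t - latency) / t2
    x = target_side * eccentricity_deg * _min_jerk(frac)
    y = np.zeros_like(x)
    x = x + rng.normal(0.0, noise_sd_deg, size=x.shape)
    y = y + rng.normal(0.0, noise_sd_deg, size=y.shape)
    valid = np.ones(len(t), dtype=bool)
    if rng.random() < observer.blink_rate:
        dur = float(rng.uniform(50.0, 150.0))
        start = float(rng.uniform(0.0, max(trace_ms - dur, 1.0)))
        mask = (t >= start) & (t < start + dur)
        valid[mask] = False
        x[mask] = np.nan
        y[mask] = np.nan

    trace = GazeTrace(t=t, x=x, y=y, valid=valid, sample_rate=sample_rate)
    return trial, trace


def simulate_fixed_duration_run(
    observer: ObserverModel,
    durations_ms,
    n_per_duration: int,
    rng: np.random.Generator,
    **trial_kwargs,
) -> tuple[list[TrialRecord], list[GazeTrace]]:
    """Fixed-presentation-time runs: each duration presented n_per_duration times."""
    trials: list[TrialRecord] = []
    traces: list[GazeTrace] = []
    tid = 0
    for d in durations_ms:
        for _ in range(n_per_duration):
            trial, trace = simulate_email_trial(observer, d, rng, trial_id=tid, **trial_kwargs)
            trials.append(trial)
            traces.append(trace)
            tid += 1
    return trials, traces


# -- cohorts ------------------------------------------------------------------

MSSB_DIMENSIONS = ("positive", "negative", "disorganized")

# (n_items, mean, sd) per dimension; mean/sd follow typical nonclinical cohorts.
_DEFAULT_MSSB_MARGINALS = {
    "positive": (13, 2.0, 2.5),
    "negative": (13, 2.4, 2.1),
    "disorganized": (12, 2.3, 3.0),
}

_DEFAULT_OUTCOMES = {
    "va_neg_arcmin": (1.27, 0.48),
    "va_pos_arcmin": (1.34, 0.53),
    "t1_ms": (123.4, 12.64),
    "saccade_end_ms": (163.7, 13.32),
    "t3_ms": (52.0, 12.5),
    "isl_ms": (215.6, 20.0),
    "gof": (0.90, 0.08),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort with planted correlations.

    ``target_correlations`` maps (dimension, outcome) pairs to the Pearson r
    the generated sample should converge to as n grows.
    """

    n_participants: int = 37
    target_correlations: dict = field(default_factory=dict)
    outcome_means_sds: dict = field(default_factory=lambda: dict(_DEFAULT_OUTCOMES))
    score_marginals: dict = field(default_factory=lambda: dict(_DEFAULT_MSSB_MARGINALS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for (dim, out), r in self.target_correlations.items():
            if dim not in self.score_marginals:
                raise ValueError(f"unknown schizotypy dimension {dim!r}")
            if out not in self.outcome_means_sds:
                raise ValueError(f"unknown outcome {out!r}")
            if not -1.0 < r < 1.0:
                raise ValueError(f"target correlation for ({dim}, {out}) must be in (-1, 1)")


def _betabinom_params(n: int, mean: float, sd: float) -> tuple[float, float]:
    """Beta-binomial (n, a, b) matched to the given mean and sd by moments."""
    p = mean / n
    var = sd**2
    binom_var = n * p * (1 - p)
    rho = max((var / binom_var - 1.0) / (n - 1), 1e-6)
    s = 1.0 / rho - 1.0  # a + b
    return max(p * s, 1e-3), max((1 - p) * s, 1e-3)


def _discrete_ppf(cdf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse CDF of a discrete distribution on 0..len(cdf)-1: smallest x
    with CDF(x) >= u.  Much faster than scipy's generic ppf search."""
    return np.searchsorted(cdf, u, side="left")


def _linear_attenuation(cdf: np.ndarray) -> float:
    """corr(T(Z), Z) for the quantile transform T of a standard normal Z.

    First Hermite coefficient over the transform's sd; used to calibrate
    latent copula correlations so realized Pearson r hits the target.
    """
    z = np.linspace(-8, 8, 8001)
    w = stats.norm.pdf(z)
    w /= w.sum()
    x = _discrete_ppf(cdf, np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)).astype(float)
    mx = np.sum(w * x)
    sx = np.sqrt(np.sum(w * (x - mx) ** 2))
    if sx == 0:
        return 1.0
    return float(np.sum(w * (x - mx) * z) / sx)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table via a Gaussian copula.

    Schizotypy dimension scores get beta-binomial marginals matched to the
    configured mean/sd; outcomes are normal with the configured moments.
    Latent correlations are inflated by the inverse of the discrete-marginal
    attenuation so that sample Pearson r converges to the planted target.
    """
    dims = list(spec.score_marginals)
    outs = list(spec.outcome_means_sds)
    names = dims + outs
    k = len(names)

    cdfs = {}
    atten = {}
    for d in dims:
        n_items, mean, sd = spec.score_marginals[d]
        a, b = _betabinom_params(n_items, mean, sd)
        pmf = stats.betabinom(n_items, a, b).pmf(np.arange(n_items + 1))
        cdfs[d] = np.cumsum(pmf)
        atten[d] = _linear_attenuation(cdfs[d])
    for o in outs:
        atten[o] = 1.0

    corr = np.eye(k)
    for (d, o), r in spec.target_correlations.items():
        latent = r / (atten[d] * atten[o])
        if not -1.0 < latent < 1.0:
            raise ValueError(
                f"target correlation {r} for ({d}, {o}) is unattainable after "
                f"marginal attenuation {atten[d] * atten[o]:.3f}"
            )
        i, j = names.index(d), names.index(o)
        corr[i, j] = corr[j, i] = latent

    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"implied latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.4g})"
        )

    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((spec.n_participants, k)) @ chol.T

    data = {"participant": np.arange(1, spec.n_participants + 1)}
    for idx, d in enumerate(dims):
        u = np.clip(stats.norm.cdf(z[:, idx]), 1e-12, 1 - 1e-12)
        data[d] = _discrete_ppf(cdfs[d], u).astype(int)
    data["overall"] = sum(data[d] for d in dims)
    for idx, o in enumerate(outs):
        mean, sd = spec.outcome_means_sds[o]
        data[o] = mean + sd * z[:, len(dims) + idx]
    return pd.DataFrame(data)


# -- CSV plumbing -------------------------------------------------------------


def write_gaze_csv(path, traces: list[GazeTrace], trial_ids=None) -> None:
    """Long-format gaze CSV: trial_id,t_ms,x_deg,y_deg,valid."""
    if trial_ids is None:
        trial_ids = range(len(traces))
    frames = []
    for tid, tr in zip(trial_ids, traces):
        f = tr.to_frame()
        f.insert(0, "trial_id", tid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(path) -> dict[int, GazeTrace]:
    df = pd.read_csv(path)
    traces = {}
    for tid, g in df.groupby("trial_id"):
        t = g["t_ms"].to_numpy(float)
        sr = 1000.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1000.0
        traces[int(tid)] = GazeTrace(
            t=t,
            x=g["x_deg"].to_numpy(float),
            y=g["y_deg"].to_numpy(float),
            valid=g["valid"].to_numpy() != 0,
            sample_rate=sr,
        )
    return traces


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "target_side": [t.target_side for t in trials],
            "eccentricity_deg": [t.eccentricity for t in trials],
            "gap_dir": [t.gap_direction for t in trials],
            "presentation_ms": [t.presentation_ms for t in trials],
            "response": [t.response for t in trials],
            "correct": [int(t.correct) for t in trials],
        }
    )


def read_trials_csv(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    return [
        TrialRecord(
            trial_id=int(r.trial_id),
            target_side=int(r.target_side),
            eccentricity=float(r.eccentricity_deg),
            gap_direction=str(r.gap_dir),
            presentation_ms=float(r.presentation_ms),
            response=None if pd.isna(r.response) else str(r.response),
            correct=bool(r.correct),
        )
        for r in df.itertuples()
    ]
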