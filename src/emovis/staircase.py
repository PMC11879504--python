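"""4AFC adaptive staircase: 2-down, 1-up with variable step sizes.

The 2-down/1-up rule makes the task harder (level decreases) after two
consecutive correct responses and easier (level increases) after every
error, so the level random-walk equilibrates where P(correct)^2 = 1/2,
i.e. at the sqrt(0.5) ~ 70.7% correct point — reported as the 71%
threshold in clinical use.  Level units are task units where LARGER is
EASIER: arcmin of Landolt-C gap for acuity, percent contrast for contrast
sensitivity, presentation milliseconds for the EMAIL test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class StaircaseError(RuntimeError):
    pass


@dataclass(frozen=True)
class StaircaseConfig:
    start_level: float
    min_level: float
    max_level: float
    initial_step: float | None = None  # default: 25% of start_level
    n_step_halvings: int = 4
    n_reversals_stop: int = 10
    max_trials: int = 80
    n_reversals_for_threshold: int = 6
    scale: str = "linear"  # "log": steps act multiplicatively (logMAR-like)

    def __post_init__(self) -> None:
        if not self.min_level < self.start_level < self.max_level:
            raise ValueError("need min_level < start_level < max_level")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.scale == "log" and self.min_level <= 0:
            raise ValueError("log scale requires positive levels")

    def step_schedule(self) -> list[float]:
        if self.scale == "log":
            s0 = self.initial_step if self.initial_step is not None else np.log(1.25)
        else:
            s0 = self.initial_step if self.initial_step is not None else 0.25 * self.start_level
        return [s0 / 2**i for i in range(self.n_step_halvings + 1)]


@dataclass(frozen=True)
class StaircaseState:
    config: StaircaseConfig
    current_level: float
    direction_of_last_step: int = 0  # +1 up (easier), -1 down (harder), 0 none
    consecutive_correct: int = 0
    reversal_levels: tuple = ()
    trials_run: int = 0
    terminated: bool = False

    @property
    def current_step(self) -> float:
        sched = self.config.step_schedule()
        return sched[min(len(self.reversal_levels), len(sched) - 1)]


def start_staircase(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(config=config, current_level=config.start_level)


def _move(level: float, signed_step: float, config: StaircaseConfig) -> float:
    if config.scale == "log":
        new = float(np.exp(np.log(level) + signed_step))
    else:
        new = level + signed_step
    return float(np.clip(new, config.min_level, config.max_level))


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """One trial of the 2-down/1-up rule; returns the successor state.

    A first correct response holds the level and arms the counter; a second
    consecutive correct steps down (harder); any error steps up (easier).
    Direction changes record the pre-step level as a reversal and advance
    the step schedule.
    """
    if state.terminated:
        raise StaircaseError("update() called on a terminated staircase")

    cfg = state.config
    trials = state.trials_run + 1
    reversals = state.reversal_levels

    if correct and state.consecutive_correct == 0:
        new = replace(state, consecutive_correct=1, trials_run=trials)
    else:
        direction = -1 if correct else +1
        if state.direction_of_last_step != 0 and direction != state.direction_of_last_step:
            reversals = reversals + (state.current_level,)
        step = cfg.step_schedule()[min(len(reversals), cfg.n_step_halvings)]
        new_level = _move(state.current_level, direction * step, cfg)
        new = replace(
            state,
            current_level=new_level,
            direction_of_last_step=direction,
            consecutive_correct=0,
            reversal_levels=reversals,
            trials_run=trials,
        )

    if len(new.reversal_levels) >= cfg.n_reversals_stop or new.trials_run >= cfg.max_trials:
        new = replace(new, terminated=True)
    return new


def threshold_from_reversals(reversal_levels, n_last: int = 6) -> float:
    """Arithmetic mean of the last ``n_last`` reversal levels."""
    levels = list(reversal_levels)
    if len(levels) < n_last:
        raise StaircaseError(
            f"only {len(levels)} reversals recorded, need {n_last}; "
            "use the flagged-estimate path of run_staircase"
        )
    return float(np.mean(levels[-n_last:]))


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    n_reversals_used: int
    all_levels: tuple
    flagged: bool = False
    diagnostic: str = ""


def run_staircase(respond, config: StaircaseConfig, seed=None) -> ThresholdEstimate:
    """Run a staircase to termination against a trial-response provider.

    ``respond(level) -> bool`` supplies each trial's correctness (simulated
    observer or replayed data).  If termination arrives with too few
    reversals for the configured readout, the estimate is flagged and falls
    back to the mean of whatever reversals exist, else the final level.
    """
    state = start_staircase(config)
    levels = [state.current_level]
    while not state.terminated:
        state = update(state, bool(respond(state.current_level)))
        levels.append(state.current_level)

    n_needed = config.n_reversals_for_threshold
    if len(state.reversal_levels) >= n_needed:
        thr = threshold_from_reversals(state.reversal_levels, n_needed)
        return ThresholdEstimate(thr, n_needed, tuple(levels))
    if state.reversal_levels:
        thr = float(np.mean(state.reversal_levels))
        diag = (
            f"terminated after {state.trials_run} trials with only "
            f"{len(state.reversal_levels)} reversals (need {n_needed})"
        )
        return ThresholdEstimate(thr, len(state.reversal_levels), tuple(levels), True, diag)
    return ThresholdEstimate(
        float(levels[-1]),
        0,
        tuple(levels),
        True,
        f"no reversals in {state.trials_run} trials (degenerate observer?)",
    )


def converged_accuracy(
    p_correct,
    start_level: float,
    step: float,
    bounds: tuple[float, float],
    n_trials: int = 100_000,
    burn_in: int = 1_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Long-run percent correct of a free-running 2-down/1-up staircase.

    Runs the update rule with a constant step (no termination, no schedule)
    against a stochastic observer whose psychometric function is
    ``p_correct(level)``; returns the empirical percent correct over the
    ``n_trials`` after ``burn_in``.  For a smooth increasing psychometric
    function and a small step this converges to 100*sqrt(0.5) ~ 70.7%.
    """
    rng = np.random.default_rng() if rng is None else rng
    level = float(start_level)
    cc = 0
    n_correct = 0
    lo, hi = bounds
    for i in range(burn_in + n_trials):
        correct = rng.random() < p_correct(level)
        if i >= burn_in:
            n_correct += correct
        if correct and cc == 0:
            cc = 1
        elif correct:
            level = max(level - step, lo)
            cc = 0
        else:
            level = min(level + step, hi)
            cc = 0
    return 100.0 * n_correct / n_trials
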