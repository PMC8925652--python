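"""Simulated 2AFC observers and adaptive up–down staircase procedures.

Two track rules are provided, matching the assay battery:

* ``weighted_1down1up_3to1`` — one-down-one-up with the up step three times
  the down step; its equilibrium is the 75%-correct point of the
  psychometric function (p·s_down = (1−p)·s_up ⇒ p = 0.75).
* ``3down1up`` — three-down-one-up; equilibrium at p³ = ½, i.e. the
  79.4%-correct point.

Tracks run on a dB-transformed stimulus axis (dB re 1 Hz for FM depth,
dB re 1 μs for ITD), where the observer's psychometric function is a
logistic.  Easy "catch" trials (FM depth > 15 Hz; ITD > 80 μs) are flagged
so a lapse rate — the nonsensory score — can be estimated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PsychometricObserver",
    "StaircaseConfig",
    "StaircaseRun",
    "observer_respond",
    "run_staircase",
    "flag_catch_trials",
    "target_percent_correct",
    "target_stimulus_db",
    "CATCH_BOUNDS_LINEAR",
]

# catch-trial bounds on the *linear* stimulus scale, strict inequality
CATCH_BOUNDS_LINEAR = {"fm": 15.0, "itd": 80.0, "am": None}


def _is_catch(x_db: float, bound_linear: float | None) -> bool:
    # strict ">" with a tolerance so a value exactly at the bound never
    # becomes a catch trial through round-off
    if bound_linear is None:
        return False
    return x_db > 20.0 * np.log10(bound_linear) + 1e-9


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(np.asarray(z, dtype=float))


@dataclass
class PsychometricObserver:
    """Stochastic 2AFC observer with independent sensory and lapse parameters.

    P(correct | x) = guess + (1 − guess − lapse) · F((x − midpoint)/spread)

    with F the logistic sigmoid on the dB stimulus axis.  ``midpoint`` is the
    sensory parameter (half-range point); ``lapse`` caps the upper asymptote
    at 1 − lapse and models attention failures rather than sensory limits.
    """

    midpoint: float
    spread: float = 3.0
    lapse: float = 0.0
    guess: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        self._rng = np.random.default_rng(self.seed)

    def p_correct(self, x: float) -> float:
        return float(self.guess + (1.0 - self.guess - self.lapse)
                     * _logistic((x - self.midpoint) / self.spread))

    def respond(self, x: float) -> bool:
        if not np.isfinite(x):
            raise ValueError("stimulus value must be finite")
        return bool(self._rng.random() < self.p_correct(x))


def observer_respond(observer: PsychometricObserver, x: float) -> bool:
    """Single Bernoulli response of ``observer`` to stimulus value ``x`` (dB)."""
    return observer.respond(x)


@dataclass
class StaircaseConfig:
    """Adaptive-track rule and bookkeeping parameters (all on the dB axis)."""

    rule: str = "3down1up"
    start_db: float = 34.0
    step_db: float = 4.0
    final_step_db: float = 2.0
    shrink_after_reversals: int = 3
    n_reversals_stop: int = 11
    threshold_rule: str = "geomean_last_9"
    floor_db: float = -40.0
    ceiling_db: float = 60.0

    def __post_init__(self) -> None:
        if self.rule not in ("3down1up", "weighted_1down1up_3to1"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.step_db <= 0 or self.final_step_db <= 0:
            raise ValueError("step sizes must be positive")
        need = 9 if self.threshold_rule == "geomean_last_9" else 1
        if self.n_reversals_stop < need:
            raise ValueError("n_reversals_stop below the threshold rule's requirement")


# presets bracketing the task threshold ranges (dB re 1 Hz / dB re 1 μs);
# start values sit clearly above the worst published thresholds (13 Hz / 89 μs)
# so every naive listener begins the track suprathreshold
TASK_PRESETS = {
    "fm": StaircaseConfig(rule="weighted_1down1up_3to1", start_db=28.0, step_db=4.0,
                          final_step_db=2.0, n_reversals_stop=11,
                          threshold_rule="median_all_reversals",
                          floor_db=-20.0, ceiling_db=40.0),
    "itd": StaircaseConfig(rule="3down1up", start_db=46.0, step_db=4.0,
                           final_step_db=2.0, n_reversals_stop=11,
                           threshold_rule="geomean_last_9",
                           floor_db=0.0, ceiling_db=55.0),
    "am": StaircaseConfig(rule="weighted_1down1up_3to1", start_db=-6.0, step_db=4.0,
                          final_step_db=2.0, n_reversals_stop=11,
                          threshold_rule="median_all_reversals",
                          floor_db=-40.0, ceiling_db=0.0),
}


@dataclass
class StaircaseRun:
    """Trial-by-trial log of one adaptive track."""

    task: str
    trials: list[tuple[float, bool, bool]] = field(default_factory=list)  # (x_db, correct, is_catch)
    reversal_values: list[float] = field(default_factory=list)
    threshold_db: float = float("nan")
    flagged: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_catch(self) -> int:
        return sum(1 for _, _, c in self.trials if c)

    @property
    def n_catch_incorrect(self) -> int:
        return sum(1 for _, ok, c in self.trials if c and not ok)


def _threshold_from_reversals(reversals: list[float], rule: str) -> float:
    r = np.asarray(reversals, dtype=float)
    if rule == "median_all_reversals":
        return float(np.median(r))
    if rule == "geomean_last_9":
        # geometric mean on the linear scale == arithmetic mean of dB values
        return float(np.mean(r[-9:]))
    raise ValueError(f"unknown threshold rule {rule!r}")


def run_staircase(observer: PsychometricObserver, config: StaircaseConfig,
                  task: str = "itd", seed: int | None = None,
                  max_trials: int = 10_000) -> StaircaseRun:
    """Run one adaptive track against a simulated observer.

    The track moves down after the rule's required number of consecutive
    correct responses and up after any incorrect one; for the weighted rule
    the up step is three times the down step.  The step size halves to
    ``final_step_db`` after ``shrink_after_reversals`` reversals.  The run
    stops at ``n_reversals_stop`` reversals and the threshold is computed by
    the configured rule.  Presented values are clamped to the configured
    floor/ceiling; more than three consecutive clamped trials flag the run.
    ``seed`` (if given) reseeds the observer so (observer, config, seed)
    fully determines the run.
    """
    if task not in CATCH_BOUNDS_LINEAR:
        raise ValueError(f"unknown task {task!r}")
    if seed is not None:
        observer._rng = np.random.default_rng(seed)
    run = StaircaseRun(task=task)
    x = config.start_db
    step = config.step_db
    n_correct_streak = 0
    direction = 0  # -1 moving down, +1 moving up
    clamp_streak = 0
    bound = CATCH_BOUNDS_LINEAR[task]
    n_down = 3 if config.rule == "3down1up" else 1
    up_factor = 3.0 if config.rule == "weighted_1down1up_3to1" else 1.0

    while len(run.reversal_values) < config.n_reversals_stop and run.n_trials < max_trials:
        x_pres = float(np.clip(x, config.floor_db, config.ceiling_db))
        clamped = x_pres != x
        clamp_streak = clamp_streak + 1 if clamped else 0
        if clamp_streak > 3:
            run.flagged = True
        is_catch = _is_catch(x_pres, bound)
        correct = observer.respond(x_pres)
        run.trials.append((x_pres, correct, is_catch))

        if correct:
            n_correct_streak += 1
            if n_correct_streak >= n_down:
                n_correct_streak = 0
                move = -1
            else:
                move = 0
        else:
            n_correct_streak = 0
            move = +1
        if move == 0:
            continue
        if direction != 0 and move != direction:
            run.reversal_values.append(x_pres)
            if len(run.reversal_values) == config.shrink_after_reversals:
                step = config.final_step_db
        direction = move
        x = x_pres + (step * up_factor if move > 0 else -step)

    if run.n_trials >= max_trials:
        run.flagged = True
    if run.reversal_values:
        run.threshold_db = _threshold_from_reversals(run.reversal_values, config.threshold_rule)
    return run


def flag_catch_trials(run: StaircaseRun, task: str | None = None) -> StaircaseRun:
    """(Re)label catch trials on the presented value: FM depth > 15 Hz, ITD > 80 μs.

    Bounds are strict ("exceeds"), so a trial exactly at the bound is not a
    catch trial.  Returns the run with is_catch recomputed in place.
    """
    task = task or run.task
    if task not in CATCH_BOUNDS_LINEAR:
        raise ValueError(f"unknown task {task!r}")
    bound = CATCH_BOUNDS_LINEAR[task]
    run.trials = [(x, ok, _is_catch(x, bound)) for x, ok, _ in run.trials]
    if run.n_catch == 0:
        run.flagged = True
    return run


def target_percent_correct(rule: str) -> float:
    """Asymptotic percent-correct tracked by a rule (2AFC)."""
    if rule == "3down1up":
        return float(0.5 ** (1.0 / 3.0))  # p³ = ½  → 0.7937
    if rule == "weighted_1down1up_3to1":
        return 0.75  # p·s = (1−p)·3s
    raise ValueError(f"unknown rule {rule!r}")


def target_stimulus_db(observer: PsychometricObserver, rule: str) -> float:
    """Stimulus value (dB) at which the observer hits the rule's tracked
    percent-correct, for a lapse-free observer: invert
    p = guess + (1−guess)·F((x−m)/s)."""
    p = target_percent_correct(rule)
    f = (p - observer.guess) / (1.0 - observer.guess)
    z = np.log(f / (1.0 - f))
    return float(observer.midpoint + observer.spread * z)
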