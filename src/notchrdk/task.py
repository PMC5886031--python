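"""3AFC odd-one-out trials, displacement-limit trials, and session running.

An oddity trial presents three RDK intervals: two *standards* drawn
independently from the same distribution and one *comparison* (the notched
distribution) at a uniformly random position.  The observer names the interval
that differed; chance is 1/3 and no feedback is ever given.  In the speed
experiments all three intervals share one random direction per trial; in the
direction experiment all intervals share one fixed dot speed.

The displacement-limit (D_max) task is single-interval: every dot is displaced
by the same amount per update, leftwards or rightwards at random, and the
observer reports the direction; chance is 1/2.

Observers are *blinded*: they receive a :class:`TrialView` carrying only the
interval dot data and shared trial parameters — never the odd position, the
true displacement direction, or any provenance labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import ConfigurationError, DiscreteDistribution, validate_matched
from .experiments import Condition
from .rdk import FrameSequence, StimulusSpec, generate_interval
from .units import arcmin_displacement_to_speed

__all__ = [
    "Trial",
    "TrialView",
    "IntervalView",
    "ProtocolError",
    "DMAX_LEVELS_ARCMIN",
    "make_oddity_trial",
    "make_dmax_trial",
    "run_session",
    "run_dmax_session",
]

#: default displacement levels (arc min): six equal steps over the tested range
DMAX_LEVELS_ARCMIN = (27.0, 54.0, 81.0, 108.0, 135.0, 162.0)

LOG_COLUMNS = [
    "trial_id",
    "experiment",
    "condition_param",
    "condition_label",
    "task",
    "trial_speed",
    "odd_index",
    "dmax_direction",
    "choice",
    "correct",
    "valid",
    "observer",
    "seed",
]


class ProtocolError(RuntimeError):
    """An observer returned a response outside the task's response set."""


@dataclass(frozen=True)
class IntervalView:
    """Blinded per-interval data an observer is allowed to inspect."""

    positions: np.ndarray  # (n_updates, n_dots, 2) deg
    speeds: np.ndarray  # (n_updates, n_dots) deg/s
    directions: np.ndarray  # (n_updates, n_dots) deg


@dataclass(frozen=True)
class TrialView:
    """What the observer sees: interval dot data plus shared trial parameters."""

    task: str  # "oddity" | "dmax"
    intervals: tuple[IntervalView, ...]
    update_rate: float
    trial_direction: float | None = None
    trial_speed: float | None = None


@dataclass(frozen=True)
class Trial:
    """One presentation, including ground truth the observer never sees."""

    trial_id: int
    task: str
    intervals: tuple[FrameSequence, ...]
    odd_index: int | None = None  # 1-based position of the comparison
    trial_direction: float | None = None
    trial_speed: float | None = None
    dmax_displacement_arcmin: float | None = None
    dmax_direction: str | None = None  # "left" | "right"

    def view(self) -> TrialView:
        return TrialView(
            task=self.task,
            intervals=tuple(
                IntervalView(s.positions, s.speeds, s.directions)
                for s in self.intervals
            ),
            update_rate=self.intervals[0].spec.update_rate,
            trial_direction=self.trial_direction,
            trial_speed=self.trial_speed,
        )


def make_oddity_trial(
    standard: DiscreteDistribution,
    comparison: DiscreteDistribution,
    spec: StimulusSpec,
    rng: np.random.Generator,
    trial_id: int = 0,
    trial_speed: float | None = None,
    direction_offset: float | None = None,
    match_tol: float = 1e-6,
) -> Trial:
    """Assemble a 3AFC trial from a matched standard/comparison pair.

    Speed distributions: one shared direction is drawn uniformly from
    [0°, 360°) for all three intervals.  Direction distributions: a fixed
    ``trial_speed`` is required and shared; an optional global
    ``direction_offset`` (deg) rotates all sampled directions modulo 360.
    """
    report = validate_matched(standard, comparison, tol=match_tol)
    if not report.passed:
        raise ConfigurationError(
            f"standard/comparison are not matched: {report.violations}"
        )
    odd_index = int(rng.integers(1, 4))
    if standard.kind == "speed":
        trial_direction = float(rng.uniform(0.0, 360.0))
        sources = [
            (comparison if i == odd_index else standard, trial_direction)
            for i in (1, 2, 3)
        ]
        intervals = tuple(
            generate_interval(spec, dist, direction, rng, provenance=("comparison" if i + 1 == odd_index else "standard"))
            for i, (dist, direction) in enumerate(sources)
        )
        return Trial(
            trial_id=trial_id,
            task="oddity",
            intervals=intervals,
            odd_index=odd_index,
            trial_direction=trial_direction,
        )
    # direction experiment: speed fixed per condition, directions sampled
    if trial_speed is None:
        raise ConfigurationError(
            "direction-distribution trials need a fixed trial_speed"
        )
    intervals = []
    for i in (1, 2, 3):
        dist = comparison if i == odd_index else standard
        seq = generate_interval(
            spec,
            trial_speed,
            dist,
            rng,
            provenance="comparison" if i == odd_index else "standard",
        )
        if direction_offset is not None:
            seq = FrameSequence(
                seq.positions,
                seq.speeds,
                np.mod(seq.directions + direction_offset, 360.0),
                seq.spec,
                provenance=seq.provenance,
            )
        intervals.append(seq)
    return Trial(
        trial_id=trial_id,
        task="oddity",
        intervals=tuple(intervals),
        odd_index=odd_index,
        trial_speed=float(trial_speed),
    )


def make_dmax_trial(
    displacement_arcmin: float,
    spec: StimulusSpec,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> Trial:
    """Single-interval direction-discrimination trial at a fixed displacement.

    All dots share the identical per-update displacement, leftwards or
    rightwards chosen at random.
    """
    if displacement_arcmin <= 0:
        raise ConfigurationError(
            f"displacement must be positive, got {displacement_arcmin}"
        )
    dmax_direction = "right" if rng.random() < 0.5 else "left"
    direction_deg = 0.0 if dmax_direction == "right" else 180.0
    speed = arcmin_displacement_to_speed(displacement_arcmin, spec.update_rate)
    seq = generate_interval(spec, speed, direction_deg, rng, provenance="dmax")
    return Trial(
        trial_id=trial_id,
        task="dmax",
        intervals=(seq,),
        dmax_displacement_arcmin=float(displacement_arcmin),
        dmax_direction=dmax_direction,
    )


def _observer_name(observer) -> str:
    return getattr(observer, "name", type(observer).__name__)


def run_session(
    conditions: Sequence[Condition] | Iterable[Condition],
    observer,
    n_trials_per_condition: int = 280,
    spec: StimulusSpec | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    interleave: bool = True,
) -> pd.DataFrame:
    """Run 3AFC oddity trials for every condition and log the responses.

    Conditions are interleaved (random trial order) by default, or blocked in
    the given order with ``interleave=False``.  The observer is called once
    per trial with a blinded :class:`TrialView` and an RNG; a response outside
    {1, 2, 3} is logged as a protocol violation and the trial marked invalid.
    The log is fully determined by (conditions, observer, seed).
    """
    spec = spec or StimulusSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    conditions = list(conditions)
    order = np.repeat(np.arange(len(conditions)), n_trials_per_condition)
    if interleave:
        order = rng.permutation(order)
    rows = []
    name = _observer_name(observer)
    for trial_id, ci in enumerate(order):
        cond = conditions[ci]
        trial = make_oddity_trial(
            cond.standard,
            cond.comparison,
            spec,
            rng,
            trial_id=trial_id,
            trial_speed=cond.trial_speed,
        )
        try:
            choice = observer(trial.view(), rng)
        except Exception as exc:  # observer bugs stay visible, not fatal
            choice = None
            valid = False
        else:
            valid = choice in (1, 2, 3)
        correct = bool(choice == trial.odd_index) if valid else np.nan
        rows.append(
            (
                trial_id,
                cond.experiment,
                cond.param,
                cond.label,
                "oddity",
                cond.trial_speed,
                trial.odd_index,
                None,
                choice if valid else None,
                correct,
                valid,
                name,
                seed,
            )
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def run_dmax_session(
    displacements_arcmin: Sequence[float] = DMAX_LEVELS_ARCMIN,
    observer=None,
    n_trials_per_level: int = 280,
    spec: StimulusSpec | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    interleave: bool = True,
) -> pd.DataFrame:
    """Run single-interval direction-discrimination trials per displacement level."""
    spec = spec or StimulusSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    levels = list(displacements_arcmin)
    order = np.repeat(np.arange(len(levels)), n_trials_per_level)
    if interleave:
        order = rng.permutation(order)
    rows = []
    name = _observer_name(observer)
    for trial_id, li in enumerate(order):
        d = levels[li]
        trial = make_dmax_trial(d, spec, rng, trial_id=trial_id)
        try:
            choice = observer(trial.view(), rng)
        except Exception:
            choice = None
            valid = False
        else:
            valid = choice in ("left", "right")
        correct = bool(choice == trial.dmax_direction) if valid else np.nan
        rows.append(
            (
                trial_id,
                0,
                float(d),
                f"dmax_{d:g}",
                "dmax",
                None,
                None,
                trial.dmax_direction,
                choice if valid else None,
                correct,
                valid,
                name,
                seed,
            )
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)
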