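"""Simulated observers for the oddity and displacement-limit tasks.

These decision rules stand in for human participants so the full pipeline —
stimulus synthesis, task, psychometrics — can be exercised and its qualitative
behaviour tested.  They are modeling devices of this package, not claims about
human vision.  All observers are stateless across trials (the task gives no
feedback, so there is nothing to learn from).

The core statistic is the *largest empty gap* in the multiset of dot speeds
(or directions) sampled within an interval: a notched comparison leaves a wide
empty interval that a dense uniform standard does not.  Perceptual limits are
modeled as noise applied to the per-dot values before the gap is measured —
multiplicative (Weber-like) noise for speed, additive (optionally
speed-scaled) noise for direction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "guessing_observer",
    "GuessingObserver",
    "gap_statistic",
    "oddity_decision",
    "SpeedGapObserver",
    "DirectionGapObserver",
    "DmaxObserver",
]


def gap_statistic(
    speed_sample, range_lo: float | None = None, range_hi: float | None = None
) -> float:
    """Largest empty interval between consecutive sorted unique sample values.

    Optionally restricted to samples within ``(range_lo, range_hi)``.  A
    sample with fewer than two distinct values has gap 0.
    """
    x = np.unique(np.asarray(speed_sample, dtype=float))
    if x.size == 0:
        raise ValueError("gap_statistic needs a non-empty sample")
    if range_lo is not None:
        x = x[x >= range_lo]
    if range_hi is not None:
        x = x[x <= range_hi]
    if x.size < 2:
        return 0.0
    return float(np.max(np.diff(x)))


def oddity_decision(stats, rng: np.random.Generator) -> int:
    """Choose the interval whose statistic is most distant from the other two.

    Score_i = Σ_j |s_i − s_j|; the maximal score wins, ties broken uniformly
    at random (a full three-way tie is a uniform guess).
    """
    s = np.asarray(stats, dtype=float)
    if s.shape != (3,) or not np.all(np.isfinite(s)):
        raise ValueError(f"need three finite statistics, got {stats}")
    scores = np.abs(s[:, None] - s[None, :]).sum(axis=1)
    top = scores.max()
    winners = np.flatnonzero(scores >= top - 1e-12 * max(1.0, abs(top)))
    return int(rng.choice(winners)) + 1


class GuessingObserver:
    """Uniform random choice — the chance-performance reference (1/3)."""

    name = "guess"
    task = "oddity"

    def __call__(self, view, rng: np.random.Generator) -> int:
        return int(rng.integers(1, 4))


def guessing_observer(view, rng: np.random.Generator) -> int:
    """Functional form of :class:`GuessingObserver`."""
    return int(rng.integers(1, 4))


guessing_observer.name = "guess"  # type: ignore[attr-defined]


class SpeedGapObserver:
    """Gap-statistic observer for speed-distribution trials.

    Each perceived dot speed is the true speed times ``1 + ε`` with
    ``ε ~ N(0, noise_fraction)`` — multiplicative, Weber-like noise, so
    absolute uncertainty grows with speed and performance collapses on fast
    ranges while surviving on slow ones.  ``noise_fraction=0`` is the
    noiseless gap oracle.
    """

    task = "oddity"

    def __init__(self, noise_fraction: float = 0.10):
        if noise_fraction < 0:
            raise ValueError("noise_fraction must be nonnegative")
        self.noise_fraction = float(noise_fraction)
        self.name = f"speed-gap(noise={noise_fraction:g})"

    def __call__(self, view, rng: np.random.Generator) -> int:
        stats = []
        for interval in view.intervals:
            speeds = interval.speeds.ravel()
            if self.noise_fraction > 0:
                speeds = speeds * (
                    1.0 + self.noise_fraction * rng.standard_normal(speeds.size)
                )
            stats.append(gap_statistic(speeds))
        return oddity_decision(stats, rng)


class DirectionGapObserver:
    """Gap-statistic observer for direction-distribution trials.

    Perceived directions are jittered by additive Gaussian noise whose
    standard deviation is ``noise_deg + speed_gain * trial_speed`` — with a
    positive ``speed_gain``, directional resolution degrades as the dots move
    faster.
    """

    task = "oddity"

    def __init__(self, noise_deg: float = 2.0, speed_gain: float = 0.35):
        if noise_deg < 0 or speed_gain < 0:
            raise ValueError("noise parameters must be nonnegative")
        self.noise_deg = float(noise_deg)
        self.speed_gain = float(speed_gain)
        self.name = f"direction-gap(noise={noise_deg:g},gain={speed_gain:g})"

    def sigma(self, trial_speed: float | None) -> float:
        return self.noise_deg + self.speed_gain * (trial_speed or 0.0)

    def __call__(self, view, rng: np.random.Generator) -> int:
        sigma = self.sigma(view.trial_speed)
        stats = []
        for interval in view.intervals:
            dirs = interval.directions.ravel()
            if sigma > 0:
                dirs = dirs + sigma * rng.standard_normal(dirs.size)
            stats.append(gap_statistic(dirs))
        return oddity_decision(stats, rng)


class DmaxObserver:
    """Psychometric test observer for the displacement-limit task.

    Responds with the true direction with probability
    ``p(d) = 1/2 + 1/2 · σ((limit − d)/slope)`` (σ the logistic function), so
    accuracy is ~1 for small displacements, exactly 0.75 at ``d = limit``, and
    falls to chance far beyond it.  Used for threshold-recovery checks of the
    psychometric fitting.
    """

    task = "dmax"

    def __init__(self, displacement_limit_arcmin: float = 100.0, slope_arcmin: float = 12.0):
        if displacement_limit_arcmin <= 0 or slope_arcmin <= 0:
            raise ValueError("limit and slope must be positive")
        self.limit = float(displacement_limit_arcmin)
        self.slope = float(slope_arcmin)
        self.name = f"dmax(limit={displacement_limit_arcmin:g})"

    def p_correct(self, displacement_arcmin: float) -> float:
        z = (self.limit - displacement_arcmin) / self.slope
        return 0.5 + 0.5 / (1.0 + np.exp(-z))

    def __call__(self, view, rng: np.random.Generator) -> str:
        interval = view.intervals[0]
        # displacement and direction are observable from the dot kinematics
        displacement_arcmin = 60.0 * interval.speeds[0, 0] / view.update_rate
        true_dir = "right" if np.cos(np.deg2rad(interval.directions[0, 0])) > 0 else "left"
        if rng.random() < self.p_correct(displacement_arcmin):
            return true_dir
        return "left" if true_dir == "right" else "right"
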