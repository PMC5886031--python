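"""Discrete speed and direction distributions for notched random-dot kinematograms.

A motion-transparency stimulus is built from a *standard* distribution — a
uniform grid of dot speeds (deg/s) or directions (deg) — and a *comparison*
distribution that covers the same outer range but has a central band of values
(the "notch" in speed, or "directional gap") removed.  The constructions here
enforce the matched-statistics constraints of the task: standard and comparison
share their outer endpoints, their span, and their global arithmetic mean, so
that an observer cannot identify the odd stimulus from any of those summary
statistics and must instead detect the gap itself.

Conventions
-----------
* Bands are gridded from the *outer* range endpoints inward: the lower band is
  anchored at ``range_lo`` and extends upward in steps of ``interval``; the
  upper band is anchored at ``range_hi`` and extends downward.  This preserves
  the declared endpoints exactly and makes symmetric notches mean-preserving.
* Bands are closed and the notch is open: a grid point falling exactly on a
  notch edge belongs to the band.  A zero-width notch therefore reproduces the
  uniform standard exactly.
* Where a band's mean must be steered away from its unweighted value (constant
  mean-distance constructions), per-point weights take the maximum-entropy
  exponential-tilting form ``w_i ∝ exp(λ x_i)`` with λ solved numerically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConfigurationError",
    "InfeasibleConstraintError",
    "DiscreteDistribution",
    "DistributionStats",
    "MatchReport",
    "build_uniform",
    "build_symmetric_notched",
    "solve_band_tilt",
    "build_mean_targeted_notched",
    "build_bandwidth_family",
    "build_constant_distance_notched",
    "build_direction_gapped",
    "moments",
    "validate_matched",
]

#: absolute tolerance for grid/boundary comparisons (deg/s or deg)
GRID_TOL = 1e-9


class ConfigurationError(ValueError):
    """A construction was asked for geometrically impossible parameters."""


class InfeasibleConstraintError(ConfigurationError):
    """A mean constraint cannot be satisfied on the given support."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteDistribution:
    """A finite distribution over speeds (deg/s) or directions (deg).

    Parameters
    ----------
    kind : {"speed", "direction"}
    support : ascending grid of values; for notched distributions this is the
        union of the lower- and upper-band grids.
    probabilities : per-point weights, nonnegative, summing to 1.
    range_lo, range_hi : declared outer endpoints; always equal to
        ``support[0]`` and ``support[-1]``.
    interval : grid spacing used to construct the support.
    notch : ``(notch_lo, notch_hi)`` excluded open interval, or ``None`` for a
        standard (un-notched) distribution.
    """

    kind: str
    support: np.ndarray
    probabilities: np.ndarray
    range_lo: float
    range_hi: float
    interval: float
    notch: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probabilities", probs)
        if self.kind not in ("speed", "direction"):
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        if support.ndim != 1 or support.size == 0:
            raise ConfigurationError("support must be a non-empty 1-D grid")
        if probs.shape != support.shape:
            raise ConfigurationError("probabilities must align with support")
        if np.any(np.diff(support) <= 0):
            raise ConfigurationError("support must be strictly increasing")
        if np.any(probs < -GRID_TOL):
            raise ConfigurationError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"probabilities sum to {probs.sum()!r}, expected 1"
            )
        if abs(support[0] - self.range_lo) > GRID_TOL or abs(
            support[-1] - self.range_hi
        ) > GRID_TOL:
            raise ConfigurationError(
                "outer support points must anchor the declared range"
            )
        if self.notch is not None:
            lo, hi = self.notch
            inside = (support > lo + GRID_TOL) & (support < hi - GRID_TOL)
            if np.any(inside):
                raise ConfigurationError(
                    f"support points {support[inside]} lie inside the notch "
                    f"({lo}, {hi})"
                )

    @property
    def n_points(self) -> int:
        return int(self.support.size)

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        """Draw values with replacement according to the point weights."""
        p = self.probabilities / self.probabilities.sum()
        return rng.choice(self.support, size=size, p=p)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "range": [self.range_lo, self.range_hi],
            "interval": self.interval,
            "notch": list(self.notch) if self.notch is not None else None,
            "support": self.support.tolist(),
            "probabilities": self.probabilities.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteDistribution":
        return cls(
            kind=d["kind"],
            support=np.asarray(d["support"], dtype=float),
            probabilities=np.asarray(d["probabilities"], dtype=float),
            range_lo=float(d["range"][0]),
            range_hi=float(d["range"][1]),
            interval=float(d["interval"]),
            notch=tuple(d["notch"]) if d.get("notch") is not None else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DiscreteDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class DistributionStats:
    """Exact moments of a :class:`DiscreteDistribution`.

    ``band_means``, ``mean_distance`` and ``notch_width`` are ``None`` for a
    standard (un-notched) distribution.
    """

    global_mean: float
    span: float
    band_means: tuple[float, float] | None = None
    mean_distance: float | None = None
    notch_width: float | None = None


@dataclass(frozen=True)
class MatchReport:
    """Result of checking the matched-statistics constraints of a pair."""

    passed: bool
    violations: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    tol: float = 1e-6

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------


def _grid_up(start: float, limit: float, interval: float) -> np.ndarray:
    """Grid anchored at ``start`` ascending in ``interval`` steps, last point
    ≤ ``limit`` (closed, within tolerance)."""
    if limit < start - GRID_TOL:
        return np.empty(0)
    n = int(np.floor((limit - start) / interval + GRID_TOL))
    return start + interval * np.arange(n + 1)

def _grid_down(start: float, limit: float, interval: float) -> np.ndarray:
    """Grid anchored at ``start`` descending to ≥ ``limit``; returned ascending."""
    if start < limit - GRID_TOL:
        return np.empty(0)
    n = int(np.floor((start - limit) / interval + GRID_TOL))
    return start - interval * np.arange(n, -1, -1)


def _commensurate_steps(range_lo, range_hi, interval) -> int | None:
    """Number of whole ``interval`` steps spanning the range, or None."""
    width = range_hi - range_lo
    if interval <= 0:
        raise ConfigurationError(f"grid interval must be positive, got {interval}")
    steps = width / interval
    if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
        return None
    return int(round(steps))


# ---------------------------------------------------------------------------
# constructions
# ---------------------------------------------------------------------------


def build_uniform(
    range_lo: float, range_hi: float, interval: float, kind: str = "speed"
) -> DiscreteDistribution:
    """Equiprobable grid over ``[range_lo, range_hi]`` — the standard distribution.

    When the range is a whole number of ``interval`` steps this is the plain
    grid from ``range_lo`` to ``range_hi``.  Otherwise the support is gridded
    from *both* endpoints toward the midpoint (two mirrored half-grids with a
    slightly larger central step): this preserves the declared endpoints
    exactly and keeps the global mean at the range midpoint, which a one-sided
    grid cannot do on a non-commensurate range.  A zero-width range yields the
    degenerate one-point distribution.
    """
    if range_hi < range_lo:
        raise ConfigurationError(f"empty range [{range_lo}, {range_hi}]")
    if abs(range_hi - range_lo) <= GRID_TOL:
        return DiscreteDistribution(
            kind, np.array([range_lo]), np.array([1.0]), range_lo, range_lo, interval
        )
    n_steps = _commensurate_steps(range_lo, range_hi, interval)
    if n_steps is not None:
        support = range_lo + interval * np.arange(n_steps + 1)
        support[-1] = range_hi  # pin the printed endpoint exactly
    else:
        mid = 0.5 * (range_lo + range_hi)
        k = int(np.floor((mid - range_lo) / interval + GRID_TOL))
        lower = range_lo + interval * np.arange(k + 1)
        if lower[-1] > mid - GRID_TOL:  # midpoint itself on the lower grid
            lower = lower[:-1]
        upper = range_hi - interval * np.arange(lower.size - 1, -1, -1)
        support = np.concatenate([lower, upper])
    probs = np.full(support.size, 1.0 / support.size)
    return DiscreteDistribution(kind, support, probs, range_lo, range_hi, interval)


def _notch_bands(range_lo, range_hi, notch_lo, notch_hi, interval):
    lower = _grid_up(range_lo, notch_lo, interval)
    upper = _grid_down(range_hi, notch_hi, interval)
    if lower.size == 0 or upper.size == 0:
        raise ConfigurationError(
            f"notch ({notch_lo}, {notch_hi}) leaves an empty band on "
            f"[{range_lo}, {range_hi}]"
        )
    return lower, upper


def build_symmetric_notched(
    range_lo: float,
    range_hi: float,
    notch_width: float,
    interval: float,
    kind: str = "speed",
) -> DiscreteDistribution:
    """Comparison distribution with a centered notch and equiprobable points.

    The notch of width ``notch_width`` is centered on the range midpoint; the
    two remaining bands are gridded from the outer endpoints inward, so they
    mirror each other and the global mean equals the midpoint exactly.  A
    zero-width notch reduces to :func:`build_uniform`.
    """
    if notch_width < 0:
        raise ConfigurationError(f"negative notch width {notch_width}")
    if abs(notch_width) <= GRID_TOL:
        return build_uniform(range_lo, range_hi, interval, kind=kind)
    if notch_width >= range_hi - range_lo - GRID_TOL:
        raise ConfigurationError(
            f"notch width {notch_width} must be smaller than the range "
            f"{range_hi - range_lo}"
        )
    mid = 0.5 * (range_lo + range_hi)
    notch_lo, notch_hi = mid - notch_width / 2, mid + notch_width / 2
    lower, upper = _notch_bands(range_lo, range_hi, notch_lo, notch_hi, interval)
    support = np.concatenate([lower, upper])
    probs = np.full(support.size, 1.0 / support.size)
    return DiscreteDistribution(
        kind, support, probs, range_lo, range_hi, interval, notch=(notch_lo, notch_hi)
    )


def solve_band_tilt(
    band: Sequence[float], target_mean: float, tolerance: float = 1e-9
) -> np.ndarray:
    """Exponentially tilted weights steering a band's mean to ``target_mean``.

    Solves for λ in ``w_i ∝ exp(λ x_i)`` such that ``Σ w_i x_i = target_mean``
    (the maximum-entropy distribution on the band under that mean constraint).
    λ = 0 — uniform weights — is returned exactly when the target equals the
    unweighted band mean.  The target must lie strictly inside the open
    interval spanned by the band.
    """
    x = np.asarray(band, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ConfigurationError("band must be a non-empty 1-D grid")
    if x.size == 1:
        if abs(target_mean - x[0]) > tolerance:
            raise InfeasibleConstraintError(
                f"single-point band at {x[0]} cannot reach mean {target_mean}"
            )
        return np.array([1.0])
    lo, hi = float(x.min()), float(x.max())
    if not (lo < target_mean < hi):
        raise InfeasibleConstraintError(
            f"target mean {target_mean} outside open band interval ({lo}, {hi})"
        )
    base_mean = float(x.mean())
    if abs(target_mean - base_mean) <= min(tolerance, 1e-12) or (
        target_mean == base_mean
    ):
        return np.full(x.size, 1.0 / x.size)

    xc = x - base_mean  # shift-invariant; conditions the exponentials

    def tilted_mean(lam: float) -> float:
        z = lam * xc
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        return float(w @ x)

    # bracket λ by doubling from ±1
    f = lambda lam: tilted_mean(lam) - target_mean
    if target_mean > base_mean:
        a, b = 0.0, 1.0
        for _ in range(200):
            if f(b) >= 0:
                break
            b *= 2.0
        else:  # pragma: no cover - defensive
            raise InfeasibleConstraintError("tilt bracket expansion failed")
    else:
        a, b = -1.0, 0.0
        for _ in range(200):
            if f(a) <= 0:
                break
            a *= 2.0
        else:  # pragma: no cover - defensive
            raise InfeasibleConstraintError("tilt bracket expansion failed")
    lam = brentq(f, a, b, xtol=1e-12, rtol=8.9e-16, maxiter=500)
    z = lam * xc
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    achieved = float(w @ x)
    if abs(achieved - target_mean) > max(tolerance, 1e-9):
        raise InfeasibleConstraintError(
            f"tilt solver reached mean {achieved}, target {target_mean}"
        )
    return w


def _tilted_notched(
    range_lo,
    range_hi,
    notch_lo,
    notch_hi,
    interval,
    band_mean_targets,
    kind,
    tolerance=1e-9,
):
    """Shared builder: two bands with mass 1/2 each, tilted to target means."""
    lower, upper = _notch_bands(range_lo, range_hi, notch_lo, notch_hi, interval)
    weights = []
    for band, target in zip((lower, upper), band_mean_targets):
        if target is None:
            weights.append(np.full(band.size, 1.0 / band.size))
        else:
            weights.append(solve_band_tilt(band, target, tolerance=tolerance))
    support = np.concatenate([lower, upper])
    probs = np.concatenate([0.5 * weights[0], 0.5 * weights[1]])
    return DiscreteDistribution(
        kind, support, probs, range_lo, range_hi, interval, notch=(notch_lo, notch_hi)
    )


def build_mean_targeted_notched(
    band_range: float = 8.1,
    notch_width: float = 7.0,
    target_mean_distance: float | None = None,
    global_mean: float = 12.0,
    interval: float = 0.2,
    kind: str = "speed",
) -> DiscreteDistribution:
    """Comparison with a fixed notch and a *targeted* distance between band means.

    Two bands of width ``band_range`` flank a notch of ``notch_width`` centered
    on ``global_mean``; each band carries probability mass 1/2 and is tilted so
    its mean sits at ``global_mean ∓ target_mean_distance/2``.  With
    ``target_mean_distance=None`` the bands stay uniform (no tilt).
    """
    if band_range <= 0:
        raise ConfigurationError(f"band range must be positive, got {band_range}")
    notch_lo = global_mean - notch_width / 2
    notch_hi = global_mean + notch_width / 2
    range_lo = notch_lo - band_range
    range_hi = notch_hi + band_range
    if target_mean_distance is None:
        targets = (None, None)
    else:
        targets = (
            global_mean - target_mean_distance / 2,
            global_mean + target_mean_distance / 2,
        )
    return _tilted_notched(
        range_lo, range_hi, notch_lo, notch_hi, interval, targets, kind
    )


def build_bandwidth_family(
    total_span: float,
    notch_width: float = 7.0,
    global_mean: float = 12.0,
    interval: float = 0.2,
    kind: str = "speed",
) -> tuple[DiscreteDistribution, DiscreteDistribution]:
    """Standard/comparison pair at a given overall speed bandwidth.

    The standard is uniform over ``global_mean ± total_span/2``; the comparison
    is the symmetric-notch construction over the same span with the fixed
    notch.  Both share span, endpoints and global mean by construction.
    """
    if total_span <= notch_width + GRID_TOL:
        raise ConfigurationError(
            f"total span {total_span} must exceed the notch width {notch_width}"
        )
    range_lo = global_mean - total_span / 2
    range_hi = global_mean + total_span / 2
    standard = build_uniform(range_lo, range_hi, interval, kind=kind)
    comparison = build_symmetric_notched(
        range_lo, range_hi, notch_width, interval, kind=kind
    )
    return standard, comparison


def build_constant_distance_notched(
    range_lo: float,
    range_hi: float,
    notch_width: float,
    mean_distance: float,
    interval: float,
    kind: str = "speed",
) -> DiscreteDistribution:
    """Comparison whose band-mean distance is held fixed across notch widths.

    The notch is centered on the range midpoint; each band is tilted so its
    mean sits at ``midpoint ∓ mean_distance/2`` regardless of the notch width,
    keeping the global mean at the midpoint.  Used to dissociate the effect of
    the notch width from the separation between the component means.
    """
    if mean_distance < notch_width - GRID_TOL:
        raise InfeasibleConstraintError(
            f"mean distance {mean_distance} smaller than notch width "
            f"{notch_width}: band means would sit inside the notch"
        )
    mid = 0.5 * (range_lo + range_hi)
    notch_lo, notch_hi = mid - notch_width / 2, mid + notch_width / 2
    targets = (mid - mean_distance / 2, mid + mean_distance / 2)
    return _tilted_notched(
        range_lo, range_hi, notch_lo, notch_hi, interval, targets, kind
    )


def build_direction_gapped(
    span: float = 58.0,
    mean_dir: float = 30.0,
    gap_width: float = 0.0,
    interval: float = 1.0,
) -> DiscreteDistribution:
    """Direction distribution with a symmetric gap about the mean direction.

    ``gap_width=0`` yields the uniform standard over ``mean_dir ± span/2``.
    Direction arithmetic is linear (no circular wrap): supports span well under
    180° around the mean; any trial-level global rotation is applied later,
    modulo 360.
    """
    range_lo = mean_dir - span / 2
    range_hi = mean_dir + span / 2
    return build_symmetric_notched(
        range_lo, range_hi, gap_width, interval, kind="direction"
    )


# ---------------------------------------------------------------------------
# statistics and validation
# ---------------------------------------------------------------------------


def moments(dist: DiscreteDistribution) -> DistributionStats:
    """Exact global and per-band expectations of a distribution."""
    p = dist.probabilities / dist.probabilities.sum()
    global_mean = float(p @ dist.support)
    span = float(dist.range_hi - dist.range_lo)
    if dist.notch is None:
        return DistributionStats(global_mean=global_mean, span=span)
    notch_lo, notch_hi = dist.notch
    lower = dist.support <= notch_lo + GRID_TOL
    upper = dist.support >= notch_hi - GRID_TOL
    means = []
    for mask in (lower, upper):
        mass = p[mask].sum()
        means.append(float(p[mask] @ dist.support[mask] / mass) if mass > 0 else np.nan)
    return DistributionStats(
        global_mean=global_mean,
        span=span,
        band_means=(means[0], means[1]),
        mean_distance=abs(means[1] - means[0]),
        notch_width=float(notch_hi - notch_lo),
    )


def validate_matched(
    standard: DiscreteDistribution,
    comparison: DiscreteDistribution,
    tol: float = 1e-6,
) -> MatchReport:
    """Check the matched-statistics constraints of a standard/comparison pair.

    Equal span, equal outer endpoints, and equal global means within ``tol``.
    Returns a report listing every violated constraint with its magnitude.
    Comparing a speed distribution against a direction distribution is a usage
    error, not a failed match.
    """
    if standard.kind != comparison.kind:
        raise ConfigurationError(
            f"cannot match kinds {standard.kind!r} and {comparison.kind!r}"
        )
    s, c = moments(standard), moments(comparison)
    checks = {
        "span": abs(s.span - c.span),
        "range_lo": abs(standard.range_lo - comparison.range_lo),
        "range_hi": abs(standard.range_hi - comparison.range_hi),
        "global_mean": abs(s.global_mean - c.global_mean),
    }
    violations = tuple((name, mag) for name, mag in checks.items() if mag > tol)
    return MatchReport(passed=not violations, violations=violations, tol=tol)
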