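"""Experiment condition catalogues.

Four experiment families probe motion transparency with the 3AFC oddity task:

1. **Speed-notch width.**  Standard uniform over 0.4–23.6 deg/s (mean 12);
   comparisons carve out centered notches of 1–19 deg/s.
2. **Summary statistics.**  (a) Fixed 7 deg/s notch, 8.1 deg/s bands; the
   distance between the band means is steered by reweighting (13–17 deg/s).
   (b) Fixed 7 deg/s notch while the overall speed bandwidth varies (8–20
   deg/s), standard and comparison matched throughout.
3. **Slow vs fast ranges.**  Same construction on a slow (1.2–8 deg/s, mean
   4.6) and a fast (17.2–24 deg/s, mean 20.6) range; notch width varies while
   the distance between band means is held constant.
4. **Direction gaps.**  Uniform directions spanning 58° about 30°; comparisons
   with directional gaps 2–50°, at three fixed dot speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    ConfigurationError,
    DiscreteDistribution,
    build_bandwidth_family,
    build_constant_distance_notched,
    build_direction_gapped,
    build_mean_targeted_notched,
    build_symmetric_notched,
    build_uniform,
)

__all__ = [
    "Condition",
    "ExperimentConfig",
    "experiment1_conditions",
    "experiment2_mean_conditions",
    "experiment2_bandwidth_conditions",
    "experiment3_conditions",
    "experiment4_conditions",
    "make_conditions",
]

# Printed stimulus parameters of the four experiment families
EXP1_RANGE = (0.4, 23.6)
EXP1_INTERVAL = 1.0
EXP1_NOTCH_WIDTHS = (1.0, 4.0, 7.0, 10.0, 13.0, 16.0, 19.0)

EXP2_BAND_RANGE = 8.1
EXP2_NOTCH_WIDTH = 7.0
EXP2_GLOBAL_MEAN = 12.0
EXP2_INTERVAL = 0.2
EXP2_MEAN_DISTANCES = (13.0, 14.0, 15.0, 16.0, 17.0)
EXP2_BANDWIDTHS = (8.0, 11.0, 14.0, 17.0, 20.0)

EXP3_SLOW_RANGE = (1.2, 8.0)
EXP3_FAST_RANGE = (17.2, 24.0)
EXP3_INTERVAL = 0.4
EXP3_NOTCH_WIDTHS = (1.2, 2.0, 3.6, 5.2)
#: constant distance between band means, feasible for every notch width on
#: both ranges (the printed record states only that it was held constant)
EXP3_MEAN_DISTANCE = 6.0

EXP4_SPAN = 58.0
EXP4_MEAN_DIR = 30.0
EXP4_INTERVAL = 1.0
EXP4_GAP_WIDTHS = (2.0, 10.0, 18.0, 26.0, 34.0, 42.0, 50.0)
EXP4_SPEEDS = (4.0, 13.0, 22.0)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a matched standard/comparison pair."""

    experiment: int
    param: float  # the manipulated value (notch width, mean distance, ...)
    standard: DiscreteDistribution
    comparison: DiscreteDistribution
    label: str
    trial_speed: float | None = None  # fixed dot speed (direction conditions)


def experiment1_conditions(
    notch_widths=EXP1_NOTCH_WIDTHS, interval: float = EXP1_INTERVAL
) -> list[Condition]:
    lo, hi = EXP1_RANGE
    standard = build_uniform(lo, hi, interval)
    return [
        Condition(
            experiment=1,
            param=float(w),
            standard=standard,
            comparison=build_symmetric_notched(lo, hi, w, interval),
            label=f"notch_{w:g}",
        )
        for w in notch_widths
    ]


def experiment2_mean_conditions(
    mean_distances=EXP2_MEAN_DISTANCES, interval: float = EXP2_INTERVAL
) -> list[Condition]:
    comparison0 = build_mean_targeted_notched(interval=interval)
    standard = build_uniform(
        comparison0.range_lo, comparison0.range_hi, interval
    )
    return [
        Condition(
            experiment=2,
            param=float(d),
            standard=standard,
            comparison=build_mean_targeted_notched(
                target_mean_distance=d, interval=interval
            ),
            label=f"mean_distance_{d:g}",
        )
        for d in mean_distances
    ]


def experiment2_bandwidth_conditions(
    bandwidths=EXP2_BANDWIDTHS, interval: float = EXP2_INTERVAL
) -> list[Condition]:
    conditions = []
    for span in bandwidths:
        standard, comparison = build_bandwidth_family(span, interval=interval)
        conditions.append(
            Condition(
                experiment=2,
                param=float(span),
                standard=standard,
                comparison=comparison,
                label=f"bandwidth_{span:g}",
            )
        )
    return conditions


def experiment3_conditions(
    speed_range: str = "slow",
    notch_widths=EXP3_NOTCH_WIDTHS,
    mean_distance: float = EXP3_MEAN_DISTANCE,
    interval: float = EXP3_INTERVAL,
) -> list[Condition]:
    if speed_range == "slow":
        lo, hi = EXP3_SLOW_RANGE
    elif speed_range == "fast":
        lo, hi = EXP3_FAST_RANGE
    else:
        lo, hi = speed_range  # explicit (lo, hi) pair
    standard = build_uniform(lo, hi, interval)
    return [
        Condition(
            experiment=3,
            param=float(w),
            standard=standard,
            comparison=build_constant_distance_notched(
                lo, hi, w, mean_distance, interval
            ),
            label=f"{speed_range}_notch_{w:g}",
        )
        for w in notch_widths
    ]


def experiment4_conditions(
    gap_widths=EXP4_GAP_WIDTHS,
    speeds=EXP4_SPEEDS,
    interval: float = EXP4_INTERVAL,
) -> list[Condition]:
    standard = build_direction_gapped(
        EXP4_SPAN, EXP4_MEAN_DIR, 0.0, interval
    )
    return [
        Condition(
            experiment=4,
            param=float(g),
            standard=standard,
            comparison=build_direction_gapped(EXP4_SPAN, EXP4_MEAN_DIR, g, interval),
            label=f"speed_{s:g}_gap_{g:g}",
            trial_speed=float(s),
        )
        for s in speeds
        for g in gap_widths
    ]


_ENUMERATIONS = {
    1: ("notch_widths", EXP1_NOTCH_WIDTHS),
    2: ("mean_distances", EXP2_MEAN_DISTANCES),
    3: ("notch_widths", EXP3_NOTCH_WIDTHS),
    4: ("gap_widths", EXP4_GAP_WIDTHS),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated parameter set for one experiment family.

    Parameter values must come from the catalogued enumerations unless
    ``strict=False`` (useful for e.g. chance-floor control conditions).
    """

    experiment: int
    notch_widths: tuple = ()
    mean_distances: tuple = ()
    bandwidths: tuple = ()
    gap_widths: tuple = ()
    speeds: tuple = EXP4_SPEEDS
    speed_range: str = "slow"
    mean_distance: float = EXP3_MEAN_DISTANCE
    variant: str = "mean"  # experiment 2: "mean" or "bandwidth"
    interval: float | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3, 4):
            raise ConfigurationError(f"unknown experiment {self.experiment}")
        if self.strict:
            for name, allowed in (
                ("notch_widths", EXP1_NOTCH_WIDTHS if self.experiment == 1 else EXP3_NOTCH_WIDTHS),
                ("mean_distances", EXP2_MEAN_DISTANCES),
                ("bandwidths", EXP2_BANDWIDTHS),
                ("gap_widths", EXP4_GAP_WIDTHS),
                ("speeds", EXP4_SPEEDS),
            ):
                for v in getattr(self, name):
                    if not any(np.isclose(v, a) for a in allowed):
                        raise ConfigurationError(
                            f"{name} value {v} is not one of the catalogued "
                            f"levels {allowed}"
                        )

    def conditions(self) -> list[Condition]:
        interval = self.interval
        if self.experiment == 1:
            widths = self.notch_widths or EXP1_NOTCH_WIDTHS
            return experiment1_conditions(widths, interval or EXP1_INTERVAL)
        if self.experiment == 2:
            if self.variant == "bandwidth":
                spans = self.bandwidths or EXP2_BANDWIDTHS
                return experiment2_bandwidth_conditions(spans, interval or EXP2_INTERVAL)
            distances = self.mean_distances or EXP2_MEAN_DISTANCES
            return experiment2_mean_conditions(distances, interval or EXP2_INTERVAL)
        if self.experiment == 3:
            widths = self.notch_widths or EXP3_NOTCH_WIDTHS
            return experiment3_conditions(
                self.speed_range, widths, self.mean_distance, interval or EXP3_INTERVAL
            )
        widths = self.gap_widths or EXP4_GAP_WIDTHS
        return experiment4_conditions(widths, self.speeds, interval or EXP4_INTERVAL)


def make_conditions(experiment: int, **overrides) -> list[Condition]:
    """Convenience: conditions for an experiment id with keyword overrides."""
    return ExperimentConfig(experiment=experiment, **overrides).conditions()
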