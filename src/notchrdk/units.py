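"""Centralized unit conversions.

All angles are degrees of visual angle, speeds deg/s, and per-update dot
displacements are quoted in arc min where the displacement-limit task uses
them.
"""

from __future__ import annotations

ARCMIN_PER_DEG = 60.0


def deg_to_arcmin(deg: float) -> float:
    return deg * ARCMIN_PER_DEG


def arcmin_to_deg(arcmin: float) -> float:
    return arcmin / ARCMIN_PER_DEG


def displacement_to_speed(displacement_deg: float, update_rate_hz: float) -> float:
    """Dot speed (deg/s) sustained by a fixed per-update displacement."""
    return displacement_deg * update_rate_hz


def arcmin_displacement_to_speed(displacement_arcmin: float, update_rate_hz: float) -> float:
    return displacement_to_speed(arcmin_to_deg(displacement_arcmin), update_rate_hz)
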