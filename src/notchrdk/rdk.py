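"""Random-dot kinematogram kinematics.

Generates the frame-by-frame dot trajectories of an RDK interval: dots are
scattered uniformly over a circular aperture, and on every positional update
each dot independently redraws its speed (or direction) from the governing
discrete distribution — dot identity carries no speed information, so an
observer cannot find the extreme speeds by tracking single dots.  Dots leaving
the aperture re-enter on the opposite side (point reflection through the
aperture center).

Positions are kept as continuous degrees of visual angle; pixel quantization
only happens in :func:`rasterize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import DiscreteDistribution

__all__ = [
    "StimulusSpec",
    "DotField",
    "FrameSequence",
    "speed_to_displacement",
    "init_dot_field",
    "wrap_position",
    "advance",
    "generate_interval",
    "rasterize",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and timing of one RDK interval.

    Defaults describe the reference stimulus: 226 dark dots (2 dots/deg²) in a
    12°-diameter aperture, 10 images at an 18.75 Hz update rate (every 4th
    frame of a 75 Hz display), i.e. a ~533 ms motion sequence, with 500 ms
    inter-stimulus intervals.
    """

    n_dots: int = 226
    aperture_diameter: float = 12.0  # deg
    dot_diameter: float = 0.1  # deg
    dot_luminance: float = 0.05  # cd/m^2
    background_luminance: float = 25.0  # cd/m^2
    update_rate: float = 18.75  # Hz
    n_updates: int = 10
    isi_ms: float = 500.0
    monitor_refresh: float = 75.0  # Hz, metadata only
    nominal_dot_density: float = 2.0  # dots/deg^2

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError(f"n_dots must be positive, got {self.n_dots}")
        if self.aperture_diameter <= 0 or self.dot_diameter <= 0:
            raise ValueError("aperture and dot diameters must be positive")
        if self.update_rate <= 0 or self.n_updates < 1:
            raise ValueError("update rate and update count must be positive")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def dot_density(self) -> float:
        """Realized dot density (dots/deg^2) over the aperture area."""
        return self.n_dots / (np.pi * self.aperture_radius**2)

    @property
    def duration_ms(self) -> float:
        """Sequence duration implied by the update count and rate."""
        return 1000.0 * self.n_updates / self.update_rate


@dataclass(frozen=True)
class DotField:
    """Instantaneous state of the dot field at one positional update."""

    positions: np.ndarray  # (n_dots, 2) deg, relative to aperture center
    speeds: np.ndarray  # (n_dots,) deg/s drawn at this update
    directions: np.ndarray  # (n_dots,) deg drawn at this update

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])


@dataclass(frozen=True)
class FrameSequence:
    """Stacked dot states of one RDK interval, one entry per update.

    ``speeds[k]`` / ``directions[k]`` are the values drawn at update ``k``
    (the draw at update 0 is the onset velocity; draws at k ≥ 1 produced the
    displacement from frame k−1 to frame k).
    """

    positions: np.ndarray  # (n_updates, n_dots, 2)
    speeds: np.ndarray  # (n_updates, n_dots)
    directions: np.ndarray  # (n_updates, n_dots)
    spec: StimulusSpec
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.positions.shape[0] != self.spec.n_updates:
            raise ValueError("frame count must equal the spec's update count")

    @property
    def n_updates(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    def frame(self, k: int) -> DotField:
        return DotField(self.positions[k], self.speeds[k], self.directions[k])


def speed_to_displacement(speed: float, update_rate: float = 18.75) -> float:
    """Per-update displacement (deg) sustained by ``speed`` deg/s."""
    if np.any(np.asarray(speed) < 0):
        raise ValueError(f"speed must be nonnegative, got {speed}")
    return speed / update_rate


def init_dot_field(spec: StimulusSpec, rng: np.random.Generator) -> DotField:
    """Scatter dots uniformly over the aperture *area* (density-uniform)."""
    r = spec.aperture_radius * np.sqrt(rng.random(spec.n_dots))
    theta = rng.uniform(0.0, 2.0 * np.pi, spec.n_dots)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    zeros = np.zeros(spec.n_dots)
    return DotField(positions, zeros.copy(), zeros.copy())


def wrap_position(pos, proposed, aperture_radius: float):
    """Wrap a single dot's proposed position to the opposite aperture side.

    A proposal inside the aperture is returned unchanged; one outside is point-
    reflected through the aperture center and pulled onto the rim, so the
    result always lies within the aperture.
    """
    proposed = np.asarray(proposed, dtype=float)
    norm = float(np.hypot(proposed[0], proposed[1]))
    if norm <= aperture_radius:
        return proposed
    return -proposed * (aperture_radius / norm)


def _wrap_many(proposed: np.ndarray, aperture_radius: float) -> np.ndarray:
    norms = np.hypot(proposed[:, 0], proposed[:, 1])
    out = norms > aperture_radius
    if np.any(out):
        proposed = proposed.copy()
        proposed[out] = -proposed[out] * (aperture_radius / norms[out])[:, None]
    return proposed


def _draw(source, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-dot values from a distribution, or a broadcast fixed value."""
    if isinstance(source, DiscreteDistribution):
        return source.sample(n, rng)
    return np.full(n, float(source))


def _check_sources(speed_source, direction_source) -> None:
    both_dist = isinstance(speed_source, DiscreteDistribution) and isinstance(
        direction_source, DiscreteDistribution
    )
    if both_dist:
        raise ValueError(
            "at most one of speed and direction may vary within an interval"
        )
    if isinstance(speed_source, DiscreteDistribution) and speed_source.kind != "speed":
        raise ValueError(f"speed source has kind {speed_source.kind!r}")
    if (
        isinstance(direction_source, DiscreteDistribution)
        and direction_source.kind != "direction"
    ):
        raise ValueError(f"direction source has kind {direction_source.kind!r}")


def advance(
    field: DotField,
    speed_source,
    direction_source,
    spec: StimulusSpec,
    rng: np.random.Generator,
) -> DotField:
    """One positional update: redraw velocities, displace, wrap.

    ``speed_source`` and ``direction_source`` are each either a
    :class:`DiscreteDistribution` (resampled with replacement per dot on this
    update) or a fixed scalar; at most one of them may be a distribution.
    """
    _check_sources(speed_source, direction_source)
    n = field.n_dots
    speeds = _draw(speed_source, n, rng)
    directions = _draw(direction_source, n, rng)
    step = speeds / spec.update_rate
    rad = np.deg2rad(directions)
    proposed = field.positions + np.column_stack(
        [step * np.cos(rad), step * np.sin(rad)]
    )
    positions = _wrap_many(proposed, spec.aperture_radius)
    return DotField(positions, speeds, directions)


def generate_interval(
    spec: StimulusSpec,
    speed_source,
    direction_source,
    rng: np.random.Generator,
    provenance: str = "",
    seed: int | None = None,
) -> FrameSequence:
    """Full dot-trajectory sequence of one RDK interval.

    Dots are scattered afresh, onset velocities drawn, then ``n_updates - 1``
    advances applied — every interval is generated anew, so two standards on
    the same trial contain different dot samples.
    """
    _check_sources(speed_source, direction_source)
    field = init_dot_field(spec, rng)
    field = DotField(
        field.positions,
        _draw(speed_source, spec.n_dots, rng),
        _draw(direction_source, spec.n_dots, rng),
    )
    positions = np.empty((spec.n_updates, spec.n_dots, 2))
    speeds = np.empty((spec.n_updates, spec.n_dots))
    directions = np.empty((spec.n_updates, spec.n_dots))
    for k in range(spec.n_updates):
        if k > 0:
            field = advance(field, speed_source, direction_source, spec, rng)
        positions[k] = field.positions
        speeds[k] = field.speeds
        directions[k] = field.directions
    return FrameSequence(
        positions, speeds, directions, spec, provenance=provenance, seed=seed
    )


def rasterize(
    field: DotField, spec: StimulusSpec, pixels_per_deg: float = 44.4
) -> np.ndarray:
    """Render a dot field to a 2-D luminance image (cd/m² values).

    Deterministic nearest-pixel stamping of dark disks of ``dot_diameter`` on
    the background level; the default resolution matches a 1.35 arc min/pixel
    display.
    """
    if pixels_per_deg <= 0:
        raise ValueError("pixels_per_deg must be positive")
    half = spec.aperture_radius + spec.dot_diameter
    n_px = int(np.ceil(2 * half * pixels_per_deg)) + 1
    image = np.full((n_px, n_px), spec.background_luminance)
    coords = (np.arange(n_px) + 0.5) / pixels_per_deg - half
    dot_r = spec.dot_diameter / 2.0
    r_px = int(np.ceil(dot_r * pixels_per_deg)) + 1
    for x, y in field.positions:
        cx = int(np.floor((x + half) * pixels_per_deg))
        cy = int(np.floor((y + half) * pixels_per_deg))
        xs = slice(max(cx - r_px, 0), min(cx + r_px + 1, n_px))
        ys = slice(max(cy - r_px, 0), min(cy + r_px + 1, n_px))
        dx = coords[xs] - x
        dy = coords[ys] - y
        mask = dx[None, :] ** 2 + dy[:, None] ** 2 <= dot_r**2
        patch = image[ys, xs]
        patch[mask] = spec.dot_luminance
        image[ys, xs] = patch
    return image
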