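"""File output: trajectory CSVs, session logs, summaries, metadata, fixtures.

Every written artifact is deterministic given (config, seed): metadata files
carry seeds, the package version and a config hash, but no timestamps, so a
re-run is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .distributions import build_symmetric_notched, build_uniform
from .rdk import StimulusSpec, generate_interval
from .task import Trial, run_session
from .experiments import experiment1_conditions
from .observers import GuessingObserver

__all__ = [
    "write_trajectory_csv",
    "write_session_log",
    "write_summary",
    "write_metadata",
    "make_fixtures",
]

TRAJECTORY_COLUMNS = [
    "trial_id",
    "interval_index",
    "update_index",
    "dot_id",
    "x_deg",
    "y_deg",
    "speed_deg_per_s",
    "direction_deg",
]

_TRAJECTORY_HEADER = (
    "# RDK dot trajectories: one row per dot per positional update\n"
    "# units: x_deg, y_deg in deg relative to aperture center; "
    "speed_deg_per_s in deg/s; direction_deg in deg\n"
)


def _sequence_rows(seq, trial_id: int, interval_index: int):
    for k in range(seq.n_updates):
        for d in range(seq.n_dots):
            yield (
                trial_id,
                interval_index,
                k,
                d,
                seq.positions[k, d, 0],
                seq.positions[k, d, 1],
                seq.speeds[k, d],
                seq.directions[k, d],
            )


def write_trajectory_csv(source, path, trial_id: int = 0) -> Path:
    """Write the dot trajectories of a Trial or FrameSequence to CSV."""
    if isinstance(source, Trial):
        sequences = list(enumerate(source.intervals, start=1))
        trial_id = source.trial_id
    else:
        sequences = [(1, source)]
    rows = [
        row
        for idx, seq in sequences
        for row in _sequence_rows(seq, trial_id, idx)
    ]
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRAJECTORY_HEADER)
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def write_session_log(log: pd.DataFrame, path) -> Path:
    path = Path(path)
    log.to_csv(path, index=False)
    return path


def write_summary(summary: pd.DataFrame, path) -> Path:
    path = Path(path)
    summary.to_csv(path, index=False, float_format="%.6g")
    return path


def write_metadata(path, seed=None, config=None, **extras) -> Path:
    """JSON sidecar describing how an output was produced (no timestamps)."""
    meta = {"package": "notchrdk", "version": __version__, "seed": seed}
    if config is not None:
        meta["config"] = config.model_dump() if hasattr(config, "model_dump") else config
        if hasattr(config, "config_hash"):
            meta["config_hash"] = config.config_hash()
    meta.update(extras)
    path = Path(path)
    path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Tiny deterministic datasets for tests and demos (< 1 s to generate).

    Writes the reference standard speed distribution, a wide-notch comparison,
    a 3-dot / 10-update trajectory, and a 30-trial guessing-observer log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import numpy as np

    paths: dict[str, Path] = {}

    standard = build_uniform(0.4, 23.6, 1.0)
    comparison = build_symmetric_notched(0.4, 23.6, 19.0, 1.0)
    paths["standard"] = out / "standard_speed.json"
    standard.to_json(paths["standard"])
    paths["comparison"] = out / "comparison_notch19.json"
    comparison.to_json(paths["comparison"])

    rng = np.random.default_rng(seed)
    tiny_spec = StimulusSpec(n_dots=3)
    seq = generate_interval(tiny_spec, standard, 90.0, rng, provenance="fixture")
    paths["trajectory"] = write_trajectory_csv(seq, out / "trajectory_3dots.csv")

    conditions = experiment1_conditions(notch_widths=(19.0,))
    log = run_session(
        conditions,
        GuessingObserver(),
        n_trials_per_condition=30,
        spec=StimulusSpec(n_dots=8, n_updates=3),
        seed=seed,
    )
    paths["log"] = write_session_log(log, out / "guessing_log_30.csv")
    write_metadata(out / "fixtures_meta.json", seed=seed, files=sorted(p.name for p in paths.values()))
    return paths
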