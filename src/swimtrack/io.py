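"""CSV readers and writers for the pipeline's tabular interchange formats.

Detections:   frame, x_um, y_um
Trajectories: track_id, frame, t_s, x_um, y_um
Truth paths:  track_id, frame, t_s, x_um, y_um, mode, phase
Labels:       track_id, frame, phase
Episodes:     track_id, episode_idx, kind, start_frame, end_frame, mean_speed_um_s
Spreading:    strain, agar_pct, t_h, diameter_mm
Modes:        run_id, strain, env, mode
"""

from __future__ import annotations

import pandas as pd

DETECTION_COLUMNS = ["frame", "x_um", "y_um"]
TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
TRUTH_COLUMNS = TRAJECTORY_COLUMNS + ["mode", "phase"]
SPREADING_COLUMNS = ["strain", "agar_pct", "t_h", "diameter_mm"]
MODE_COLUMNS = ["run_id", "strain", "env", "mode"]


def _require(df: pd.DataFrame, columns, what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing columns {missing}")
    return df


def read_detections(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), DETECTION_COLUMNS, "detections")


def write_detections(df: pd.DataFrame, path) -> None:
    _require(df, DETECTION_COLUMNS, "detections")[DETECTION_COLUMNS].to_csv(
        path, index=False
    )


def read_trajectories(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), TRAJECTORY_COLUMNS, "trajectories")


def write_trajectories(df: pd.DataFrame, path, truth: bool = False) -> None:
    cols = TRUTH_COLUMNS if truth else TRAJECTORY_COLUMNS
    _require(df, cols, "trajectories")[cols].to_csv(path, index=False)


def read_spreading(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), SPREADING_COLUMNS, "spreading")


def write_spreading(df: pd.DataFrame, path) -> None:
    _require(df, SPREADING_COLUMNS, "spreading")[SPREADING_COLUMNS].to_csv(
        path, index=False
    )


def read_mode_annotations(path) -> pd.DataFrame:
    return _require(pd.read_csv(path), MODE_COLUMNS, "mode annotations")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
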