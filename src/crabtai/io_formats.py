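"""Readers and writers for the pipeline's tabular file formats.

Pose tracks use the standard pose-estimation CSV dialect: three header rows
(``scorer``, ``bodyparts``, ``coords``), a frame-index first column, and an
``x, y, likelihood`` column triple per keypoint. Bout tables, confidence
traces and cohort tables are plain single-header CSV files. All writers are
inverted exactly by the matching readers (field-for-field round trips), and
parsing is locale-independent: decimal points only, columns in the
documented order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import BoutRecord
from .config import BEHAVIORS, KEYPOINTS, load_config  # noqa: F401  (re-export)
from .errors import FormatError, ParseError, SchemaError, ValidationError
from .tracks import ConfidenceTrace, PoseTrack

__all__ = [
    "read_pose_csv",
    "write_pose_csv",
    "read_confidence_csv",
    "write_confidence_csv",
    "read_bout_table",
    "write_bout_table",
    "read_cohort_table",
    "write_cohort_table",
    "load_config",
]

BOUT_COLUMNS = ["behavior", "start_frame", "end_frame", "duration_s", "mean_confidence"]


# ---------------------------------------------------------------------------
# pose tracks


def write_pose_csv(track: PoseTrack, path: str | Path, scorer: str = "crabtai") -> None:
    """Write a pose track in the three-header-row CSV dialect."""
    k = len(track.keypoints)
    header1 = ["scorer"] + [scorer] * (3 * k)
    header2 = ["bodyparts"] + [kp for kp in track.keypoints for _ in range(3)]
    header3 = ["coords"] + ["x", "y", "likelihood"] * k
    data = np.empty((track.n_frames, 3 * k))
    data[:, 0::3] = track.x
    data[:, 1::3] = track.y
    data[:, 2::3] = track.likelihood
    with open(path, "w") as fh:
        for row in (header1, header2, header3):
            fh.write(",".join(row) + "\n")
        for i in range(track.n_frames):
            fh.write(str(i) + "," + ",".join(repr(float(v)) for v in data[i]) + "\n")


def read_pose_csv(path: str | Path, fps: float = 30.0,
                  require_13_keypoints: bool = True) -> PoseTrack:
    """Read a pose track from the three-header-row CSV dialect.

    The frame rate is not stored in the file and must be supplied. By
    default exactly 13 keypoints are required (set
    ``require_13_keypoints=False`` to accept other body plans).

    Raises
    ------
    FormatError
        Missing or misnamed header rows.
    SchemaError
        Wrong column multiple or keypoint count.
    ParseError
        A non-numeric data cell (named by row and column).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: expected 3 header rows, found {len(lines)} lines")
    headers = [line.split(",") for line in lines[:3]]
    labels = [h[0].strip().lower() for h in headers]
    if labels != ["scorer", "bodyparts", "coords"]:
        raise FormatError(
            f"{path}: header rows must be scorer/bodyparts/coords, got {labels}"
        )
    bodyparts_row, coords_row = headers[1][1:], headers[2][1:]
    n_cols = len(coords_row)
    if n_cols == 0 or n_cols % 3 != 0 or len(bodyparts_row) != n_cols:
        raise SchemaError(f"{path}: expected an x,y,likelihood triple per keypoint")
    if coords_row != ["x", "y", "likelihood"] * (n_cols // 3):
        raise FormatError(f"{path}: coords row must cycle x,y,likelihood")
    keypoints = tuple(bodyparts_row[0::3])
    if bodyparts_row != [kp for kp in keypoints for _ in range(3)]:
        raise SchemaError(f"{path}: bodyparts row does not repeat each name 3 times")
    if require_13_keypoints and len(keypoints) != 13:
        raise SchemaError(
            f"{path}: expected 13 keypoints, found {len(keypoints)} "
            "(pass require_13_keypoints=False to override)"
        )
    n_frames = len(lines) - 3
    data = np.empty((n_frames, n_cols))
    for i, line in enumerate(lines[3:]):
        cells = line.split(",")
        if len(cells) != n_cols + 1:
            raise SchemaError(
                f"{path}: data row {i} has {len(cells)} cells, expected {n_cols + 1}"
            )
        for j, cell in enumerate(cells[1:]):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at data row {i}, "
                    f"column {j + 1}"
                ) from None
    track = PoseTrack(
        fps=fps,
        x=data[:, 0::3],
        y=data[:, 1::3],
        likelihood=data[:, 2::3],
        keypoints=keypoints,
    )
    return track


# ---------------------------------------------------------------------------
# confidence traces


def write_confidence_csv(trace: ConfidenceTrace, path: str | Path) -> None:
    """Write a per-frame confidence trace (frame + one column per category)."""
    df = pd.DataFrame(trace.probabilities, columns=list(trace.behaviors))
    df.insert(0, "frame", np.arange(trace.n_frames))
    df.to_csv(path, index=False)


def read_confidence_csv(path: str | Path, fps: float = 30.0) -> ConfidenceTrace:
    """Read a per-frame confidence trace written by :func:`write_confidence_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["frame", *BEHAVIORS]
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return ConfidenceTrace(fps=fps, probabilities=df[list(BEHAVIORS)].to_numpy())


# ---------------------------------------------------------------------------
# bout tables


def write_bout_table(bouts: list[BoutRecord], path: str | Path) -> None:
    """Write one row per bout: behavior, start/end frame, duration, confidence."""
    df = pd.DataFrame(
        [
            {
                "behavior": b.behavior,
                "start_frame": b.start_frame,
                "end_frame": b.end_frame,
                "duration_s": b.duration_s,
                "mean_confidence": b.mean_confidence,
            }
            for b in bouts
        ],
        columns=BOUT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_bout_table(path: str | Path, fps: float = 30.0,
                    duration_tol_s: float | None = None) -> list[BoutRecord]:
    """Read a bout table, validating durations against the frame interval.

    Each row's duration is checked against ``(end - start + 1) / fps``; a
    discrepancy beyond the tolerance (half a frame by default, to absorb
    rounded durations) is a validation error, as is ``end < start``.
    """
    df = pd.read_csv(path)
    if list(df.columns) != BOUT_COLUMNS:
        raise SchemaError(f"{path}: expected columns {BOUT_COLUMNS}, got {list(df.columns)}")
    tol = duration_tol_s if duration_tol_s is not None else 0.51 / fps
    bouts = []
    for i, row in df.iterrows():
        start, end = int(row["start_frame"]), int(row["end_frame"])
        if end < start:
            raise ValidationError(f"{path}: row {i}: end_frame {end} < start_frame {start}")
        implied = (end - start + 1) / fps
        if abs(float(row["duration_s"]) - implied) > tol:
            raise ValidationError(
                f"{path}: row {i}: duration {row['duration_s']} inconsistent with "
                f"frames [{start}, {end}] at {fps} fps (implied {implied:.4f} s)"
            )
        bouts.append(
            BoutRecord(
                behavior=str(row["behavior"]),
                start_frame=start,
                end_frame=end,
                duration_s=float(row["duration_s"]),
                mean_confidence=float(row["mean_confidence"]),
            )
        )
    return bouts


# ---------------------------------------------------------------------------
# cohort tables


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a per-individual cohort table (id, tai, frequency, ...)."""
    if "id" not in cohort.columns or "tai" not in cohort.columns:
        raise SchemaError("cohort table requires at least 'id' and 'tai' columns")
    cohort.to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns or "tai" not in df.columns:
        raise SchemaError(f"{path}: cohort table requires 'id' and 'tai' columns")
    return df
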