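"""Kinematic features from pose tracks.

The two features consumed by the reference regression model are computed
here: the relative movement distance X1 (centroid path length normalized by
the animal's carapace width, hence dimensionless and invariant to camera
placement and pixel scale) and the freezing duration X2 (total time in
sustained low-speed spells). Both are built on a per-frame body centroid
from the carapace keypoints. Low-likelihood keypoint detections are masked
before any feature is computed, and short gaps are filled by linear
interpolation; gaps longer than the interpolation window remain missing and
simply do not contribute to distances or speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import ConfigError, FeatureError, ValidationError
from .tracks import PoseTrack

__all__ = [
    "CentroidPath",
    "filter_low_likelihood",
    "body_centroid",
    "carapace_width",
    "relative_movement_distance",
    "freezing_duration",
    "keypoint_error",
]


@dataclass
class CentroidPath:
    """Per-frame body centroid with a validity flag.

    Invalid frames (too few visible body keypoints) are flagged rather than
    interpolated; downstream distance/speed computations skip them.
    """

    fps: float
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]


def _fill_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap.

    Leading and trailing gaps are never extrapolated.
    """
    out = values.copy()
    if max_gap <= 0:
        return out
    isnan = np.isnan(out)
    if not isnan.any() or isnan.all():
        return out
    n = out.size
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap <= max_gap:
            left, right = out[i - 1], out[j]
            t = np.arange(1, gap + 1) / (gap + 1)
            out[i:j] = left + t * (right - left)
        i = j
    return out


def filter_low_likelihood(
    track: PoseTrack,
    likelihood_threshold: float = 0.95,
    max_interp_frames: int = 5,
) -> PoseTrack:
    """Mask keypoint observations below the likelihood threshold.

    Observations with likelihood strictly below the threshold are marked
    missing (NaN coordinates, likelihood 0). Interior gaps of at most
    ``max_interp_frames`` frames are then filled by linear interpolation per
    coordinate; longer gaps and gaps touching either end of the track stay
    missing.
    """
    if not 0.0 <= likelihood_threshold <= 1.0:
        raise ConfigError("likelihood_threshold must lie in [0, 1]")
    out = track.copy()
    low = out.likelihood < likelihood_threshold
    out.x[low] = np.nan
    out.y[low] = np.nan
    out.likelihood[low] = 0.0
    for k in range(len(out.keypoints)):
        out.x[:, k] = _fill_short_gaps(out.x[:, k], max_interp_frames)
        out.y[:, k] = _fill_short_gaps(out.y[:, k], max_interp_frames)
    return out


def body_centroid(
    track: PoseTrack,
    keypoints: tuple[str, ...] = ("LBODY", "RBOD", "HEAD"),
) -> CentroidPath:
    """Per-frame mean position of the available body keypoints.

    A frame is valid only if at least two of the chosen keypoints are
    visible; invalid frames are flagged and their coordinates set to NaN.
    """
    if len(keypoints) == 0:
        raise ConfigError("centroid keypoint set must not be empty")
    cols = [track.keypoint_index(k) for k in keypoints]
    xs = track.x[:, cols]
    ys = track.y[:, cols]
    available = ~(np.isnan(xs) | np.isnan(ys))
    n_avail = available.sum(axis=1)
    valid = n_avail >= min(2, len(keypoints))
    denom = np.where(n_avail > 0, n_avail, 1)
    cx = np.where(valid, np.where(available, xs, 0.0).sum(axis=1) / denom, np.nan)
    cy = np.where(valid, np.where(available, ys, 0.0).sum(axis=1) / denom, np.nan)
    return CentroidPath(fps=track.fps, x=cx, y=cy, valid=valid)


def carapace_width(track: PoseTrack) -> float:
    """Median Euclidean LBODY–RBOD distance over frames where both are visible."""
    li, ri = track.keypoint_index("LBODY"), track.keypoint_index("RBOD")
    dx = track.x[:, li] - track.x[:, ri]
    dy = track.y[:, li] - track.y[:, ri]
    d = np.hypot(dx, dy)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise FeatureError("carapace width undefined: LBODY/RBOD never jointly visible")
    width = float(np.median(d))
    if width <= 0:
        raise FeatureError("median carapace width is zero")
    return width


def relative_movement_distance(
    track: PoseTrack, config: PipelineConfig | None = None
) -> float:
    """Relative movement distance X1 (dimensionless).

    Sum of Euclidean centroid displacements over consecutive valid frame
    pairs, divided by the median carapace width. Displacements spanning an
    invalid frame are skipped, never bridged.
    """
    config = config or PipelineConfig()
    path = body_centroid(track, config.centroid_keypoints)
    ok = path.valid[:-1] & path.valid[1:]
    if not ok.any():
        raise FeatureError("no valid consecutive frame pair for movement distance")
    dx = np.diff(path.x)[ok]
    dy = np.diff(path.y)[ok]
    return float(np.hypot(dx, dy).sum() / carapace_width(track))


def _centroid_speed(path: CentroidPath) -> np.ndarray:
    """Per-frame centroid speed (px/s); NaN where neighbors are invalid.

    Central differences over valid neighbors in the interior; one-sided
    differences at the track ends so a fully stationary trial is freezing
    for its entire duration.
    """
    n = path.n_frames
    speed = np.full(n, np.nan)
    if n < 2:
        return speed
    x, y, v = path.x, path.y, path.valid
    # interior: central difference
    ok = v[:-2] & v[2:]
    disp = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    speed[1:-1] = np.where(ok, disp * path.fps / 2.0, np.nan)
    if v[0] and v[1]:
        speed[0] = np.hypot(x[1] - x[0], y[1] - y[0]) * path.fps
    if v[-1] and v[-2]:
        speed[-1] = np.hypot(x[-1] - x[-2], y[-1] - y[-2]) * path.fps
    return speed


def freezing_duration(track: PoseTrack, config: PipelineConfig | None = None) -> float:
    """Freezing duration X2 (seconds).

    Total time spent in maximal runs of frames whose centroid speed is below
    ``config.freeze_speed_threshold`` (carapace widths per second) that last
    at least ``config.min_freeze_s`` seconds. Frames with undefined speed
    (invalid neighbors) break runs.
    """
    config = config or PipelineConfig()
    path = body_centroid(track, config.centroid_keypoints)
    if not path.valid.any():
        raise FeatureError("no valid frames for freezing detection")
    speed = _centroid_speed(path)
    threshold_px = config.freeze_speed_threshold * carapace_width(track)
    with np.errstate(invalid="ignore"):
        still = ~np.isnan(speed) & (speed < threshold_px)
    min_frames = max(1, int(np.ceil(config.min_freeze_s * path.fps)))
    total_frames = 0
    run = 0
    for flag in still:
        if flag:
            run += 1
        else:
            if run >= min_frames:
                total_frames += run
            run = 0
    if run >= min_frames:
        total_frames += run
    return total_frames / path.fps


def keypoint_error(
    predicted: PoseTrack, annotated: PoseTrack
) -> tuple[float, float, dict[str, float]]:
    """Mean pixel localization error between predicted and annotated tracks.

    The error of one (frame, keypoint) pair is the Euclidean distance
    between the predicted and annotated coordinates; pairs where either
    observation is missing are excluded. Returns the overall mean, the
    standard deviation over pairs, and a per-keypoint mean breakdown.
    """
    if predicted.n_frames != annotated.n_frames:
        raise ValidationError("tracks cover different frame sets")
    if predicted.keypoints != annotated.keypoints:
        raise ValidationError("tracks have different keypoint sets")
    d = np.hypot(predicted.x - annotated.x, predicted.y - annotated.y)
    usable = ~(predicted.missing() | annotated.missing())
    if not usable.any():
        raise ValidationError("no jointly annotated (frame, keypoint) pair")
    flat = d[usable]
    per_kp = {}
    for j, name in enumerate(predicted.keypoints):
        col = d[:, j][usable[:, j]]
        per_kp[name] = float(col.mean()) if col.size else float("nan")
    return float(flat.mean()), float(flat.std(ddof=1)) if flat.size > 1 else 0.0, per_kp
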