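"""Bout extraction: from per-frame classifier confidence to discrete episodes.

A *bout* is a maximal contiguous run of frames whose classifier confidence
strictly exceeds the confidence threshold and whose length meets the minimum
bout duration. The strict inequality follows the classifier's operating
rule (confidence > 0.5), so frames at exactly the threshold are excluded;
the minimum duration (180 ms by default) is converted to frames with a
ceiling, because it is a lower bound the bout must meet.

Frame intervals are 0-based and inclusive at both ends, so a bout spanning
frames ``[s, e]`` lasts ``(e - s + 1) / fps`` seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import BEHAVIORS, PipelineConfig
from .errors import ParameterError, ValidationError
from .tracks import ConfidenceTrace

__all__ = [
    "BoutRecord",
    "TrialSummary",
    "min_bout_frames",
    "extract_bouts",
    "extract_all_bouts",
    "aggregate_durations",
    "first_attack_latency",
]


@dataclass(frozen=True)
class BoutRecord:
    """One contiguous episode of a behavior category."""

    behavior: str
    start_frame: int
    end_frame: int
    duration_s: float
    mean_confidence: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {self.behavior!r}")
        if self.end_frame < self.start_frame:
            raise ValidationError(
                f"end_frame {self.end_frame} < start_frame {self.start_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial behavioral aggregates feeding the aggression index.

    Durations are in seconds over a trial of length ``t_total``; ``t_first``
    is the first-attack latency (equal to ``t_total`` when no attack
    occurred, so the latency reward term is exactly zero); ``n_acts`` counts
    behavioral bouts (fractional after repeat averaging). ``rel_movement``
    (X1, dimensionless) and
    ``freezing_s`` (X2, seconds) are the kinematic features of the
    reference regression model; NaN when no pose track was available.
    """

    d_anxious: float
    d_demonstration: float
    d_fighting: float
    t_first: float
    n_acts: float
    t_total: float
    rel_movement: float = float("nan")
    freezing_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.t_total <= 0:
            raise ValidationError("t_total must be > 0")
        for name in ("d_anxious", "d_demonstration", "d_fighting", "t_first"):
            v = getattr(self, name)
            if not 0.0 <= v <= self.t_total + 1e-9:
                raise ValidationError(
                    f"{name} = {v} outside [0, t_total = {self.t_total}]"
                )
        if self.n_acts < 0:
            raise ValidationError("n_acts must be >= 0")

    def duration(self, behavior: str) -> float:
        return {
            "anxious": self.d_anxious,
            "demonstration": self.d_demonstration,
            "fighting": self.d_fighting,
        }[behavior]

    def with_features(self, rel_movement: float, freezing_s: float) -> "TrialSummary":
        return replace(self, rel_movement=rel_movement, freezing_s=freezing_s)


def min_bout_frames(min_bout_ms: float, fps: float) -> int:
    """Minimum bout length in frames for a minimum duration in milliseconds.

    The duration is a lower bound the bout must meet, so the conversion
    rounds up (180 ms at 30 fps -> 6 frames); the result is never below one
    frame.
    """
    if fps <= 0:
        raise ParameterError("fps must be > 0")
    if min_bout_ms < 0:
        raise ParameterError("min_bout_ms must be >= 0")
    # min_bout_ms * fps first: keeps e.g. (180, 100) exactly 18 in floats
    return max(1, math.ceil(min_bout_ms * fps / 1000.0))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) frame pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def extract_bouts(
    trace: ConfidenceTrace,
    behavior: str,
    config: PipelineConfig | None = None,
) -> list[BoutRecord]:
    """Detect bouts of one behavior category in a confidence trace.

    Maximal runs of frames with probability strictly above
    ``config.confidence_threshold`` are located; runs separated by at most
    ``config.gap_merge_frames`` below-threshold frames are merged (merging
    is off by default); merged runs shorter than the frame equivalent of
    ``config.min_bout_ms`` are discarded. The reported mean confidence is
    the mean probability over the run's frames.
    """
    config = config or PipelineConfig()
    if behavior not in trace.behaviors:
        raise ParameterError(f"unknown behavior {behavior!r}")
    if trace.n_frames == 0:
        raise ParameterError("trace is empty")
    p = trace.prob(behavior)
    runs = _runs_above(p > config.confidence_threshold)
    if config.gap_merge_frames > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= config.gap_merge_frames:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    min_frames = min_bout_frames(config.min_bout_ms, trace.fps)
    bouts = []
    for s, e in runs:
        if e - s + 1 < min_frames:
            continue
        bouts.append(
            BoutRecord(
                behavior=behavior,
                start_frame=s,
                end_frame=e,
                duration_s=(e - s + 1) / trace.fps,
                mean_confidence=float(np.mean(p[s : e + 1])),
            )
        )
    return bouts


def extract_all_bouts(
    trace: ConfidenceTrace, config: PipelineConfig | None = None
) -> dict[str, list[BoutRecord]]:
    """Bouts for every behavior category, keyed by category."""
    return {b: extract_bouts(trace, b, config) for b in trace.behaviors}


def aggregate_durations(
    bouts_by_behavior: dict[str, list[BoutRecord]],
    config: PipelineConfig | None = None,
) -> TrialSummary:
    """Sum bout durations per category and count behavioral acts.

    Per-category totals are clipped to the trial duration; categories may
    overlap in time (the classifier emits independent traces), so no
    cross-category renormalization is applied. The act count covers all
    three categories by default; set ``config.count_all_categories = False``
    to count fighting bouts only.
    """
    config = config or PipelineConfig()
    last_frame = config.n_frames - 1
    durations: dict[str, float] = {}
    n_acts = 0
    for behavior in BEHAVIORS:
        bouts = bouts_by_behavior.get(behavior, [])
        for b in bouts:
            if b.end_frame > last_frame:
                raise ValidationError(
                    f"{behavior} bout [{b.start_frame}, {b.end_frame}] extends past "
                    f"the trial's last frame {last_frame}"
                )
        durations[behavior] = min(sum(b.duration_s for b in bouts), config.t_total)
        if config.count_all_categories or behavior == "fighting":
            n_acts += len(bouts)
    return TrialSummary(
        d_anxious=durations["anxious"],
        d_demonstration=durations["demonstration"],
        d_fighting=durations["fighting"],
        t_first=first_attack_latency(bouts_by_behavior.get("fighting", []), config),
        n_acts=n_acts,
        t_total=config.t_total,
    )


def first_attack_latency(
    fighting_bouts: list[BoutRecord], config: PipelineConfig | None = None
) -> float:
    """Start time (s) of the earliest fighting bout.

    Trials with no fighting bout return the full trial duration, which makes
    the index's latency reward term exactly zero.
    """
    config = config or PipelineConfig()
    starts = [b.start_frame for b in fighting_bouts if b.behavior == "fighting"]
    if not starts:
        return config.t_total
    return min(starts) / config.fps
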