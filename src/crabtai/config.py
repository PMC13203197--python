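"""Pipeline configuration.

The configuration gathers every threshold the scoring pipeline uses: video
frame rate, trial duration, the classifier confidence cut-off, the minimum
bout duration, the pose-likelihood filter, the index weights, and the
stratification / resampling parameters. Defaults correspond to the standard
30-min resident–intruder assay recorded at 30 frames per second.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

#: The three classified behavior categories, in canonical order.
BEHAVIORS: tuple[str, str, str] = ("anxious", "demonstration", "fighting")

#: The 13 tracked keypoints, in canonical file order.
KEYPOINTS: tuple[str, ...] = (
    "LBODY", "RBOD", "HEAD",
    "LFOOTS", "LFOOTE", "RFOOTS", "RFOOTE",
    "LCLAWS", "LCLAWJ", "LCLAWE",
    "RCLAWS", "RCLAWJ", "RCLAWE",
)


@dataclass(frozen=True)
class TaiWeights:
    """Weights of the time-weighted aggression index.

    The duration terms weight the fraction of the trial spent in each
    behavior category; the latency term rewards an early first attack.
    The default set sums to exactly 1.00.
    """

    w_anxious: float = 0.14
    w_demonstration: float = 0.21
    w_fighting: float = 0.35
    w_latency: float = 0.30

    def __post_init__(self) -> None:
        for name in ("w_anxious", "w_demonstration", "w_fighting", "w_latency"):
            if getattr(self, name) < 0:
                raise ConfigError(f"TAI weight {name!r} must be non-negative")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_anxious, self.w_demonstration, self.w_fighting, self.w_latency)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the scoring pipeline."""

    fps: float = 30.0
    t_total: float = 1800.0
    confidence_threshold: float = 0.5
    min_bout_ms: float = 180.0
    likelihood_threshold: float = 0.95
    tai_weights: TaiWeights = field(default_factory=TaiWeights)
    quartile_fraction: float = 0.25
    n_repeats: int = 5
    bootstrap_b: int = 100
    rng_seed: int | None = None
    # bout extraction
    gap_merge_frames: int = 0
    count_all_categories: bool = True  # aggressive acts = bouts of all three categories
    # trajectory features
    max_interp_frames: int = 5
    centroid_keypoints: tuple[str, ...] = ("LBODY", "RBOD", "HEAD")
    freeze_speed_threshold: float = 0.2  # carapace widths / s
    min_freeze_s: float = 2.0

    def __post_init__(self) -> None:
        checks = [
            ("fps", self.fps > 0, "must be > 0"),
            ("t_total", self.t_total > 0, "must be > 0"),
            ("confidence_threshold", 0.0 <= self.confidence_threshold < 1.0,
             "must lie in [0, 1)"),
            ("min_bout_ms", self.min_bout_ms >= 0, "must be >= 0"),
            ("likelihood_threshold", 0.0 <= self.likelihood_threshold <= 1.0,
             "must lie in [0, 1]"),
            ("quartile_fraction", 0.0 < self.quartile_fraction <= 0.5,
             "must lie in (0, 0.5]"),
            ("n_repeats", self.n_repeats >= 1, "must be >= 1"),
            ("bootstrap_b", self.bootstrap_b >= 1, "must be >= 1"),
            ("gap_merge_frames", self.gap_merge_frames >= 0, "must be >= 0"),
            ("max_interp_frames", self.max_interp_frames >= 0, "must be >= 0"),
            ("freeze_speed_threshold", self.freeze_speed_threshold >= 0, "must be >= 0"),
            ("min_freeze_s", self.min_freeze_s >= 0, "must be >= 0"),
        ]
        for key, ok, why in checks:
            if not ok:
                raise ConfigError(f"config key {key!r} {why} (got {getattr(self, key)!r})")
        if len(self.centroid_keypoints) == 0:
            raise ConfigError("centroid_keypoints must not be empty")

    @property
    def n_frames(self) -> int:
        """Number of frames in a full trial."""
        return int(round(self.t_total * self.fps))


_SCALAR_KEYS = {
    "fps": float,
    "t_total": float,
    "confidence_threshold": float,
    "min_bout_ms": float,
    "likelihood_threshold": float,
    "quartile_fraction": float,
    "n_repeats": int,
    "bootstrap_b": int,
    "rng_seed": int,
    "gap_merge_frames": int,
    "max_interp_frames": int,
    "freeze_speed_threshold": float,
    "min_freeze_s": float,
    "count_all_categories": lambda s: s.strip().lower() in ("1", "true", "yes"),
}
_WEIGHT_KEYS = {"w_anxious", "w_demonstration", "w_fighting", "w_latency"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key = value`` configuration file.

    Absent keys take their defaults; unknown keys produce a warning rather
    than an error, so older configurations keep loading after new keys are
    added. Decimal points only; blank lines and ``#`` comments are ignored.

    Raises
    ------
    ConfigError
        If a value fails to parse or is out of range (the offending key is
        named in the message).
    """
    overrides: dict[str, object] = {}
    weights: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _WEIGHT_KEYS:
            try:
                weights[key] = float(value)
            except ValueError as exc:
                raise ConfigError(f"config key {key!r}: cannot parse {value!r}") from exc
        elif key in _SCALAR_KEYS:
            try:
                overrides[key] = _SCALAR_KEYS[key](value)
            except ValueError as exc:
                raise ConfigError(f"config key {key!r}: cannot parse {value!r}") from exc
        else:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
    if weights:
        defaults = dataclasses.asdict(TaiWeights())
        defaults.update(weights)
        overrides["tai_weights"] = TaiWeights(**defaults)
    return PipelineConfig(**overrides)
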