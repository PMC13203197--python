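"""In-memory containers for pose tracks and behavior-confidence traces.

A :class:`PoseTrack` holds per-frame (x, y, likelihood) triples for the 13
named keypoints of one animal; coordinates are in pixels with the origin at
the top-left of the video frame and y increasing downward. Frames are
indexed 0, 1, 2, ... with no gaps. A missing keypoint observation is encoded
as ``x = y = NaN`` with likelihood 0 — rows are never dropped, so the track
stays gap-free.

A :class:`ConfidenceTrace` holds one per-frame classifier probability per
behavior category (anxious, demonstration, fighting). The categories need
not sum to one: the residual mass corresponds to frames the classifier
leaves unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BEHAVIORS, KEYPOINTS
from .errors import ValidationError


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates with detection likelihoods.

    Parameters
    ----------
    fps
        Frame rate of the source video (frames per second, > 0).
    x, y
        Arrays of shape ``(n_frames, n_keypoints)``, pixel coordinates.
        NaN marks a missing observation.
    likelihood
        Array of the same shape with values in [0, 1].
    keypoints
        Keypoint names in column order; defaults to the canonical 13.
    """

    fps: float
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    keypoints: tuple[str, ...] = field(default=KEYPOINTS)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.keypoints = tuple(self.keypoints)
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValidationError("x, y and likelihood must share one shape")
        if self.x.ndim != 2 or self.x.shape[1] != len(self.keypoints):
            raise ValidationError(
                f"expected shape (n_frames, {len(self.keypoints)}), got {self.x.shape}"
            )
        lik = self.likelihood
        if np.isnan(lik).any() or (lik < 0).any() or (lik > 1).any():
            raise ValidationError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(self.n_frames)

    def missing(self) -> np.ndarray:
        """Boolean (n_frames, n_keypoints) mask of missing observations."""
        return np.isnan(self.x) | np.isnan(self.y)

    def keypoint_index(self, name: str) -> int:
        try:
            return self.keypoints.index(name)
        except ValueError:
            raise KeyError(f"unknown keypoint {name!r}") from None

    def copy(self) -> "PoseTrack":
        return PoseTrack(self.fps, self.x.copy(), self.y.copy(),
                         self.likelihood.copy(), self.keypoints)

    def equals(self, other: "PoseTrack") -> bool:
        """Field-for-field equality (NaNs compare equal in coordinates)."""
        return (
            self.fps == other.fps
            and self.keypoints == other.keypoints
            and self.x.shape == other.x.shape
            and np.array_equal(self.x, other.x, equal_nan=True)
            and np.array_equal(self.y, other.y, equal_nan=True)
            and np.array_equal(self.likelihood, other.likelihood)
        )


@dataclass
class ConfidenceTrace:
    """Per-frame classifier probabilities for the three behavior categories.

    ``probabilities`` has shape ``(n_frames, 3)`` with columns in the order
    of :data:`crabtai.config.BEHAVIORS`.
    """

    fps: float
    probabilities: np.ndarray
    behaviors: tuple[str, ...] = field(default=BEHAVIORS)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.behaviors = tuple(self.behaviors)
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        p = self.probabilities
        if p.ndim != 2 or p.shape[1] != len(self.behaviors):
            raise ValidationError(
                f"expected shape (n_frames, {len(self.behaviors)}), got {p.shape}"
            )
        if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.probabilities.shape[0]

    def prob(self, behavior: str) -> np.ndarray:
        """The probability column for one behavior category."""
        try:
            j = self.behaviors.index(behavior)
        except ValueError:
            raise KeyError(f"unknown behavior {behavior!r}") from None
        return self.probabilities[:, j]

    def equals(self, other: "ConfidenceTrace") -> bool:
        return (
            self.fps == other.fps
            and self.behaviors == other.behaviors
            and self.probabilities.shape == other.probabilities.shape
            and np.array_equal(self.probabilities, other.probabilities)
        )
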