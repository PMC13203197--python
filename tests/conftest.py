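import numpy as np
import pytest

from crabtai import ConfidenceTrace, PipelineConfig, PoseTrack
from crabtai.config import BEHAVIORS, KEYPOINTS
from crabtai.synthetic import _KP_OFFSETS


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig()


def make_track(centroid: np.ndarray, fps: float = 30.0, cw: float = 50.0,
               likelihood: np.ndarray | None = None) -> PoseTrack:
    """Build a 13-keypoint track from a centroid path using a fixed body plan."""
    centroid = np.asarray(centroid, dtype=float)
    n = centroid.shape[0]
    x = np.empty((n, 13))
    y = np.empty((n, 13))
    for j, name in enumerate(KEYPOINTS):
        ox, oy = _KP_OFFSETS[name]
        x[:, j] = centroid[:, 0] + ox * cw
        y[:, j] = centroid[:, 1] + oy * cw
    lik = np.ones((n, 13)) if likelihood is None else likelihood
    return PoseTrack(fps=fps, x=x, y=y, likelihood=lik)


def make_trace(fighting: np.ndarray | None = None,
               anxious: np.ndarray | None = None,
               demonstration: np.ndarray | None = None,
               fps: float = 30.0) -> ConfidenceTrace:
    """Build a trace from per-behavior probability vectors (default all 0.1)."""
    given = {"anxious": anxious, "demonstration": demonstration, "fighting": fighting}
    n = next(len(v) for v in given.values() if v is not None)
    probs = np.column_stack(
        [np.full(n, 0.1) if given[b] is None else np.asarray(given[b], dtype=float)
         for b in BEHAVIORS]
    )
    return ConfidenceTrace(fps=fps, probabilities=probs)
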