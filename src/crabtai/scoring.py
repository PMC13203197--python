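"""The time-weighted aggression index (TAI) and its weight derivation.

The index combines how much of a contest an animal spends in each
aggression-related category with how quickly it attacks::

    TAI = (w_a * D_anxious + w_d * D_demonstration + w_f * D_fighting) / T_total
          + w_lat * (T_total - T_first) / T_total

with default weights (0.14, 0.21, 0.35, 0.30). The weights were originally
derived by regressing the per-individual aggression frequency (acts per
second) on the four behavioral predictors and normalizing the coefficients;
:func:`derive_weights` reproduces that procedure so the weighting can be
re-fit for other species or assay designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import fmean

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bouts import TrialSummary, aggregate_durations, extract_all_bouts
from .config import PipelineConfig, TaiWeights
from .errors import EstimationError, ParameterError
from .tracks import ConfidenceTrace, PoseTrack
from .trajectory import freezing_duration, relative_movement_distance

__all__ = [
    "AggressionScore",
    "compute_tai",
    "tai_upper_bound",
    "aggression_frequency",
    "average_repeats",
    "derive_weights",
    "summarize_trial",
    "score_cohort",
]

_PREDICTORS = ("d_anxious", "d_demonstration", "d_fighting", "latency_reward")


@dataclass(frozen=True)
class AggressionScore:
    """Final per-individual score after repeat averaging."""

    individual_id: str
    tai: float
    frequency: float
    n_repeats: int


def compute_tai(summary: TrialSummary, weights: TaiWeights | None = None) -> float:
    """Evaluate the time-weighted aggression index for one trial summary."""
    w = weights or TaiWeights()
    if summary.t_total <= 0:
        raise ParameterError("t_total must be > 0")
    t = summary.t_total
    duration_term = (
        w.w_anxious * summary.d_anxious
        + w.w_demonstration * summary.d_demonstration
        + w.w_fighting * summary.d_fighting
    ) / t
    latency_term = w.w_latency * (t - summary.t_first) / t
    return duration_term + latency_term


def tai_upper_bound(weights: TaiWeights | None = None, exclusive: bool = True) -> float:
    """Attainable supremum of the index under the given weights.

    With temporally exclusive categories the whole trial can at best be
    spent in the highest-weighted category (default weights: 0.35 + 0.30 =
    0.65); if categories may fully overlap every duration term saturates and
    the bound is the sum of all weights (1.00 for the defaults). Useful for
    optional rescaling of scores to [0, 1].
    """
    w = weights or TaiWeights()
    if exclusive:
        return max(w.w_anxious, w.w_demonstration, w.w_fighting) + w.w_latency
    return w.w_anxious + w.w_demonstration + w.w_fighting + w.w_latency


def aggression_frequency(summary: TrialSummary) -> float:
    """Aggressive acts per second: bout count divided by trial duration."""
    if summary.t_total <= 0:
        raise ParameterError("t_total must be > 0")
    return summary.n_acts / summary.t_total


def average_repeats(
    summaries: list[TrialSummary], config: PipelineConfig | None = None
) -> tuple[TrialSummary, int]:
    """Field-wise mean over repeated trials of one individual.

    All repeats must share the same trial duration. Returns the averaged
    summary and the number of repeats; a repeat count different from
    ``config.n_repeats`` triggers a warning, not an error.
    """
    config = config or PipelineConfig()
    if not summaries:
        raise ParameterError("need at least one trial summary")
    t_totals = {s.t_total for s in summaries}
    if len(t_totals) > 1:
        raise ParameterError(f"mixed trial durations: {sorted(t_totals)}")
    n = len(summaries)
    if n != config.n_repeats:
        warnings.warn(
            f"{n} repeats averaged (assay design uses {config.n_repeats})",
            stacklevel=2,
        )
    mean = TrialSummary(
        d_anxious=fmean(s.d_anxious for s in summaries),
        d_demonstration=fmean(s.d_demonstration for s in summaries),
        d_fighting=fmean(s.d_fighting for s in summaries),
        t_first=fmean(s.t_first for s in summaries),
        n_acts=fmean(s.n_acts for s in summaries),
        t_total=summaries[0].t_total,
        rel_movement=fmean(s.rel_movement for s in summaries),
        freezing_s=fmean(s.freezing_s for s in summaries),
    )
    return mean, n


def derive_weights(
    cohort: list[tuple[TrialSummary, float]]
) -> TaiWeights:
    """Re-derive index weights from a cohort by the regression procedure.

    Ordinary least squares of the aggression frequency on the four
    predictors — the three category durations and the transformed latency
    ``T_total - T_first`` (so an early attacker has a large, positively
    signed predictor) — with an intercept that is fit and discarded. The
    slope coefficients are normalized to sum to one in absolute value and
    mapped onto the four weight slots.

    Raises
    ------
    EstimationError
        If fewer than 10 individuals are supplied or the design is rank
        deficient (the offending predictor is named).
    """
    if len(cohort) < 10:
        raise EstimationError("need at least 10 individuals to derive weights")
    rows = np.array(
        [
            [s.d_anxious, s.d_demonstration, s.d_fighting, s.t_total - s.t_first]
            for s, _ in cohort
        ]
    )
    y = np.array([freq for _, freq in cohort], dtype=float)
    for j, name in enumerate(_PREDICTORS):
        if np.ptp(rows[:, j]) == 0:
            raise EstimationError(f"predictor {name!r} is constant")
    X = sm.add_constant(rows)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a predictor explained by the others
        for j, name in enumerate(_PREDICTORS):
            others = np.delete(rows, j, axis=1)
            resid = rows[:, j] - others @ np.linalg.lstsq(others, rows[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(rows[:, j]).max())):
                raise EstimationError(f"predictor {name!r} is collinear with the others")
        raise EstimationError("design matrix is rank deficient")
    coef = sm.OLS(y, X).fit().params[1:]
    if coef[0] < 0 or coef[1] < 0 or coef[2] < 0:
        warnings.warn(
            "negative coefficient on a duration predictor; its sign is lost "
            "under absolute-value normalization",
            stacklevel=2,
        )
    total = np.abs(coef).sum()
    if total == 0:
        raise EstimationError("all regression coefficients are zero")
    w = np.abs(coef) / total
    return TaiWeights(
        w_anxious=float(w[0]),
        w_demonstration=float(w[1]),
        w_fighting=float(w[2]),
        w_latency=float(w[3]),
    )


def summarize_trial(
    trace: ConfidenceTrace,
    pose: PoseTrack | None = None,
    config: PipelineConfig | None = None,
) -> TrialSummary:
    """Bout extraction + aggregation (+ kinematic features) for one trial."""
    config = config or PipelineConfig()
    summary = aggregate_durations(extract_all_bouts(trace, config), config)
    if pose is not None:
        summary = summary.with_features(
            relative_movement_distance(pose, config),
            freezing_duration(pose, config),
        )
    return summary


def score_cohort(
    trials: dict[str, list[tuple[PoseTrack | None, ConfidenceTrace]]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Score a cohort end to end: bouts -> summaries -> repeat means -> TAI.

    ``trials`` maps each individual id to its list of repeated trials, each
    a ``(pose_track_or_None, confidence_trace)`` pair. Returns one row per
    individual with columns ``id, tai, frequency, x1, x2, n_repeats``.
    """
    config = config or PipelineConfig()
    records = []
    for individual_id, trial_list in trials.items():
        if not trial_list:
            raise ParameterError(f"individual {individual_id!r} has no trials")
        summaries = [summarize_trial(trace, pose, config) for pose, trace in trial_list]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_summary, n_rep = average_repeats(summaries, config)
        records.append(
            {
                "id": individual_id,
                "tai": compute_tai(mean_summary, config.tai_weights),
                "frequency": aggression_frequency(mean_summary),
                "x1": mean_summary.rel_movement,
                "x2": mean_summary.freezing_s,
                "n_repeats": n_rep,
            }
        )
    return pd.DataFrame.from_records(records)
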