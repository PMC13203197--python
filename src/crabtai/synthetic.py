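"""Synthetic resident–intruder cohorts for end-to-end pipeline testing.

No public pose/behavior dataset exists for this assay, so this module
generates cohorts with the statistical structure the analysis assumes:

* each individual carries a latent aggressiveness trait ``a`` in [0, 1],
  drawn from a truncated normal so the induced aggression index is
  approximately normally distributed across the cohort;
* expected category durations increase in ``a`` and the expected
  first-attack latency decreases in ``a`` (so index components correlate
  with the trait with the observed sign pattern: earlier first attack,
  longer fighting, more movement, less freezing at high ``a``);
* behavior bouts follow a semi-Markov renewal process with exponential
  dwell times — the simplest process matching the target occupancies;
* classifier confidence is high (0.8–1.0) inside true bouts and low
  (0.0–0.2) outside;
* hemolymph serotonin follows a linear-plus-noise link to ``a`` for the
  majority, with a discordant subcluster (20% by default) of low-``a``
  individuals with elevated serotonin — the two-subtype structure that
  k-means is expected to resolve;
* pairing-trial attack counts are negative binomial with context-specific
  means and optional zero inflation (low-aggression pairings produce a
  configurable fraction of zero-attack trials).

All generators are deterministic under a fixed seed; per-individual streams
are derived from the master seed and the individual id, so results do not
depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .bouts import TrialSummary
from .config import BEHAVIORS, KEYPOINTS
from .errors import ParameterError
from .tracks import ConfidenceTrace, PoseTrack

__all__ = [
    "SimParams",
    "IndividualProfile",
    "generate_profiles",
    "simulate_trial",
    "sample_trial_summary",
    "simulate_summary_cohort",
    "simulate_serotonin",
    "simulate_pairing_trials",
    "PAIRING_CONTEXTS",
]

PAIRING_CONTEXTS = ("H-H", "M-M", "L-L", "H-L")

# fixed body plan: keypoint offsets from the centroid in carapace-width units
_KP_OFFSETS = {
    "LBODY": (-0.50, 0.00), "RBOD": (0.50, 0.00), "HEAD": (0.00, -0.60),
    "LFOOTS": (-0.45, 0.25), "LFOOTE": (-0.80, 0.45),
    "RFOOTS": (0.45, 0.25), "RFOOTE": (0.80, 0.45),
    "LCLAWS": (-0.30, -0.50), "LCLAWJ": (-0.50, -0.90), "LCLAWE": (-0.60, -1.30),
    "RCLAWS": (0.30, -0.50), "RCLAWJ": (0.50, -0.90), "RCLAWE": (0.60, -1.30),
}


@dataclass(frozen=True)
class SimParams:
    """Generator parameters. Defaults encode the standard assay conditions
    (200 individuals, 30-min trials at 30 fps, five repeats) and the
    reported pairing-context attack means."""

    n: int = 200
    t_total: float = 1800.0
    fps: float = 30.0
    n_repeats: int = 5
    # latent trait distribution (truncated normal on [0, 1])
    latent_mean: float = 0.5
    latent_sd: float = 0.15
    # expected category duration (s) = base + slope * a
    duration_base: dict[str, float] = field(
        default_factory=lambda: {"anxious": 40.0, "demonstration": 30.0, "fighting": 10.0}
    )
    duration_slope: dict[str, float] = field(
        default_factory=lambda: {"anxious": 260.0, "demonstration": 220.0, "fighting": 290.0}
    )
    # expected first-attack latency (s) = t_total * (1 - latency_slope * a)
    latency_slope: float = 0.85
    # trial-to-trial multiplicative noise (lognormal coefficient of variation)
    duration_noise_cv: float = 0.25
    latency_noise_cv: float = 0.25
    mean_bout_s: float = 5.0
    # classifier confidence inside / outside true bouts
    conf_in: tuple[float, float] = (0.8, 1.0)
    conf_out: tuple[float, float] = (0.0, 0.2)
    # locomotion: centroid speed (px/s) = speed_base + speed_slope * a
    speed_base: float = 20.0
    speed_slope: float = 40.0
    # freezing occupancy = freeze_base + freeze_slope * (1 - a)
    freeze_base: float = 0.05
    freeze_slope: float = 0.35
    mean_freeze_s: float = 8.0
    carapace_width_px: float = 120.0
    arena_px: tuple[float, float] = (1000.0, 700.0)
    keypoint_jitter_px: float = 1.0
    dropout_rate: float = 0.02
    # serotonin (ng/mL): 5HT = intercept + slope * a + N(0, noise_sd)
    serotonin_intercept: float = 50.0
    serotonin_slope: float = 100.0
    serotonin_noise_sd: float = 10.0
    discordant_fraction: float = 0.20
    discordant_offset: float = 110.0
    # pairing trials
    pairing_means: dict[str, float] = field(
        default_factory=lambda: {"H-H": 7.08, "L-L": 0.96, "H-L": 2.41, "M-M": 2.25}
    )
    pairing_dispersion: float = 2.0
    ll_zero_fraction: float = 0.48
    zero_inflation: dict[str, float] | None = None
    rng_seed: int = 0

    def scaled_to(self, t_total: float, fps: float | None = None, **overrides) -> "SimParams":
        """A copy with trial length rescaled and duration links scaled with it.

        Expected durations, latencies and bout/freeze spell lengths are
        proportional to the trial length, so a 60-s trial keeps the same
        occupancy structure as the default 1800-s assay. Useful for fast
        small-scale simulations.
        """
        import dataclasses

        ratio = t_total / self.t_total
        fields = dataclasses.asdict(self)
        fields.update(
            t_total=t_total,
            fps=fps if fps is not None else self.fps,
            duration_base={b: v * ratio for b, v in self.duration_base.items()},
            duration_slope={b: v * ratio for b, v in self.duration_slope.items()},
            mean_bout_s=max(0.5, self.mean_bout_s * ratio),
            mean_freeze_s=max(2.0, self.mean_freeze_s * ratio),
        )
        fields.update(overrides)
        return SimParams(**fields)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ParameterError("discordant_fraction must lie in [0, 1]")
        if not 0.0 <= self.ll_zero_fraction <= 1.0:
            raise ParameterError("ll_zero_fraction must lie in [0, 1]")
        if self.serotonin_noise_sd < 0:
            raise ParameterError("serotonin_noise_sd must be >= 0")
        for ctx, m in self.pairing_means.items():
            if m < 0:
                raise ParameterError(f"pairing mean for {ctx!r} must be >= 0")


@dataclass(frozen=True)
class IndividualProfile:
    """Latent trait and induced behavioral tendencies of one individual."""

    individual_id: int
    a: float
    mean_durations: dict[str, float]  # seconds, per behavior category
    mean_latency_s: float
    speed_scale: float  # px/s
    freeze_propensity: float  # occupancy fraction in [0, 1)


def _master_rng(params: SimParams) -> np.random.Generator:
    return np.random.default_rng(params.rng_seed)


def _individual_rng(params: SimParams, individual_id: int, stream: int = 0
                    ) -> np.random.Generator:
    # stream keyed by (seed, id, stream): reproducible regardless of order
    return np.random.default_rng([params.rng_seed, individual_id, stream])


def generate_profiles(params: SimParams) -> list[IndividualProfile]:
    """Draw a cohort of individual profiles.

    The latent trait is truncated normal on [0, 1]; every behavioral
    tendency is a deterministic monotone function of the trait, so
    between-individual variation is carried entirely by the trait while
    within-individual (trial-to-trial) variation is added at simulation
    time.
    """
    rng = _master_rng(params)
    lo = (0.0 - params.latent_mean) / params.latent_sd
    hi = (1.0 - params.latent_mean) / params.latent_sd
    a = sps.truncnorm.rvs(lo, hi, loc=params.latent_mean, scale=params.latent_sd,
                          size=params.n, random_state=rng)
    profiles = []
    for i, ai in enumerate(a):
        durations = {
            b: params.duration_base[b] + params.duration_slope[b] * ai
            for b in BEHAVIORS
        }
        profiles.append(
            IndividualProfile(
                individual_id=i,
                a=float(ai),
                mean_durations=durations,
                mean_latency_s=params.t_total * (1.0 - params.latency_slope * ai),
                speed_scale=params.speed_base + params.speed_slope * ai,
                freeze_propensity=params.freeze_base + params.freeze_slope * (1.0 - ai),
            )
        )
    return profiles


def _duration_scale(params: SimParams, behavior: str) -> float:
    """Cohort-typical duration for one category (evaluated at a = 0.5)."""
    return params.duration_base[behavior] + 0.5 * params.duration_slope[behavior]


def _draw_duration(profile: IndividualProfile, behavior: str, params: SimParams,
                   rng: np.random.Generator) -> float:
    """Noisy per-trial category duration.

    Noise is additive Gaussian with a constant cohort-level scale
    (``duration_noise_cv`` times the cohort-typical duration) rather than
    proportional to the individual mean: constant-variance noise keeps the
    induced index symmetric across the cohort, which the assay's normality
    gate assumes. Clipped to the physical range [0, t_total]. A profile
    with zero expected duration never expresses the behavior at all.
    """
    if profile.mean_durations[behavior] == 0.0:
        return 0.0
    sd = params.duration_noise_cv * _duration_scale(params, behavior)
    d = profile.mean_durations[behavior] + rng.normal(0.0, sd)
    return float(np.clip(d, 0.0, params.t_total))


def _draw_latency(profile: IndividualProfile, params: SimParams,
                  rng: np.random.Generator) -> float:
    """Noisy first-attack latency.

    Noise is added to the *earliness* (1 - latency/t_total) with a constant
    cohort-level scale, so low-aggression individuals do not pile up at the
    trial end and the induced index stays symmetric across the cohort.
    """
    earliness = 1.0 - profile.mean_latency_s / params.t_total
    sd = params.latency_noise_cv * 0.5 * params.latency_slope
    earliness = float(np.clip(earliness + rng.normal(0.0, sd), 0.0, 1.0))
    return params.t_total * (1.0 - earliness)


def _renewal_activity(n_frames: int, fps: float, occupancy: float,
                      mean_on_s: float, rng: np.random.Generator,
                      start_frame: int = 0, start_on: bool = False) -> np.ndarray:
    """Alternating exponential off/on renewal process as a boolean vector."""
    active = np.zeros(n_frames, dtype=bool)
    occupancy = min(max(occupancy, 0.0), 0.95)
    if occupancy == 0.0 or start_frame >= n_frames:
        return active
    mean_on = mean_on_s * fps
    mean_off = mean_on * (1.0 - occupancy) / occupancy
    pos = start_frame
    on = start_on
    while pos < n_frames:
        dwell = max(1, int(round(rng.exponential(mean_on if on else mean_off))))
        if on:
            active[pos : pos + dwell] = True
        pos += dwell
        on = not on
    return active


def _behavior_activity(profile: IndividualProfile, params: SimParams,
                       rng: np.random.Generator) -> tuple[dict[str, np.ndarray], float]:
    """True activity masks per category plus the drawn first-attack time."""
    n_frames = int(round(params.t_total * params.fps))
    activity: dict[str, np.ndarray] = {}
    latency = _draw_latency(profile, params, rng)
    for b in BEHAVIORS:
        target = _draw_duration(profile, b, params, rng)
        if b == "fighting":
            window_s = params.t_total - latency
            if target <= 0.0 or window_s <= 0.0:
                activity[b] = np.zeros(n_frames, dtype=bool)
                continue
            occupancy = target / window_s
            start = int(round(latency * params.fps))
            # the window opens with activity, so the first attack lands at
            # the drawn latency
            activity[b] = _renewal_activity(
                n_frames, params.fps, occupancy, params.mean_bout_s, rng,
                start_frame=start, start_on=True,
            )
        else:
            occupancy = target / params.t_total
            mask = _renewal_activity(
                n_frames, params.fps, occupancy, params.mean_bout_s, rng
            )
            activity[b] = mask
    return activity, latency


def _confidence_from_activity(activity: dict[str, np.ndarray], params: SimParams,
                              rng: np.random.Generator) -> ConfidenceTrace:
    n_frames = len(next(iter(activity.values())))
    probs = np.empty((n_frames, len(BEHAVIORS)))
    lo_in, hi_in = params.conf_in
    lo_out, hi_out = params.conf_out
    for j, b in enumerate(BEHAVIORS):
        inside = rng.uniform(lo_in, hi_in, size=n_frames)
        outside = rng.uniform(lo_out, hi_out, size=n_frames)
        probs[:, j] = np.where(activity[b], inside, outside)
    return ConfidenceTrace(fps=params.fps, probabilities=probs)


def _pose_from_activity(profile: IndividualProfile, activity: dict[str, np.ndarray],
                        params: SimParams, rng: np.random.Generator) -> PoseTrack:
    n = len(next(iter(activity.values())))
    fps, cw = params.fps, params.carapace_width_px
    any_active = np.zeros(n, dtype=bool)
    for mask in activity.values():
        any_active |= mask
    # freezing spells: renewal process, suppressed during active behavior
    freezing = _renewal_activity(n, fps, profile.freeze_propensity,
                                 params.mean_freeze_s, rng)
    freezing &= ~any_active
    # per-frame speed: zero while frozen, doubled while fighting
    speed = np.full(n, profile.speed_scale)
    speed[activity["fighting"]] *= 2.0
    speed[freezing] = 0.0
    # heading random walk, positions reflected inside the arena
    heading = np.cumsum(rng.normal(0.0, 0.3, size=n))
    step = speed / fps
    dx = np.cumsum(step * np.cos(heading))
    dy = np.cumsum(step * np.sin(heading))
    w, h = params.arena_px
    margin = 1.5 * cw
    cx = margin + _reflect(w / 2 - margin + dx, w - 2 * margin)
    cy = margin + _reflect(h / 2 - margin + dy, h - 2 * margin)
    # keypoints: fixed body-plan offsets + slowly varying AR(1) jitter, so
    # jitter inflates frame-to-frame displacements only marginally
    k = len(KEYPOINTS)
    x = np.empty((n, k))
    y = np.empty((n, k))
    lik = np.empty((n, k))
    innov_sd = params.keypoint_jitter_px * 0.2
    for j, name in enumerate(KEYPOINTS):
        ox, oy = _KP_OFFSETS[name]
        jx = _ar1(rng.normal(0.0, innov_sd, size=n), 0.98)
        jy = _ar1(rng.normal(0.0, innov_sd, size=n), 0.98)
        x[:, j] = cx + ox * cw + jx
        y[:, j] = cy + oy * cw + jy
        lik[:, j] = 0.96 + 0.04 * rng.random(n)
        drop = rng.random(n) < params.dropout_rate
        lik[drop, j] = rng.uniform(0.0, 0.9, size=int(drop.sum()))
    return PoseTrack(fps=fps, x=x, y=y, likelihood=lik)


def _ar1(innovations: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(innovations)
    acc = 0.0
    for i, e in enumerate(innovations):
        acc = rho * acc + e
        out[i] = acc
    return out


def _reflect(values: np.ndarray, width: float) -> np.ndarray:
    """Fold an unbounded coordinate into [0, width] by reflection."""
    period = 2.0 * width
    v = np.mod(values, period)
    return np.where(v > width, period - v, v)


def simulate_trial(profile: IndividualProfile, params: SimParams | None = None,
                   repeat: int = 0) -> tuple[PoseTrack, ConfidenceTrace]:
    """Simulate one resident–intruder trial for one individual.

    Returns the pose track and the classifier confidence trace, both of
    length ``round(t_total * fps)`` frames. The random stream is keyed by
    (master seed, individual id, repeat), so any trial can be regenerated
    independently.
    """
    params = params or SimParams()
    rng = _individual_rng(params, profile.individual_id, stream=repeat)
    activity, _ = _behavior_activity(profile, params, rng)
    trace = _confidence_from_activity(activity, params, rng)
    pose = _pose_from_activity(profile, activity, params, rng)
    return pose, trace


def sample_trial_summary(profile: IndividualProfile, params: SimParams | None = None,
                         rng: np.random.Generator | None = None) -> TrialSummary:
    """Draw one trial's behavioral summary directly (no frame simulation).

    Fast path for cohort-level statistics: durations and latency are drawn
    from the profile's expected values with the same multiplicative noise
    the frame-level simulator uses; the act count is the implied bout count
    (total duration / mean bout length).
    """
    params = params or SimParams()
    rng = rng if rng is not None else _master_rng(params)
    durations = {}
    for b in BEHAVIORS:
        durations[b] = _draw_duration(profile, b, params, rng)
    latency = _draw_latency(profile, params, rng)
    if durations["fighting"] <= 0.0:
        latency = params.t_total
    n_acts = int(round(sum(durations.values()) / params.mean_bout_s))
    return TrialSummary(
        d_anxious=durations["anxious"],
        d_demonstration=durations["demonstration"],
        d_fighting=durations["fighting"],
        t_first=latency,
        n_acts=n_acts,
        t_total=params.t_total,
    )


def simulate_summary_cohort(params: SimParams | None = None) -> list[TrialSummary]:
    """One summary per individual, deterministic under the master seed."""
    params = params or SimParams()
    profiles = generate_profiles(params)
    return [
        sample_trial_summary(p, params, _individual_rng(params, p.individual_id, stream=10_000))
        for p in profiles
    ]


def simulate_serotonin(profiles: list[IndividualProfile],
                       params: SimParams | None = None) -> np.ndarray:
    """Per-individual hemolymph serotonin concentrations (ng/mL).

    The majority follows ``intercept + slope * a`` plus Gaussian noise. A
    discordant fraction — drawn from the lower half of the trait
    distribution — receives an additive offset, producing the
    high-serotonin / low-aggression subcluster.
    """
    params = params or SimParams()
    if not profiles:
        raise ParameterError("profiles must be non-empty")
    if params.serotonin_noise_sd < 0:
        raise ParameterError("serotonin_noise_sd must be >= 0")
    rng = np.random.default_rng([params.rng_seed, 777])
    a = np.array([p.a for p in profiles])
    n = a.size
    values = (params.serotonin_intercept + params.serotonin_slope * a
              + rng.normal(0.0, params.serotonin_noise_sd, size=n))
    n_disc = int(round(params.discordant_fraction * n))
    if n_disc > 0:
        low_half = np.argsort(a, kind="stable")[: max(n_disc, n // 2)]
        chosen = rng.choice(low_half, size=n_disc, replace=False)
        values[chosen] += params.discordant_offset
    return values


def _solve_structural_zero(mean: float, dispersion: float, target: float) -> float:
    """Structural-zero probability making the total zero fraction hit target.

    The count is 0 with probability pi, else NB with mean ``mean/(1-pi)``
    (so the overall mean is preserved). Returns 0 when the plain NB already
    produces at least the target zero fraction.
    """
    r = dispersion

    def total_zero(pi: float) -> float:
        mu = mean / (1.0 - pi)
        p_nb0 = (r / (r + mu)) ** r
        return pi + (1.0 - pi) * p_nb0

    if mean == 0 or total_zero(0.0) >= target:
        return 0.0
    return float(optimize.brentq(lambda pi: total_zero(pi) - target, 0.0, 0.999))


def simulate_pairing_trials(n_trials_by_context: dict[str, int],
                            params: SimParams | None = None) -> dict[str, np.ndarray]:
    """Attack counts for dyadic pairing trials, per context.

    Counts are negative binomial with the configured context means and a
    common dispersion. The low-aggression (L-L) context is zero-inflated so
    its total zero fraction matches ``params.ll_zero_fraction`` while the
    configured mean is preserved; explicit structural-zero probabilities can
    be supplied via ``params.zero_inflation``.
    """
    params = params or SimParams()
    unknown = set(n_trials_by_context) - set(params.pairing_means)
    if unknown:
        raise ParameterError(f"unknown pairing context(s): {sorted(unknown)}")
    rng = np.random.default_rng([params.rng_seed, 888])
    r = params.pairing_dispersion
    out: dict[str, np.ndarray] = {}
    for ctx in n_trials_by_context:
        n_trials = n_trials_by_context[ctx]
        if n_trials < 1:
            raise ParameterError(f"context {ctx!r} needs at least 1 trial")
        mean = params.pairing_means[ctx]
        if params.zero_inflation is not None:
            pi = params.zero_inflation.get(ctx, 0.0)
        elif ctx == "L-L":
            pi = _solve_structural_zero(mean, r, params.ll_zero_fraction)
        else:
            pi = 0.0
        if pi >= 1.0 or mean == 0.0:
            out[ctx] = np.zeros(n_trials, dtype=int)
            continue
        mu = mean / (1.0 - pi)
        counts = rng.negative_binomial(n=r, p=r / (r + mu), size=n_trials)
        structural = rng.random(n_trials) < pi
        counts[structural] = 0
        out[ctx] = counts
    return out
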