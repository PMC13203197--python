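"""Stratification and validation statistics for scored cohorts.

Covers the full battery used to validate an automated aggression score
against a reference method and to relate it to physiology:

* quartile stratification into high- / medium- / low-aggression groups,
* a normality gate choosing parametric vs nonparametric branches,
* z-scoring and Pearson/Spearman correlation,
* the reference kinematic regression model ``Y = 0.023 X1 - 0.001 X2 - 0.002``,
* method agreement: two-way mixed consistency ICCs with F-based confidence
  intervals, the single-to-average (Spearman–Brown) relation, and
  Bland–Altman limits of agreement,
* subtype discovery: k-means with silhouette and bootstrap Jaccard
  cluster stability,
* pairing-trial analysis: Kruskal–Wallis with Dunn's post hoc and
  Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DomainError, ParameterError, ValidationError

__all__ = [
    "stratify",
    "normality_gate",
    "NormalityResult",
    "zscore",
    "correlate",
    "reference_model_predict",
    "icc_consistency",
    "IccReport",
    "spearman_brown",
    "bland_altman",
    "BlandAltmanReport",
    "kmeans_silhouette",
    "bootstrap_jaccard",
    "ClusterReport",
    "pairing_analysis",
    "PairingReport",
    "group_difference_test",
]

GROUPS = ("HA", "MA", "LA")


# ---------------------------------------------------------------------------
# stratification


def stratify(scores, quartile_fraction: float = 0.25) -> np.ndarray:
    """Assign HA / MA / LA group labels by score quartile.

    The ``floor(q * n)`` largest scores form the high-aggression group (HA),
    the ``floor(q * n)`` smallest the low-aggression group (LA), and the
    rest the medium group (MA) — 50/100/50 at n = 200 with q = 0.25. Ties at
    a boundary are broken by stable input order: among equal scores, earlier
    entries go to the lower group.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 4:
        raise ParameterError("need at least 4 scores to stratify")
    if not 0.0 < quartile_fraction <= 0.5:
        raise ParameterError("quartile_fraction must lie in (0, 0.5]")
    m = int(np.floor(quartile_fraction * n))
    order = np.argsort(scores, kind="stable")
    labels = np.full(n, "MA", dtype=object)
    labels[order[:m]] = "LA"
    labels[order[n - m:]] = "HA"
    return labels.astype(str)


# ---------------------------------------------------------------------------
# normality gate, z-score, correlation


@dataclass(frozen=True)
class NormalityResult:
    branch: str  # "parametric" | "nonparametric"
    statistic: float
    pvalue: float
    method: str


def normality_gate(values, alpha: float = 0.05, method: str = "shapiro") -> NormalityResult:
    """Decide the parametric vs nonparametric analysis branch.

    Shapiro–Wilk by default; ``method="ks"`` uses the Lilliefors variant of
    the Kolmogorov–Smirnov test (normal with estimated mean and SD). The
    branch is parametric iff p > alpha.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ParameterError("need at least 3 values for a normality test")
    if np.ptp(values) == 0:
        raise ParameterError("normality statistic undefined for a constant vector")
    if method == "shapiro":
        stat, p = sps.shapiro(values)
    elif method == "ks":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(values, dist="norm")
    else:
        raise ParameterError(f"unknown normality test {method!r}")
    branch = "parametric" if p > alpha else "nonparametric"
    return NormalityResult(branch, float(stat), float(p), method)


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, n - 1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("need at least 2 values to z-score")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ParameterError("cannot z-score a constant vector")
    return (values - values.mean()) / sd


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < 3:
        raise ParameterError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def reference_model_predict(x1, x2):
    """Reference kinematic aggression model: Y = 0.023 X1 - 0.001 X2 - 0.002.

    X1 is the relative movement distance and X2 the freezing duration; the
    coefficients come from the previously established regression model the
    index is validated against.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    out = 0.023 * x1 - 0.001 * x2 - 0.002
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# method agreement: ICC, Spearman-Brown, Bland-Altman


@dataclass(frozen=True)
class IccReport:
    """Consistency ICCs from the two-way mixed-effects model."""

    icc_c1: float
    icc_ck: float
    ci_c1: tuple[float, float]
    ci_ck: tuple[float, float]
    ms_rows: float
    ms_error: float
    n_subjects: int
    k_raters: int


def icc_consistency(ratings, alpha: float = 0.05) -> IccReport:
    """Single- and average-measurement consistency ICCs with F-based CIs.

    ``ratings`` is an n x k matrix (n subjects, k measurement methods, no
    missing cells). The two-way ANOVA decomposition gives

    * ICC(C,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)
    * ICC(C,K) = (MS_R - MS_E) / MS_R

    with MS_R the between-subject and MS_E the residual mean square after
    removing the column (method) effect. Confidence intervals follow the
    F-distribution interval of the consistency model.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ParameterError("ratings must be a 2-D matrix")
    n, k = m.shape
    if n < 5:
        raise ParameterError("need at least 5 subjects")
    if k < 2:
        raise ParameterError("need at least 2 measurements per subject")
    if np.isnan(m).any():
        raise ParameterError("missing cells are not supported (no imputation)")
    grand = m.mean()
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r == 0:
        raise ParameterError("no between-subject variance; ICC undefined")
    icc1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    icck = (ms_r - ms_e) / ms_r
    # F-based interval (consistency model)
    if ms_e > 0:
        f_obs = ms_r / ms_e
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_c1 = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
        ci_ck = (1 - 1 / f_l if f_l > 0 else -np.inf, 1 - 1 / f_u)
    else:  # perfect consistency: the interval degenerates
        ci_c1 = ci_ck = (1.0, 1.0)
    return IccReport(
        icc_c1=float(icc1),
        icc_ck=float(icck),
        ci_c1=(float(ci_c1[0]), float(ci_c1[1])),
        ci_ck=(float(ci_ck[0]), float(ci_ck[1])),
        ms_rows=float(ms_r),
        ms_error=float(ms_e),
        n_subjects=n,
        k_raters=k,
    )


def spearman_brown(icc1: float, k: int) -> float:
    """Average-measurement reliability implied by a single-measure ICC.

    ``k * icc1 / (1 + (k - 1) * icc1)`` — e.g. a single-measure consistency
    ICC of 0.554 over k = 2 methods implies an average-measure ICC of 0.713.
    """
    if not -1.0 < icc1 <= 1.0:
        raise DomainError("icc1 must lie in (-1, 1]")
    if k < 1:
        raise DomainError("k must be >= 1")
    denom = 1.0 + (k - 1) * icc1
    if denom <= 0:
        raise DomainError("Spearman-Brown denominator is non-positive")
    return k * icc1 / denom


@dataclass(frozen=True)
class BlandAltmanReport:
    mean_diff: float
    loa_low: float
    loa_high: float
    ci_mean_diff: tuple[float, float]
    fraction_within_loa: float
    n: int


def bland_altman(a, b) -> BlandAltmanReport:
    """Bland–Altman agreement between two paired measurement methods.

    Differences are taken as ``a - b``. Limits of agreement are
    ``mean(d) +/- 1.96 * SD(d)`` and the CI of the mean difference is
    ``mean(d) +/- 1.96 * SD(d) / sqrt(n)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ParameterError("inputs must have equal length")
    if a.size < 3:
        raise ParameterError("need at least 3 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = mean - 1.96 * sd, mean + 1.96 * sd
    half = 1.96 * sd / np.sqrt(d.size)
    inside = float(np.mean((d >= loa_low) & (d <= loa_high)))
    return BlandAltmanReport(
        mean_diff=mean,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_mean_diff=(float(mean - half), float(mean + half)),
        fraction_within_loa=inside,
        n=int(d.size),
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class ClusterReport:
    labels: np.ndarray
    sizes: tuple[int, ...]
    fractions: tuple[float, ...]
    silhouette: float
    jaccard: tuple[float, ...] = field(default=())


def kmeans_silhouette(points, k: int = 2, seed: int | None = None,
                      n_restarts: int = 10) -> ClusterReport:
    """K-means clustering with the mean silhouette coefficient.

    ``points`` is an (n, d) array (typically z-scored TAI and 5-HT columns).
    The best of ``n_restarts`` seeded initializations by inertia is kept.
    Cluster ids are relabeled by descending size so cluster 0 is always the
    majority cluster.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ParameterError("points must be an (n, d) array")
    n = points.shape[0]
    if n <= k:
        raise ParameterError(f"need more than k = {k} points, got {n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(points)
    # stable relabeling: descending cluster size, ties by first occurrence
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw]
    sizes = tuple(int(s) for s in np.bincount(labels, minlength=k))
    sil = float(silhouette_score(points, labels)) if k > 1 else 0.0
    return ClusterReport(
        labels=labels,
        sizes=sizes,
        fractions=tuple(s / n for s in sizes),
        silhouette=sil,
    )


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.sum(a & b)
    union = np.sum(a | b)
    return float(inter / union) if union else 0.0


def bootstrap_jaccard(points, labels, b: int = 100, seed: int | None = None,
                      k: int | None = None) -> tuple[float, ...]:
    """Cluster stability as mean bootstrap Jaccard similarity per cluster.

    For each of ``b`` bootstrap resamples the resampled points are
    re-clustered; each original cluster is matched to the re-clustering's
    maximum-Jaccard counterpart (computed on the resampled point multiset)
    and that Jaccard recorded. Values near 1 indicate stable clusters;
    values above ~0.75 are conventionally read as stable.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if b < 1:
        raise ParameterError("b must be >= 1")
    if points.shape[0] != labels.shape[0]:
        raise ParameterError("points and labels must have equal length")
    clusters = np.unique(labels)
    if k is None:
        k = clusters.size
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    sums = np.zeros(clusters.size)
    for _ in range(b):
        idx = rng.integers(0, n, size=n)
        km = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        new = km.fit_predict(points[idx])
        orig = labels[idx]
        for ci, c in enumerate(clusters):
            mask = orig == c
            if not mask.any():
                continue  # cluster absent from this resample; contributes 0
            best = max(_jaccard(mask, new == g) for g in range(k))
            sums[ci] += best
    return tuple(float(s / b) for s in sums)


# ---------------------------------------------------------------------------
# pairing-trial analysis


@dataclass(frozen=True)
class PairingReport:
    """Kruskal–Wallis + Dunn/Bonferroni summary of pairing-context counts."""

    contexts: tuple[str, ...]
    n_per_context: dict[str, int]
    mean_per_context: dict[str, float]
    sd_per_context: dict[str, float]
    h_statistic: float
    df: int
    pvalue: float
    dunn_z: dict[tuple[str, str], float]
    dunn_p_adjusted: dict[tuple[str, str], float]


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> tuple[dict, dict]:
    """Dunn's pairwise rank z tests with tie correction and Bonferroni."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        size = groups[g].size
        mean_ranks[g] = ranks[start : start + size].mean()
        sizes[g] = size
        start += size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    z_values, p_adj = {}, {}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        z_values[(g1, g2)] = float(z)
        p_adj[(g1, g2)] = float(min(1.0, p * n_pairs))
    return z_values, p_adj


def pairing_analysis(counts_by_context: dict[str, "np.ndarray | list"]) -> PairingReport:
    """Compare attack counts across pairing contexts.

    Kruskal–Wallis (tie-corrected, chi-square p with df = groups - 1)
    followed by Dunn's pairwise z tests on mean ranks with Bonferroni
    adjustment over all pairwise comparisons.
    """
    if len(counts_by_context) < 2:
        raise ParameterError("need at least 2 contexts")
    groups = {}
    for name, values in counts_by_context.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ParameterError(f"context {name!r} has fewer than 2 trials")
        groups[name] = arr
    h, p = sps.kruskal(*groups.values())
    dunn_z, dunn_p = _dunn_posthoc(groups)
    return PairingReport(
        contexts=tuple(groups),
        n_per_context={g: int(v.size) for g, v in groups.items()},
        mean_per_context={g: float(v.mean()) for g, v in groups.items()},
        sd_per_context={g: float(v.std(ddof=1)) for g, v in groups.items()},
        h_statistic=float(h),
        df=len(groups) - 1,
        pvalue=float(p),
        dunn_z=dunn_z,
        dunn_p_adjusted=dunn_p,
    )


def group_difference_test(groups: dict[str, "np.ndarray | list"],
                          gate: NormalityResult | str = "nonparametric"):
    """Dispatch a group comparison on the normality gate.

    Two groups on the parametric branch get a Welch t-test; every other
    combination takes the Kruskal–Wallis path of :func:`pairing_analysis`.
    Returns ``(statistic, pvalue, detail)`` where detail is either
    ``"welch-t"`` or the full :class:`PairingReport`.
    """
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    branch = gate.branch if isinstance(gate, NormalityResult) else gate
    if branch == "parametric" and len(groups) == 2:
        a, b = (np.asarray(v, dtype=float) for v in groups.values())
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        return float(stat), float(p), "welch-t"
    report = pairing_analysis(groups)
    return report.h_statistic, report.pvalue, report
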