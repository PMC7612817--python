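"""Descriptive and inferential statistics for trial tables.

Implements the study-style analysis battery: bootstrapped percent correct
with exact binomial chance tests, condition-balanced response-probability
maps over the joint (head angle x world angle) grid, the across-angle
variance statistic that quantifies how strongly behavior is modulated by
sound angle in each coordinate frame, a permutation test on the difference
of those variances, and the adjusted response-probability transform used in
reaction-time analyses.

Correction trials and no-response trials are excluded everywhere; probe
trials enter only the response-map analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import ALL_SLOTS, N_SLOTS
from .simulate import exclude_for_analysis

__all__ = [
    "ResponseMap",
    "VarianceResult",
    "bootstrap_percent_correct",
    "binomial_chance_test",
    "response_map",
    "variance_by_frame",
    "permutation_frame_test",
    "adjusted_response_probability",
    "first_n_trials_performance",
]


def _infer_primary_response(trials: pd.DataFrame) -> str:
    responses = set(trials["response"].unique()) - {"none"}
    if responses <= {"West", "East"}:
        return "West"
    if responses <= {"Left", "Right"}:
        return "Left"
    raise ValueError(f"cannot infer primary response from labels {sorted(responses)}")


def bootstrap_percent_correct(trials: pd.DataFrame, platform_angle: float | None = None,
                              n_per_sample: int = 400, n_iter: int = 100,
                              rng: np.random.Generator | None = None) -> float:
    """Mean percent correct over bootstrap subsamples of test trials.

    Subsamples of ``n_per_sample`` trials are drawn *without* replacement
    ``n_iter`` times; the mean percent correct across subsamples is
    returned.  Correction trials and probe trials are excluded.  Raises if
    fewer than ``n_per_sample`` trials are available.
    """
    rng = np.random.default_rng() if rng is None else rng
    df = exclude_for_analysis(trials, keep_probes=False)
    if platform_angle is not None:
        df = df[df["platform_angle"] == platform_angle]
    correct = df["is_correct"].to_numpy()
    if len(correct) < n_per_sample:
        raise ValueError(
            f"need at least {n_per_sample} trials, have {len(correct)} "
            f"(short by {n_per_sample - len(correct)})")
    means = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(len(correct), size=n_per_sample, replace=False)
        means[i] = correct[idx].mean()
    return float(100.0 * means.mean())


@dataclass(frozen=True)
class BinomialTestResult:
    p_value: float
    p_corrected: float
    significant: bool


def binomial_chance_test(mean_correct_count: int, n: int = 400,
                         n_comparisons: int = 1, alpha: float = 0.001) -> BinomialTestResult:
    """Exact two-sided binomial test against chance (p0 = 0.5).

    ``mean_correct_count`` is the mean number of correct trials across
    bootstrap iterations, rounded to the nearest integer.  The p-value is
    Bonferroni-corrected by ``n_comparisons`` (e.g. twelve platform angles
    per subject).
    """
    count = int(mean_correct_count)
    if not (0 <= count <= n):
        raise ValueError(f"count {count} outside [0, {n}]")
    p = sps.binomtest(count, n, p=0.5, alternative="two-sided").pvalue
    p_corr = min(1.0, p * n_comparisons)
    return BinomialTestResult(p_value=float(p), p_corrected=float(p_corr),
                              significant=bool(p_corr < alpha))


@dataclass
class ResponseMap:
    """Resampled primary-response probabilities over the condition grid.

    ``p_primary`` is a 12 x 12 array indexed [head angle, world angle] with
    axes in :data:`~frameloc.geometry.ALL_SLOTS` order; marginals are means
    of the joint over the complementary coordinate, each based on
    ``n_per_cell`` x 12 resampled trials per angle.
    """

    p_primary: np.ndarray
    n_per_cell: int
    angles: tuple[float, ...] = ALL_SLOTS

    @property
    def marginal_by_world(self) -> np.ndarray:
        return self.p_primary.mean(axis=0)

    @property
    def marginal_by_head(self) -> np.ndarray:
        return self.p_primary.mean(axis=1)

    @property
    def n_resampled(self) -> int:
        return self.n_per_cell * self.p_primary.size


def _cell_counts(trials: pd.DataFrame, primary: str):
    """Per-cell trial counts and primary-response counts on the 12x12 grid."""
    hi = np.searchsorted(ALL_SLOTS, trials["speaker_head"].to_numpy())
    wi = np.searchsorted(ALL_SLOTS, trials["speaker_world"].to_numpy())
    flat = hi * N_SLOTS + wi
    n = np.bincount(flat, minlength=N_SLOTS * N_SLOTS).reshape(N_SLOTS, N_SLOTS)
    k = np.bincount(flat, weights=(trials["response"] == primary).to_numpy(float),
                    minlength=N_SLOTS * N_SLOTS).reshape(N_SLOTS, N_SLOTS)
    return n, k


def response_map(trials: pd.DataFrame, n_per_cell: int = 3,
                 rng: np.random.Generator | None = None,
                 primary_response: str | None = None) -> ResponseMap:
    """Condition-balanced response-probability map.

    For each of the 144 (head angle, world angle) cells, ``n_per_cell``
    trials are resampled with replacement (432 trials in total at the
    default), equalizing the contribution of each condition.  Because the
    resample is with replacement, the resampled primary-response count per
    cell is an exact Binomial(n_per_cell, observed cell frequency) draw,
    which is how it is generated here.  Raises if any grid cell has no
    trials, listing the missing conditions.
    """
    rng = np.random.default_rng() if rng is None else rng
    df = exclude_for_analysis(trials, keep_probes=True)
    primary = primary_response or _infer_primary_response(df)
    n, k = _cell_counts(df, primary)
    if np.any(n == 0):
        empty = [(ALL_SLOTS[h], ALL_SLOTS[w]) for h, w in zip(*np.nonzero(n == 0))]
        raise ValueError(
            f"{len(empty)} empty (head, world) condition cells: {empty[:10]}"
            + ("..." if len(empty) > 10 else ""))
    p_hat = k / n
    resampled = rng.binomial(n_per_cell, p_hat) / n_per_cell
    return ResponseMap(p_primary=resampled, n_per_cell=n_per_cell)


@dataclass
class VarianceResult:
    """Across-angle variance of the response-map marginals per frame."""

    var_world: float
    var_head: float
    abs_difference: float
    p_value: float | None = None
    n_shuffles: int | None = None


def _across_angle_variance(x: np.ndarray, normalization: str) -> float:
    x = np.asarray(x, dtype=float)
    denom = {"n_minus_1": len(x) - 1, "n": len(x)}.get(normalization)
    if denom is None:
        raise ValueError("normalization must be 'n_minus_1' or 'n'")
    return float(np.sum((x - x.mean()) ** 2) / denom)


def variance_by_frame(rmap: ResponseMap, normalization: str = "n_minus_1") -> VarianceResult:
    """Variance of each marginal across the twelve sound angles.

    var = sum((x_theta - mean)^2) / denom with denom = n - 1 = 11 by
    default.  Under the /n normalization the variance of probabilities in
    [0, 1] is bounded by 0.25; the (n - 1) form can reach 3/11.
    """
    vw = _across_angle_variance(rmap.marginal_by_world, normalization)
    vh = _across_angle_variance(rmap.marginal_by_head, normalization)
    return VarianceResult(var_world=vw, var_head=vh, abs_difference=abs(vw - vh))


def permutation_frame_test(trials: pd.DataFrame, n_shuffles: int = 1000,
                           rng: np.random.Generator | None = None,
                           n_per_cell: int = 3,
                           normalization: str = "n_minus_1",
                           primary_response: str | None = None) -> VarianceResult:
    """Permutation test on the across-frame difference in variance.

    Responses are shuffled against (head angle, world angle) condition-label
    *pairs* -- labels stay coupled, preserving the physical link between the
    two frames fixed by task geometry -- and the response map, marginal
    variances, and |var_world - var_head| are recomputed for each shuffle.
    The p-value (1 + #{shuffled >= observed}) / (1 + n_shuffles) is the
    probability of an equal or larger difference by chance.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    df = exclude_for_analysis(trials, keep_probes=True)
    primary = primary_response or _infer_primary_response(df)

    n, _ = _cell_counts(df, primary)
    if np.any(n == 0):
        # delegate the informative error
        response_map(df, n_per_cell, rng, primary)
    observed_map = response_map(df, n_per_cell, rng, primary)
    observed = variance_by_frame(observed_map, normalization)

    hi = np.searchsorted(ALL_SLOTS, df["speaker_head"].to_numpy())
    wi = np.searchsorted(ALL_SLOTS, df["speaker_world"].to_numpy())
    flat = hi * N_SLOTS + wi
    y = (df["response"] == primary).to_numpy(float)
    n_flat = n.reshape(-1)

    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(y)
        k = np.bincount(flat, weights=perm, minlength=N_SLOTS * N_SLOTS)
        p_hat = (k / n_flat).reshape(N_SLOTS, N_SLOTS)
        resampled = rng.binomial(n_per_cell, p_hat) / n_per_cell
        vw = _across_angle_variance(resampled.mean(axis=0), normalization)
        vh = _across_angle_variance(resampled.mean(axis=1), normalization)
        if abs(vw - vh) >= observed.abs_difference:
            exceed += 1
    p = (1 + exceed) / (1 + n_shuffles)
    return VarianceResult(var_world=observed.var_world, var_head=observed.var_head,
                          abs_difference=observed.abs_difference,
                          p_value=float(p), n_shuffles=n_shuffles)


def adjusted_response_probability(p):
    """Distance of a response probability from chance: p' = |p - 0.5| / 0.5.

    0 at chance, 1 at determinism; accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.abs(arr - 0.5) / 0.5
    return float(out) if out.ndim == 0 else out


def first_n_trials_performance(trials: pd.DataFrame, n: int = 10,
                               n_per_sample: int = 50, n_iter: int = 100,
                               rng: np.random.Generator | None = None) -> pd.Series:
    """Bootstrapped percent correct restricted to each session's first trials.

    The first ``n`` positions of each session are taken *before* excluding
    correction trials (probes never occur there by design), then the same
    bootstrap as :func:`bootstrap_percent_correct` runs per platform angle
    with a reduced subsample size.  Returns a Series indexed by platform
    angle.
    """
    rng = np.random.default_rng() if rng is None else rng
    early = trials[trials["trial_index"] <= n]
    out = {}
    for angle, group in early.groupby("platform_angle", sort=True):
        out[float(angle)] = bootstrap_percent_correct(
            group, n_per_sample=n_per_sample, n_iter=n_iter, rng=rng)
    return pd.Series(out, name="percent_correct")
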