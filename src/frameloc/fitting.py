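"""Cross-validated maximum-likelihood fitting and model comparison.

Trials are split into ``n_folds`` contiguous folds after a single seeded
shuffle.  Within each training split the condition distribution is
flattened (a fixed number of trials per (head angle, world angle) cell,
sampled with replacement when a cell is short) before minimizing the
negative log likelihood with ``n_restarts`` bounded local minimizations
from random starting points; the restart with the lowest NLL is kept.
Fitted per-fold parameters then predict single-trial responses in the
held-out fold; accuracy (argmax prediction, exact ties scored 0.5) and
mean held-out log loss are reported overall and separately for test and
probe trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .geometry import ALL_SLOTS, N_SLOTS, TaskVariant, load_task_variant
from .models import (
    PARAM_BOUNDS,
    ModelParams,
    ModelSpec,
    param_names,
    primary_probability,
)
from .simulate import exclude_for_analysis

__all__ = [
    "FitConfig",
    "FitResult",
    "flatten_training_set",
    "negative_log_likelihood",
    "fit_model",
    "crossval_evaluate",
    "compare_models",
]

_P_FLOOR = 1e-9  # probability floor inside the log, guards boundary params


@dataclass
class FitConfig:
    """Cross-validation and optimizer settings."""

    n_folds: int = 20
    n_restarts: int = 20
    flatten_per_condition: int = 10
    seed: int | np.random.SeedSequence | None = None
    #: scale of the exponential from which inverse-temperature starting
    #: values are drawn (other parameters start uniform within bounds)
    eta_init_scale: float = 2.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(PARAM_BOUNDS))


@dataclass
class FitResult:
    """Per-fold fitted parameters with held-out evaluation."""

    spec: ModelSpec  # family/strategy/response space template
    task_variant: str
    per_fold: list[dict]            # params, train_nll, n_train per fold
    fold_of_trial: np.ndarray       # fold index of every analysed trial
    evaluation: pd.DataFrame | None = None   # one row per fold x subset
    summary: dict | None = None              # median accuracy / nll by subset

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def fold_params(self, k: int) -> ModelParams:
        return self.per_fold[k]["params"]


def _cell_ids(trials: pd.DataFrame) -> np.ndarray:
    hi = np.searchsorted(ALL_SLOTS, trials["speaker_head"].to_numpy())
    wi = np.searchsorted(ALL_SLOTS, trials["speaker_world"].to_numpy())
    return hi * N_SLOTS + wi


def flatten_training_set(trials: pd.DataFrame, per_condition: int = 10,
                         rng: np.random.Generator | None = None,
                         require_full_grid: bool = False) -> pd.DataFrame:
    """Equalize the condition distribution of a training set.

    Samples ``per_condition`` trials per populated (head, world) grid cell:
    without replacement when the cell holds enough trials, with replacement
    otherwise.  Output size is ``per_condition`` x (number of populated
    cells) -- 1440 when the full 144-cell grid is populated.  With
    ``require_full_grid`` an empty cell raises, listing the missing
    conditions.
    """
    rng = np.random.default_rng() if rng is None else rng
    cells = _cell_ids(trials)
    present = np.unique(cells)
    if require_full_grid and len(present) < N_SLOTS * N_SLOTS:
        missing = sorted(set(range(N_SLOTS * N_SLOTS)) - set(present.tolist()))
        pairs = [(ALL_SLOTS[m // N_SLOTS], ALL_SLOTS[m % N_SLOTS]) for m in missing]
        raise ValueError(f"{len(pairs)} empty (head, world) cells: {pairs[:10]}"
                         + ("..." if len(pairs) > 10 else ""))
    picks = []
    positions = np.arange(len(trials))
    for cell in present:
        pool = positions[cells == cell]
        replace = len(pool) < per_condition
        picks.append(rng.choice(pool, size=per_condition, replace=replace))
    idx = np.concatenate(picks)
    return trials.iloc[idx].reset_index(drop=True)


def _aggregate(trials: pd.DataFrame, variant: TaskVariant):
    """Collapse trials to per-condition (n_primary, n_secondary) counts."""
    cells = _cell_ids(trials)
    primary = (trials["response"] == variant.primary_response).to_numpy(float)
    size = N_SLOTS * N_SLOTS
    n = np.bincount(cells, minlength=size)
    k = np.bincount(cells, weights=primary, minlength=size)
    keep = n > 0
    flat = np.nonzero(keep)[0]
    heads = np.asarray(ALL_SLOTS)[flat // N_SLOTS]
    worlds = np.asarray(ALL_SLOTS)[flat % N_SLOTS]
    return heads, worlds, k[keep], (n - k)[keep]


def _nll_from_counts(spec: ModelSpec, heads, worlds, k_primary, k_secondary,
                     layout) -> float:
    p = np.atleast_1d(primary_probability(spec, heads, worlds, layout,
                                          require_slot=False))
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(-(k_primary * np.log(p) + k_secondary * np.log1p(-p)).sum())


def negative_log_likelihood(spec: ModelSpec, params: ModelParams,
                            trials: pd.DataFrame,
                            task_variant: str | TaskVariant = "world_NS") -> float:
    """NLL of a parameterized model on a trial table.

    ``-sum log P(observed response | condition)`` with probabilities from
    the model, floored at 1e-9 before the log.
    """
    variant = load_task_variant(task_variant)
    heads, worlds, k1, k0 = _aggregate(trials, variant)
    return _nll_from_counts(spec.with_params(params), heads, worlds, k1, k0,
                            variant.layout)


def _pack(params: ModelParams, names) -> np.ndarray:
    return np.array([getattr(params, n) for n in names], dtype=float)


def _unpack(x: np.ndarray, names) -> ModelParams:
    return ModelParams(**dict(zip(names, (float(v) for v in x))))


def _draw_start(names, bounds, eta_scale, rng) -> np.ndarray:
    start = []
    for n in names:
        lo, hi = bounds[n]
        if n == "beta_inv_temp":
            start.append(float(np.clip(rng.exponential(eta_scale), lo, hi)))
        else:
            start.append(float(rng.uniform(lo, hi)))
    return np.array(start)


def _minimize(spec: ModelSpec, heads, worlds, k1, k0, layout, names, bounds,
              x0: np.ndarray):
    def objective(x):
        return _nll_from_counts(spec.with_params(_unpack(x, names)),
                                heads, worlds, k1, k0, layout)

    box = [bounds[n] for n in names]
    # The offset family is piecewise smooth in beta_offset (port targeting
    # changes in 30-degree plateaus); Powell handles that better than a
    # gradient-based method.  The sinusoid likelihood is smooth.
    method = "Powell" if spec.family == "head_offset" else "L-BFGS-B"
    res = optimize.minimize(objective, x0, method=method, bounds=box)
    return res


def _fit_one(spec: ModelSpec, train: pd.DataFrame, variant: TaskVariant,
             config: FitConfig, rng: np.random.Generator):
    names = param_names(spec.family)
    heads, worlds, k1, k0 = _aggregate(train, variant)
    best = None
    failures = []
    for _ in range(config.n_restarts):
        x0 = _draw_start(names, config.bounds, config.eta_init_scale, rng)
        res = _minimize(spec, heads, worlds, k1, k0, variant.layout, names,
                        config.bounds, x0)
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {config.n_restarts} restarts failed: {failures[:3]}")
    return _unpack(np.clip(best.x, [config.bounds[n][0] for n in names],
                           [config.bounds[n][1] for n in names]), names), float(best.fun)


def fit_model(spec: ModelSpec, trials: pd.DataFrame, config: FitConfig | None = None,
              task_variant: str | TaskVariant = "world_NS") -> FitResult:
    """Cross-validated maximum-likelihood fit of one model family.

    ``spec`` provides family, strategy and response space; its parameters
    are ignored.  Correction and no-response trials are excluded, trials
    are shuffled once with the config seed and split into contiguous folds;
    each fold's training split is flattened and fitted by multi-start
    bounded minimization.  Held-out evaluation is filled in by
    :func:`crossval_evaluate` before returning.
    """
    config = config or FitConfig()
    variant = load_task_variant(task_variant)
    master = (config.seed if isinstance(config.seed, np.random.SeedSequence)
              else np.random.SeedSequence(config.seed))
    rng = np.random.default_rng(master)
    df = exclude_for_analysis(trials, keep_probes=True)
    if len(df) < config.n_folds:
        raise ValueError("fewer analysable trials than folds")

    order = rng.permutation(len(df))
    fold_of_trial = np.empty(len(df), dtype=int)
    for k, chunk in enumerate(np.array_split(order, config.n_folds)):
        fold_of_trial[chunk] = k

    per_fold = []
    for k in range(config.n_folds):
        train = df.iloc[fold_of_trial != k]
        flat = flatten_training_set(train, config.flatten_per_condition, rng)
        params, nll = _fit_one(spec, flat, variant, config, rng)
        per_fold.append({"fold": k, "params": params, "train_nll": nll,
                         "n_train": len(flat)})

    result = FitResult(spec=spec, task_variant=variant.name, per_fold=per_fold,
                       fold_of_trial=fold_of_trial)
    crossval_evaluate(result, df)
    return result


def _predict_scores(p: np.ndarray, observed_primary: np.ndarray) -> np.ndarray:
    """Score argmax predictions against observed responses; ties get 0.5."""
    predicted_primary = p > 0.5
    score = (predicted_primary == observed_primary).astype(float)
    score[p == 0.5] = 0.5
    return score


def crossval_evaluate(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Held-out single-trial prediction accuracy and log loss per fold.

    ``trials`` must be the analysable trials in the order used by
    :func:`fit_model` (it re-applies the same exclusions defensively).
    Populates ``fit.evaluation`` (one row per fold and subset) and
    ``fit.summary`` (median accuracy and mean log loss per subset across
    folds) and returns the evaluation frame.
    """
    df = exclude_for_analysis(trials, keep_probes=True)
    if len(df) != len(fit.fold_of_trial):
        raise ValueError("trial table does not match the fitted fold structure")
    variant = load_task_variant(fit.task_variant)
    heads = df["speaker_head"].to_numpy()
    worlds = df["speaker_world"].to_numpy()
    observed_primary = (df["response"] == variant.primary_response).to_numpy()
    is_probe = (df["trial_type"] == "probe").to_numpy()

    rows = []
    condition_scores = np.zeros(len(df))
    for entry in fit.per_fold:
        k = entry["fold"]
        mask = fit.fold_of_trial == k
        spec_k = fit.spec.with_params(entry["params"])
        p = np.atleast_1d(primary_probability(spec_k, heads[mask], worlds[mask],
                                              variant.layout, require_slot=False))
        p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)
        scores = _predict_scores(p, observed_primary[mask])
        logloss = -(np.where(observed_primary[mask], np.log(p), np.log1p(-p)))
        condition_scores[mask] = scores
        for subset, sel in (("all", np.ones(mask.sum(), bool)),
                            ("test", ~is_probe[mask]),
                            ("probe", is_probe[mask])):
            if sel.sum() == 0:
                continue
            rows.append({
                "fold": k, "subset": subset, "n_trials": int(sel.sum()),
                "accuracy_pct": 100.0 * scores[sel].mean(),
                "mean_logloss": float(logloss[sel].mean()),
            })
    evaluation = pd.DataFrame(rows)
    summary = {}
    for subset, grp in evaluation.groupby("subset"):
        summary[subset] = {
            "median_accuracy_pct": float(grp["accuracy_pct"].median()),
            "median_logloss": float(grp["mean_logloss"].median()),
        }
    per_condition = (
        pd.DataFrame({"speaker_head": heads, "speaker_world": worlds,
                      "score": condition_scores})
        .groupby(["speaker_head", "speaker_world"])["score"].mean() * 100.0
    )
    fit.evaluation = evaluation
    fit.summary = summary
    fit.summary["per_condition_accuracy_pct"] = per_condition
    return evaluation


def compare_models(trials: pd.DataFrame, specs: list[ModelSpec],
                   config: FitConfig | None = None,
                   task_variant: str | TaskVariant = "world_NS") -> pd.DataFrame:
    """Fit and evaluate several model families on the same trial table.

    Returns one row per model and subset with the median held-out accuracy
    and median held-out log loss across folds, ranked by accuracy within
    each subset (rank 1 = best).  No winner is declared beyond the ranking;
    note that models whose decision boundaries coincide are not separable
    by argmax accuracy, in which case the log-loss column is the
    discriminating metric.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    config = config or FitConfig()
    rows = []
    fits = {}
    for i, spec in enumerate(specs):
        sub = FitConfig(**{**config.__dict__,
                           "seed": np.random.SeedSequence(entropy=_entropy_of(config.seed),
                                                          spawn_key=(i,))})
        fit = fit_model(spec, trials, sub, task_variant)
        name = spec.family if spec.strategy == "none" else f"{spec.family}:{spec.strategy}"
        fits[name] = fit
        for subset, vals in fit.summary.items():
            if subset == "per_condition_accuracy_pct":
                continue
            rows.append({"model": name, "subset": subset, **vals})
    report = pd.DataFrame(rows)
    report["rank_accuracy"] = (report.groupby("subset")["median_accuracy_pct"]
                               .rank(ascending=False, method="min").astype(int))
    report["rank_logloss"] = (report.groupby("subset")["median_logloss"]
                              .rank(ascending=True, method="min").astype(int))
    report.attrs["fits"] = fits
    return report.sort_values(["subset", "rank_accuracy"]).reset_index(drop=True)


def _entropy_of(seed) -> int:
    if seed is None:
        return int(np.random.SeedSequence().entropy)
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.entropy)
    return int(seed)
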