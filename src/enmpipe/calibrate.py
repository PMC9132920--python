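"""Candidate-model calibration, evaluation, selection and thresholding.

Candidate maximum-entropy models over a grid of regularization multipliers,
feature-class combinations and predictor sets are evaluated with partial ROC
(statistical significance), omission rates (predictive ability) and AICc
(complexity), then filtered by the cascade: significant -> omission below the
tolerance (falling back to the minimal-omission set) -> within 2 AICc of the
best survivor. The selected configuration is refitted on bootstrap replicates,
averaged on the cloglog scale, and binarized with a percentile
training-presence threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import EnvStack
from .maxent import (
    ConvergenceError,
    MaxentModel,
    predict_points_raw,
    predict_raw,
    raw_to_cloglog,
    train_maxent,
    training_gain,
)

DEFAULT_RMS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1, 2, 3, 4, 5, 6, 8, 10)
DEFAULT_CLASS_COMBOS = (
    "l", "q", "h", "lq", "lp", "lt", "lh", "qp", "qt", "qh", "pt", "ph", "th",
    "lqp", "lqt", "lqh", "lpt", "lph", "lth", "qpt", "qph", "qth", "pth",
    "lqpt", "lqph", "lqth", "lpth", "qpth", "lqpth",
)
DEFAULT_PREDICTOR_SETS = ("bioclimatic", "topographic", "combination")


class InsufficientRecordsError(ValueError):
    """Raised when a species has too few usable records to model."""


@dataclass(frozen=True)
class CandidateSpec:
    rm: float
    classes: str
    predictor_set: str

    def label(self) -> str:
        return f"rm{self.rm:g}_{self.classes}_{self.predictor_set}"


@dataclass
class EvalConfig:
    """Evaluation and selection settings."""

    E: float = 0.05                      # pROC/omission tolerance
    proc_replicates: int = 500
    proc_resample: float = 0.5
    or_threshold: float = 0.05
    delta_aicc: float = 2.0
    threshold_percentile: float = 10.0
    n_background: int = 2000
    test_fraction: float = 0.05
    min_independent: int = 5
    aggregation_factors: tuple[int, int] = (2, 4)
    bootstrap_replicates: int = 10

    def __post_init__(self):
        if not (0 < self.E < 1 and 0 < self.or_threshold < 1):
            raise ValueError("E and or_threshold must be in (0, 1)")
        if not (0 < self.proc_resample <= 1):
            raise ValueError("proc_resample must be in (0, 1]")
        if self.delta_aicc < 0 or self.threshold_percentile < 0:
            raise ValueError("delta_aicc and threshold_percentile must be >= 0")


@dataclass
class PartitionSet:
    """Record partitions: independent test set plus four spatial bins."""

    seed: int
    independent_idx: np.ndarray          # indices into the record array
    spatial_bin: np.ndarray              # bin 0..3 per record, -1 for independent
    test_bin: int
    background_rc: np.ndarray            # (n_background, 2) raster (row, col)
    fallback: bool                       # independent set was too small

    @property
    def train_idx(self) -> np.ndarray:
        return np.nonzero((self.spatial_bin >= 0) & (self.spatial_bin != self.test_bin))[0]

    @property
    def test_idx(self) -> np.ndarray:
        return np.nonzero(self.spatial_bin == self.test_bin)[0]

    @property
    def non_independent_idx(self) -> np.ndarray:
        return np.nonzero(self.spatial_bin >= 0)[0]

    @property
    def final_eval_idx(self) -> np.ndarray:
        """Points for final model evaluation (independent set, or the testing
        partition when the independent set was below the minimum size)."""
        return self.test_idx if self.fallback else self.independent_idx


def checkerboard_bin(rows: np.ndarray, cols: np.ndarray,
                     factors: tuple[int, int] = (2, 4)) -> np.ndarray:
    """Two-level checkerboard bin (0..3) of raster cells.

    ``factors = (fine, coarse)`` aggregation factors; the bin is
    ``2 * parity(coarse) + parity(fine)`` where the parity of a cell at
    aggregation ``f`` is ``((row // f) + (col // f)) % 2``.
    """
    fine, coarse = factors
    pf = ((rows // fine) + (cols // fine)) % 2
    pc = ((rows // coarse) + (cols // coarse)) % 2
    return (2 * pc + pf).astype(int)


def make_partitions(
    lons: np.ndarray,
    lats: np.ndarray,
    env: EnvStack,
    seed: int,
    config: Optional[EvalConfig] = None,
) -> PartitionSet:
    """Partition records into an independent test set and four spatial bins.

    Fewer than 10 records inside the modeling grid is an error instructing
    the caller to skip the species. Background cells are sampled uniformly
    over valid cells (without replacement when possible).
    """
    config = config or EvalConfig()
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    n = lons.size
    inside = np.array([env.spec.contains(lo, la) for lo, la in zip(lons, lats)])
    if int(inside.sum()) < 10:
        raise InsufficientRecordsError(
            f"only {int(inside.sum())} records inside the modeling grid (<10); skip this species")
    if not inside.all():
        raise ValueError("records outside the modeling grid; crop or filter first")

    rng = np.random.default_rng(seed)
    n_ind = int(round(config.test_fraction * n))
    independent = rng.choice(n, size=n_ind, replace=False) if n_ind else np.array([], dtype=int)
    fallback = n_ind < config.min_independent

    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    for i, (lo, la) in enumerate(zip(lons, lats)):
        rows[i], cols[i] = env.spec.index_of(lo, la)
    bins = checkerboard_bin(rows, cols, config.aggregation_factors)
    bins[independent] = -1
    test_bin = int(rng.integers(0, 4))

    valid = env.valid_indices()
    if len(valid) >= config.n_background:
        pick = rng.choice(len(valid), size=config.n_background, replace=False)
    else:
        pick = rng.choice(len(valid), size=config.n_background, replace=True)
    return PartitionSet(seed=seed, independent_idx=np.sort(independent),
                        spatial_bin=bins, test_bin=test_bin,
                        background_rc=valid[pick], fallback=fallback)


def enumerate_candidates(
    rms: Sequence[float] = DEFAULT_RMS,
    class_combos: Sequence[str] = DEFAULT_CLASS_COMBOS,
    predictor_sets: Sequence[str] = DEFAULT_PREDICTOR_SETS,
) -> list[CandidateSpec]:
    """Cartesian candidate grid in deterministic rm-major order."""
    for name, seq in (("rms", rms), ("class_combos", class_combos),
                      ("predictor_sets", predictor_sets)):
        seq = list(seq)
        if not seq:
            raise ValueError(f"{name} must be non-empty")
        if len(set(seq)) != len(seq):
            raise ValueError(f"duplicate values in {name}")
    if any(rm <= 0 for rm in rms):
        raise ValueError("regularization multipliers must be > 0")
    return [CandidateSpec(float(rm), combo, pset)
            for rm in rms for combo in class_combos for pset in predictor_sets]


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def partial_roc(
    test_pred: np.ndarray,
    background_pred: np.ndarray,
    E: float = 0.05,
    replicates: int = 500,
    resample_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC AUC ratio and significance for one model.

    The curve plots sensitivity (fraction of test presences at or above a
    threshold) against the proportion of background area predicted present,
    restricted to sensitivity >= 1 - E. Each bootstrap replicate resamples a
    fraction of the test points; the ratio is partial AUC over the null
    (diagonal) partial AUC, and p is the fraction of replicate ratios <= 1.

    Sensitivity uses a plotting-position (rank / (n + 1)) interpolated ECDF
    of the test predictions rather than the raw step ECDF: with small test
    samples the step curve sits at sensitivity 1 over a finite area fraction
    even for uninformative predictions, which would bias the ratio above 1
    under the null. The interpolated curve is anchored at the overall
    prediction minimum/maximum so it still spans sensitivity 0..1.
    """
    test_pred = np.asarray(test_pred, float)
    background_pred = np.asarray(background_pred, float)
    if test_pred.size < 1 or background_pred.size < 1:
        raise ValueError("empty prediction arrays")
    if np.ptp(test_pred) == 0 and np.ptp(background_pred) == 0:
        return 1.0, 1.0

    lo = min(test_pred.min(), background_pred.min())
    hi = max(test_pred.max(), background_pred.max())
    thresholds = np.unique(np.concatenate([[lo, hi], test_pred, background_pred]))
    if thresholds.size > 300:
        thresholds = np.unique(np.concatenate(
            [[lo, hi], np.quantile(thresholds, np.linspace(0, 1, 300))]))
    # x: proportion of area predicted present at each threshold
    x_area = np.mean(background_pred[None, :] >= thresholds[:, None], axis=1)
    x_area[thresholds == lo] = 1.0

    rng = np.random.default_rng(seed)
    n_take = max(1, int(math.ceil(resample_fraction * test_pred.size)))
    ratios = np.empty(replicates)
    for r in range(replicates):
        sample = np.sort(rng.choice(test_pred, size=n_take, replace=True))
        # smoothed ECDF: F(sample_(i)) = i/(n+1), anchored at [lo, hi]
        xs = np.concatenate([[lo], sample, [hi]])
        fs = np.concatenate([[0.0], np.arange(1, n_take + 1) / (n_take + 1), [1.0]])
        sens = 1.0 - np.interp(thresholds, xs, fs)
        keep = sens >= 1.0 - E
        x = x_area[keep]
        y = sens[keep]
        order = np.argsort(x)
        x, y = x[order], y[order]
        if x.size < 2 or x[-1] - x[0] <= 0:
            ratios[r] = 1.0
            continue
        pauc = np.trapezoid(y, x)
        null = np.trapezoid(x, x)
        ratios[r] = pauc / null if null > 0 else 1.0
    return float(ratios.mean()), float(np.mean(ratios <= 1.0))


def omission_rate(calibration_pred: np.ndarray, evaluation_pred: np.ndarray,
                  E: float = 0.05) -> float:
    """Fraction of evaluation presences below the E-omission threshold.

    The threshold is the smallest calibration-presence prediction after
    discarding the lowest E fraction of calibration predictions.
    """
    cal = np.sort(np.asarray(calibration_pred, float))
    ev = np.asarray(evaluation_pred, float)
    if cal.size == 0 or ev.size == 0:
        raise ValueError("empty prediction arrays")
    discard = int(math.floor(E * cal.size))
    T = cal[min(discard, cal.size - 1)]
    return float(np.mean(ev < T))


def aicc(model: MaxentModel, presence_raw: np.ndarray) -> float:
    """Small-sample AICc from normalized raw scores at the presences.

    ``presence_raw`` must already be on the scale where raw sums to 1 over
    the full modeling grid. k counts nonzero weights; n <= k + 1 yields NaN
    (the candidate is excluded).
    """
    raw = np.asarray(presence_raw, float)
    n = raw.size
    k = model.n_nonzero
    if n <= k + 1 or np.any(raw <= 0):
        return float("nan")
    lnL = float(np.sum(np.log(raw)))
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Candidate evaluation driver
# ---------------------------------------------------------------------------

def _fit_candidate(spec: CandidateSpec, env: EnvStack,
                   predictor_sets: dict[str, list[str]],
                   pres_xy: np.ndarray, fit_idx: np.ndarray,
                   bias_weights: Optional[np.ndarray]) -> tuple[MaxentModel, list[str]]:
    variables = predictor_sets[spec.predictor_set]
    Xp = env.values_at(pres_xy[fit_idx, 0], pres_xy[fit_idx, 1], variables)
    if np.isnan(Xp).any():
        raise ValueError("presence point on a nodata cell")
    Xb = env.table(variables)
    model = train_maxent(Xp, Xb, variables, classes=spec.classes, rm=spec.rm,
                         weights=bias_weights)
    return model, variables


def evaluate_candidates(
    candidates: Sequence[CandidateSpec],
    env: EnvStack,
    predictor_sets: dict[str, list[str]],
    pres_xy: np.ndarray,
    parts: PartitionSet,
    config: Optional[EvalConfig] = None,
    bias_weights: Optional[np.ndarray] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit and evaluate every candidate; one metrics row per candidate.

    Models are trained on the training partition against the full valid grid
    as background (optionally bias-weighted); partial ROC compares testing-
    partition presences with predictions at the evaluation background points;
    the omission threshold comes from training-presence predictions; AICc
    uses all non-independent presences under grid-normalized raw scores.
    """
    config = config or EvalConfig()
    pres_xy = np.asarray(pres_xy, float)
    rows = []
    bg_rc = parts.background_rc
    for i, spec in enumerate(candidates):
        row = {"rm": spec.rm, "classes": spec.classes, "predictor_set": spec.predictor_set,
               "auc_ratio": np.nan, "p": np.nan, "omission_rate": np.nan,
               "aicc": np.nan, "n_nonzero": 0, "converged": False}
        try:
            model, variables = _fit_candidate(spec, env, predictor_sets, pres_xy,
                                              parts.train_idx, bias_weights)
            train_pred = predict_points_raw(
                model, env.values_at(pres_xy[parts.train_idx, 0],
                                     pres_xy[parts.train_idx, 1], variables))
            test_pred = predict_points_raw(
                model, env.values_at(pres_xy[parts.test_idx, 0],
                                     pres_xy[parts.test_idx, 1], variables))
            bg_vals = np.column_stack([env.layers[v][bg_rc[:, 0], bg_rc[:, 1]]
                                       for v in variables])
            bg_pred = predict_points_raw(model, bg_vals)

            ratio, p = partial_roc(test_pred, bg_pred, E=config.E,
                                   replicates=config.proc_replicates,
                                   resample_fraction=config.proc_resample,
                                   seed=seed + i)
            orate = omission_rate(train_pred, test_pred, E=config.E)

            raw_grid = predict_raw(model, env.subset(variables), normalize=True)
            ni = parts.non_independent_idx
            rc = np.array([env.spec.index_of(lo, la)
                           for lo, la in pres_xy[ni]])
            pres_raw = raw_grid[rc[:, 0], rc[:, 1]]
            row.update(auc_ratio=ratio, p=p, omission_rate=orate,
                       aicc=aicc(model, pres_raw), n_nonzero=model.n_nonzero,
                       converged=True)
        except (ConvergenceError, ValueError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def select_candidates(metrics: pd.DataFrame, config: Optional[EvalConfig] = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Apply the selection cascade to a candidate metrics table.

    Returns the retained rows and an info dict with ``or_fallback`` (the
    minimal-omission branch was taken) and ``no_significant`` (nothing passed
    the significance test; the retained table is then empty).
    """
    config = config or EvalConfig()
    info = {"or_fallback": False, "no_significant": False}
    sig = metrics[(metrics["p"] < 0.05) & metrics["converged"]]
    if sig.empty:
        info["no_significant"] = True
        return sig, info
    low = sig[sig["omission_rate"] < config.or_threshold]
    if low.empty:
        info["or_fallback"] = True
        low = sig[sig["omission_rate"] == sig["omission_rate"].min()]
    with_aicc = low.dropna(subset=["aicc"])
    if with_aicc.empty:
        return low, info
    best = with_aicc["aicc"].min()
    return with_aicc[with_aicc["aicc"] <= best + config.delta_aicc], info


# ---------------------------------------------------------------------------
# Final models
# ---------------------------------------------------------------------------

def bootstrap_final(
    spec: CandidateSpec,
    env: EnvStack,
    predictor_sets: dict[str, list[str]],
    pres_xy: np.ndarray,
    parts: PartitionSet,
    config: Optional[EvalConfig] = None,
    bias_weights: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[list[MaxentModel], dict]:
    """Refit the selected candidate on bootstrap resamples and evaluate.

    Each replicate resamples the non-independent records with replacement
    (fallback rule: when the independent set was too small, fitting uses the
    training partition only and evaluation the testing partition). Failed
    replicates are dropped; more than half failing is an error. Final metrics
    (AUC ratio, p, omission rate) are computed from the replicate-mean cloglog
    surface at the final evaluation points.
    """
    config = config or EvalConfig()
    pres_xy = np.asarray(pres_xy, float)
    rng = np.random.default_rng(seed)
    fit_pool = parts.train_idx if parts.fallback else parts.non_independent_idx
    variables = predictor_sets[spec.predictor_set]

    models: list[MaxentModel] = []
    n_failed = 0
    for _ in range(config.bootstrap_replicates):
        take = rng.choice(fit_pool, size=fit_pool.size, replace=True)
        try:
            model, _ = _fit_candidate(spec, env, predictor_sets, pres_xy, take,
                                      bias_weights)
            models.append(model)
        except (ConvergenceError, ValueError):
            n_failed += 1
    if n_failed > config.bootstrap_replicates / 2:
        raise RuntimeError(f"{n_failed}/{config.bootstrap_replicates} bootstrap replicates failed")

    surface = average_models(models, env.subset(variables))
    eval_idx = parts.final_eval_idx
    rc_eval = np.array([env.spec.index_of(lo, la) for lo, la in pres_xy[eval_idx]]
                       ) if eval_idx.size else np.empty((0, 2), int)
    rc_fit = np.array([env.spec.index_of(lo, la) for lo, la in pres_xy[fit_pool]])
    eval_pred = surface[rc_eval[:, 0], rc_eval[:, 1]] if eval_idx.size else np.array([])
    fit_pred = surface[rc_fit[:, 0], rc_fit[:, 1]]
    bg_pred = surface[parts.background_rc[:, 0], parts.background_rc[:, 1]]

    metrics = {"n_replicates": len(models), "n_failed": n_failed,
               "auc_ratio": np.nan, "p": np.nan, "omission_rate": np.nan}
    if eval_idx.size:
        ratio, p = partial_roc(eval_pred, bg_pred, E=config.E,
                               replicates=config.proc_replicates,
                               resample_fraction=config.proc_resample, seed=seed)
        metrics.update(auc_ratio=ratio, p=p,
                       omission_rate=omission_rate(fit_pred, eval_pred, E=config.E))
    return models, metrics


def jackknife_importance(
    env: EnvStack,
    predictor_sets: dict[str, list[str]],
    spec: CandidateSpec,
    pres_xy: np.ndarray,
    fit_idx: np.ndarray,
    bias_weights: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Training gain with only / without each variable of the chosen set."""
    variables = predictor_sets[spec.predictor_set]
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    pres_xy = np.asarray(pres_xy, float)
    Xp = env.values_at(pres_xy[fit_idx, 0], pres_xy[fit_idx, 1], variables)
    Xb = env.table(variables)

    def gain_for(names):
        cols = [variables.index(v) for v in names]
        m = train_maxent(Xp[:, cols], Xb[:, cols], names, classes=spec.classes,
                         rm=spec.rm, weights=bias_weights)
        Fp = m.expander.transform(Xp[:, cols])
        Fb = m.expander.transform(Xb[:, cols])
        return training_gain(m, Fp, Fb, bias_weights)

    rows = []
    for v in variables:
        rows.append({"variable": v,
                     "gain_only": gain_for([v]),
                     "gain_without": gain_for([x for x in variables if x != v])})
    return pd.DataFrame(rows)


def average_models(models: Sequence[MaxentModel], env: EnvStack) -> np.ndarray:
    """Cell-wise mean cloglog surface of one or more models on one grid."""
    if not models:
        raise ValueError("need at least one model")
    surfaces = []
    for m in models:
        raw = predict_raw(m, env, normalize=True)
        surfaces.append(raw_to_cloglog(np.nan_to_num(raw, nan=0.0), m.H))
    out = np.mean(surfaces, axis=0)
    out[~env.mask] = np.nan
    return out


def pick_final(winners: dict[str, dict]) -> str:
    """Choose among per-predictor-set winners: minimal omission rate, then
    maximal AUC ratio, then fewest nonzero parameters."""
    if not winners:
        raise ValueError("no winners to choose from")

    def key(name):
        m = winners[name]
        return (m.get("omission_rate", np.inf),
                -m.get("auc_ratio", -np.inf),
                m.get("n_nonzero", np.inf),
                name)

    return min(winners, key=key)


def threshold_map(cloglog: np.ndarray, training_suitabilities: np.ndarray,
                  percentile: float = 10.0) -> tuple[np.ndarray, float]:
    """Binarize a cloglog surface at a percentile training-presence cutoff.

    The threshold is the linear-interpolation percentile of the training
    presence suitabilities, stepped down to the nearest order statistic when
    interpolation would leave more than ``percentile`` percent of training
    presences strictly below it. Cells at or above the threshold become 1;
    NaN cells stay NaN.
    """
    suits = np.sort(np.asarray(training_suitabilities, float))
    if suits.size == 0:
        raise ValueError("empty training presence set")
    T = float(np.percentile(suits, percentile))
    allowed = percentile / 100.0 * suits.size
    while np.sum(suits < T) > allowed + 1e-9:
        below = suits[suits < T]
        T = float(below[-1])
    binary = np.where(np.isnan(cloglog), np.nan, (cloglog >= T).astype(float))
    return binary, T
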