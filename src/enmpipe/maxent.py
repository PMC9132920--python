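"""Self-contained maximum-entropy presence/background model.

The model estimates a probability distribution q over background cells that
maximizes the average log-score of presence localities subject to an L1
penalty on the feature weights:

    minimize_lam   -mean_p( f(x_p) . lam ) + log Z(lam) + sum_j beta_j |lam_j|

with ``Z = sum_i w_i exp(f(x_i) . lam)`` over (optionally bias-weighted)
background cells, ``beta_j = rm * sigma_j / sqrt(n)`` (sigma_j = background
standard deviation of feature j, n = number of presences, rm the
regularization multiplier). The raw output is q itself, normalized to sum to
one over the background grid; the cloglog and logistic transforms rescale raw
scores through the entropy H of the fitted distribution.

Feature classes follow the usual maximum-entropy conventions on variables
scaled to [0, 1] using background minima/maxima: linear (l), quadratic (q),
pairwise product (p), threshold step (t) and forward hinge (h), the latter
two on fixed grids of equally spaced knots.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .grid import EnvStack

FEATURE_CLASSES = "lqpth"
DEFAULT_KNOTS = 10


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, grad_norm: float):
        super().__init__(f"{msg} (final gradient norm {grad_norm:.3e})")
        self.grad_norm = grad_norm


class FeatureExpander:
    """Expand raw predictor values into bounded maximum-entropy features.

    Scaling constants (per-variable min/max) and knot grids are derived from
    the background sample only; transformed presences are clamped into
    [0, 1]. Constant variables are dropped with a warning.
    """

    def __init__(self, variables: Sequence[str], classes: str, n_knots: int = DEFAULT_KNOTS):
        classes = "".join(dict.fromkeys(classes.lower()))
        bad = set(classes) - set(FEATURE_CLASSES)
        if bad or not classes:
            raise ValueError(f"invalid feature classes {classes!r}")
        self.variables = list(variables)
        self.classes = classes
        self.n_knots = int(n_knots)
        self.mins: Optional[np.ndarray] = None
        self.maxs: Optional[np.ndarray] = None
        self.active: Optional[list[int]] = None
        self.feature_names: list[str] = []
        # hinge knots in [0, 1): max(0, (x-k)/(1-k)); threshold knots interior
        self.hinge_knots = np.arange(self.n_knots) / self.n_knots
        self.threshold_knots = np.arange(1, self.n_knots + 1) / (self.n_knots + 1)

    def fit(self, background: np.ndarray) -> "FeatureExpander":
        X = np.asarray(background, float)
        if X.ndim != 2 or X.shape[1] != len(self.variables):
            raise ValueError("background shape does not match variable list")
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        self.active = []
        for j, name in enumerate(self.variables):
            if self.maxs[j] - self.mins[j] <= 0:
                warnings.warn(f"variable {name!r} is constant over the background; "
                              "its features are dropped", stacklevel=2)
            else:
                self.active.append(j)
        if not self.active:
            raise ValueError("all variables are constant over the background")
        self.feature_names = self._names()
        return self

    def _names(self) -> list[str]:
        names = []
        act = [self.variables[j] for j in self.active]
        if "l" in self.classes:
            names += [f"l:{v}" for v in act]
        if "q" in self.classes:
            names += [f"q:{v}" for v in act]
        if "p" in self.classes:
            names += [f"p:{a}*{b}" for i, a in enumerate(act) for b in act[i + 1:]]
        if "t" in self.classes:
            names += [f"t:{v}:{i}" for v in act for i in range(self.n_knots)]
        if "h" in self.classes:
            names += [f"h:{v}:{i}" for v in act for i in range(self.n_knots)]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.active is None:
            raise RuntimeError("expander not fitted")
        X = np.atleast_2d(np.asarray(X, float))
        span = self.maxs[self.active] - self.mins[self.active]
        S = (X[:, self.active] - self.mins[self.active]) / span
        S = np.clip(S, 0.0, 1.0)
        cols = []
        if "l" in self.classes:
            cols.append(S)
        if "q" in self.classes:
            cols.append(S**2)
        if "p" in self.classes:
            k = S.shape[1]
            cols.append(np.column_stack([S[:, i] * S[:, j]
                                         for i in range(k) for j in range(i + 1, k)])
                        if k >= 2 else np.empty((len(S), 0)))
        if "t" in self.classes:
            cols.append(np.column_stack([
                (S[:, v] > kn).astype(float)
                for v in range(S.shape[1]) for kn in self.threshold_knots
            ]))
        if "h" in self.classes:
            cols.append(np.column_stack([
                np.maximum(0.0, (S[:, v] - kn) / (1.0 - kn))
                for v in range(S.shape[1]) for kn in self.hinge_knots
            ]))
        return np.column_stack([c for c in cols if c.size or len(c.shape) == 2])


def expand_features(presence: np.ndarray, background: np.ndarray,
                    variables: Sequence[str], classes: str,
                    n_knots: int = DEFAULT_KNOTS) -> tuple[np.ndarray, np.ndarray, FeatureExpander]:
    """Fit an expander on the background and transform both samples."""
    exp = FeatureExpander(variables, classes, n_knots).fit(background)
    return exp.transform(presence), exp.transform(background), exp


@dataclass
class MaxentModel:
    """Fitted weights plus the normalizers needed for prediction.

    ``Z`` is the background partition function and ``H`` the entropy (nats)
    of the fitted distribution over the training background; both are needed
    to place new predictions on the raw and cloglog scales.
    """

    lam: np.ndarray
    feature_names: list[str]
    rm: float
    n_presence: int
    Z: float
    H: float
    expander: Optional[FeatureExpander] = None
    variables: list[str] = field(default_factory=list)
    classes: str = ""
    converged: bool = True
    n_iter: int = 0

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lam) > 1e-12))

    def linear_score(self, F: np.ndarray) -> np.ndarray:
        return np.asarray(F, float) @ self.lam

    def to_json(self, path: str | Path) -> None:
        exp = self.expander
        payload = {
            "lam": self.lam.tolist(),
            "feature_names": self.feature_names,
            "rm": self.rm,
            "n_presence": self.n_presence,
            "Z": self.Z,
            "H": self.H,
            "variables": self.variables,
            "classes": self.classes,
            "expander": None if exp is None else {
                "variables": exp.variables,
                "classes": exp.classes,
                "n_knots": exp.n_knots,
                "mins": exp.mins.tolist(),
                "maxs": exp.maxs.tolist(),
                "active": exp.active,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        payload = json.loads(Path(path).read_text())
        exp = None
        if payload["expander"] is not None:
            e = payload["expander"]
            exp = FeatureExpander(e["variables"], e["classes"], e["n_knots"])
            exp.mins = np.array(e["mins"])
            exp.maxs = np.array(e["maxs"])
            exp.active = list(e["active"])
            exp.feature_names = exp._names()
        return cls(
            lam=np.array(payload["lam"]),
            feature_names=list(payload["feature_names"]),
            rm=payload["rm"],
            n_presence=payload["n_presence"],
            Z=payload["Z"],
            H=payload["H"],
            expander=exp,
            variables=list(payload["variables"]),
            classes=payload["classes"],
        )


def _normalize_weights(weights: Optional[np.ndarray], n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, float)
    if w.shape != (n,):
        raise ValueError("weights length must match background size")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w / total


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    rm: float = 1.0,
    weights: Optional[np.ndarray] = None,
    beta: Optional[float] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    feature_names: Optional[list[str]] = None,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model by proximal gradient (FISTA).

    ``beta`` overrides the per-feature penalty ``rm * sigma_j / sqrt(n)`` with
    a single shared value (useful for closed-form checks). The convex problem
    is solved in the split form ``lam = u - v`` (u, v >= 0, penalty
    ``beta . (u + v)``) with L-BFGS-B; it raises :class:`ConvergenceError`
    when the L1 subgradient-optimality residual has not fallen below ``tol``
    within ``max_iter`` iterations.
    """
    Fp = np.atleast_2d(np.asarray(presence_features, float))
    Fb = np.atleast_2d(np.asarray(background_features, float))
    n, m = Fp.shape
    if n < 1:
        raise ValueError("need at least one presence")
    if Fb.shape[0] < 10:
        raise ValueError("need at least 10 background points")
    if Fb.shape[1] != m:
        raise ValueError("presence/background feature dimensions differ")
    if rm <= 0:
        raise ValueError("rm must be > 0")
    w = _normalize_weights(weights, Fb.shape[0])

    if beta is not None:
        betas = np.full(m, float(beta))
    else:
        sigma = Fb.std(axis=0)
        betas = rm * sigma / np.sqrt(n)

    mean_p = Fp.mean(axis=0)

    def smooth_parts(lam):
        s = Fb @ lam
        smax = s.max()
        e = w * np.exp(s - smax)
        Z = e.sum()
        q = e / Z
        logZ = smax + np.log(Z)
        return -mean_p @ lam + logZ, Fb.T @ q - mean_p

    def fun(z):
        lam = z[:m] - z[m:]
        f, g = smooth_parts(lam)
        return f + betas @ (z[:m] + z[m:]), np.concatenate([g + betas, -g + betas])

    from scipy.optimize import minimize

    def residual(lam):
        _, g_now = smooth_parts(lam)
        # subgradient optimality residual of the L1 problem
        r = np.where(np.abs(lam) > 0,
                     np.abs(g_now + betas * np.sign(lam)),
                     np.maximum(np.abs(g_now) - betas, 0.0))
        return float(np.max(r)) if m else 0.0

    x0 = np.zeros(2 * m)
    it = 0
    grad_norm = np.inf
    lam = np.zeros(m)
    for attempt in range(3):  # restart when the line search stalls early
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * (2 * m),
                       options={"maxiter": max_iter, "maxfun": 20 * max_iter,
                                "ftol": 1e-14, "gtol": tol / 10})
        it += int(res.nit)
        lam = res.x[:m] - res.x[m:]
        lam[np.abs(lam) < 1e-12] = 0.0
        grad_norm = residual(lam)
        if grad_norm < tol:
            break
        x0 = np.concatenate([np.maximum(lam, 0.0), np.maximum(-lam, 0.0)])
    if grad_norm >= tol:
        raise ConvergenceError("maximum-entropy fit did not converge", grad_norm)

    s = Fb @ lam
    smax = s.max()
    e = w * np.exp(s - smax)
    q = e / e.sum()
    Z = float(np.exp(smax) * np.sum(w * np.exp(s - smax)))
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    return MaxentModel(
        lam=lam,
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{i}" for i in range(m)],
        rm=rm, n_presence=n, Z=Z, H=H,
        converged=True, n_iter=it,
    )


def train_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    variables: Sequence[str],
    classes: str = "lq",
    rm: float = 1.0,
    weights: Optional[np.ndarray] = None,
    n_knots: int = DEFAULT_KNOTS,
    **kwargs,
) -> MaxentModel:
    """Expand raw variable values and fit; attaches the expander for reuse."""
    Fp, Fb, exp = expand_features(presence, background, variables, classes, n_knots)
    model = fit_maxent(Fp, Fb, rm=rm, weights=weights,
                       feature_names=exp.feature_names, **kwargs)
    model.expander = exp
    model.variables = list(variables)
    model.classes = exp.classes
    return model


# ---------------------------------------------------------------------------
# Prediction and output transforms
# ---------------------------------------------------------------------------

def predict_raw(model: MaxentModel, env: "EnvStack | np.ndarray",
                normalize: bool = True) -> np.ndarray:
    """Raw scores over an environment stack (2D, NaN outside) or feature rows.

    Over a grid the scores are normalized to sum to 1 across valid cells; for
    plain feature matrices ``normalize=False`` returns intensities on the
    training-background scale (``exp(f.lam)/Z``).
    """
    if isinstance(env, EnvStack):
        if model.expander is None:
            raise ValueError("model has no feature expander; predict from features instead")
        missing = [v for v in model.variables if v not in env.layers]
        if missing:
            raise KeyError(f"environment stack missing variables: {missing}")
        X = env.table(model.variables)
        F = model.expander.transform(X)
        s = F @ model.lam
        out = np.full((env.spec.nrows, env.spec.ncols), np.nan)
        e = np.exp(s - s.max())
        out[env.mask] = e / e.sum() if normalize else np.exp(s) / model.Z
        return out
    F = np.atleast_2d(np.asarray(env, float))
    s = F @ model.lam
    if normalize:
        e = np.exp(s - s.max())
        return e / e.sum()
    return np.exp(s) / model.Z


def predict_points_raw(model: MaxentModel, X: np.ndarray) -> np.ndarray:
    """Training-scale raw intensity at raw-variable rows (needs the expander)."""
    if model.expander is None:
        raise ValueError("model has no feature expander")
    F = model.expander.transform(np.atleast_2d(np.asarray(X, float)))
    return np.exp(F @ model.lam) / model.Z


def raw_to_cloglog(raw: np.ndarray, H: float) -> np.ndarray:
    """Complementary log-log transform of raw scores: 1 - exp(-e^H * raw)."""
    raw = np.asarray(raw, float)
    if np.nanmin(raw) < 0:
        raise ValueError("raw scores must be non-negative")
    if H < 0:
        raise ValueError("entropy must be non-negative")
    return 1.0 - np.exp(-np.exp(H) * raw)


def raw_to_logistic(raw: np.ndarray, H: float) -> np.ndarray:
    """Logistic transform of raw scores: e^H * raw / (1 + e^H * raw)."""
    raw = np.asarray(raw, float)
    if np.nanmin(raw) < 0:
        raise ValueError("raw scores must be non-negative")
    if H < 0:
        raise ValueError("entropy must be non-negative")
    s = np.exp(H) * raw
    return s / (1.0 + s)


def training_gain(model: MaxentModel, presence_features: np.ndarray,
                  background_features: np.ndarray,
                  weights: Optional[np.ndarray] = None) -> float:
    """Mean presence log raw-score relative to the background distribution."""
    Fp = np.atleast_2d(presence_features)
    Fb = np.atleast_2d(background_features)
    w = _normalize_weights(weights, Fb.shape[0])
    s = Fb @ model.lam
    smax = s.max()
    logZ = smax + np.log(np.sum(w * np.exp(s - smax)))
    return float(np.mean(Fp @ model.lam) - logZ)


# ---------------------------------------------------------------------------
# Variable diagnostics and selection
# ---------------------------------------------------------------------------

def permutation_importance(
    model: MaxentModel,
    presence: np.ndarray,
    background: np.ndarray,
    repeats: int = 5,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Percent importance per variable from permutation gain drops.

    Each variable's values are permuted jointly across presences and
    background, features re-expanded with the fitted scalers, and the drop in
    training gain recorded; drops are averaged over repeats, clipped at zero
    and normalized to sum to 100.
    """
    if model.expander is None:
        raise ValueError("model has no feature expander")
    rng = np.random.default_rng(seed)
    Xp = np.atleast_2d(np.asarray(presence, float))
    Xb = np.atleast_2d(np.asarray(background, float))
    n_p = Xp.shape[0]
    base = training_gain(model, model.expander.transform(Xp),
                         model.expander.transform(Xb), weights)
    k = Xp.shape[1]
    drops = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for _ in range(repeats):
            combined = np.concatenate([Xp[:, j], Xb[:, j]])
            rng.shuffle(combined)
            Xp2 = Xp.copy()
            Xb2 = Xb.copy()
            Xp2[:, j] = combined[:n_p]
            Xb2[:, j] = combined[n_p:]
            g = training_gain(model, model.expander.transform(Xp2),
                              model.expander.transform(Xb2), weights)
            acc += base - g
        drops[j] = max(0.0, acc / repeats)
    total = drops.sum()
    if total <= 0:
        return np.full(k, 100.0 / k)
    return 100.0 * drops / total


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column: 1 / (1 - R^2_j).

    R^2_j comes from the ordinary least-squares regression of column j on all
    other columns plus an intercept; exact collinearity yields ``inf``.
    """
    X = np.asarray(X, float)
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 variables")
    if n < k + 2:
        raise ValueError("VIF needs at least n_vars + 2 samples")
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def select_variables(
    presence: np.ndarray,
    background: np.ndarray,
    variables: Sequence[str],
    seed: int = 0,
    classes: str = "lq",
    rm: float = 1.0,
    weights: Optional[np.ndarray] = None,
    vif_threshold: float = 10.0,
    min_importance: float = 1.0,
    repeats: int = 5,
) -> list[str]:
    """Three-phase collinearity-aware variable selection.

    1. Fit a default model on every variable and drop those with zero
       permutation importance.
    2. While the maximum VIF over the background sample is at least
       ``vif_threshold`` (and at least two variables remain, VIF being
       undefined for one), take the two highest-VIF variables and drop
       whichever has the lower permutation importance under a model refitted
       on the current set.
    3. Refit and drop variables with importance below ``min_importance``
       percent, keeping at least one.
    """
    variables = list(variables)
    Xp = np.atleast_2d(np.asarray(presence, float))
    Xb = np.atleast_2d(np.asarray(background, float))
    idx = {v: i for i, v in enumerate(variables)}

    def fit_and_importance(names, sub_seed):
        cols = [idx[v] for v in names]
        model = train_maxent(Xp[:, cols], Xb[:, cols], names, classes=classes,
                             rm=rm, weights=weights)
        if len(names) == 1:
            return np.array([100.0])
        return permutation_importance(model, Xp[:, cols], Xb[:, cols],
                                      repeats=repeats, seed=sub_seed, weights=weights)

    # phase 1: zero-importance removal
    imp = fit_and_importance(variables, seed)
    current = [v for v, i in zip(variables, imp) if i > 1e-6]
    if not current:
        current = [variables[int(np.argmax(imp))]]

    # phase 2: iterative VIF reduction
    round_no = 1
    while len(current) >= 2:
        v = vif(Xb[:, [idx[x] for x in current]])
        if np.nanmax(v) < vif_threshold:
            break
        top2 = np.argsort(v)[-2:]
        imp = fit_and_importance(current, seed + round_no)
        drop_local = min(top2, key=lambda i: imp[i])
        current = [x for i, x in enumerate(current) if i != drop_local]
        round_no += 1

    # phase 3: drop weak contributors
    imp = fit_and_importance(current, seed + 10_000)
    kept = [v for v, i in zip(current, imp) if i >= min_importance]
    if not kept:
        kept = [current[int(np.argmax(imp))]]
    return kept
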