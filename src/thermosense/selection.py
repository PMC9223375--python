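"""Greedy two-stage wrapper feature selection over regression backends.

Stage 1 (feature increment) grows the selected set from empty: each round
every unselected feature is appended to the running best combination, all
candidates are scored, and the best one is kept while it improves on the
overall best.  Stage 2 (redundant feature removal) then tries deleting each
single feature; a deletion that improves the overall best is committed, one
non-improving round is tolerated (the search continues from the worse
combination), and a second consecutive non-improving round since the last
improvement terminates the search.

"Better" means strictly lower cross-validated RMSE, with ties broken toward
fewer features and then lexicographic feature order, so runs are fully
deterministic for a fixed protocol seed.

Candidate scoring is repeated k-fold cross-validation (default 5 folds x 3
repeats); the empty feature set is scored as the mean predictor.  The four
regression families -- linear, Gaussian process, SVM and decision tree --
are wrapped behind a common :class:`ModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.dummy import DummyRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

MODEL_FAMILIES = ("linear", "gpr", "svr", "tree")

_ALIASES = {
    "linear": "linear",
    "linear_regression": "linear",
    "ols": "linear",
    "gpr": "gpr",
    "gaussian_process": "gpr",
    "svr": "svr",
    "svm": "svr",
    "svm_regression": "svr",
    "tree": "tree",
    "decision_tree": "tree",
}


@dataclass(frozen=True)
class Protocol:
    """Inner evaluation protocol: repeated k-fold CV with a fixed seed."""

    folds: int = 5
    repeats: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """A regression backend: family name, hyperparameter overrides, seed."""

    family: str = "gpr"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _ALIASES:
            raise ValueError(
                f"unknown model family {self.family!r}; known: {sorted(set(_ALIASES))}"
            )

    @property
    def canonical_family(self) -> str:
        return _ALIASES[self.family]


def _lbfgs_capped(obj_func, initial_theta, bounds):
    # cap marginal-likelihood optimization cost; selection fits thousands of GPs
    res = minimize(
        obj_func, initial_theta, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 30},
    )
    return res.x, res.fun


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a model spec.

    Kernel methods (GPR, SVR) get z-score standardization fitted on the
    training fold; the linear and tree fits use raw feature values.
    """
    family = spec.canonical_family
    hp = dict(spec.hyperparameters)
    if family == "linear":
        return LinearRegression(**hp)
    if family == "tree":
        hp.setdefault("max_depth", 5)
        return DecisionTreeRegressor(random_state=spec.seed, **hp)
    if family == "svr":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("epsilon", 0.1)
        return Pipeline([("scale", StandardScaler()), ("svr", SVR(**hp))])
    kernel = hp.pop(
        "kernel",
        ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3))
        + WhiteKernel(1e-2, (1e-8, 1e1)),
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        optimizer=_lbfgs_capped,
        n_restarts_optimizer=0,
        random_state=spec.seed,
        **hp,
    )
    return Pipeline([("scale", StandardScaler()), ("gpr", gpr)])


@dataclass(frozen=True)
class PerformanceEstimate:
    rmse: float
    r2: float
    protocol: Protocol

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass
class EvalRecord:
    """One scored candidate combination in the selection trace."""

    stage: str  # "baseline" | "increment" | "removal"
    round: int
    features: tuple
    rmse: float
    r2: float


@dataclass
class SelectionState:
    """Bookkeeping of the two-stage search."""

    s_best: frozenset
    t_best: frozenset
    s_uc: frozenset
    p_best: PerformanceEstimate
    time_worse: int = 0
    trace: list = field(default_factory=list)

    @property
    def explored(self) -> int:
        return len(self.trace)


def evaluate_subset(
    features,
    table: pd.DataFrame,
    model: ModelSpec,
    protocol: Protocol,
    target: str = "reported_ts",
) -> PerformanceEstimate:
    """Repeated k-fold CV score of one feature subset.

    Returns mean per-fold RMSE as the scalar criterion and a pooled
    out-of-fold R^2 alongside.  The empty subset is scored as the
    mean-predictor baseline.
    """
    features = sorted(features)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    n = len(table)
    if n < 2 * protocol.folds:
        raise ValueError(f"need >= {2 * protocol.folds} rows for {protocol.folds}-fold CV, got {n}")
    y = table[target].to_numpy(dtype=float)
    X = table[features].to_numpy(dtype=float) if features else np.zeros((n, 0))

    cv = RepeatedKFold(
        n_splits=protocol.folds, n_repeats=protocol.repeats, random_state=protocol.seed
    )
    fold_rmse = []
    preds = np.empty(protocol.repeats * n)
    truth = np.empty(protocol.repeats * n)
    pos = 0
    for train_idx, test_idx in cv.split(np.zeros((n, 1))):
        est = DummyRegressor(strategy="mean") if not features else make_estimator(model)
        Xtr = X[train_idx] if features else np.zeros((train_idx.size, 1))
        Xte = X[test_idx] if features else np.zeros((test_idx.size, 1))
        est.fit(Xtr, y[train_idx])
        p = est.predict(Xte)
        fold_rmse.append(float(np.sqrt(np.mean((p - y[test_idx]) ** 2))))
        preds[pos: pos + test_idx.size] = p
        truth[pos: pos + test_idx.size] = y[test_idx]
        pos += test_idx.size
    preds, truth = preds[:pos], truth[:pos]
    ss_res = float(np.sum((preds - truth) ** 2))
    ss_tot = float(np.sum((truth - np.mean(truth)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return PerformanceEstimate(rmse=float(np.mean(fold_rmse)), r2=r2, protocol=protocol)


def _key(rmse: float, combo: frozenset):
    return (rmse, len(combo), tuple(sorted(combo)))


def _better(rmse_a: float, combo_a: frozenset, rmse_b: float, combo_b: frozenset) -> bool:
    """Strictly lower RMSE wins; ties go to fewer features, then lexicographic order."""
    return _key(rmse_a, combo_a) < _key(rmse_b, combo_b)


def _make_perf_fn(table, model, protocol, target, performance_fn):
    if performance_fn is not None:
        def fn(combo):
            out = performance_fn(frozenset(combo))
            if isinstance(out, PerformanceEstimate):
                return out
            rmse, r2 = out if isinstance(out, tuple) else (out, np.nan)
            return PerformanceEstimate(rmse=float(rmse), r2=float(r2), protocol=protocol)
        return fn
    return lambda combo: evaluate_subset(combo, table, model, protocol, target)


def feature_increment(
    table: pd.DataFrame | None = None,
    model: ModelSpec | None = None,
    protocol: Protocol | None = None,
    candidates=None,
    target: str = "reported_ts",
    performance_fn=None,
) -> SelectionState:
    """Stage 1: grow the best combination one feature at a time.

    ``performance_fn`` (a mapping from feature sets to performance) replaces
    model fitting entirely when supplied, which makes the search decisions
    testable against hand-simulated traces.
    """
    model = model or ModelSpec()
    protocol = protocol or Protocol()
    if candidates is None:
        if table is None:
            raise ValueError("need a table or an explicit candidate list")
        candidates = [c for c in table.columns if c not in ("subject_id", "sex", target)]
    if not candidates:
        raise ValueError("need at least one candidate feature")
    perf = _make_perf_fn(table, model, protocol, target, performance_fn)

    s_uc = frozenset(candidates)
    s_best = frozenset()
    t_best = frozenset()
    p_best = perf(s_best)
    state = SelectionState(s_best=s_best, t_best=t_best, s_uc=s_uc, p_best=p_best)
    state.trace.append(EvalRecord("baseline", 0, (), p_best.rmse, p_best.r2))

    rnd = 0
    while s_uc:
        rnd += 1
        scored = []
        for f in sorted(s_uc):
            combo = t_best | {f}
            est = perf(combo)
            state.trace.append(
                EvalRecord("increment", rnd, tuple(sorted(combo)), est.rmse, est.r2)
            )
            scored.append((est, combo))
        est, combo = min(scored, key=lambda sc: _key(sc[0].rmse, sc[1]))
        t_best = combo
        s_uc = s_uc - combo
        if _better(est.rmse, combo, p_best.rmse, s_best):
            s_best, p_best = combo, est
        else:
            break
    state.s_best, state.t_best, state.s_uc, state.p_best = s_best, t_best, s_uc, p_best
    return state


def redundant_removal(
    state: SelectionState,
    table: pd.DataFrame | None = None,
    model: ModelSpec | None = None,
    protocol: Protocol | None = None,
    target: str = "reported_ts",
    performance_fn=None,
) -> SelectionState:
    """Stage 2: try dropping single features from the selected combination.

    An improving deletion is committed and resets the worse-step counter; a
    single non-improving round is tolerated (the next round removes from the
    worse combination), and the second consecutive non-improving round since
    the last improvement ends the stage.
    """
    model = model or ModelSpec()
    protocol = protocol or Protocol()
    if len(state.s_best) <= 1:
        return state  # nothing removable
    perf = _make_perf_fn(table, model, protocol, target, performance_fn)

    s_best, p_best = state.s_best, state.p_best
    t_best = s_best
    time_worse = 0
    rnd = 0
    while t_best:
        rnd += 1
        scored = []
        for f in sorted(t_best):
            combo = t_best - {f}
            est = perf(combo)
            state.trace.append(
                EvalRecord("removal", rnd, tuple(sorted(combo)), est.rmse, est.r2)
            )
            scored.append((est, combo))
        est, combo = min(scored, key=lambda sc: _key(sc[0].rmse, sc[1]))
        t_best = combo
        if _better(est.rmse, combo, p_best.rmse, s_best):
            s_best, p_best = combo, est
            time_worse = 0
        else:
            time_worse += 1
            if time_worse >= 2:
                break
    state.s_best, state.t_best, state.p_best, state.time_worse = (
        s_best, t_best, p_best, time_worse,
    )
    return state


@dataclass
class SelectionResult:
    s_best: frozenset
    performance: PerformanceEstimate
    state: SelectionState
    fitted_model: object

    @property
    def features(self) -> tuple:
        return tuple(sorted(self.s_best))


def select(
    table: pd.DataFrame,
    model: ModelSpec | None = None,
    protocol: Protocol | None = None,
    candidates=None,
    target: str = "reported_ts",
    performance_fn=None,
) -> SelectionResult:
    """Run both stages and refit the backend on the selected combination
    over the full table."""
    model = model or ModelSpec()
    protocol = protocol or Protocol()
    state = feature_increment(table, model, protocol, candidates, target, performance_fn)
    state = redundant_removal(state, table, model, protocol, target, performance_fn)
    fitted = None
    if performance_fn is None and table is not None and len(table) and state.s_best:
        fitted = make_estimator(model)
        fitted.fit(table[sorted(state.s_best)].to_numpy(dtype=float),
                   table[target].to_numpy(dtype=float))
    return SelectionResult(
        s_best=state.s_best, performance=state.p_best, state=state, fitted_model=fitted
    )
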