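"""Report-shaped analyses over a feature table.

Four protocols, each mirroring a standard way this kind of chamber study is
reported:

* per-feature Pearson correlation with the thermal-sensation vote,
  with 0.05/0.01 significance stars;
* resampled train/test comparison of the physiological model against the
  Fanger PMV baseline (RMSE and out-of-sample R^2 per trial plus averages);
* gender error analysis: signed prediction errors on a sex-stratified split,
  compared with a pooled-variance t-test and a tie-corrected Mann-Whitney U;
* greedy signal-importance ranking: starting from environment-only features,
  whole signal-wise feature groups are added one best group per round.

Out-of-sample R^2 is 1 - SS_res/SS_tot on the evaluation rows and may be
negative for a predictor worse than the test-set mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pmv import pmv_for_trial
from .selection import ModelSpec, Protocol, evaluate_subset, make_estimator


def metrics(pred, truth) -> tuple:
    """(RMSE, R^2) of predictions against truth on the evaluation set."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must have equal non-zero length")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance truth: R^2 undefined")
        return rmse, float("nan")
    r2 = 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot
    return rmse, r2


def correlation_table(
    table: pd.DataFrame,
    target: str = "reported_ts",
    feature_cols=None,
) -> pd.DataFrame:
    """Pearson r and exact two-tailed p (t distribution, n-2 df) of every
    feature against the vote; stars at p<0.05 (*) and p<0.01 (**).

    Constant features get an NaN row flagged ``constant``.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("subject_id", "sex", target)]
    y = table[target].to_numpy(dtype=float)
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    if np.ptp(y) == 0:
        raise ValueError(f"target {target!r} is constant")
    rows = []
    for name in feature_cols:
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.any(~np.isfinite(x)):
            rows.append({"feature": name, "r": np.nan, "p": np.nan, "sig": "",
                         "flag": "constant" if np.ptp(x) == 0 else "non-finite"})
            continue
        r, p = stats.pearsonr(x, y)
        sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append({"feature": name, "r": float(r), "p": float(p), "sig": sig, "flag": ""})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Per-trial and average RMSE/R^2 of the proposed model vs the PMV
    baseline on resampled train/test splits."""

    trials: pd.DataFrame  # columns: trial, model_rmse, model_r2, pmv_rmse, pmv_r2
    train_n: int
    test_n: int
    seed: int

    @property
    def averages(self) -> dict:
        return {
            c: float(self.trials[c].mean())
            for c in ("model_rmse", "model_r2", "pmv_rmse", "pmv_r2")
        }


def compare_with_pmv(
    table: pd.DataFrame,
    model: ModelSpec,
    best_features,
    n_trials: int = 3,
    train_n: int | None = None,
    seed: int = 0,
    target: str = "reported_ts",
    met: float = 1.0,
    clo: float = 0.5,
) -> ComparisonReport:
    """Resampled comparison: per trial a random train/test split, the model
    retrained on ``best_features``, and PMV scored on the same test rows.

    The default split holds out one fifth of the rows (72 train / 18 test on
    a 90-row table).
    """
    best_features = sorted(best_features)
    missing = [f for f in best_features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    n = len(table)
    if train_n is None:
        train_n = int(round(0.8 * n))
    test_n = n - train_n
    if test_n < 1 or train_n < 1:
        raise ValueError(f"table of {n} rows cannot support a {train_n}-row training set")

    rng = np.random.default_rng(seed)
    y = table[target].to_numpy(dtype=float)
    X = table[best_features].to_numpy(dtype=float)
    pmv_all = np.array([
        pmv_for_trial(r["EnvTemp"], r["EnvRH"], r["EnvWind"], met=met, clo=clo)
        for _, r in table.iterrows()
    ])
    rows = []
    for k in range(n_trials):
        perm = rng.permutation(n)
        tr, te = perm[:train_n], perm[train_n:]
        est = make_estimator(model)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        m_rmse, m_r2 = metrics(pred, y[te])
        p_rmse, p_r2 = metrics(pmv_all[te], y[te])
        rows.append({"trial": k + 1, "model_rmse": m_rmse, "model_r2": m_r2,
                     "pmv_rmse": p_rmse, "pmv_r2": p_r2})
    return ComparisonReport(
        trials=pd.DataFrame(rows), train_n=train_n, test_n=test_n, seed=seed
    )


def mann_whitney_z(a, b) -> tuple:
    """Mann-Whitney U with the tie-corrected normal approximation.

    Returns (U, Z, two-tailed p).  Z is signed with respect to the first
    sample's rank sum, matching how chamber studies report the statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nn = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if var <= 0:
        return u1, 0.0, 1.0  # all values tied
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(z), float(p)


@dataclass
class GenderReport:
    """Error-by-sex analysis of one stratified train/test split."""

    rmse_overall: float
    rmse_male: float
    rmse_female: float
    t_stat: float
    t_p: float
    u_stat: float
    z_stat: float
    u_p: float
    group_summary: pd.DataFrame  # mean/SD/median/quartiles of signed errors
    train_counts: tuple
    test_counts: tuple
    seed: int


def gender_error_test(
    table: pd.DataFrame,
    model: ModelSpec,
    best_features,
    train_counts: tuple | None = None,
    seed: int = 0,
    target: str = "reported_ts",
    welch: bool = False,
    exact: bool = False,
) -> GenderReport:
    """Sex-stratified split, model retrained, signed test errors compared.

    ``train_counts`` gives (male, female) training sample counts; by default
    four fifths of each sex group.  The t-test uses pooled variance unless
    ``welch``; ``exact`` switches the Mann-Whitney p to scipy's exact method
    (small, tie-free samples only).
    """
    best_features = sorted(best_features)
    males = table.index[table["sex"] == "male"].to_numpy()
    females = table.index[table["sex"] == "female"].to_numpy()
    if train_counts is None:
        train_counts = (int(round(0.8 * males.size)), int(round(0.8 * females.size)))
    tm, tf = train_counts
    if not (0 < tm < males.size and 0 < tf < females.size):
        raise ValueError(
            f"train counts {train_counts} leave an empty group "
            f"(available: {males.size} male, {females.size} female)"
        )
    rng = np.random.default_rng(seed)
    train_idx = np.concatenate([
        rng.choice(males, size=tm, replace=False),
        rng.choice(females, size=tf, replace=False),
    ])
    test_idx = np.setdiff1d(table.index.to_numpy(), train_idx)

    est = make_estimator(model)
    est.fit(
        table.loc[train_idx, best_features].to_numpy(dtype=float),
        table.loc[train_idx, target].to_numpy(dtype=float),
    )
    pred = est.predict(table.loc[test_idx, best_features].to_numpy(dtype=float))
    err = pred - table.loc[test_idx, target].to_numpy(dtype=float)
    is_male = (table.loc[test_idx, "sex"] == "male").to_numpy()
    err_m, err_f = err[is_male], err[~is_male]
    if err_m.size == 0 or err_f.size == 0:
        raise ValueError("a sex group is empty in the test set")

    t_stat, t_p = stats.ttest_ind(err_m, err_f, equal_var=not welch)
    if exact:
        res = stats.mannwhitneyu(err_m, err_f, alternative="two-sided", method="exact")
        u, z, u_p = float(res.statistic), float("nan"), float(res.pvalue)
    else:
        u, z, u_p = mann_whitney_z(err_m, err_f)

    def summary(e, label):
        q1, med, q3 = np.percentile(e, [25, 50, 75])
        return {"group": label, "n": e.size, "mean": float(e.mean()),
                "sd": float(e.std(ddof=1)) if e.size > 1 else np.nan,
                "median": float(med), "q1": float(q1), "q3": float(q3),
                "rmse": float(np.sqrt(np.mean(e**2)))}

    return GenderReport(
        rmse_overall=float(np.sqrt(np.mean(err**2))),
        rmse_male=float(np.sqrt(np.mean(err_m**2))),
        rmse_female=float(np.sqrt(np.mean(err_f**2))),
        t_stat=float(t_stat), t_p=float(t_p),
        u_stat=u, z_stat=z, u_p=u_p,
        group_summary=pd.DataFrame([summary(err_m, "male"), summary(err_f, "female")]),
        train_counts=(tm, tf),
        test_counts=(int(err_m.size), int(err_f.size)),
        seed=seed,
    )


def ttest_type1_rate(
    n_a: int = 10,
    n_b: int = 8,
    repeats: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the pooled t-test under the null (both
    groups drawn from the same normal).  Calibration utility: the rate should
    sit near ``alpha``."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(repeats):
        a = rng.standard_normal(n_a)
        b = rng.standard_normal(n_b)
        _, p = stats.ttest_ind(a, b, equal_var=True)
        if p < alpha:
            rej += 1
    return rej / repeats


#: default signal-wise groups of the ranking protocol, restricted to the
#: features a selected combination typically retains; order breaks ties
DEFAULT_RANK_GROUPS = (
    ("EMG", ("EMG_MAV", "EMG_IEMG", "EMG_RMS")),
    ("BodyTemp", ("T3_calf", "T1_chest")),
    ("ECG", ("ECG_LF/HF", "ECG_SDNN")),
    ("EEG", ("EEG_beta_power", "EEG_beta")),
)

ENV_FEATURES = ("EnvTemp", "EnvWind", "EnvRH")


def rank_signals(
    table: pd.DataFrame,
    model: ModelSpec,
    groups=DEFAULT_RANK_GROUPS,
    protocol: Protocol | None = None,
    base_features=ENV_FEATURES,
    target: str = "reported_ts",
) -> pd.DataFrame:
    """Greedy forward addition of whole signal-wise feature groups.

    Row 0 is the environment-only model; each following row adds the single
    group that minimizes cross-validated RMSE (ties broken by declared group
    order), until every group is included.
    """
    protocol = protocol or Protocol()
    for gname, feats in groups:
        missing = [f for f in feats if f not in table.columns]
        if missing:
            raise KeyError(f"group {gname!r} features not in table: {missing}")
    order = {g: i for i, (g, _) in enumerate(groups)}
    current = list(base_features)
    included = []
    est = evaluate_subset(current, table, model, protocol, target)
    rows = [{"n_signals": 0, "signals": "Environment", "rmse": est.rmse, "r2": est.r2}]
    remaining = list(groups)
    while remaining:
        scored = []
        for gname, feats in remaining:
            est = evaluate_subset(current + list(feats), table, model, protocol, target)
            scored.append((est.rmse, order[gname], gname, feats, est))
        scored.sort(key=lambda s: (s[0], s[1]))
        _, _, gname, feats, est = scored[0]
        current += list(feats)
        included.append(gname)
        remaining = [g for g in remaining if g[0] != gname]
        rows.append({
            "n_signals": len(included),
            "signals": "Environment, " + ", ".join(included),
            "rmse": est.rmse,
            "r2": est.r2,
        })
    return pd.DataFrame(rows)
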