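"""Repeated leave-group-out cross-validation and model-fit metrics.

The resampling scheme is Monte Carlo cross-validation: within each of
``n_repeats`` repeats, ``n_runs`` random stratified 75/25 train/test splits
are drawn; a forest is fitted on each training set, test-set fit metrics
and permutation importances are computed, and run-level values are averaged
into one repeat-level estimate.  The repeat is the unit of inference —
downstream t statistics on importances carry n_repeats - 1 degrees of
freedom — and reported "mean +/- value" summaries are means and standard
deviations over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .exposure import PredictorTable
from .forest import ForestConfig, fit_forest, permutation_importance, predict_proba

__all__ = [
    "CVConfig",
    "CVResult",
    "lgocv",
    "cohen_kappa",
    "roc_area",
    "odds_ratio_ci",
    "confusion_table",
    "full_data_fit_summary",
    "multiplicity_trend",
]


# ---------------------------------------------------------------------------
# metrics


def confusion_table(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2x2 confusion counts [[TP, FN], [FP, TN]] for 0/1 labels."""
    y_true = np.asarray(y_true) > 0.5
    y_pred = np.asarray(y_pred) > 0.5
    tp = int(np.sum(y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    return np.array([[tp, fn], [fp, tn]])


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a 2x2 confusion table.

    kappa = (p_o - p_e) / (1 - p_e); defined as 0 when chance agreement is
    exactly 1 (constant marginals).
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("confusion table must be 2x2")
    if (c < 0).any():
        raise ValueError("negative counts")
    n = c.sum()
    if n <= 0:
        raise ValueError("empty confusion table")
    po = (c[0, 0] + c[1, 1]) / n
    row = c.sum(axis=1) / n
    col = np.array([c[0, 0] + c[1, 0], c[0, 1] + c[1, 1]]) / n
    pe = row[0] * col[0] + row[1] * col[1]
    if pe >= 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def roc_area(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordance probability (ties counted 1/2) — the rank-sum AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels) > 0.5
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_area needs both classes present")
    r = rankdata(scores, method="average")
    return float((r[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def odds_ratio_ci(table: np.ndarray, level: float = 0.95) -> tuple:
    """Cross-product odds ratio with a Wald log-scale confidence interval.

    The Haldane-Anscombe 0.5 continuity correction is applied iff any cell
    is zero; a zero row or column leaves the OR undefined and raises.
    """
    c = np.asarray(table, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (c < 0).any():
        raise ValueError("negative counts")
    if (c.sum(axis=1) == 0).any() or (c.sum(axis=0) == 0).any():
        raise ValueError("odds ratio undefined: zero row or column")
    if (c == 0).any():
        c = c + 0.5
    orr = (c[0, 0] * c[1, 1]) / (c[0, 1] * c[1, 0])
    se = float(np.sqrt((1.0 / c).sum()))
    z = float(ndtri(0.5 + level / 2.0))
    lo = float(np.exp(np.log(orr) - z * se))
    hi = float(np.exp(np.log(orr) + z * se))
    return float(orr), lo, hi


def full_data_fit_summary(y_true: np.ndarray, y_pred: np.ndarray, level: float = 0.95) -> dict:
    """Sensitivity, specificity, kappa and the predicted-risk odds ratio
    from a classifier's full-sample predictions."""
    conf = confusion_table(y_true, y_pred)
    tp, fn = conf[0]
    fp, tn = conf[1]
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (fp + tn) if (fp + tn) else float("nan")
    out = {
        "confusion": conf.tolist(),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "kappa": cohen_kappa(conf),
    }
    try:
        orr, lo, hi = odds_ratio_ci(conf, level=level)
        out.update({"odds_ratio": orr, "or_ci_low": lo, "or_ci_high": hi})
    except ValueError:
        out.update({"odds_ratio": float("nan"), "or_ci_low": float("nan"), "or_ci_high": float("nan")})
    return out


# ---------------------------------------------------------------------------
# LGOCV


@dataclass
class CVConfig:
    n_runs: int = 10
    n_repeats: int = 10
    train_fraction: float = 0.75
    stratify_on_stratum: bool = False
    forest: ForestConfig = field(default_factory=ForestConfig)

    def validate(self) -> None:
        if self.n_runs < 1 or self.n_repeats < 1:
            raise ValueError("n_runs and n_repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class CVResult:
    repeat_metrics: pd.DataFrame          # one row per repeat
    repeat_importance: np.ndarray         # (n_features, n_repeats)
    feature_names: list
    overall: dict                         # metric -> {"mean": ..., "sd": ...}
    config: CVConfig
    task: str
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_metrics)


def _stratified_split(
    strata: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple:
    """One random split preserving per-stratum proportions within +/-1."""
    train_idx = []
    test_idx = []
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        rows = rng.permutation(rows)
        k = int(round(train_fraction * rows.size))
        k = min(max(k, 1), rows.size - 1) if rows.size > 1 else rows.size
        train_idx.append(rows[:k])
        test_idx.append(rows[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _fit_metrics(task, y_test, pred_label, pred_score) -> dict:
    if task == "classification":
        conf = confusion_table(y_test, pred_label)
        out = {
            "accuracy": float(np.mean(pred_label == y_test)),
            "kappa": cohen_kappa(conf),
        }
        try:
            out["roc_area"] = roc_area(pred_score, y_test)
        except ValueError:
            out["roc_area"] = float("nan")
        return out
    ss_res = float(np.sum((y_test - pred_score) ** 2))
    ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
    return {"r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")}


def lgocv(table: PredictorTable, config: Optional[CVConfig] = None, seed: int = 0) -> CVResult:
    """Repeated leave-group-out cross-validation of a conditional forest.

    Splits are stratified on the outcome for binary outcomes (joined with
    the stratum label when ``stratify_on_stratum``), which guarantees both
    classes in every training set.  Deterministic given ``seed``.
    """
    config = config or CVConfig()
    config.validate()
    X = table.feature_matrix
    y = table.outcome
    task = "classification" if table.outcome_kind == "binary" else "regression"
    if task == "classification" and np.unique(y).size < 2:
        raise ValueError("binary outcome must contain both classes")

    if task == "classification":
        strata = y.astype(int).astype(str)
    else:
        strata = np.full(y.size, "all")
    if config.stratify_on_stratum:
        strata = np.char.add(np.char.add(strata, "|"), table.stratum.astype(str))

    root = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    repeat_seeds = root.spawn(config.n_repeats)
    repeat_rows = []
    rep_imp = np.zeros((X.shape[1], config.n_repeats))
    for rep in range(config.n_repeats):
        split_rng = np.random.default_rng(repeat_seeds[rep])
        fit_seeds = split_rng.integers(0, 2**31 - 1, size=2 * config.n_runs)
        run_metrics = []
        run_imp = np.zeros((X.shape[1], config.n_runs))
        for run in range(config.n_runs):
            tr, te = _stratified_split(strata, config.train_fraction, split_rng)
            model = fit_forest(
                X[tr], y[tr], config.forest, seed=int(fit_seeds[2 * run]),
                task=task, feature_names=table.feature_names,
            )
            score = predict_proba(model, X[te])
            label = (score > 0.5).astype(float) if task == "classification" else score
            run_metrics.append(_fit_metrics(task, y[te], label, score))
            run_imp[:, run] = permutation_importance(
                model, X[tr], y[tr], seed=int(fit_seeds[2 * run + 1])
            )
        rep_imp[:, rep] = run_imp.mean(axis=1)
        repeat_rows.append(pd.DataFrame(run_metrics).mean().to_dict())

    repeat_metrics = pd.DataFrame(repeat_rows)
    overall = {
        m: {"mean": float(repeat_metrics[m].mean()), "sd": float(repeat_metrics[m].std(ddof=1))}
        for m in repeat_metrics.columns
    }
    return CVResult(
        repeat_metrics=repeat_metrics,
        repeat_importance=rep_imp,
        feature_names=table.feature_names,
        overall=overall,
        config=config,
        task=task,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# multiplicity trend


def multiplicity_trend(
    outcome: np.ndarray,
    groups: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    outcome_kind: str = "binary",
) -> dict:
    """Association between outcome and grouped multiplicity (0..cap).

    Binary outcome: logistic regression with the group entered as a
    categorical factor; the group term is tested by a likelihood-ratio
    chi-square (df = n_groups - 1).  Continuous outcome: OLS with a partial
    F-test for the group term.  Covariates enter both the null and the full
    model.  Perfect separation falls back to an L2-penalized logistic fit,
    flagged in the result.
    """
    import statsmodels.api as sm

    outcome = np.asarray(outcome, dtype=float)
    groups = np.asarray(groups)
    dummies = pd.get_dummies(pd.Categorical(groups), drop_first=True, dtype=float)
    X_null = pd.DataFrame({"const": np.ones(outcome.size)})
    if covariates is not None:
        for c in covariates.columns:
            X_null[c] = np.asarray(covariates[c], dtype=float)
    X_full = pd.concat([X_null, dummies.set_axis([f"group_{c}" for c in dummies.columns], axis=1)], axis=1)
    df_group = dummies.shape[1]

    if outcome_kind == "binary":
        flagged = False
        try:
            full = sm.Logit(outcome, X_full).fit(disp=0)
            null = sm.Logit(outcome, X_null).fit(disp=0)
            llf_full, llf_null = full.llf, null.llf
            if not (np.isfinite(llf_full) and np.isfinite(llf_null)):
                raise ValueError("non-finite likelihood")
        except Exception:
            flagged = True
            full = sm.Logit(outcome, X_full).fit_regularized(alpha=1e-4, disp=0)
            null = sm.Logit(outcome, X_null).fit_regularized(alpha=1e-4, disp=0)
            llf_full = sm.Logit(outcome, X_full).loglike(np.asarray(full.params))
            llf_null = sm.Logit(outcome, X_null).loglike(np.asarray(null.params))
        from scipy.stats import chi2

        stat = 2.0 * (llf_full - llf_null)
        p = float(chi2.sf(stat, df_group))
        return {
            "test": "likelihood_ratio_chi2",
            "statistic": float(stat),
            "df": int(df_group),
            "p_value": p,
            "separation_fallback": flagged,
            "group_coefs": {c: float(v) for c, v in zip(X_full.columns, np.asarray(full.params)) if c.startswith("group_")},
        }

    full = sm.OLS(outcome, X_full).fit()
    null = sm.OLS(outcome, X_null).fit()
    from scipy.stats import f as f_dist

    df_resid = full.df_resid
    f_stat = ((null.ssr - full.ssr) / df_group) / (full.ssr / df_resid)
    p = float(f_dist.sf(f_stat, df_group, df_resid))
    return {
        "test": "partial_F",
        "statistic": float(f_stat),
        "ss_group": float(null.ssr - full.ssr),
        "df": (int(df_group), int(df_resid)),
        "p_value": p,
        "separation_fallback": False,
        "group_coefs": {c: float(v) for c, v in zip(X_full.columns, np.asarray(full.params)) if c.startswith("group_")},
    }
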