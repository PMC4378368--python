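"""Sensitive-period inference: focal-vs-global importance tests and profiles.

A sensitive exposure period is declared when exposure to one maltreatment
type at one age — or at two adjacent ages — is a significantly more
important predictor of the outcome than every global exposure measure
(duration, multiplicity, severity).  The unit of evidence is the
repeat-level mean importance from repeated leave-group-out
cross-validation: each focal predictor is compared to each global by a
one-sided paired t-test over the repeat-level values (df = n_repeats - 1).
The null of "no sensitive period" is retained unless all three comparisons
are significant for the focal single cell or for the focal adjacent pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .cv import CVConfig, CVResult, lgocv
from .exposure import GlobalExposure, PredictorTable

__all__ = [
    "ImportanceTable",
    "SensitivePeriodReport",
    "aggregate_importance",
    "paired_one_sided_t",
    "test_focal_vs_globals",
    "collapse_profiles",
    "detect",
]

GLOBAL_NAMES = list(GlobalExposure.NAMES)


@dataclass
class ImportanceTable:
    """Repeat-level importance values with per-feature summaries."""

    values: np.ndarray          # (n_features, n_repeats)
    feature_meta: pd.DataFrame  # name, kind, type_label, age
    summary: pd.DataFrame       # name, mean, sd, ci_low, ci_high

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    def repeat_values(self, name: str) -> np.ndarray:
        idx = self.feature_meta.index[self.feature_meta["name"] == name]
        if len(idx) == 0:
            raise KeyError(name)
        return self.values[idx[0]]


@dataclass
class SensitivePeriodReport:
    focal_single: Optional[dict]
    focal_pair: Optional[dict]
    tests_single: list
    tests_pair: list
    decision: str               # "sensitive period declared" | "null retained"
    single_passes: bool
    pair_passes: bool
    alpha: float
    age_profile: dict           # age -> max mean importance over types
    type_profile: dict          # type label (and globals) -> max mean over ages
    cv_overall: dict = field(default_factory=dict)
    full_fit: dict = field(default_factory=dict)

    @property
    def declared(self) -> bool:
        return self.decision == "sensitive period declared"

    def to_dict(self) -> dict:
        return {
            "focal_single": self.focal_single,
            "focal_pair": self.focal_pair,
            "tests_single": self.tests_single,
            "tests_pair": self.tests_pair,
            "decision": self.decision,
            "single_passes": self.single_passes,
            "pair_passes": self.pair_passes,
            "alpha": self.alpha,
            "age_profile": {str(k): v for k, v in self.age_profile.items()},
            "type_profile": self.type_profile,
            "cv_overall": self.cv_overall,
            "full_fit": self.full_fit,
        }


def aggregate_importance(cv: CVResult, ci_level: float = 0.95, meta: Optional[pd.DataFrame] = None) -> ImportanceTable:
    """Per-feature mean, sd and t-based CI over repeat-level importances."""
    vals = np.asarray(cv.repeat_importance, dtype=float)
    n_rep = vals.shape[1]
    if n_rep < 2:
        raise ValueError("need at least 2 repeats to aggregate importance")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    half = float(t_dist.ppf(0.5 + ci_level / 2.0, n_rep - 1)) * sd / np.sqrt(n_rep)
    if meta is None:
        meta = _meta_from_names(cv.feature_names)
    summary = pd.DataFrame({
        "name": cv.feature_names,
        "mean": mean,
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
    })
    return ImportanceTable(values=vals, feature_meta=meta.reset_index(drop=True), summary=summary)


def _meta_from_names(names: list) -> pd.DataFrame:
    rows = []
    for nm in names:
        if nm in GLOBAL_NAMES:
            rows.append({"name": nm, "kind": "global", "type_label": None, "age": None})
        else:
            t, a = nm.rsplit("_", 1)
            rows.append({"name": nm, "kind": "cell", "type_label": t, "age": int(a)})
    return pd.DataFrame(rows)


def paired_one_sided_t(focal: np.ndarray, other: np.ndarray) -> tuple:
    """One-sided paired t-test of focal > other over repeat-level values.

    Returns (t, df, p).  A zero-variance difference degenerates to
    certainty: p = 0 when the constant difference is positive, else p = 1.
    """
    d = np.asarray(focal, dtype=float) - np.asarray(other, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired repeats")
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() > 0:
            return float("inf"), df, 0.0
        return (0.0 if d.mean() == 0 else -float("inf")), df, 1.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    return t, df, float(t_dist.sf(t, df))


def _cell_order_key(meta_row, type_order: list) -> tuple:
    # deterministic tie-break: lowest canonical type index, then youngest age
    t = meta_row["type_label"]
    ti = type_order.index(t) if t in type_order else len(type_order)
    return (ti, meta_row["age"])


def test_focal_vs_globals(
    table: ImportanceTable,
    alpha: float = 0.05,
    pair_mode: str = "mean",
) -> dict:
    """Select focal predictors and test them against the three globals.

    focal_single: the cell with the highest mean importance.  focal_pair:
    the same-type adjacent-age pair with the highest combined repeat-level
    importance (``pair_mode`` "mean" averages the two members per repeat;
    "max" takes the per-repeat maximum).  Each focal is compared to each
    global by a one-sided paired t-test.
    """
    if pair_mode not in ("mean", "max"):
        raise ValueError("pair_mode must be 'mean' or 'max'")
    meta = table.feature_meta
    cells = meta[meta["kind"] == "cell"]
    if len(cells) == 0:
        raise ValueError("no cell features retained")
    glob_rows = {nm: table.repeat_values(nm) for nm in GLOBAL_NAMES if (meta["name"] == nm).any()}
    if not glob_rows:
        raise ValueError("no global features present in the importance table")
    type_order = list(dict.fromkeys(cells["type_label"]))

    means = table.summary.set_index("name")["mean"]

    # focal single: max mean, deterministic tie-break
    best = None
    for _, row in cells.iterrows():
        key = (-means[row["name"]], *_cell_order_key(row, type_order))
        if best is None or key < best[0]:
            best = (key, row)
    single_row = best[1]
    single_vals = table.repeat_values(single_row["name"])
    focal_single = {
        "name": single_row["name"],
        "type_label": single_row["type_label"],
        "age": int(single_row["age"]),
        "mean_importance": float(means[single_row["name"]]),
    }

    # focal pair: same type, adjacent ages, both retained
    pair_best = None
    by_type = {}
    for _, row in cells.iterrows():
        by_type.setdefault(row["type_label"], {})[int(row["age"])] = row["name"]
    for t in type_order:
        ages = sorted(by_type[t])
        for a in ages:
            if a + 1 in by_type[t]:
                v1 = table.repeat_values(by_type[t][a])
                v2 = table.repeat_values(by_type[t][a + 1])
                pv = 0.5 * (v1 + v2) if pair_mode == "mean" else np.maximum(v1, v2)
                key = (-pv.mean(), type_order.index(t), a)
                if pair_best is None or key < pair_best[0]:
                    pair_best = (key, t, a, pv)
    focal_pair = None
    pair_vals = None
    if pair_best is not None:
        _, t, a, pair_vals = pair_best
        focal_pair = {
            "type_label": t,
            "ages": [int(a), int(a + 1)],
            "mode": pair_mode,
            "mean_importance": float(pair_vals.mean()),
        }

    def run_tests(vals):
        out = []
        for nm in GLOBAL_NAMES:
            if nm not in glob_rows:
                continue
            t_stat, df, p = paired_one_sided_t(vals, glob_rows[nm])
            out.append({"global": nm, "t": t_stat, "df": df, "p": p, "significant": bool(p < alpha)})
        return out

    tests_single = run_tests(single_vals)
    tests_pair = run_tests(pair_vals) if pair_vals is not None else []
    single_passes = len(tests_single) == 3 and all(r["significant"] for r in tests_single)
    pair_passes = len(tests_pair) == 3 and all(r["significant"] for r in tests_pair)
    decision = "sensitive period declared" if (single_passes or pair_passes) else "null retained"
    return {
        "focal_single": focal_single,
        "focal_pair": focal_pair,
        "tests_single": tests_single,
        "tests_pair": tests_pair,
        "single_passes": single_passes,
        "pair_passes": pair_passes,
        "decision": decision,
        "alpha": alpha,
    }


def collapse_profiles(table: ImportanceTable) -> tuple:
    """Collapse mean importances to per-age and per-type maxima.

    age_profile[a] = max over types of the mean importance of exposure at
    age a (cells absent after filtering are skipped); type_profile[t] = max
    over ages, with the three globals appended for display.
    """
    meta = table.feature_meta
    means = table.summary["mean"].to_numpy()
    age_profile: dict = {}
    type_profile: dict = {}
    for i, row in meta.iterrows():
        if row["kind"] == "cell":
            a = int(row["age"])
            t = row["type_label"]
            age_profile[a] = max(age_profile.get(a, -np.inf), means[i])
            type_profile[t] = max(type_profile.get(t, -np.inf), means[i])
        else:
            type_profile[row["name"]] = float(means[i])
    age_profile = {a: float(v) for a, v in sorted(age_profile.items())}
    type_profile = {t: float(v) for t, v in type_profile.items()}
    return age_profile, type_profile


def detect(
    table: PredictorTable,
    cv_config: Optional[CVConfig] = None,
    seed: int = 0,
    alpha: float = 0.05,
    pair_mode: str = "mean",
) -> tuple:
    """Full inference: LGOCV -> importance aggregation -> focal tests ->
    collapsed profiles.  Returns (SensitivePeriodReport, CVResult)."""
    cv = lgocv(table, cv_config, seed=seed)
    imp = aggregate_importance(cv, meta=table.feature_meta)
    core = test_focal_vs_globals(imp, alpha=alpha, pair_mode=pair_mode)
    age_profile, type_profile = collapse_profiles(imp)
    report = SensitivePeriodReport(
        focal_single=core["focal_single"],
        focal_pair=core["focal_pair"],
        tests_single=core["tests_single"],
        tests_pair=core["tests_pair"],
        decision=core["decision"],
        single_passes=core["single_passes"],
        pair_passes=core["pair_passes"],
        alpha=alpha,
        age_profile=age_profile,
        type_profile=type_profile,
        cv_overall=cv.overall,
    )
    return report, cv
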