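"""Exposure data model: subject x type x age severity tensors.

The analytical substrate is a retrospective exposure history: for each
subject, a non-negative severity score for each maltreatment type during
each year of childhood.  From it we derive the three global exposure
measures (multiplicity, summed severity, duration), apply the prevalence
filter that keeps only (type, age) cells experienced by a minimum fraction
of the analyzed sample, and assemble the predictor table fed to the forest.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_TYPES",
    "ExposureMatrix",
    "GlobalExposure",
    "PredictorTable",
    "load_exposure_table",
    "write_exposure_table",
    "compute_globals",
    "group_multiplicity",
    "prevalence_filter",
    "build_feature_table",
]

#: Canonical 10-type maltreatment label set (user-extensible).
CANONICAL_TYPES = [
    "SexA",    # sexual abuse
    "PVA",     # parental verbal abuse
    "NVEA",    # non-verbal emotional abuse
    "PPhys",   # parental physical abuse
    "WIPV",    # witnessing interparental violence
    "Wsib",    # witnessing violence to siblings
    "EN",      # emotional neglect
    "PN",      # physical neglect
    "Peer_E",  # peer emotional abuse
    "Peer_P",  # peer physical abuse
]


class SchemaError(ValueError):
    """Raised when an input table's columns do not match the expected layout."""


@dataclass
class ExposureMatrix:
    """Subject x type x age severity tensor with per-subject metadata.

    ``observed`` marks (type, age) cells that are structurally present in
    the source data; cells absent from an input file are distinguished from
    observed zeros and never enter modeling.
    """

    subject_ids: list
    type_labels: list
    ages: list
    severity: np.ndarray  # (n_subjects, n_types, n_ages), >= 0
    stratum: np.ndarray   # (n_subjects,) categorical labels
    covariates: Optional[pd.DataFrame] = None
    observed: Optional[np.ndarray] = None  # (n_types, n_ages) bool

    def __post_init__(self) -> None:
        self.severity = np.asarray(self.severity, dtype=float)
        n, t, a = len(self.subject_ids), len(self.type_labels), len(self.ages)
        if self.severity.shape != (n, t, a):
            raise ValueError(
                f"severity shape {self.severity.shape} inconsistent with labels ({n},{t},{a})"
            )
        if np.any(self.severity < 0):
            raise ValueError("severity values must be non-negative")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        self.stratum = np.asarray(self.stratum)
        if self.stratum.shape != (n,):
            raise ValueError("every subject needs a stratum label")
        if self.observed is None:
            self.observed = np.ones((t, a), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (t, a):
                raise ValueError("observed mask shape mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    def subset(self, rows: np.ndarray) -> "ExposureMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ExposureMatrix(
            subject_ids=[self.subject_ids[i] for i in rows],
            type_labels=list(self.type_labels),
            ages=list(self.ages),
            severity=self.severity[rows],
            stratum=self.stratum[rows],
            covariates=None if self.covariates is None else self.covariates.iloc[rows].reset_index(drop=True),
            observed=self.observed.copy(),
        )


@dataclass
class GlobalExposure:
    """The three global exposure measures, one value per subject.

    multiplicity: number of distinct types with any supra-threshold exposure;
    severity_sum: total severity over all cells; duration: number of ages
    (years) with any supra-threshold exposure of any type.
    """

    multiplicity: np.ndarray
    severity_sum: np.ndarray
    duration: np.ndarray

    NAMES = ("duration", "multiplicity", "severity")

    def as_columns(self) -> np.ndarray:
        """Columns in canonical order: duration, multiplicity, severity."""
        return np.column_stack([
            self.duration.astype(float),
            self.multiplicity.astype(float),
            self.severity_sum.astype(float),
        ])


@dataclass
class PredictorTable:
    """Feature matrix plus metadata, ready for forest fitting.

    feature_meta rows carry: name, kind ("cell" | "global"), type_label,
    age (cells only), global_name (globals only).
    """

    feature_matrix: np.ndarray
    feature_meta: pd.DataFrame
    outcome: np.ndarray
    outcome_kind: str  # "binary" | "continuous"
    stratum: np.ndarray
    subject_ids: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.feature_matrix.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.feature_meta["name"])

    def cell_indices(self) -> np.ndarray:
        return np.flatnonzero((self.feature_meta["kind"] == "cell").to_numpy())

    def global_indices(self) -> np.ndarray:
        return np.flatnonzero((self.feature_meta["kind"] == "global").to_numpy())

    def write(self, feature_path: str, meta_path: Optional[str] = None) -> None:
        """TSV feature table with a sidecar JSON of feature metadata."""
        df = pd.DataFrame(self.feature_matrix, columns=self.feature_names)
        df.insert(0, "subject", self.subject_ids or np.arange(len(self.outcome)))
        df["outcome"] = self.outcome
        df["stratum"] = self.stratum
        df.to_csv(feature_path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "outcome_kind": self.outcome_kind,
                "features": self.feature_meta.to_dict(orient="records"),
            }
            with open(meta_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# I/O

_CELL_RE = re.compile(r"^(?P<type>.+)_(?P<age>\d+)$")
_RESERVED = {"subject", "id", "stratum", "outcome"}


def load_exposure_table(
    path: str,
    schema: str = "auto",
    type_labels: Optional[Sequence[str]] = None,
    ages: Optional[Sequence[int]] = None,
) -> ExposureMatrix:
    """Read an exposure CSV in wide (TYPE_AGE columns) or long format.

    Wide: one row per subject, cell columns named ``TYPE_AGE`` (e.g.
    ``NVEA_14``), plus ``subject``/``id`` and optional ``stratum`` and
    covariate columns.  Cell columns missing from the file are treated as
    structurally absent, not as zero.  Long: columns
    (subject, type, age, severity) with optional ``stratum``.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if schema == "auto":
        schema = "long" if {"type", "age", "severity"} <= cols else "wide"
    if schema == "wide":
        return _load_wide(df, type_labels, ages)
    if schema == "long":
        return _load_long(df, type_labels, ages)
    raise ValueError(f"unknown schema {schema!r}")


def _load_wide(df, type_labels, ages) -> ExposureMatrix:
    id_col = "subject" if "subject" in df.columns else ("id" if "id" in df.columns else None)
    if id_col is None:
        raise SchemaError("wide table needs a 'subject' or 'id' column")
    cell_cols = {}
    other_cols = []
    for c in df.columns:
        if c == id_col or c in _RESERVED:
            continue
        m = _CELL_RE.match(c)
        if m and (type_labels is None or m.group("type") in type_labels):
            cell_cols[c] = (m.group("type"), int(m.group("age")))
        else:
            other_cols.append(c)
    if not cell_cols:
        raise SchemaError("no TYPE_AGE severity columns found")
    if type_labels is None:
        seen = {t for t, _ in cell_cols.values()}
        type_labels = [t for t in CANONICAL_TYPES if t in seen]
        type_labels += sorted(seen - set(type_labels))
    if ages is None:
        seen_a = {a for _, a in cell_cols.values()}
        ages = list(range(min(seen_a), max(seen_a) + 1))
    type_labels = list(type_labels)
    ages = [int(a) for a in ages]
    t_idx = {t: i for i, t in enumerate(type_labels)}
    a_idx = {a: i for i, a in enumerate(ages)}

    n = len(df)
    sev = np.zeros((n, len(type_labels), len(ages)))
    observed = np.zeros((len(type_labels), len(ages)), dtype=bool)
    for c, (t, a) in cell_cols.items():
        if t not in t_idx or a not in a_idx:
            raise SchemaError(f"column {c!r} outside the declared type/age grid")
        vals = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise SchemaError(f"non-numeric severity in column {c!r}")
        if (vals < 0).any():
            raise ValueError(f"negative severity in column {c!r}")
        sev[:, t_idx[t], a_idx[a]] = vals
        observed[t_idx[t], a_idx[a]] = True

    stratum = df["stratum"].astype(str).to_numpy() if "stratum" in df.columns else np.full(n, "all")
    cov_cols = [c for c in other_cols if c != "outcome"]
    if "outcome" in df.columns:
        cov_cols = ["outcome"] + cov_cols
    covariates = df[cov_cols].reset_index(drop=True) if cov_cols else None
    return ExposureMatrix(
        subject_ids=df[id_col].tolist(),
        type_labels=type_labels,
        ages=ages,
        severity=sev,
        stratum=stratum,
        covariates=covariates,
        observed=observed,
    )


def _load_long(df, type_labels, ages) -> ExposureMatrix:
    need = {"subject", "type", "age", "severity"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"long table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject", "type", "age"])
    if dup.any():
        bad = df.loc[dup, ["subject", "type", "age"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, type, age) rows, e.g. {tuple(bad)}"
        )
    if (df["severity"] < 0).any():
        raise ValueError("negative severity values")
    subjects = list(dict.fromkeys(df["subject"]))
    if type_labels is None:
        seen = set(df["type"])
        type_labels = [t for t in CANONICAL_TYPES if t in seen]
        type_labels += sorted(seen - set(type_labels))
    if ages is None:
        ages = list(range(int(df["age"].min()), int(df["age"].max()) + 1))
    type_labels, ages = list(type_labels), [int(a) for a in ages]
    s_idx = {s: i for i, s in enumerate(subjects)}
    t_idx = {t: i for i, t in enumerate(type_labels)}
    a_idx = {a: i for i, a in enumerate(ages)}
    sev = np.zeros((len(subjects), len(type_labels), len(ages)))
    observed = np.zeros((len(type_labels), len(ages)), dtype=bool)
    for _, row in df.iterrows():
        sev[s_idx[row["subject"]], t_idx[row["type"]], a_idx[int(row["age"])]] = row["severity"]
        observed[t_idx[row["type"]], a_idx[int(row["age"])]] = True
    if "stratum" in df.columns:
        per = df.drop_duplicates("subject").set_index("subject")["stratum"]
        stratum = np.array([str(per[s]) for s in subjects])
    else:
        stratum = np.full(len(subjects), "all")
    return ExposureMatrix(
        subject_ids=subjects,
        type_labels=type_labels,
        ages=ages,
        severity=sev,
        stratum=stratum,
        observed=observed,
    )


def write_exposure_table(
    x: ExposureMatrix,
    path: str,
    outcome: Optional[np.ndarray] = None,
) -> None:
    """Write a wide CSV (TYPE_AGE columns); inverse of the wide loader."""
    data = {"subject": x.subject_ids, "stratum": x.stratum}
    if outcome is not None:
        data["outcome"] = np.asarray(outcome)
    for ti, t in enumerate(x.type_labels):
        for ai, a in enumerate(x.ages):
            if x.observed[ti, ai]:
                data[f"{t}_{a}"] = x.severity[:, ti, ai]
    if x.covariates is not None:
        for c in x.covariates.columns:
            if c not in data:
                data[c] = x.covariates[c].to_numpy()
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived quantities


def compute_globals(x: ExposureMatrix, presence_threshold: float = 0.0) -> GlobalExposure:
    """Multiplicity, summed severity and duration per subject.

    A (type, year) is counted as experienced when severity exceeds
    ``presence_threshold`` (default 0: any endorsed item counts).
    """
    if presence_threshold < 0:
        raise ValueError("presence_threshold must be >= 0")
    exposed = x.severity > presence_threshold
    return GlobalExposure(
        multiplicity=exposed.any(axis=2).sum(axis=1),
        severity_sum=x.severity.sum(axis=(1, 2)),
        duration=exposed.any(axis=1).sum(axis=1),
    )


def group_multiplicity(g: GlobalExposure, cap: int = 4) -> np.ndarray:
    """Ordinal multiplicity groups 0..cap ('cap plus' absorbs the tail)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    return np.minimum(g.multiplicity, cap).astype(int)


def prevalence_filter(
    x: ExposureMatrix,
    min_prevalence: float = 0.05,
    stratum: Optional[str] = None,
) -> np.ndarray:
    """Boolean (type, age) mask of cells exposed in >= min_prevalence of
    the sample (within one stratum when given).  Inclusive at the boundary;
    structurally absent cells are never retained."""
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    if stratum is not None:
        rows = x.stratum == stratum
        if not rows.any():
            raise ValueError(f"empty stratum {stratum!r}")
        sev = x.severity[rows]
    else:
        sev = x.severity
    prev = (sev > 0).mean(axis=0)
    return (prev >= min_prevalence) & x.observed


def build_feature_table(
    x: ExposureMatrix,
    mask: np.ndarray,
    outcome: np.ndarray,
    outcome_kind: str,
    include_globals: bool = True,
    presence_threshold: float = 0.0,
) -> PredictorTable:
    """Assemble the predictor table: retained cells then the three globals.

    Feature order is deterministic: types in their canonical order, ages
    ascending within type, then duration, multiplicity, severity.  Global
    measures are computed from the full matrix; the prevalence filter
    applies to cell features only.
    """
    outcome = np.asarray(outcome, dtype=float)
    if outcome.size != x.n_subjects:
        raise ValueError("outcome length does not match subject count")
    if outcome_kind == "binary":
        if not np.isin(np.unique(outcome), [0.0, 1.0]).all():
            raise ValueError("binary outcome must contain only 0 and 1")
    elif outcome_kind != "continuous":
        raise ValueError("outcome_kind must be 'binary' or 'continuous'")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (x.n_types, x.n_ages):
        raise ValueError("mask shape does not match the (type, age) grid")

    cols = []
    meta = []
    for ti, t in enumerate(x.type_labels):
        for ai, a in enumerate(x.ages):
            if mask[ti, ai]:
                cols.append(x.severity[:, ti, ai])
                meta.append({
                    "name": f"{t}_{a}", "kind": "cell",
                    "type_label": t, "age": a, "global_name": None,
                })
    if include_globals:
        g = compute_globals(x, presence_threshold)
        for name, col in zip(GlobalExposure.NAMES, g.as_columns().T):
            cols.append(col)
            meta.append({
                "name": name, "kind": "global",
                "type_label": None, "age": None, "global_name": name,
            })
    if not cols:
        raise ValueError("no features retained")
    return PredictorTable(
        feature_matrix=np.column_stack(cols),
        feature_meta=pd.DataFrame(meta),
        outcome=outcome,
        outcome_kind=outcome_kind,
        stratum=x.stratum.copy(),
        subject_ids=list(x.subject_ids),
    )
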