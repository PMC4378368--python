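"""End-to-end pipeline: load -> filter -> feature table -> detect -> report.

A single :class:`RunConfig` carries every stage's parameters plus one
master seed; per-stage seeds are derived by hashing the stage name, so the
same configuration and seed reproduce every output byte-for-byte
(timestamps live only in the log).  Every structured output embeds the
SHA-256 hash of the canonical configuration JSON, so files from different
runs cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .cv import CVConfig, full_data_fit_summary
from .exposure import (
    PredictorTable,
    build_feature_table,
    compute_globals,
    load_exposure_table,
    prevalence_filter,
)
from .forest import ForestConfig, fit_forest, predict
from .mediation import mediate
from .sensitive import detect

__all__ = ["RunConfig", "run_pipeline", "render_report"]

log = logging.getLogger("sensiperiod")


@dataclass
class RunConfig:
    input_path: str = ""
    output_dir: str = "sensiperiod_out"
    outcome_column: str = "outcome"
    outcome_kind: str = "binary"
    stratum: Optional[str] = None
    min_prevalence: float = 0.05
    include_globals: bool = True
    presence_threshold: float = 0.0
    alpha: float = 0.05
    pair_mode: str = "mean"
    n_runs: int = 10
    n_repeats: int = 10
    train_fraction: float = 0.75
    n_trees: int = 500
    mtry: Optional[int] = None
    alpha_split: float = 0.05
    min_node: int = 7
    subsample_fraction: float = 0.632
    n_permutations: int = 5
    run_mediation: bool = False
    mediation_n_boot: int = 5000
    seed: int = 0

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_trees=self.n_trees,
            mtry=self.mtry,
            alpha_split=self.alpha_split,
            min_node=self.min_node,
            subsample_fraction=self.subsample_fraction,
            n_permutations=self.n_permutations,
        )

    def cv_config(self) -> CVConfig:
        return CVConfig(
            n_runs=self.n_runs,
            n_repeats=self.n_repeats,
            train_fraction=self.train_fraction,
            forest=self.forest_config(),
        )

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if path.endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def quick(self) -> "RunConfig":
        """Reduced settings for smoke runs."""
        import dataclasses

        return dataclasses.replace(self, n_trees=25, n_runs=2, n_repeats=3, n_permutations=2)


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, table: Optional[PredictorTable] = None) -> dict:
    """Execute the full analysis and write the report bundle.

    ``table`` may be passed directly (e.g. from the simulator) to skip file
    loading.  Returns the report bundle as a dict; files are written under
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("run config hash %s, master seed %d", chash, config.seed)

    if table is None:
        log.info("stage load: %s", config.input_path)
        x = load_exposure_table(config.input_path)
        if config.stratum is not None:
            rows = x.stratum == config.stratum
            if not rows.any():
                raise ValueError(f"stratum filter {config.stratum!r} matches no subjects")
            x = x.subset(rows)
        log.info("stage load: %d subjects", x.n_subjects)
        if x.covariates is None or config.outcome_column not in x.covariates.columns:
            raise ValueError(f"outcome column {config.outcome_column!r} not found")
        outcome = x.covariates[config.outcome_column].to_numpy(dtype=float)
        mask = prevalence_filter(x, config.min_prevalence)
        table = build_feature_table(
            x, mask, outcome, config.outcome_kind,
            include_globals=config.include_globals,
            presence_threshold=config.presence_threshold,
        )
    log.info("stage features: %d features x %d subjects", table.n_features, len(table.outcome))

    detect_seed = int(stage_rng(config.seed, "detect").integers(0, 2**31 - 1))
    report, cv = detect(
        table, config.cv_config(), seed=detect_seed,
        alpha=config.alpha, pair_mode=config.pair_mode,
    )

    # full-data fit (classification only): refit on all rows
    if table.outcome_kind == "binary":
        fit_seed = int(stage_rng(config.seed, "full_fit").integers(0, 2**31 - 1))
        model = fit_forest(
            table.feature_matrix, table.outcome, config.forest_config(),
            seed=fit_seed, task="classification",
        )
        report.full_fit = full_data_fit_summary(table.outcome, predict(model, table.feature_matrix))

    bundle = {
        "config": json.loads(config.canonical_json()),
        "config_hash": chash,
        "n_subjects": int(len(table.outcome)),
        "n_features": int(table.n_features),
        "report": report.to_dict(),
    }

    if config.run_mediation and report.focal_single is not None:
        med_seed = int(stage_rng(config.seed, "mediation").integers(0, 2**31 - 1))
        g = _globals_from_table(table)
        focal_col = table.feature_names.index(report.focal_single["name"])
        med = mediate(
            x=g, m=table.feature_matrix[:, focal_col], y=table.outcome,
            n_boot=config.mediation_n_boot, seed=med_seed,
        )
        bundle["mediation"] = {"mediator": report.focal_single["name"], **med.to_dict()}

    _write_json(outdir / "report.json", bundle)
    _write_tsvs(outdir, cv, report, chash)
    log.info("decision: %s", report.decision)
    return bundle


def _globals_from_table(table: PredictorTable) -> np.ndarray:
    """Multiplicity column if present, else recomputed from cell features."""
    if "multiplicity" in table.feature_names:
        return table.feature_matrix[:, table.feature_names.index("multiplicity")]
    cells = table.cell_indices()
    meta = table.feature_meta.iloc[cells]
    mult = np.zeros(table.feature_matrix.shape[0])
    for t in meta["type_label"].unique():
        cols = cells[(meta["type_label"] == t).to_numpy()]
        mult += (table.feature_matrix[:, cols] > 0).any(axis=1)
    return mult


def _write_tsvs(outdir: Path, cv, report, chash: str) -> None:
    header = f"# config_hash={chash}\n"
    rm = cv.repeat_metrics.copy()
    rm.insert(0, "repeat", np.arange(1, len(rm) + 1))
    with open(outdir / "repeat_metrics.tsv", "w", encoding="utf-8") as fh:
        fh.write(header)
        rm.to_csv(fh, sep="\t", index=False)
    imp = pd.DataFrame(
        cv.repeat_importance,
        index=cv.feature_names,
        columns=[f"repeat_{i+1}" for i in range(cv.repeat_importance.shape[1])],
    )
    with open(outdir / "repeat_importance.tsv", "w", encoding="utf-8") as fh:
        fh.write(header)
        imp.to_csv(fh, sep="\t", index_label="feature")
    with open(outdir / "age_profile.tsv", "w", encoding="utf-8") as fh:
        fh.write(header + "age\tmax_importance\n")
        for a, v in report.age_profile.items():
            fh.write(f"{a}\t{v!r}\n")
    with open(outdir / "type_profile.tsv", "w", encoding="utf-8") as fh:
        fh.write(header + "type\tmax_importance\n")
        for t, v in report.type_profile.items():
            fh.write(f"{t}\t{v!r}\n")


def render_report(bundle: dict) -> str:
    """Plain-text summary of a report bundle."""
    lines = []
    warn = []
    rep = bundle.get("report", {})
    lines.append("sensitive-period analysis report")
    lines.append(f"config hash: {bundle.get('config_hash', '?')}")
    lines.append(
        f"subjects: {bundle.get('n_subjects', '?')}   features: {bundle.get('n_features', '?')}"
    )
    cvo = rep.get("cv_overall") or {}
    if cvo:
        lines.append("cross-validated fit (mean +/- sd over repeats):")
        for m, v in cvo.items():
            lines.append(f"  {m:12s} {v['mean']:.3f} +/- {v['sd']:.3f}")
    ff = rep.get("full_fit") or {}
    if ff:
        lines.append(
            "full-data fit: sensitivity {sensitivity:.3f}  specificity {specificity:.3f}  "
            "kappa {kappa:.3f}  OR {odds_ratio:.1f} ({or_ci_low:.1f}-{or_ci_high:.1f})".format(**ff)
        )
    fs = rep.get("focal_single")
    if fs:
        lines.append(
            f"focal single cell: {fs['name']} (mean importance {fs['mean_importance']:.5g})"
        )
        for t in rep.get("tests_single", []):
            lines.append(
                f"  vs {t['global']:12s} t({t['df']}) = {t['t']:.2f}, p = {t['p']:.3g}"
                + ("  *" if t["significant"] else "")
            )
    fp = rep.get("focal_pair")
    if fp:
        lines.append(
            f"focal adjacent pair: {fp['type_label']} ages {fp['ages'][0]}-{fp['ages'][1]} "
            f"(mean importance {fp['mean_importance']:.5g})"
        )
        for t in rep.get("tests_pair", []):
            lines.append(
                f"  vs {t['global']:12s} t({t['df']}) = {t['t']:.2f}, p = {t['p']:.3g}"
                + ("  *" if t["significant"] else "")
            )
    if "decision" in rep:
        lines.append(f"decision: {rep['decision']} (alpha = {rep.get('alpha')})")
    ap = rep.get("age_profile") or {}
    if ap:
        lines.append("age profile (max importance over types):")
        for a in sorted(ap, key=lambda k: int(k)):
            lines.append(f"  age {int(a):>2d}: {ap[a]:.5g}")
    else:
        warn.append("no retained cell features")
    tp = rep.get("type_profile") or {}
    if tp:
        lines.append("type profile (max importance over ages; globals appended):")
        for t, v in tp.items():
            lines.append(f"  {t:12s} {v:.5g}")
    med = bundle.get("mediation")
    if med:
        lines.append(
            "mediation via {mediator}: a={a:.3f} b={b:.3f} c={c:.3f} c'={c_prime:.3f} "
            "ab={ab:.3f} (CI {lo:.3f}..{hi:.3f}), |ab|/|c'|={ratio:.3f}".format(
                mediator=med["mediator"], a=med["a"], b=med["b"], c=med["c"],
                c_prime=med["c_prime"], ab=med["ab"],
                lo=med["ab_ci"][0], hi=med["ab_ci"][1], ratio=med["ratio"],
            )
        )
    for w in warn:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"
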