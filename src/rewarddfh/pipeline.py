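"""End-to-end orchestration: simulate -> select -> train -> score -> stats.

``analyze_cohort`` is the in-memory workhorse: given a feature table and
phenotypes it fits the standardizer and lasso selection on the TD training
subjects, trains the oriented SVM hyperplane, builds the norm reference
from the training reward distances, scores every row, and runs the
downstream statistics. ``run_all`` wraps it with file I/O, a run manifest
(config hash, seed, per-file digests) and a Markdown report.

A single global seed fans out to per-stage seeds through a fixed
``SeedSequence`` spawn order (simulation, selection, cross-validation), so
each stage is independently reproducible and two runs with the same config
and seed produce identical output bytes (timestamps live only in the
manifest's ``timestamps`` block).
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import features as feat
from . import io as dio
from . import norming, stats
from .errors import DegenerateDataError, ValidationError
from .synthetic import REWARD, SimulationConfig, simulate_cohort

__all__ = ["AnalysisBundle", "RunManifest", "analyze_cohort", "run_all",
           "stage_seeds", "DEFAULT_CORRELATION_VARIABLES"]

__version__ = "0.1.0"

DEFAULT_CORRELATION_VARIABLES = (
    "age", "IQ", "SDQ-CP", "RPAQ-Reactive", "RPAQ-Proactive", "Conners-ADHD",
    "SDQ-Hyperactivity", "SDQ-Emotional", "CDI", "SCARED-Total", "SCARED-GAD",
    "CTQ-Abuse", "CTQ-Neglect", "AUDIT", "CUDIT", "ICU", "ARI",
)
DEFAULT_SEVERITY_SCALES = (
    "SDQ-CP", "RPAQ-Reactive", "RPAQ-Proactive", "Conners-ADHD",
    "SDQ-Hyperactivity", "SDQ-Emotional", "CDI", "SCARED-Total", "SCARED-GAD",
    "CTQ-Abuse", "CTQ-Neglect", "AUDIT", "CUDIT", "ICU", "ARI",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from one global seed.

    Fixed spawn order: simulate, select, cv. Seeds stay below 2**31.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    names = ("simulate", "select", "cv")
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class AnalysisBundle:
    """Everything one analysis run produces, in memory."""

    standardizer: feat.Standardizer
    selection: feat.FeatureSelection
    hyperplane: clf.Hyperplane
    norm_reference: norming.NormReference
    dfh: pd.DataFrame
    cv: clf.CVResult | None
    tests: dict = field(default_factory=dict)

    def to_results(self) -> dict[str, dict]:
        out = {
            "standardizer": self.standardizer.to_dict(),
            "selection": self.selection.to_dict(),
            "hyperplane": self.hyperplane.to_dict(),
            "norm_reference": self.norm_reference.to_dict(),
            "stats": self.tests,
        }
        if self.cv is not None:
            out["cv"] = self.cv.to_dict()
        return out


def _training_ids(phenotypes: pd.DataFrame) -> list[str]:
    ids = phenotypes.loc[phenotypes["group"] == "TD_train", "subject_id"].tolist()
    if len(ids) < 2:
        raise ValidationError("need >= 2 TD_train subjects in phenotypes")
    return ids


def run_group_stats(
    dfh: pd.DataFrame,
    phenotypes: pd.DataFrame,
    correlation_variables: Sequence[str] = DEFAULT_CORRELATION_VARIABLES,
    severity_scales: Sequence[str] = DEFAULT_SEVERITY_SCALES,
    deficient_def: str = "below_minus2",
) -> dict:
    """The downstream battery: contingency, correlations, severity tests."""
    tests: dict = {"contingency": {}, "correlations": [],
                   "severity": {}, "severity_skipped": {}}

    def add_contingency(name: str, group_names: list[str]) -> None:
        try:
            groups = stats.groups_from_phenotypes(phenotypes, group_names)
            table = stats.category_table(dfh, groups)
        except (ValidationError, DegenerateDataError) as exc:
            tests["contingency"][name] = {"skipped": str(exc)}
            return
        entry = {"table": table.to_dict()}
        for scheme in ("full5", "low3", "high3"):
            collapsed = stats.collapse_bins(table, scheme)
            try:
                entry[scheme] = stats.chi_square(collapsed, scheme=scheme).to_dict()
            except DegenerateDataError as exc:
                entry[scheme] = {"skipped": str(exc)}
        tests["contingency"][name] = entry

    add_contingency("td_test_vs_clinical", ["TD_test", "clinical"])
    add_contingency("td_train_vs_td_test", ["TD_train", "TD_test"])
    for dx in ("CD", "ADHD", "MDD", "GAD"):
        if dx in phenotypes.columns and phenotypes[dx].astype(bool).any():
            add_contingency(f"td_test_vs_{dx}", ["TD_test", dx])

    variables = [v for v in correlation_variables if v in phenotypes.columns]
    tests["correlations"] = [
        r.to_dict() for r in stats.correlate_dfh(dfh, phenotypes, variables)
    ]

    for scale in severity_scales:
        if scale not in phenotypes.columns:
            continue
        try:
            res = stats.compare_symptom_severity(
                dfh, phenotypes, scale, deficient_def=deficient_def
            )
            tests["severity"][scale] = res.to_dict()
        except DegenerateDataError as exc:
            tests["severity_skipped"][scale] = str(exc)
    return tests


def analyze_cohort(
    features_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    C: float = 1.0,
    selection_kwargs: dict | None = None,
    seed: int = 0,
    run_cv: bool = True,
    cv_folds: int = 10,
    run_stats: bool = True,
    deficient_def: str = "below_minus2",
) -> AnalysisBundle:
    """Fit the full pipeline on one cohort.

    The standardizer, selection, final hyperplane and norm reference use
    only TD_train rows; every subject is then scored with the final
    hyperplane (per-fold CV models are used only for the CV metrics).
    """
    dio.validate_feature_table(features_table)
    dio.validate_phenotype_table(phenotypes, feature_subjects=features_table["subject_id"])
    seeds = stage_seeds(seed)
    train_ids = _training_ids(phenotypes)
    selection_kwargs = dict(selection_kwargs or {})

    std = feat.fit_standardizer(features_table, train_ids)
    standardized = std.transform(features_table)
    Xtr, ytr, gtr = feat.training_matrix(standardized, train_ids)
    selection = feat.select_features(
        Xtr, ytr, gtr, seed=seeds["select"], **selection_kwargs
    )
    if selection.empty:
        raise DegenerateDataError("feature selection is empty; cannot train")
    plane = clf.fit_hyperplane(Xtr[selection.region_ids], ytr, C=C)

    train_rew = standardized[
        standardized["subject_id"].isin(train_ids)
        & (standardized["condition"] == REWARD)
    ]
    ref = norming.build_norm_reference(
        norming.signed_distance(plane, train_rew[selection.region_ids])
    )
    if ref.n < 10:
        import warnings

        warnings.warn(
            f"norm reference built from only n={ref.n} training subjects; "
            "category boundaries are unstable", stacklevel=2,
        )
    dfh = norming.score_cohort(standardized, plane, ref)

    cv = None
    if run_cv:
        cv = clf.grouped_cv_evaluate(
            features_table, train_ids, k=cv_folds, C=C, seed=seeds["cv"],
            selection_kwargs=selection_kwargs,
        )

    tests: dict = {}
    if run_stats:
        tests = run_group_stats(dfh, phenotypes, deficient_def=deficient_def)

    return AnalysisBundle(
        standardizer=std, selection=selection, hyperplane=plane,
        norm_reference=ref, dfh=dfh, cv=cv, tests=tests,
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_seeds: dict[str, int]
    digests: dict[str, str]
    timestamps: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "stage_seeds": self.stage_seeds,
            "digests": self.digests, "timestamps": self.timestamps,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _report_markdown(bundle: AnalysisBundle) -> str:
    lines = ["# Reward-DFH pipeline report", ""]
    if bundle.cv is not None:
        cv = bundle.cv
        lines += [
            "## Cross-validated classifier performance",
            "",
            "| metric | value |", "|---|---|",
            f"| accuracy | {cv.accuracy:.4f} |",
            f"| sensitivity | {cv.sensitivity:.4f} |",
            f"| specificity | {cv.specificity:.4f} |",
            f"| folds | {cv.folds} |", "",
        ]
    sel = bundle.selection
    lines += [
        "## Selected features",
        "",
        f"{sel.n_selected} regions at C = {sel.penalty:.4g} "
        f"({sum(1 for s in sel.signs.values() if s > 0)} reward-preferring, "
        f"{sum(1 for s in sel.signs.values() if s < 0)} punishment-preferring)",
        "",
        "| region | sign | coefficient |", "|---|---|---|",
    ]
    for r in sel.region_ids:
        lines.append(f"| {r} | {'+' if sel.signs[r] > 0 else '-'} | {sel.coefficients[r]:.4f} |")
    lines.append("")

    cont = bundle.tests.get("contingency", {})
    if cont:
        lines += ["## Normed category proportions by group", ""]
        for name, entry in cont.items():
            if "table" not in entry:
                continue
            tab = entry["table"]
            lines += [f"### {name}", "",
                      "| group | " + " | ".join(tab["col_labels"]) + " |",
                      "|" + "---|" * (len(tab["col_labels"]) + 1)]
            for lbl, row in zip(tab["row_labels"], tab["counts"]):
                lines.append("| " + lbl + " | " + " | ".join(str(c) for c in row) + " |")
            for scheme in ("full5", "low3", "high3"):
                res = entry.get(scheme, {})
                if "statistic" in res:
                    lines.append(
                        f"- {scheme}: chi2({res['df']}, N={res['n']}) = "
                        f"{res['statistic']:.2f}, p = {res['p']:.4g}"
                    )
                elif "skipped" in res:
                    lines.append(f"- {scheme}: skipped ({res['skipped']})")
            lines.append("")

    corr = bundle.tests.get("correlations", [])
    if corr:
        lines += ["## DFH-phenotype correlations", "",
                  "| variable | condition | r | p | n | tier |", "|---|---|---|---|---|---|"]
        for c in corr:
            lines.append(
                f"| {c['variable']} | {c['dfh_condition']} | {c['r']:.3f} | "
                f"{c['p']:.4g} | {c['n']} | {c['tier']} |"
            )
        lines.append("")

    sev = bundle.tests.get("severity", {})
    if sev:
        lines += ["## Symptom severity: typical vs deficient reward response", "",
                  "| scale | typical mean (s.d.) | deficient mean (s.d.) | t | df | p |",
                  "|---|---|---|---|---|---|"]
        for scale, r in sev.items():
            lines.append(
                f"| {scale} | {r['means'][0]:.2f} ({r['sds'][0]:.2f}) | "
                f"{r['means'][1]:.2f} ({r['sds'][1]:.2f}) | {r['t']:.3f} | "
                f"{r['df']:.1f} | {r['p']:.4g} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_all(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the whole pipeline from a configuration dictionary.

    ``config`` needs either a ``simulate`` block (SimulationConfig fields)
    or an ``inputs`` block with ``features``/``phenotypes`` paths, plus
    optional ``selection`` (penalty_grid/folds), ``classifier`` (C,
    cv_folds), ``stats`` (deficient_def) blocks and a global ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = stage_seeds(seed)
    timestamps: dict[str, float] = {"start": time.time()}

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs.setdefault("seed", seeds["simulate"])
        sim = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        features_table, phenotypes = cohort.features, cohort.phenotypes
        dio.write_feature_table(features_table, out_dir / "features.tsv")
        dio.write_phenotype_table(phenotypes, out_dir / "phenotypes.tsv")
        dio.write_json(cohort.truth, out_dir / "ground_truth.json")
    elif "inputs" in config:
        features_table = dio.read_feature_table(config["inputs"]["features"])
        phenotypes = dio.read_phenotype_table(
            config["inputs"]["phenotypes"],
            feature_subjects=features_table["subject_id"],
        )
    else:
        raise ValidationError("config needs a 'simulate' or 'inputs' block")
    timestamps["data"] = time.time()

    sel_cfg = dict(config.get("selection") or {})
    clf_cfg = dict(config.get("classifier") or {})
    stats_cfg = dict(config.get("stats") or {})
    bundle = analyze_cohort(
        features_table, phenotypes,
        C=float(clf_cfg.get("C", 1.0)),
        selection_kwargs=sel_cfg,
        seed=seed,
        run_cv=bool(clf_cfg.get("run_cv", True)),
        cv_folds=int(clf_cfg.get("cv_folds", 10)),
        run_stats=False,
    )
    timestamps["analysis"] = time.time()

    dfh_path = out_dir / "dfh.tsv"
    # full round-trip precision, and the stats stage below consumes the
    # *written* intermediates: re-running `stats` alone from stored files
    # reproduces stats.json byte-for-byte
    bundle.dfh.to_csv(dfh_path, sep="\t", index=False, float_format="%.17g")
    if "simulate" in config:
        pheno_for_stats = dio.read_phenotype_table(out_dir / "phenotypes.tsv")
    else:
        pheno_for_stats = phenotypes
    dfh_back = pd.read_csv(dfh_path, sep="\t", keep_default_na=False,
                           na_values=[""])
    bundle.tests = run_group_stats(
        dfh_back, pheno_for_stats,
        deficient_def=stats_cfg.get("deficient_def", "below_minus2"),
    )
    timestamps["stats"] = time.time()

    results = bundle.to_results()
    paths = dio.write_results(
        {k: v for k, v in results.items()}, out_dir
    )
    paths["dfh"] = dfh_path
    report_path = out_dir / "report.md"
    report_path.write_text(_report_markdown(bundle))
    paths["report"] = report_path
    for extra in ("features", "phenotypes", "ground_truth"):
        p = out_dir / f"{extra}.tsv"
        pj = out_dir / f"{extra}.json"
        if p.exists():
            paths[extra] = p
        elif pj.exists():
            paths[extra] = pj
    timestamps["end"] = time.time()

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=seed,
        version=__version__,
        stage_seeds=seeds,
        digests={name: _sha256(Path(p)) for name, p in sorted(paths.items())},
        timestamps=timestamps,
    )
    dio.write_json(manifest.to_dict(), out_dir / "manifest.json")
    return manifest
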