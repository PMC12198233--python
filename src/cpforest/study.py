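"""End-to-end study orchestration and artifact reporting.

``run_study`` reproduces the full two-scenario analysis on a synthetic or
user-supplied cohort: preprocessing (complete cases, grouping), the
cross-validated benchmark per case, the final explainability forest refit
on the full balanced analysis sample, decision-path mining, and root
ranking.  Every artifact is a plain CSV/JSON/YAML file and every random
stage takes an explicit seed, so re-running the same manifest reproduces
every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    CaseConfig,
    EvalReport,
    STUDY_OPTIMUM,
    crossval_benchmark,
    make_forest,
    run_leaderboard,
)
from .cohort import (
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    read_cohort_csv,
    spec_to_yaml,
    write_cohort_csv,
)
from .forest import (
    HighLeafRule,
    attach_precisions,
    depth_frequency,
    enumerate_high_paths,
    extract_forest,
    merge_paths,
    path_table,
)
from .preprocess import balance_training_set, filter_complete_cases, assign_outcome_groups
from .roots import (
    QualificationRule,
    extract_roots,
    rank_best_roots,
    root_table,
    select_root_length,
)

__all__ = ["RunConfig", "StudyResult", "CaseResult", "run_study", "demo_config"]

OUTCOME = "CP.2"


@dataclass
class RunConfig:
    """Replayable recipe for one study run."""

    cohort_path: str | None = None  # CSV input; None -> synthetic
    cohort_spec: CohortSpec | None = None
    cases: tuple[str, ...] = ("A", "B")
    k_folds: int = 10
    seed_cohort: int = 0
    seed_cv: int = 1
    seed_model: int = 2
    seed_balance: int = 3
    hyperparams: dict | None = None  # None -> per-case study optimum
    min_count: int = 10
    min_roots: int = 5
    top_k: int = 5
    run_comparators: bool = False

    def __post_init__(self):
        bad = [c for c in self.cases if c not in ("A", "B")]
        if bad:
            raise ValueError(f"unknown case id(s) {bad}")
        if self.cohort_path is None and self.cohort_spec is None:
            self.cohort_spec = default_cohort_spec(seed=self.seed_cohort)

    def to_manifest(self) -> dict:
        return {
            "version": __version__,
            "cohort_path": self.cohort_path,
            "cohort_spec": None
            if self.cohort_spec is None
            else yaml.safe_load(spec_to_yaml(self.cohort_spec)),
            "cases": list(self.cases),
            "k_folds": self.k_folds,
            "seeds": {
                "cohort": self.seed_cohort,
                "cv": self.seed_cv,
                "model": self.seed_model,
                "balance": self.seed_balance,
            },
            "hyperparams": self.hyperparams,
            "min_count": self.min_count,
            "min_roots": self.min_roots,
            "top_k": self.top_k,
            "run_comparators": self.run_comparators,
        }


def demo_config(n: int = 500, n_estimators: int = 60, k_folds: int = 5) -> RunConfig:
    """Scaled-down configuration exercising both cases end to end quickly."""
    params = {
        "n_estimators": n_estimators,
        "max_features": None,
        "max_depth": 6,
        "min_samples_split": 0.001,
        "min_samples_leaf": 0.001,
        "criterion": "squared_error",
    }
    return RunConfig(
        cohort_spec=default_cohort_spec(n=n, seed=0),
        k_folds=k_folds,
        hyperparams=params,
    )


@dataclass
class CaseResult:
    case: CaseConfig
    report: EvalReport
    depth_table: pd.DataFrame
    canonical_paths: list
    root_length: int
    frequent_roots: list
    best_roots: list
    leaderboard: pd.DataFrame | None = None


@dataclass
class StudyResult:
    config: RunConfig
    table: pd.DataFrame
    labeling: object
    filter_report: object
    cases: dict[str, CaseResult] = field(default_factory=dict)


def run_study(config: RunConfig, outdir: str | Path | None = None) -> StudyResult:
    """Execute preprocess -> benchmark -> final forest -> paths -> roots.

    When ``outdir`` is given, all report tables and serialized artifacts are
    written there (plain text only).
    """
    if config.cohort_path is not None:
        raw = read_cohort_csv(config.cohort_path)
    else:
        raw = generate_cohort(config.cohort_spec)
        if config.cohort_spec.missing_rate > 0:
            from .cohort import inject_missingness

            raw = inject_missingness(
                raw, config.cohort_spec.missing_rate, config.seed_cohort + 1
            )

    required = list(raw.columns)
    table, filt = filter_complete_cases(raw, required)
    labeling = assign_outcome_groups(table[OUTCOME].to_numpy())

    result = StudyResult(
        config=config, table=table, labeling=labeling, filter_report=filt
    )

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _dump_yaml(out / "manifest.yaml", config.to_manifest())
        write_cohort_csv(raw, out / "cohort.csv")
        _dump_yaml(
            out / "preprocess.yaml",
            {
                "n_in": filt.n_in,
                "n_retained": filt.n_retained,
                "n_discarded": filt.n_discarded,
                "outcome_mean": round(labeling.mean, 6),
                "outcome_sd": round(labeling.sd, 6),
                "low_cut": round(labeling.low_cut, 6),
                "high_cut": round(labeling.high_cut, 6),
                "group_counts": labeling.counts(),
            },
        )

    for case_id in config.cases:
        case = (
            CaseConfig.case_a(table.columns)
            if case_id == "A"
            else CaseConfig.case_b(table.columns)
        )
        params = config.hyperparams or STUDY_OPTIMUM[case_id]
        model = make_forest(params, case_id, config.seed_model)
        report = crossval_benchmark(
            table, case, model, labeling, k=config.k_folds, seed=config.seed_cv
        )
        leaderboard = (
            run_leaderboard(table, case, labeling, k=config.k_folds, seed=config.seed_cv)
            if config.run_comparators
            else None
        )

        # one explainability forest per case, refit on the balanced full sample
        balanced = balance_training_set(table, labeling.labels, seed=config.seed_balance)
        final = make_forest(params, case_id, config.seed_model)
        final.fit(
            balanced[list(case.predictor_set)], balanced[OUTCOME].to_numpy(dtype=float)
        )
        structure = extract_forest(final, case.predictor_set)
        depth_tbl, _ = depth_frequency(structure)
        rule = HighLeafRule(high_cut=labeling.high_cut)
        raw_paths = enumerate_high_paths(structure, rule)
        raw_paths = attach_precisions(raw_paths, table, labeling)
        canonical = merge_paths(raw_paths)
        n_root, profile = select_root_length(
            canonical, min_count=config.min_count, min_roots=config.min_roots
        ) if canonical else (1, {})
        frequent, _ = extract_roots(canonical, n_root) if canonical else ([], 0)
        qrule = QualificationRule(
            min_count=config.min_count, min_precision=report.precision
        )
        best = rank_best_roots(frequent, qrule, top_k=config.top_k)

        cres = CaseResult(
            case=case,
            report=report,
            depth_table=depth_tbl,
            canonical_paths=canonical,
            root_length=n_root,
            frequent_roots=frequent,
            best_roots=best,
            leaderboard=leaderboard,
        )
        result.cases[case_id] = cres

        if out is not None:
            cdir = out / f"case_{case_id}"
            cdir.mkdir(exist_ok=True)
            _dump_yaml(
                cdir / "metrics.yaml",
                {
                    "pcc": round(report.pcc, 6),
                    "mae": round(report.mae, 6),
                    "precision": round(report.precision, 6),
                    "recall": round(report.recall, 6),
                    "recall_high": round(report.recall_high, 6),
                    "accuracy": round(report.accuracy(), 6),
                    "root_length": n_root,
                    "root_length_profile": {int(k): int(v) for k, v in profile.items()},
                },
            )
            report.confusion.to_csv(cdir / "confusion.csv")
            report.per_fold.to_csv(cdir / "per_fold.csv", index=False)
            depth_tbl.to_csv(cdir / "depth_frequency.csv", index_label="Variable")
            path_table(canonical[:100]).to_csv(cdir / "high_paths.csv", index=False)
            root_table(frequent[: config.top_k], n_root).to_csv(
                cdir / "frequent_roots.csv", index=False
            )
            root_table(best, n_root).to_csv(cdir / "best_roots.csv", index=False)
            structure.to_json(cdir / "forest.json")
            if leaderboard is not None:
                leaderboard.to_csv(cdir / "leaderboard.csv", index=False)

    return result


def _dump_yaml(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
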