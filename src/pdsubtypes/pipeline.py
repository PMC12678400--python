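"""End-to-end subtyping pipeline.

Chains the stages: paired cohorts -> onset labels -> feature selection ->
train/test split -> normative imputation -> oversampling -> grid-searched
tree -> leaf rule extraction -> three-criteria external filtering ->
characterization. Works on synthetic cohorts out of the box and on any
loaded cohort pair that shares a vocabulary (harmonize first if not).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .preprocess import (PreprocessConfig, assign_onset_labels, class_counts,
                         impute_missing, random_oversample, select_features,
                         split_train_test)
from .rules import SubtypeRule
from .subtyping import FilterReport, extract_candidate_subtypes, run_filter_pipeline
from .synthetic import GeneratorConfig, generate_paired_cohorts
from .tree import CVGrid, OnsetTreeClassifier, cross_validate_grid, evaluate


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    train: Cohort
    test: Cohort
    external: Cohort
    features: list[str]
    label_report: dict
    selection_report: dict
    best_params: dict
    cv_table: pd.DataFrame
    model: OnsetTreeClassifier
    metrics: dict
    rules: list[SubtypeRule]
    filter_report: FilterReport
    train_class_counts: tuple[int, int]

    @property
    def final_subtypes(self) -> list[SubtypeRule]:
        return [r for r in self.rules if r.name in self.filter_report.survivors]


def prepare_cohorts(training: Cohort, external: Cohort,
                    config: PreprocessConfig
                    ) -> tuple[Cohort, Cohort, Cohort, list[str], dict, dict]:
    """Label, select, split and impute; returns train/test/external plus reports."""
    labeled, label_report = assign_onset_labels(training)
    selected, selection_report = select_features(labeled, config)
    train, test = split_train_test(selected, config)
    (train, test), _ = impute_missing(train, test)

    ext_labeled, ext_report = assign_onset_labels(external)
    label_report = {"training": label_report, "external": ext_report}
    features = [c for c in selected.frame.columns
                if c not in ("patient_id", "onset_label")]
    # the external cohort is imputed with its own normative values
    keep = ["patient_id", "onset_label"] + [c for c in features
                                            if c in ext_labeled.frame.columns]
    ext_view = Cohort(ext_labeled.frame[keep].copy(),
                      dict(ext_labeled.dictionary), ext_labeled.planted)
    (ext_view,), _ = impute_missing(ext_view)
    return train, test, ext_view, features, label_report, selection_report


def run_pipeline(training: Cohort, external: Cohort,
                 preprocess_config: PreprocessConfig | None = None,
                 grid: CVGrid | None = None,
                 oversample_before_cv: bool = False) -> PipelineResult:
    """Run the full subtyping analysis on a training/external cohort pair."""
    preprocess_config = preprocess_config or PreprocessConfig()
    grid = grid or CVGrid(seed=preprocess_config.seed)
    train, test, ext_view, features, label_report, selection_report = \
        prepare_cohorts(training, external, preprocess_config)

    best, cv_table = cross_validate_grid(
        train.frame, features, grid, oversample_before_cv=oversample_before_cv)
    balanced = random_oversample(train.frame, seed=preprocess_config.seed)
    model = OnsetTreeClassifier(best["max_depth"], best["min_samples_leaf"]).fit(
        balanced[features], balanced["onset_label"],
        patient_ids=balanced["patient_id"].to_numpy())
    metrics = evaluate(model, test.frame[features], test.frame["onset_label"])

    rules = extract_candidate_subtypes(model, balanced)
    filter_report = run_filter_pipeline(rules, ext_view.frame)
    return PipelineResult(
        train=train, test=test, external=ext_view, features=features,
        label_report=label_report, selection_report=selection_report,
        best_params=best, cv_table=cv_table, model=model, metrics=metrics,
        rules=rules, filter_report=filter_report,
        train_class_counts=class_counts(train.frame),
    )


def run_synthetic_pipeline(config: GeneratorConfig | None = None,
                           preprocess_config: PreprocessConfig | None = None,
                           grid: CVGrid | None = None) -> PipelineResult:
    """Generate a synthetic cohort pair and run the full analysis on it."""
    config = config or GeneratorConfig()
    training, external = generate_paired_cohorts(config)
    if preprocess_config is None:
        preprocess_config = PreprocessConfig(seed=config.seed)
    if grid is None:
        grid = CVGrid(seed=config.seed)
    return run_pipeline(training, external, preprocess_config, grid)


def planted_recovery(result: PipelineResult, training: Cohort) -> dict[str, float]:
    """Best Jaccard overlap between each planted subtype and any learned rule.

    Planted member sets are restricted to patients present in the training
    split (the only patients a learned rule can contain).
    """
    if not training.planted:
        raise ValueError("cohort carries no planted-subtype bookkeeping")
    train_ids = set(result.train.frame["patient_id"])
    scores: dict[str, float] = {}
    for name, members in training.planted.items():
        target = set(members) & train_ids
        best = 0.0
        for rule in result.rules:
            got = set(rule.member_ids)
            union = target | got
            if union:
                best = max(best, len(target & got) / len(union))
        scores[name] = best
    return scores
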