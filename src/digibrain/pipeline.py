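"""End-to-end analysis pipeline.

``run_pipeline`` sequences the stages: simulate (or load) → quality
control → adherence filter → feature extraction → aggregation →
confounder-adjusted correlation grid → explained-variance models.  Every
stage logs its counts (records read, flagged, subjects excluded) and the
result object keeps them for inspection.  A single seed in the config
drives all randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .aggregate import (aggregate_clinical, aggregate_digital, aggregate_mri,
                        build_measure_table, extract_valid_tests)
from .corrstats import FdrFamilySpec, correlation_grid
from .qc import QCThresholds, adherence_filter, run_qc
from .regions import REGION_NAMES
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort
from .varexplained import VarianceReport, whole_brain_vs_parcellation

log = logging.getLogger("digibrain")


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run; JSON round-trippable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    study_weeks: float = 24.0
    adherence_rate: float = 1.5          # valid tests per week
    fdr_mode: str = "per_measure"        # or "global_36x21"
    per_shape: bool = False
    signed_r2: bool = False
    run_variance: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        cohort = d.pop("cohort", {})
        if "age_range" in cohort:
            cohort["age_range"] = tuple(cohort["age_range"])
        qc = d.pop("qc_thresholds", {})
        return cls(cohort=CohortConfig(**cohort),
                   qc_thresholds=QCThresholds(**qc), **d)


@dataclass
class PipelineResult:
    correlations: pd.DataFrame
    variance: list[VarianceReport]
    measure_table: pd.DataFrame
    region_table: pd.DataFrame
    covariates: pd.DataFrame
    counts: dict
    cohort: SyntheticCohort | None = None


def run_pipeline(config: PipelineConfig | None = None,
                 cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Run the full analysis on a simulated (or supplied) cohort."""
    config = config or PipelineConfig()
    if cohort is None:
        cohort = simulate_cohort(config.cohort)
    records = cohort.records
    counts = {"n_enrolled": len(cohort.covariates), "n_records": len(records)}
    log.info("read %d records from %d subjects",
             counts["n_records"], counts["n_enrolled"])

    run_qc(records, config.qc_thresholds)
    counts["n_flagged"] = sum(not r.valid for r in records)
    log.info("QC flagged %d of %d records", counts["n_flagged"], len(records))

    included = adherence_filter(records, study_weeks=config.study_weeks,
                                min_rate=config.adherence_rate)
    counts["n_low_adherence_excluded"] = counts["n_enrolled"] - len(included)
    log.info("adherence filter kept %d subjects (excluded %d)",
             len(included), counts["n_low_adherence_excluded"])

    test_level = extract_valid_tests(
        [r for r in records if r.subject_id in included],
        per_shape=config.per_shape)
    digital = aggregate_digital(test_level)
    clinical = aggregate_clinical(cohort.clinical_visits)
    measures = build_measure_table(digital, clinical.reindex(digital.index))

    regions = aggregate_mri(cohort.region_scans) if "scan" in cohort.region_scans \
        else cohort.region_table
    with_mri = measures.index.intersection(regions.index)
    counts["n_missing_mri_excluded"] = len(measures.index) - len(with_mri)
    counts["n_analyzed"] = len(with_mri)
    log.info("%d subjects excluded for missing MRI; %d analyzed",
             counts["n_missing_mri_excluded"], counts["n_analyzed"])

    region_cols = [c for c in REGION_NAMES if c in regions.columns]
    grid = correlation_grid(measures.loc[with_mri],
                            regions.loc[with_mri, region_cols],
                            cohort.covariates.loc[with_mri],
                            FdrFamilySpec(config.fdr_mode))
    log.info("correlation grid: %d pairs, %d significant at q<0.05",
             len(grid), int(grid["significant"].sum()))

    variance: list[VarianceReport] = []
    if config.run_variance:
        variance = whole_brain_vs_parcellation(
            measures.loc[with_mri], regions.loc[with_mri],
            cohort.covariates.loc[with_mri], signed=config.signed_r2)

    return PipelineResult(grid, variance, measures.loc[with_mri],
                          regions.loc[with_mri], cohort.covariates.loc[with_mri],
                          counts, cohort)
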