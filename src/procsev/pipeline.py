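"""Orchestration: cohort split, feature-frame construction, and the chained
derive / score / validate stages with their reports.

All randomness is funnelled through named seeds; no global RNG state is
touched, so identical configurations reproduce identical reports.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import comorbidity
from .cohort import (AdmissionRecord, FeatureCatalog, extract_features,
                     DEFAULT_DIAGNOSES)
from .collinearity import CorrelationGroup, find_groups, resolve
from .derivation import (FittedModel, PointTable, assign_points, fit_logistic,
                         reference_coefficient, score_frame)
from .errors import ConfigError
from .screening import ScreeningResult, results_to_frame, screen
from .validation import ValidationReport, run_validation

log = logging.getLogger("procsev")


@dataclass
class RunConfig:
    """Thresholds and seeds of a full derivation/validation run."""

    prevalence_threshold: float = 0.01
    screen_p_threshold: float = 0.1
    phi_threshold: float = 0.6
    significance_level: float = 0.05
    split_fraction: float = 0.5
    split_seed: int = 0
    bootstrap_seed: int = 0
    simulation_seed: int = 0
    n_boot: int = 200
    group_policies: List[CorrelationGroup] = field(default_factory=list)

    def __post_init__(self):
        for v, what in ((self.prevalence_threshold, "prevalence_threshold"),
                        (self.screen_p_threshold, "screen_p_threshold"),
                        (self.significance_level, "significance_level"),
                        (self.split_fraction, "split_fraction")):
            if not 0 < v < 1:
                raise ConfigError(f"{what} must lie in (0,1)")
        if not 0 < self.phi_threshold <= 1:
            raise ConfigError("phi_threshold must lie in (0,1]")


def split(cohort: Sequence[AdmissionRecord], seed: int,
          fraction: float = 0.5, method: str = "shuffle",
          ) -> Tuple[list, list]:
    """Randomly partition admissions into derivation and validation cohorts.

    ``method="shuffle"`` (default) permutes and cuts, so sizes are within one
    admission of ``n * fraction``; ``method="bernoulli"`` assigns each
    admission independently.  The split is at admission level and is
    exhaustive and disjoint.
    """
    if not cohort:
        raise ConfigError("cannot split an empty cohort")
    if not 0 < fraction < 1:
        raise ConfigError("fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if method == "shuffle":
        perm = rng.permutation(n)
        cut = round(n * fraction)
        first = set(perm[:cut].tolist())
        a = [r for i, r in enumerate(cohort) if i in first]
        b = [r for i, r in enumerate(cohort) if i not in first]
    elif method == "bernoulli":
        pick = rng.random(n) < fraction
        a = [r for r, t in zip(cohort, pick) if t]
        b = [r for r, t in zip(cohort, pick) if not t]
    else:
        raise ConfigError(f"unknown split method {method!r}")
    return a, b


def feature_frame(cohort: Sequence[AdmissionRecord],
                  catalog: FeatureCatalog,
                  weights: Optional[comorbidity.WeightTable] = None,
                  condition_map: Optional[comorbidity.ConditionMap] = None,
                  use_precomputed_cci: bool = False,
                  diagnoses: Sequence[str] = DEFAULT_DIAGNOSES,
                  ) -> pd.DataFrame:
    """One row per admission: binary procedure indicators plus the binned
    demographic columns, the outcome and any strata labels.

    The Charlson index comes from the present-on-admission ICD-10 codes via
    the bundled Quan mapping unless ``use_precomputed_cci`` (then the
    record-level ``cci`` field is required).
    """
    if not use_precomputed_cci:
        if condition_map is None:
            condition_map = comorbidity.load_condition_map()
        if weights is None:
            weights = comorbidity.load_weights()
    cci_cache: Dict[tuple, int] = {}
    rows = []
    strata_cols = sorted({k for r in cohort for k in r.strata})
    for r in cohort:
        if use_precomputed_cci:
            if r.cci is None:
                raise ConfigError(
                    f"admission {r.admission_id!r} lacks a precomputed CCI")
            cci = r.cci
        else:
            key = tuple(sorted(r.comorbidity_codes))
            if key not in cci_cache:
                cci_cache[key] = comorbidity.cci_for_codes(
                    r.comorbidity_codes, condition_map, weights)[0]
            cci = cci_cache[key]
        fv = extract_features(r, catalog, cci=cci, diagnoses=diagnoses)
        row = dict(fv.indicators)
        row["admission_id"] = fv.admission_id
        row["diagnosis"] = fv.diagnosis
        row["sex"] = fv.sex
        row["age_category"] = fv.age_category
        row["cci_category"] = fv.cci_category
        row["death"] = int(fv.death)
        for c in strata_cols:
            row[c] = r.strata.get(c, "")
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = (["admission_id", "diagnosis", "sex", "age_category",
                "cci_category", "death"] + list(catalog.names) + strata_cols)
    return frame[ordered]


@dataclass
class DerivationResult:
    point_table: PointTable
    screening: List[ScreeningResult]
    groups: List[CorrelationGroup]
    candidate_variables: List[str]
    model: Optional[FittedModel]
    warnings: List[str] = field(default_factory=list)

    def screening_frame(self) -> pd.DataFrame:
        return results_to_frame(self.screening)

    def model_frame(self) -> Optional[pd.DataFrame]:
        return None if self.model is None else self.model.to_frame()


def derive(frame: pd.DataFrame, procedure_columns: Sequence[str],
           config: Optional[RunConfig] = None) -> DerivationResult:
    """Run the three derivation stages on a derivation-cohort feature frame.

    Stage 1 screens each procedure (prevalence >= 1%, chi-square P < 0.1,
    positive association); stage 2 groups retained procedures with phi > 0.6
    and consolidates them under the configured policies; stage 3 fits the
    multivariable logistic model and assigns Sullivan points against the CCI
    reference.  Returns the point table together with all stage reports.
    """
    if config is None:
        config = RunConfig()
    captured: List[str] = []

    log.info("derivation stage 1/4: screening %d procedures",
             len(procedure_columns))
    results = screen(frame[list(procedure_columns)], frame["death"],
                     config.prevalence_threshold, config.screen_p_threshold)
    retained = [r.feature for r in results if r.retained]
    log.info("derivation stage 2/4: collinearity on %d retained procedures",
             len(retained))
    if not retained:
        msg = "no procedure passed the screening stage; empty point table"
        warnings.warn(msg, stacklevel=2)
        captured.append(msg)
        return DerivationResult(PointTable({}, float("nan")), results, [],
                                [], None, captured)
    detected = find_groups(frame[retained], config.phi_threshold)
    configured = {frozenset(g.members): g for g in config.group_policies}
    groups = [configured.get(frozenset(g.members), g) for g in detected]
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        consolidated, variables = resolve(frame[retained], groups)
    captured.extend(str(w.message) for w in wlist)
    log.info("derivation stage 3/4: logistic model on %d candidate variables",
             len(variables))
    model_frame = pd.concat(
        [frame[["diagnosis", "sex", "age_category", "cci_category", "death"]],
         consolidated], axis=1)
    model = fit_logistic(model_frame, variables)
    log.info("derivation stage 4/4: Sullivan point assignment")
    ref = reference_coefficient(model, config.significance_level)
    table = assign_points(model, ref, config.significance_level, variables)
    return DerivationResult(table, results, groups, variables, model,
                            captured)


def add_severity_index(frame: pd.DataFrame, table: PointTable
                       ) -> pd.DataFrame:
    """Return a copy of the frame with the integer ``severity_index``
    column appended."""
    out = frame.copy()
    out["severity_index"] = score_frame(frame, table)
    return out


def validate(frame: pd.DataFrame, table: PointTable,
             config: Optional[RunConfig] = None,
             subgroup_columns: Sequence[str] = (),
             ) -> ValidationReport:
    """Score the validation frame with the point table and run the full
    validation battery."""
    if config is None:
        config = RunConfig()
    scored = add_severity_index(frame, table)
    return run_validation(scored, subgroup_columns=subgroup_columns,
                          n_boot=config.n_boot, seed=config.bootstrap_seed)
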