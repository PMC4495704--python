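"""Stage 4: discrimination, grouped-predictor contribution and calibration.

Four nested logistic models are compared on the validation cohort:

* model 1 — severity index alone (continuous);
* model 2 — index + diagnosis + age + sex;
* model 3 — diagnosis + age + sex + CCI (no index);
* model 4 — index + diagnosis + age + sex + CCI.

Discrimination is the c-statistic (AUC, DeLong 95% CI); the added value of
the index is the integrated discrimination improvement of model 4 over
model 3; the omega statistic is the ratio of the across-patient variances of
the index's and the other covariates' contributions to the model-4 log odds
(bootstrap percentile CI, refitting per replicate); calibration uses the
Hosmer-Lemeshow decile partition and a per-index-value table whose sparse
extreme values are merged until every bin holds at least 1% of patients.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .derivation import FittedModel, fit_logistic
from .errors import ConfigError, ZeroMarginError

DEMOGRAPHIC_COVARIATES = ("diagnosis", "sex", "age_category", "cci_category")

#: label -> (categorical covariates, numeric columns)
STANDARD_MODELS = {
    "model1": ((), ("severity_index",)),
    "model2": (("diagnosis", "sex", "age_category"), ("severity_index",)),
    "model3": (DEMOGRAPHIC_COVARIATES, ()),
    "model4": (DEMOGRAPHIC_COVARIATES, ("severity_index",)),
}


@dataclass(frozen=True)
class ModelSpec:
    label: str
    covariates: Tuple[str, ...]
    numeric: Tuple[str, ...]

    @classmethod
    def standard(cls, label: str) -> "ModelSpec":
        if label not in STANDARD_MODELS:
            raise ConfigError(f"unknown model label {label!r}")
        cov, num = STANDARD_MODELS[label]
        return cls(label, tuple(cov), tuple(num))


# ------------------------------------------------------------- c-statistic

def _midranks(x):
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    i = 0
    xs = x[order]
    while i < len(x):
        j = i
        while j < len(x) and xs[j] == xs[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def c_statistic(p, y) -> Tuple[float, Tuple[float, float]]:
    """Area under the ROC curve with a DeLong 95% confidence interval.

    The point estimate is (concordant pairs + half ties) / (events x
    non-events), computed via midranks; the CI uses the DeLong structural-
    component variance, clipped to [0, 1].  Requires both outcome classes.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    if len(p) != len(y):
        raise ValueError("length mismatch between predictions and outcomes")
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    pos, neg = p[y], p[~y]
    all_r = _midranks(p)
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[y].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[y] - pos_r) / n
    v01 = 1.0 - (all_r[~y] - neg_r) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return float(auc), ci


# --------------------------------------------------------------------- IDI

def discrimination_slope(p, y) -> float:
    """Mean predicted probability among events minus the mean among
    non-events."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    return float(p[y].mean() - p[~y].mean())


def idi(p_new, p_old, y) -> Tuple[float, Tuple[float, float]]:
    """Integrated discrimination improvement of the new over the old model:
    the difference of the two discrimination slopes.  The CI is
    IDI +- 1.96 sqrt(se_events^2 + se_nonevents^2) where each se is the
    standard error of the mean within-person probability difference in that
    outcome class."""
    p_new = np.asarray(p_new, dtype=np.float64)
    p_old = np.asarray(p_old, dtype=np.float64)
    y = np.asarray(y, dtype=bool)
    if not (len(p_new) == len(p_old) == len(y)):
        raise ValueError("length mismatch between probability vectors")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    d = p_new - p_old
    est = float(d[y].mean() - d[~y].mean())
    se_ev = d[y].std(ddof=1) / np.sqrt(y.sum()) if y.sum() > 1 else 0.0
    se_ne = d[~y].std(ddof=1) / np.sqrt((~y).sum()) if (~y).sum() > 1 else 0.0
    half = 1.96 * float(np.hypot(se_ev, se_ne))
    return est, (est - half, est + half)


# ------------------------------------------------------------------- omega

def _contribution_variance_ratio(model: FittedModel, frame: pd.DataFrame,
                                 group_a, group_b) -> float:
    contrib = model.linear_contributions(frame)
    missing = (set(group_a) | set(group_b)) - set(contrib.columns)
    if missing:
        raise ConfigError(f"terms not in model: {sorted(missing)}")
    ca = contrib[list(group_a)].sum(axis=1).to_numpy()
    cb = contrib[list(group_b)].sum(axis=1).to_numpy()
    var_b = float(np.var(cb, ddof=1))
    if var_b == 0.0:
        raise ZeroMarginError(
            "variance of the reference group's contribution is zero")
    return float(np.var(ca, ddof=1)) / var_b


def omega_statistic(model: FittedModel, frame: pd.DataFrame,
                    group_a: Sequence[str], group_b: Sequence[str],
                    n_boot: int = 200, seed: Optional[int] = None,
                    ) -> Tuple[float, Tuple[float, float]]:
    """Ratio of the across-patient variances of two covariate groups'
    contributions to the log odds.

    The contribution of group g for patient i is sum_{j in g} beta_j x_ij.
    omega > 1 means group_a explains more of the linear predictor's spread
    than group_b.  The CI is a seeded nonparametric bootstrap over patients
    (model refitted per replicate), percentile method; ``n_boot=0`` skips it.
    """
    ga, gb = tuple(group_a), tuple(group_b)
    if not ga or not gb:
        raise ConfigError("both term groups must be non-empty")
    if set(ga) & set(gb):
        raise ConfigError("term groups must be disjoint")
    est = _contribution_variance_ratio(model, frame, ga, gb)
    if n_boot == 0:
        return est, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n = len(frame)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bframe = frame.iloc[idx].reset_index(drop=True)
        bmodel = fit_logistic(bframe, model.extra_columns,
                              covariates=model.covariates)
        reps.append(_contribution_variance_ratio(bmodel, bframe, ga, gb))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return est, (float(lo), float(hi))


# ------------------------------------------------------------- calibration

def hosmer_lemeshow(p, y, g: int = 10) -> pd.DataFrame:
    """Observed and expected event counts within ``g`` near-equal groups of
    ranked predicted risk (the Hosmer-Lemeshow partition; the table behind
    the usual calibration plot).

    Ties at group boundaries stay together in the lower-risk group (stable
    sort, boundary pushed past the tied run), so the grouping is
    deterministic.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(p)
    if n < g:
        raise ValueError(f"need at least g={g} observations")
    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]
    bounds = [round(k * n / g) for k in range(1, g)]
    adj = []
    for b in bounds:
        while 0 < b < n and ps[b - 1] == ps[b]:
            b += 1
        adj.append(min(b, n))
    edges = [0] + sorted(set(adj)) + [n]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == hi:
            continue
        rows.append({
            "n": hi - lo,
            "observed": float(ys[lo:hi].sum()),
            "expected": float(ps[lo:hi].sum()),
            "mean_p": float(ps[lo:hi].mean()),
            "observed_rate": float(ys[lo:hi].mean()),
        })
    return pd.DataFrame(rows)


def calibration_by_index(index_values, y, p, min_fraction: float = 0.01
                         ) -> pd.DataFrame:
    """Observed vs expected death rate per severity-index value.

    Distinct integer index values are merged with adjacent values, sweeping
    inward from both extremes, until every bin holds at least ``min_fraction``
    of the patients (the sparse tails of the index distribution collapse into
    range bins).  Observed-rate CIs use the Wald binomial approximation;
    expected rates average the supplied model predictions.
    """
    idx = np.asarray(index_values)
    if not np.issubdtype(idx.dtype, np.integer):
        if not np.allclose(idx, np.round(idx)):
            raise ValueError("index values must be integers")
        idx = np.round(idx).astype(np.int64)
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    n = len(idx)
    values = np.unique(idx)
    counts = {v: int((idx == v).sum()) for v in values}
    min_count = min_fraction * n
    bins = [[v] for v in values]  # each bin: contiguous list of values

    def bin_count(b):
        return sum(counts[v] for v in b)

    # sweep inward from the low extreme ...
    while len(bins) > 1 and bin_count(bins[0]) < min_count:
        bins[1] = bins[0] + bins[1]
        del bins[0]
    # ... and from the high extreme
    while len(bins) > 1 and bin_count(bins[-1]) < min_count:
        bins[-2] = bins[-2] + bins[-1]
        del bins[-1]
    # safety pass: any residual sparse interior bin joins its smaller neighbour
    changed = True
    while changed and len(bins) > 1:
        changed = False
        for i, b in enumerate(bins):
            if bin_count(b) < min_count:
                if i == 0:
                    j = 1
                elif i == len(bins) - 1:
                    j = i - 1
                else:
                    j = i - 1 if bin_count(bins[i - 1]) <= bin_count(
                        bins[i + 1]) else i + 1
                lo, hi = min(i, j), max(i, j)
                bins[lo] = bins[lo] + bins[hi]
                del bins[hi]
                changed = True
                break
    rows = []
    for b in bins:
        mask = (idx >= b[0]) & (idx <= b[-1])
        nb = int(mask.sum())
        rate = float(y[mask].mean())
        half = 1.96 * np.sqrt(rate * (1 - rate) / nb)
        rows.append({
            "index_low": int(b[0]),
            "index_high": int(b[-1]),
            "label": str(b[0]) if len(b) == 1 else f"{b[0]} to {b[-1]}",
            "n": nb,
            "fraction": nb / n,
            "observed_rate": rate,
            "observed_ci_low": max(0.0, rate - half),
            "observed_ci_high": min(1.0, rate + half),
            "expected_rate": float(p[mask].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- reporting

@dataclass
class ValidationReport:
    n: int
    death_rate: float
    models: Dict[str, dict] = field(default_factory=dict)
    idi: Optional[dict] = None
    omega: Optional[dict] = None
    hosmer_lemeshow: Optional[list] = None
    calibration: Optional[list] = None
    subgroups: Dict[str, dict] = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "death_rate": self.death_rate,
            "models": self.models,
            "idi": self.idi,
            "omega": self.omega,
            "hosmer_lemeshow": self.hosmer_lemeshow,
            "calibration": self.calibration,
            "subgroups": self.subgroups,
            "warnings": self.warnings,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ValidationReport":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(**obj)


def _fit_spec(frame, spec: ModelSpec) -> FittedModel:
    return fit_logistic(frame, spec.numeric, covariates=spec.covariates)


def run_validation(frame: pd.DataFrame,
                   model_labels: Sequence[str] = ("model1", "model2",
                                                  "model3", "model4"),
                   subgroup_columns: Sequence[str] = (),
                   per_diagnosis: bool = True,
                   n_boot: int = 200,
                   seed: Optional[int] = None,
                   min_fraction: float = 0.01) -> ValidationReport:
    """Full validation battery on a feature frame that already carries a
    ``severity_index`` column.

    Fits the requested standard models; reports the c-statistic per model,
    the IDI of model 4 over model 3, omega (index vs the four demographic
    covariate groups) in model 4, the Hosmer-Lemeshow decile table and the
    per-index-value calibration (expected rates from model 1 when available,
    else model 4).  Subgroup c-statistics (model 4 refitted) are computed per
    stratum column and, with index + age + sex + CCI as covariates, per
    admission-precipitating diagnosis.  Subgroups with a single outcome class
    are skipped with a warning.
    """
    if "severity_index" not in frame.columns:
        raise ConfigError("frame lacks a 'severity_index' column")
    y = frame["death"].to_numpy(dtype=bool)
    report = ValidationReport(n=len(frame), death_rate=float(y.mean()))
    fitted: Dict[str, FittedModel] = {}
    preds: Dict[str, np.ndarray] = {}
    for label in model_labels:
        spec = ModelSpec.standard(label)
        m = _fit_spec(frame, spec)
        fitted[label] = m
        preds[label] = m.predict(frame)
        auc, ci = c_statistic(preds[label], y)
        report.models[label] = {"c": auc, "ci95": list(ci), "n": len(frame)}
    if "model3" in fitted and "model4" in fitted:
        est, ci = idi(preds["model4"], preds["model3"], y)
        report.idi = {"estimate": est, "ci95": list(ci),
                      "comparison": "model4 vs model3"}
    if "model4" in fitted:
        m4 = fitted["model4"]
        demo_terms = [t for t in m4.terms
                      if t not in ("intercept", "severity_index")]
        om, om_ci = omega_statistic(m4, frame, ["severity_index"], demo_terms,
                                    n_boot=n_boot, seed=seed)
        report.omega = {
            "estimate": om, "ci95": list(om_ci), "n_boot": n_boot,
            "groups": "severity_index vs diagnosis+age+sex+cci",
        }
        hl = hosmer_lemeshow(preds["model4"], y)
        report.hosmer_lemeshow = hl.to_dict(orient="records")
        p_cal = preds.get("model1", preds["model4"])
        cal = calibration_by_index(
            frame["severity_index"].to_numpy(), y, p_cal, min_fraction)
        report.calibration = cal.to_dict(orient="records")

    def _subgroup(name, mask, spec):
        sub = frame[mask].reset_index(drop=True)
        ysub = sub["death"].to_numpy(dtype=bool)
        if ysub.all() or not ysub.any():
            msg = f"subgroup {name!r} has a single outcome class; skipped"
            warnings.warn(msg, stacklevel=2)
            report.warnings.append(msg)
            return
        m = _fit_spec(sub, spec)
        auc, ci = c_statistic(m.predict(sub), ysub)
        report.subgroups[name] = {
            "n": int(mask.sum()),
            "mortality": float(ysub.mean()),
            "c": auc, "ci95": list(ci),
        }

    m4_spec = ModelSpec.standard("model4")
    for col in subgroup_columns:
        for value in sorted(frame[col].astype(str).unique()):
            _subgroup(f"{col}={value}",
                      (frame[col].astype(str) == value).to_numpy(), m4_spec)
    if per_diagnosis:
        diag_spec = ModelSpec(
            "per_diagnosis", ("sex", "age_category", "cci_category"),
            ("severity_index",))
        for value in sorted(frame["diagnosis"].unique()):
            _subgroup(f"diagnosis={value}",
                      (frame["diagnosis"] == value).to_numpy(), diag_spec)
    return report
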