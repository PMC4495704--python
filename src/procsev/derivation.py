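"""Stage 3 of index derivation: logistic regression and Sullivan points.

The consolidated candidate procedures enter a multivariable logistic model of
in-hospital death together with the admission-precipitating diagnosis, sex,
age band and CCI category (all dummy-coded; references: acute myocardial
infarction, male, <60, CCI=0).  Points follow the Sullivan method anchored to
the Charlson index: each significant procedure coefficient is divided by the
coefficient of one CCI step and rounded to the nearest integer, so a point
means "as much excess mortality risk as one CCI unit".  When CCI=1 is itself
not significantly harmful, half the CCI=2 coefficient serves as the
reference.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .cohort import AGE_BANDS, CCI_CATEGORIES, DEFAULT_DIAGNOSES, FeatureVector
from .errors import (ConfigError, ConvergenceError, NoReferenceError,
                     SingularDesignError)
from . import published as _published

#: categorical model covariates: column -> (levels, reference level)
CATEGORICAL_COVARIATES = {
    "diagnosis": (DEFAULT_DIAGNOSES, "acute_myocardial_infarction"),
    "sex": (("male", "female"), "male"),
    "age_category": (AGE_BANDS, "<60"),
    "cci_category": (CCI_CATEGORIES, "0"),
}

_TERM_PREFIX = {"diagnosis": "diagnosis", "sex": "sex",
                "age_category": "age", "cci_category": "cci"}


@dataclass(frozen=True)
class TermEstimate:
    beta: float
    se: float
    z: float
    p: float

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci95(self) -> Tuple[float, float]:
        return (math.exp(self.beta - 1.96 * self.se),
                math.exp(self.beta + 1.96 * self.se))


class FittedModel:
    """A fitted logistic model keyed by term name.

    Term names are ``intercept``, ``diagnosis=<level>``, ``sex=female``,
    ``age=<band>``, ``cci=<category>`` and the plain procedure / numeric
    column names; reference levels carry no coefficient.  The model remembers
    its design recipe so it can predict on new data frames.
    """

    def __init__(self, terms, covariates, extra_columns, loglike, n,
                 n_iter, params, term_order, levels_map=None):
        self.terms: Dict[str, TermEstimate] = terms
        self.covariates = tuple(covariates)
        self.extra_columns = tuple(extra_columns)
        self.reference_levels = {
            c: CATEGORICAL_COVARIATES[c][1] for c in covariates}
        self.loglike = loglike
        self.n = n
        self.n_iter = n_iter
        self._params = params  # in term_order
        self._term_order = list(term_order)
        #: non-reference levels realised at fit time, per covariate
        self._levels_map = levels_map or {
            c: [l for l in CATEGORICAL_COVARIATES[c][0]
                if l != CATEGORICAL_COVARIATES[c][1]]
            for c in self.covariates}

    def __getitem__(self, term) -> TermEstimate:
        return self.terms[term]

    def __contains__(self, term):
        return term in self.terms

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted death probabilities for a feature frame with the same
        columns the model was fitted on.  Categorical levels unseen at fit
        time count as the reference level."""
        X, _ = build_design(frame, self.covariates, self.extra_columns,
                            self._levels_map)
        return 1.0 / (1.0 + np.exp(-(X @ self._params)))

    def linear_contributions(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Per-admission, per-term contribution beta_j * x_ij to the log
        odds (intercept excluded)."""
        X, names = build_design(frame, self.covariates, self.extra_columns,
                                self._levels_map)
        contrib = X * self._params[np.newaxis, :]
        out = pd.DataFrame(contrib, columns=names)
        return out.drop(columns=["intercept"])

    def to_frame(self) -> pd.DataFrame:
        """Regression table (one row per non-reference term)."""
        rows = []
        for name in self._term_order:
            if name == "intercept":
                est = self.terms["intercept"]
            else:
                est = self.terms[name]
            lo, hi = est.ci95
            rows.append({"term": name, "beta": est.beta, "se": est.se,
                         "odds_ratio": est.odds_ratio, "ci_low": lo,
                         "ci_high": hi, "z": est.z, "p": est.p})
        return pd.DataFrame(rows)


def build_design(frame: pd.DataFrame,
                 covariates: Sequence[str] = tuple(CATEGORICAL_COVARIATES),
                 extra_columns: Sequence[str] = (),
                 levels_map: Optional[Mapping[str, Sequence[str]]] = None,
                 ) -> Tuple[np.ndarray, list]:
    """Design matrix with intercept, dummy-coded categoricals (fixed
    references) and numeric pass-through columns, in a deterministic order.

    Without ``levels_map``, dummies cover the non-reference levels actually
    present in the frame (absent levels would create all-zero columns);
    passing a model's fitted ``levels_map`` pins the dummy set instead.
    """
    n = len(frame)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        levels, ref = CATEGORICAL_COVARIATES[cov]
        values = frame[cov].to_numpy()
        present = set(np.unique(values))
        unknown = present - set(levels)
        if unknown:
            raise ConfigError(f"unknown {cov} level(s): {sorted(unknown)}")
        if levels_map is not None:
            use = levels_map[cov]
        else:
            use = [l for l in levels if l != ref and l in present]
        for level in use:
            cols.append((values == level).astype(np.float64))
            names.append(f"{_TERM_PREFIX[cov]}={level}")
    for c in extra_columns:
        cols.append(frame[c].to_numpy(dtype=np.float64))
        names.append(c)
    return np.column_stack(cols), names


def _check_rank(X, names):
    gram = X.T @ X
    rank = np.linalg.matrix_rank(gram)
    if rank == X.shape[1]:
        return
    # identify aliased columns via pivoted QR of the gram matrix
    _, r, piv = scipy.linalg.qr(gram, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(gram.shape) * np.finfo(float).eps
    aliased = [names[piv[i]] for i in range(len(names)) if diag[i] <= tol]
    raise SingularDesignError(aliased or ["<undetermined>"])


def fit_logistic(frame: pd.DataFrame,
                 procedure_terms: Sequence[str],
                 covariates: Sequence[str] = tuple(CATEGORICAL_COVARIATES),
                 outcome: str = "death",
                 maxiter: int = 100) -> FittedModel:
    """Maximum-likelihood logistic fit of the outcome on the dummy-coded
    demographic covariates plus the given procedure indicator columns.

    Raises :class:`SingularDesignError` (naming aliased terms) on a rank-
    deficient design and :class:`ConvergenceError` (with iteration
    diagnostics) if Newton iterations fail to converge, e.g. under
    separation.
    """
    y = frame[outcome].to_numpy(dtype=np.float64)
    X, names = build_design(frame, covariates, procedure_terms)
    levels_map = {
        c: [n.split("=", 1)[1] for n in names
            if n.startswith(_TERM_PREFIX[c] + "=")]
        for c in covariates}
    if X.shape[0] <= X.shape[1]:
        raise ConfigError("more model terms than observations")
    _check_rank(X, names)
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled explicitly
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-8,
                            disp=False)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"Newton step failed ({exc}); possible separation") from exc
    retvals = getattr(res, "mle_retvals", {})
    if not retvals.get("converged", True):
        raise ConvergenceError(
            f"no convergence after {retvals.get('iterations', maxiter)} "
            f"iterations (|grad| not below tolerance); possible separation")
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    zvals = params / se
    pvals = np.asarray(res.pvalues)
    terms = {
        name: TermEstimate(float(b), float(s), float(z), float(p))
        for name, b, s, z, p in zip(names, params, se, zvals, pvals)
    }
    return FittedModel(terms, covariates, procedure_terms,
                       float(res.llf), len(y),
                       retvals.get("iterations", None), params, names,
                       levels_map)


# ------------------------------------------------------------- Sullivan rule

def round_half_away(x: float) -> int:
    """Nearest integer, exact halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def reference_coefficient(model: FittedModel, alpha: float = 0.05) -> float:
    """The Sullivan anchor: beta(CCI=1) when significantly positive at
    ``alpha``, otherwise beta(CCI=2)/2.  Raises :class:`NoReferenceError`
    when neither CCI level is significant (no further fallback is defined)."""
    for term in ("cci=1", "cci=2"):
        if term not in model:
            raise NoReferenceError(f"model lacks term {term!r}")
    cci1, cci2 = model["cci=1"], model["cci=2"]
    if cci1.p < alpha:
        return cci1.beta
    if cci2.p < alpha:
        return cci2.beta / 2.0
    raise NoReferenceError(
        f"CCI=1 (P={cci1.p:.3f}) and CCI=2 (P={cci2.p:.3f}) are both "
        f"non-significant at alpha={alpha}")


@dataclass
class PointTable:
    """procedure name -> integer points, with the reference coefficient the
    points were divided by."""

    points: Dict[str, int]
    reference_coefficient: float
    note: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.points.items()
               if not isinstance(v, (int, np.integer))}
        if bad:
            raise ConfigError(f"points must be integers: {bad}")
        self.points = {k: int(v) for k, v in self.points.items()}

    def __len__(self):
        return len(self.points)

    def __getitem__(self, name):
        return self.points[name]

    def to_json(self) -> dict:
        out = dict(self.points)
        out["_reference_coefficient"] = self.reference_coefficient
        if self.note:
            out["_note"] = self.note
        return out

    @classmethod
    def from_json(cls, obj: Mapping) -> "PointTable":
        points = {k: v for k, v in obj.items() if not k.startswith("_")}
        return cls(points, obj.get("_reference_coefficient", math.nan),
                   obj.get("_note", ""))


def assign_points(model: FittedModel, ref: float,
                  alpha: float = 0.05,
                  procedure_terms: Optional[Sequence[str]] = None
                  ) -> PointTable:
    """Sullivan point assignment: for each procedure term significant at
    ``alpha`` (Wald), the point is the nearest integer to beta/ref (exact
    halves away from zero); non-significant procedures get no entry."""
    if ref == 0:
        raise ConfigError("reference coefficient must be nonzero")
    if procedure_terms is None:
        procedure_terms = model.extra_columns
    points = {}
    for name in procedure_terms:
        est = model[name]
        if est.p < alpha:
            points[name] = round_half_away(est.beta / ref)
    return PointTable(points, ref)


def score_index(fv, table: PointTable) -> int:
    """Severity index of one admission: the sum of points over procedures
    performed (indicator 1).  ``fv`` is a :class:`FeatureVector` or a plain
    name -> 0/1 mapping; indicator names missing from it count as not
    performed, with a warning."""
    indicators = fv.indicators if isinstance(fv, FeatureVector) else fv
    missing = [k for k in table.points if k not in indicators]
    if missing:
        warnings.warn(
            f"indicators missing for {len(missing)} scored procedure(s) "
            f"(treated as not performed): {sorted(missing)}", stacklevel=2)
    return int(sum(pts for name, pts in table.points.items()
                   if indicators.get(name, 0)))


def score_frame(features: pd.DataFrame, table: PointTable) -> np.ndarray:
    """Vectorised :func:`score_index` over a feature-matrix data frame."""
    scores = np.zeros(len(features), dtype=np.int64)
    missing = []
    for name, pts in table.points.items():
        if name in features.columns:
            scores += pts * features[name].to_numpy(dtype=np.int64)
        else:
            missing.append(name)
    if missing:
        warnings.warn(
            f"indicators missing for {len(missing)} scored procedure(s) "
            f"(treated as not performed): {sorted(missing)}", stacklevel=2)
    return scores


def index_range(table: PointTable) -> Tuple[int, int]:
    """Attainable (min, max) of the index: the sums of the negative and the
    positive points respectively."""
    lo = sum(v for v in table.points.values() if v < 0)
    hi = sum(v for v in table.points.values() if v > 0)
    return lo, hi


def published_index() -> PointTable:
    """The bundled published 19-procedure point table (points -3..23,
    attainable index range -13..69, reference coefficient 0.091)."""
    obj = _published._load("published_index.json")
    return PointTable(dict(obj["points"]),
                      obj["reference_coefficient"],
                      obj.get("_note", ""))
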