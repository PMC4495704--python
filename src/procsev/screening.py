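"""Stage 1 of index derivation: prevalence filter and chi-square screen.

Each admission-day procedure is cross-tabulated against in-hospital death.
Procedures are retained for the collinearity stage when (i) their prevalence
in the whole derivation cohort is at least ``prevalence_threshold`` (default
1%), (ii) the uncorrected Pearson chi-square P value is below ``p_threshold``
(default 0.1), and (iii) the association is *positive* (used more often in
the deceased).  Protective or non-significant procedures drop out here; no
multiplicity adjustment is applied at this stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .errors import ZeroMarginError


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table.

    For outcome screening the cells are a = deceased with the feature,
    b = deceased without, c = surviving with, d = surviving without.  The
    same container serves for feature-by-feature cross-tabulations in the
    collinearity stage (a = both, b = first only, c = second only, d =
    neither).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self):
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)

    def swapped(self) -> "TwoByTwo":
        """Rows and columns interchanged (transpose)."""
        return TwoByTwo(self.a, self.c, self.b, self.d)


@dataclass
class ScreeningResult:
    feature: str
    prevalence: float
    table: Optional[TwoByTwo]
    chi2: float
    p: float
    direction: Optional[str]  # "positive" | "negative" | None (tie/undefined)
    retained: bool
    note: str = ""


def chisq_2x2(t: TwoByTwo) -> Tuple[float, float]:
    """Pearson chi-square for a 2x2 table, 1 df, no continuity correction.

    X^2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), with the two-sided P value
    from the upper tail of chi-square(1).  Raises :class:`ZeroMarginError`
    when any margin is empty.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ZeroMarginError(f"zero margin in table {t}")
    num = t.n * (t.a * t.d - t.b * t.c) ** 2
    x2 = num / (r1 * r2 * c1 * c2)
    return x2, float(_chi2_dist.sf(x2, 1))


def screen_feature(name: str, table: TwoByTwo,
                   prevalence_threshold: float = 0.01,
                   p_threshold: float = 0.1) -> ScreeningResult:
    """Evaluate one procedure's 2x2 outcome table against the retention rule."""
    n = table.n
    prevalence = (table.a + table.c) / n
    deceased = table.a + table.b
    surviving = table.c + table.d
    note = ""
    direction: Optional[str] = None
    try:
        x2, p = chisq_2x2(table)
    except ZeroMarginError:
        x2, p = math.nan, math.nan
        note = "constant feature or empty outcome class; test undefined"
    else:
        rate_dec = table.a / deceased
        rate_sur = table.c / surviving
        if rate_dec > rate_sur:
            direction = "positive"
        elif rate_dec < rate_sur:
            direction = "negative"
        else:
            note = "identical proportions in both outcome groups"
    retained = (
        prevalence >= prevalence_threshold
        and not math.isnan(p)
        and p < p_threshold
        and direction == "positive"
    )
    return ScreeningResult(name, prevalence, table, x2, p, direction,
                           retained, note)


def screen(features: pd.DataFrame, outcome,
           prevalence_threshold: float = 0.01,
           p_threshold: float = 0.1) -> list:
    """Screen every binary feature column against a binary outcome vector.

    Returns one :class:`ScreeningResult` per column, in column order.
    """
    if not 0 < prevalence_threshold < 1 or not 0 < p_threshold < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    y = np.asarray(outcome, dtype=bool)
    if len(y) != len(features):
        raise ValueError("outcome length does not match feature matrix")
    n_dead = int(y.sum())
    n_alive = int((~y).sum())
    results = []
    for name in features.columns:
        x = np.asarray(features[name], dtype=bool)
        a = int((x & y).sum())
        c = int((x & ~y).sum())
        table = TwoByTwo(a, n_dead - a, c, n_alive - c)
        results.append(
            screen_feature(name, table, prevalence_threshold, p_threshold))
    return results


def results_to_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Tabular screening report (one row per procedure, mirroring the usage
    rates per outcome group, the P value and the retention flag)."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "feature": r.feature,
            "prevalence": r.prevalence,
            "surviving_pct": 100 * t.c / (t.c + t.d) if t else math.nan,
            "surviving_n": t.c if t else 0,
            "deceased_pct": 100 * t.a / (t.a + t.b) if t else math.nan,
            "deceased_n": t.a if t else 0,
            "chi2": r.chi2,
            "p": r.p,
            "direction": r.direction or "",
            "retained": r.retained,
            "note": r.note,
        })
    return pd.DataFrame(rows)
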