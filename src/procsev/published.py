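"""Bundled summary data of the original published severity index.

The original index was derived from a nationwide Japanese acute-care
administrative claims cohort (fiscal year 2012; 270 054 derivation
admissions).  What is bundled here is the published *summary* of that
derivation -- admission-day procedure usage counts by outcome, the five
collinearity group policies, the regression coefficients and the final
19-procedure point table -- not any patient-level data.  These summaries act
as screening/consolidation fixtures and as defaults for the synthetic cohort
generator.
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Dict, List, Tuple

from .collinearity import CorrelationGroup
from .screening import TwoByTwo


def _load(name):
    with resources.files("procsev.data").joinpath(name).open() as fh:
        return json.load(fh)


def published_derivation() -> dict:
    """Raw bundled derivation summary (counts, groups, coefficients,
    marginals)."""
    return _load("published_derivation.json")


def published_screen_tables() -> List[Tuple[str, TwoByTwo]]:
    """The 38 outcome 2x2 tables of the published derivation cohort, one per
    procedure with >=1% prevalence (a/b = deceased with/without, c/d =
    surviving with/without)."""
    d = published_derivation()
    dead, alive = d["deceased_n"], d["surviving_n"]
    out = []
    for p in d["procedures"]:
        a, c = p["deceased_with"], p["surviving_with"]
        out.append((p["name"], TwoByTwo(a, dead - a, c, alive - c)))
    return out


def published_groups() -> List[CorrelationGroup]:
    """The five published correlation-group policies (three any-of combines,
    two keep-first reductions)."""
    d = published_derivation()
    return [
        CorrelationGroup(tuple(g["members"]), g["policy"], g["arg"])
        for g in d["groups"]
    ]


def published_coefficients() -> dict:
    """Published log-odds coefficients: keys ``diagnosis``, ``sex_female``,
    ``age_category``, ``cci_category``, ``procedures`` (22 candidate
    variables)."""
    return published_derivation()["model_terms"]


def published_marginals() -> dict:
    """Study-population marginal counts (diagnosis, sex, age band, CCI
    category) and overall in-hospital death rate."""
    return published_derivation()["marginals"]


def procedure_prevalences() -> Dict[str, float]:
    """Marginal admission-day prevalence of each of the 38 procedures in the
    published derivation cohort."""
    d = published_derivation()
    n = d["deceased_n"] + d["surviving_n"]
    return {
        p["name"]: (p["deceased_with"] + p["surviving_with"]) / n
        for p in d["procedures"]
    }


def procedure_blocks() -> Dict[str, str]:
    """Co-occurrence block id per procedure (procedures outside any block are
    absent)."""
    d = published_derivation()
    return {p["name"]: p["group"] for p in d["procedures"]
            if p["group"] is not None}
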