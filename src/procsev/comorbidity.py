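"""Charlson comorbidity index from present-on-admission ICD-10 codes.

The condition map is the Quan ICD-10 coding algorithm (17 Charlson
conditions, prefix matching); two weight tables are bundled, the original
Charlson weights and the Quan-updated weights (the default).  Hierarchy rules
suppress the milder member of condition pairs (metastatic disease over any
malignancy, moderate/severe over mild liver disease, complicated over
uncomplicated diabetes) before summing weights.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Set, Tuple

from .cohort import cci_category
from .errors import ConfigError


@dataclass(frozen=True)
class ConditionMap:
    """condition name -> tuple of ICD-10 code prefixes (dot-insensitive)."""

    conditions: Mapping[str, Tuple[str, ...]]
    note: str = ""

    def __post_init__(self):
        norm = {
            name: tuple(_normalize(p) for p in prefixes)
            for name, prefixes in self.conditions.items()
        }
        object.__setattr__(self, "conditions", norm)


@dataclass(frozen=True)
class WeightTable:
    name: str
    weights: Mapping[str, int]
    #: list of (superior, suppressed) condition pairs
    hierarchy: Sequence[Tuple[str, str]] = field(default_factory=tuple)
    note: str = ""


def _normalize(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def _load_json(name):
    with resources.files("procsev.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_condition_map() -> ConditionMap:
    """The bundled Quan ICD-10 condition map."""
    obj = _load_json("charlson_icd10_quan.json")
    return ConditionMap(
        {k: tuple(v) for k, v in obj["conditions"].items()},
        note=obj.get("_note", ""),
    )


def load_weights(table: str = "quan_updated") -> WeightTable:
    """A bundled weight table: ``"quan_updated"`` (default) or
    ``"charlson_original"``."""
    obj = _load_json("charlson_weights.json")
    if table not in obj["tables"]:
        raise ConfigError(
            f"unknown weight table {table!r}; choose from "
            f"{sorted(obj['tables'])}")
    return WeightTable(
        name=table,
        weights=dict(obj["tables"][table]),
        hierarchy=tuple((a, b) for a, b in obj["hierarchy"]),
        note=obj.get("_note", ""),
    )


def map_conditions(codes: Iterable[str], cmap: Optional[ConditionMap] = None
                   ) -> Set[str]:
    """Map ICD-10 code strings to the set of Charlson condition names.

    Matching is by prefix after uppercasing and removing dots/whitespace;
    codes matching no condition are ignored.  Hierarchy suppression is *not*
    applied here (see :func:`cci_score`).
    """
    if cmap is None:
        cmap = load_condition_map()
    normed = [_normalize(c) for c in codes]
    hit = set()
    for name, prefixes in cmap.conditions.items():
        for code in normed:
            if code.startswith(prefixes):
                hit.add(name)
                break
    return hit


def cci_score(conditions: Set[str], weights: Optional[WeightTable] = None
              ) -> Tuple[int, str]:
    """Weighted Charlson score and its category.

    Applies the hierarchy rules (the suppressed member of a pair contributes
    nothing when its superior is present), sums the weights, and bins the
    score into {0, 1, 2, >=3}.
    """
    if weights is None:
        weights = load_weights()
    missing = [c for c in conditions if c not in weights.weights]
    if missing:
        raise ConfigError(
            f"condition(s) missing from weight table {weights.name!r}: "
            f"{sorted(missing)}")
    active = set(conditions)
    for superior, suppressed in weights.hierarchy:
        if superior in active:
            active.discard(suppressed)
    score = sum(weights.weights[c] for c in active)
    return score, cci_category(score)


def cci_for_codes(codes: Iterable[str], cmap: Optional[ConditionMap] = None,
                  weights: Optional[WeightTable] = None) -> Tuple[int, str]:
    """Convenience: ICD-10 codes straight to (score, category)."""
    return cci_score(map_conditions(codes, cmap), weights)
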