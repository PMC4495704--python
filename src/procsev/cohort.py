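"""Admission-level domain types, cohort file I/O, exclusion filtering and
admission-day binary feature extraction.

An :class:`AdmissionRecord` is one hospitalization of an adult admitted for one
of six high-mortality conditions (acute myocardial infarction, congestive
heart failure, acute cerebrovascular disease, gastrointestinal hemorrhage,
pneumonia, septicemia).  Every diagnostic or therapeutic event (procedure,
drug, special reimbursement) carries an integer day offset from admission;
day 0 is the admission day, and only day-0 events enter the severity features.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .errors import CohortLoadError, ConfigError, SchemaError

DEFAULT_DIAGNOSES = (
    "acute_myocardial_infarction",
    "congestive_heart_failure",
    "acute_cerebrovascular_disease",
    "gastrointestinal_hemorrhage",
    "pneumonia",
    "septicemia",
)

AGE_BANDS = ("<60", "60-69", "70-79", "80-89", ">=90")
CCI_CATEGORIES = ("0", "1", "2", ">=3")

EVENT_KINDS = ("procedure", "drug", "reimbursement")


class Event(NamedTuple):
    """A dated clinical event; ``day`` is the 0-based offset from admission."""

    code: str
    day: int
    kind: str = "procedure"


def age_category(age_years: int) -> str:
    """Bin an age in years into the five bands used throughout (<60, 60-69,
    70-79, 80-89, >=90).  Bands close on the left: 60 -> "60-69"."""
    if age_years < 60:
        return "<60"
    if age_years < 70:
        return "60-69"
    if age_years < 80:
        return "70-79"
    if age_years < 90:
        return "80-89"
    return ">=90"


def cci_category(score: int) -> str:
    """Bin a Charlson comorbidity index into {0, 1, 2, >=3}."""
    return str(score) if score < 3 else ">=3"


@dataclass
class AdmissionRecord:
    admission_id: str
    diagnosis: str
    age_years: int
    sex: str  # "male" | "female"
    comorbidity_codes: list = field(default_factory=list)
    events: list = field(default_factory=list)  # list of Event
    icu_day0: bool = False
    life_support_day0: bool = False
    death: bool = False
    strata: dict = field(default_factory=dict)
    cci: Optional[int] = None  # precomputed Charlson index, bypasses mapping


@dataclass(frozen=True)
class CatalogEntry:
    """One feature of the catalog: the indicator is 1 iff at least one day-0
    event code is in ``codes`` (any-of rule).  Composites (e.g. one feature
    matching several catecholamine drug codes) are plain multi-code entries."""

    name: str
    codes: tuple
    rule: str = "any-of"


class FeatureCatalog:
    """Mapping from feature names to the event codes that realise them."""

    def __init__(self, entries: Sequence[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ConfigError("feature names must be unique")
        for e in entries:
            if not e.codes:
                raise ConfigError(f"feature {e.name!r} has an empty code list")
            if e.rule != "any-of":
                raise ConfigError(f"unsupported match rule {e.rule!r}")
        self.entries = tuple(entries)
        # reverse map code -> feature names, for O(#events) extraction
        self._by_code: dict = {}
        for e in entries:
            for c in e.codes:
                self._by_code.setdefault(c, []).append(e.name)

    @property
    def names(self):
        return tuple(e.name for e in self.entries)

    @classmethod
    def identity(cls, names: Iterable[str]) -> "FeatureCatalog":
        """Catalog in which every feature matches the single code of its own
        name (the layout the synthetic generator emits)."""
        return cls([CatalogEntry(n, (n,)) for n in names])

    @classmethod
    def from_json(cls, obj) -> "FeatureCatalog":
        return cls(
            [
                CatalogEntry(
                    d["name"], tuple(d["codes"]), d.get("rule", "any-of")
                )
                for d in obj
            ]
        )

    def to_json(self):
        return [
            {"name": e.name, "codes": list(e.codes), "rule": e.rule}
            for e in self.entries
        ]


@dataclass
class FeatureVector:
    admission_id: str
    indicators: dict  # feature name -> 0/1
    age_category: str
    cci_category: str
    diagnosis: str
    sex: str
    death: bool


@dataclass
class ExclusionTally:
    under_18: int = 0
    icu: int = 0
    life_support: int = 0

    @property
    def total(self):
        return self.under_18 + self.icu + self.life_support


# --------------------------------------------------------------------- file IO

#: canonical field -> default column name
DEFAULT_SCHEMA = {
    "admission_id": "admission_id",
    "diagnosis": "diagnosis",
    "age_years": "age_years",
    "sex": "sex",
    "comorbidity_codes": "comorbidity_codes",
    "events": "events",
    "icu_day0": "icu_day0",
    "life_support_day0": "life_support_day0",
    "death": "death",
    "cci": "cci",
}

_MANDATORY = ("admission_id", "diagnosis", "age_years", "sex", "death")
_STRATA_FIELDS = ("ambulance", "referral", "hospital_type")
_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f", ""}


def _parse_bool(raw, what):
    v = raw.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"unparseable {what} {raw!r}")


def _parse_events(raw):
    """Parse a packed event list 'code|day|kind;code|day;...'; kind defaults
    to 'procedure'."""
    events = []
    for tok in raw.split(";"):
        tok = tok.strip()
        if not tok:
            continue
        parts = tok.split("|")
        if len(parts) not in (2, 3):
            raise ValueError(f"malformed event {tok!r}")
        code = parts[0]
        day = int(parts[1])
        if day < 0:
            raise ValueError(f"negative day offset in event {tok!r}")
        kind = parts[2] if len(parts) == 3 else "procedure"
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        events.append(Event(code, day, kind))
    return events


def load_cohort(path, schema: Optional[Mapping[str, str]] = None,
                events_path=None) -> list:
    """Read admissions from a delimited text file (UTF-8, header row).

    ``schema`` maps canonical field names to column names (defaults to the
    identity mapping of :data:`DEFAULT_SCHEMA`).  Events may arrive packed in
    an ``events`` column ('code|day|kind;...') or long form in a separate
    ``events_path`` CSV with columns admission_id, code, day, kind.

    Raises :class:`SchemaError` if a mandatory column is absent and
    :class:`CohortLoadError` (listing offending line numbers) if any row is
    malformed; the file is rejected as a whole in that case.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for f in _MANDATORY:
            if colmap[f] not in header:
                raise SchemaError(f"missing mandatory column {colmap[f]!r}"
                                  f" (field {f!r})")
        records = []
        row_errors = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, colmap, header))
            except (ValueError, KeyError) as exc:
                row_errors.append((lineno, str(exc)))
    if row_errors:
        raise CohortLoadError(row_errors)

    if events_path is not None:
        _attach_long_events(records, events_path)
    return records


def _parse_row(row, colmap, header):
    get = lambda f: row.get(colmap[f], "") or ""
    age = int(get("age_years"))
    if age < 0:
        raise ValueError(f"negative age {age}")
    sex = get("sex").strip().lower()
    if sex not in ("male", "female"):
        raise ValueError(f"unparseable sex {get('sex')!r}")
    codes = [c.strip() for c in get("comorbidity_codes").split(";") if c.strip()]
    events = _parse_events(get("events")) if colmap["events"] in header else []
    cci_raw = get("cci").strip() if colmap["cci"] in header else ""
    strata = {
        f: row[f].strip()
        for f in _STRATA_FIELDS
        if f in header and row.get(f, "").strip() != ""
    }
    return AdmissionRecord(
        admission_id=get("admission_id").strip(),
        diagnosis=get("diagnosis").strip(),
        age_years=age,
        sex=sex,
        comorbidity_codes=codes,
        events=events,
        icu_day0=_parse_bool(get("icu_day0"), "icu_day0"),
        life_support_day0=_parse_bool(get("life_support_day0"),
                                      "life_support_day0"),
        death=_parse_bool(get("death"), "death"),
        strata=strata,
        cci=int(cci_raw) if cci_raw else None,
    )


def _attach_long_events(records, events_path):
    by_id = {r.admission_id: r for r in records}
    row_errors = []
    with open(events_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("admission_id", "code", "day"):
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"missing mandatory column {col!r} in events file")
        for lineno, row in enumerate(reader, start=2):
            try:
                day = int(row["day"])
                if day < 0:
                    raise ValueError(f"negative day offset {day}")
                kind = (row.get("kind") or "procedure").strip()
                if kind not in EVENT_KINDS:
                    raise ValueError(f"unknown event kind {kind!r}")
                rec = by_id.get(row["admission_id"].strip())
                if rec is None:
                    raise ValueError(
                        f"unknown admission_id {row['admission_id']!r}")
                rec.events.append(Event(row["code"].strip(), day, kind))
            except ValueError as exc:
                row_errors.append((lineno, str(exc)))
    if row_errors:
        raise CohortLoadError(row_errors)


def write_cohort(cohort: Sequence[AdmissionRecord], path) -> None:
    """Write admissions as CSV with packed events (inverse of
    :func:`load_cohort` under the default schema)."""
    strata_cols = sorted({k for r in cohort for k in r.strata})
    cols = (
        ["admission_id", "diagnosis", "age_years", "sex", "comorbidity_codes",
         "events", "icu_day0", "life_support_day0", "death", "cci"]
        + strata_cols
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for r in cohort:
            packed = ";".join(f"{e.code}|{e.day}|{e.kind}" for e in r.events)
            row = [
                r.admission_id, r.diagnosis, r.age_years, r.sex,
                ";".join(r.comorbidity_codes), packed,
                int(r.icu_day0), int(r.life_support_day0), int(r.death),
                "" if r.cci is None else r.cci,
            ] + [r.strata.get(c, "") for c in strata_cols]
            w.writerow(row)


# ----------------------------------------------------------------- operations

def apply_exclusions(cohort: Sequence[AdmissionRecord]):
    """Drop admissions aged under 18 or flagged for day-0 intensive care /
    cardiopulmonary life support.

    Reasons are disjoint with precedence under-18 > ICU > life support (an
    admission with both day-0 flags counts under ICU), so the tally plus the
    kept count always reproduces the input count.
    Returns ``(kept, ExclusionTally)``.
    """
    kept = []
    tally = ExclusionTally()
    for r in cohort:
        if r.age_years < 18:
            tally.under_18 += 1
        elif r.icu_day0:
            tally.icu += 1
        elif r.life_support_day0:
            tally.life_support += 1
        else:
            kept.append(r)
    return kept, tally


def extract_features(record: AdmissionRecord, catalog: FeatureCatalog,
                     cci: Optional[int] = None,
                     diagnoses: Sequence[str] = DEFAULT_DIAGNOSES,
                     ) -> FeatureVector:
    """Turn one admission into a binary feature vector.

    An indicator is 1 iff at least one *admission-day* (day 0) event code
    matches any code of the feature; events on later days never count.  Age
    and the Charlson index are binned into the standard categories.  ``cci``
    overrides ``record.cci``; one of the two must be available.
    """
    if record.diagnosis not in diagnoses:
        raise ConfigError(f"unknown diagnosis label {record.diagnosis!r}")
    if cci is None:
        cci = record.cci
    if cci is None:
        raise ConfigError(
            f"no Charlson index available for admission {record.admission_id!r}")
    indicators = dict.fromkeys(catalog.names, 0)
    lookup = catalog._by_code
    for ev in record.events:
        if ev.day != 0:
            continue
        for name in lookup.get(ev.code, ()):
            indicators[name] = 1
    return FeatureVector(
        admission_id=record.admission_id,
        indicators=indicators,
        age_category=age_category(record.age_years),
        cci_category=cci_category(cci),
        diagnosis=record.diagnosis,
        sex=record.sex,
        death=bool(record.death),
    )
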