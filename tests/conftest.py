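import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_record(admission_id="A1", diagnosis="pneumonia", age=74,
                sex="male", codes=(), events=(), icu=False, life=False,
                death=False, cci=None, strata=None):
    from procsev.cohort import AdmissionRecord, Event

    evs = [e if isinstance(e, Event) else Event(*e) for e in events]
    return AdmissionRecord(
        admission_id=admission_id, diagnosis=diagnosis, age_years=age,
        sex=sex, comorbidity_codes=list(codes), events=evs, icu_day0=icu,
        life_support_day0=life, death=death, cci=cci, strata=strata or {})


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-condition cohort (n=200 000), shared across the
    statistical tests to keep the suite fast."""
    from procsev.synthetic import default_config, generate

    cfg = default_config(n=200_000)
    return cfg, generate(cfg, seed=42)


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    from procsev.cohort import FeatureCatalog
    from procsev.pipeline import feature_frame

    cfg, cohort = default_cohort
    names = [p.name for p in cfg.procedures]
    return feature_frame(cohort, FeatureCatalog.identity(names))


@pytest.fixture(scope="session")
def small_scored_frame(default_cohort):
    """First 20 000 admissions of the shared cohort, with consolidated
    indicators, scored with the published point table (for validation-
    battery smoke tests)."""
    from procsev.cohort import FeatureCatalog
    from procsev.collinearity import consolidated_catalog
    from procsev.derivation import published_index
    from procsev.pipeline import add_severity_index, feature_frame
    from procsev.published import published_groups

    cfg, cohort = default_cohort
    names = [p.name for p in cfg.procedures]
    catalog = consolidated_catalog(FeatureCatalog.identity(names),
                                   published_groups())
    frame = feature_frame(cohort[:20_000], catalog)
    return add_severity_index(frame, published_index())
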