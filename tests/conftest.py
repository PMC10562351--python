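import numpy as np
import pytest

from fedaki.types import EventStream, IcuStay


def _hours(n, start=1.0):
    return np.arange(start, start + n)


def make_stay(stay_id="s", source="ward", weight=70.0, discharge=96.0,
              baseline=1.0, urine_rate=1.2, age=60.0, **kw):
    """A clean stay: flat creatinine at baseline, adequate urine."""
    ct = np.array([-48.0, -12.0] if source == "ward" else [0.5])
    cv = np.full(ct.size, baseline)
    icu_t = np.arange(6.0, discharge, 12.0)
    ct = np.concatenate([ct, icu_t])
    cv = np.concatenate([cv, np.full(icu_t.size, baseline)])
    n_h = int(discharge)
    return IcuStay(
        stay_id=stay_id, site_id="t", age=age, sex="M", weight=weight,
        admission_source=source, discharge_time=discharge, era="derivation",
        creatinine=EventStream(ct, cv, "mg/dL"),
        urine=EventStream(_hours(n_h), np.full(n_h, urine_rate * weight), "mL"),
        **kw,
    )


@pytest.fixture
def clean_stay():
    return make_stay()


@pytest.fixture
def six_stay_attrition_cohort():
    """One stay violating each exclusion criterion, in tally order, plus one
    clean stay."""
    stays = [
        make_stay("too_young", age=17.0),
        make_stay("esrd_rrt", esrd=True, prior_rrt=True),
        make_stay("prior_aki"),
        make_stay("early_hd", dialysis_times=[10.0]),
        make_stay("short_stay", discharge=25.0),
        make_stay("readmit", first_icu_admission=False),
        make_stay("clean"),
    ]
    # pre-admission acute rise (>= 0.3 mg/dL within 48 h, before admission)
    prior = stays[2]
    prior.creatinine = EventStream(
        np.concatenate([[-60.0, -20.0], prior.creatinine.times[2:]]),
        np.concatenate([[1.0, 1.5], prior.creatinine.values[2:]]), "mg/dL")
    return stays


@pytest.fixture(scope="session")
def small_site():
    """One generated site (n=400, seed 7) shared across tests."""
    from fedaki.cohort import apply_exclusions
    from fedaki.kdigo import label_aki
    from fedaki.synthgen import SiteConfig, generate_multisite

    data = generate_multisite([SiteConfig("s1", 400, 0.30)], master_seed=7)
    stays = data["s1"]
    included, tally = apply_exclusions(stays)
    events = [label_aki(s) for s in included]
    return {"stays": stays, "included": included, "events": events,
            "tally": tally}
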