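import numpy as np
import pandas as pd
import pytest

from cd4slope import GeneratorConfig, generate_cohort
from cd4slope.cohort import CohortTables


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_patients=60, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort_2000():
    """The documented default cohort (n=2000, seed=1) used by the
    calibration checks; generated once per session."""
    return generate_cohort(GeneratorConfig(n_patients=2000, seed=1))


def make_cohort(patients=None, labs=None, events=None, treatments=None) -> CohortTables:
    """Hand-crafted cohort tables for unit tests.

    ``patients`` rows: (patient_id, sex, age_years, ...); labs rows:
    (patient_id, day, analyte, value) with day relative to a fixed start.
    """
    start = pd.Timestamp("2005-01-01")

    def pat_row(patient_id, sex="M", age=35.0, nnrti=1, bpi=0, nbpi=0, aba=0, hep=0):
        return {
            "patient_id": patient_id,
            "sex": sex,
            "birth_date": start - pd.Timedelta(days=round(age * 365.25)),
            "cart_start": start,
            "regimen_nnrti": nnrti,
            "regimen_boosted_pi": bpi,
            "regimen_nonboosted_pi": nbpi,
            "abacavir": aba,
            "hepatitis_bc": hep,
        }

    patients = patients or [{"patient_id": "A"}]
    pat = pd.DataFrame([pat_row(**p) if isinstance(p, dict) else pat_row(p)
                        for p in patients])
    labs = labs or []
    lab = pd.DataFrame(
        [{"patient_id": p, "date": start + pd.Timedelta(days=d), "analyte": a, "value": v}
         for p, d, a, v in labs],
        columns=["patient_id", "date", "analyte", "value"],
    )
    if not len(lab):
        lab = lab.astype({"date": "datetime64[ns]", "value": float})
    events = events or []
    ev = pd.DataFrame(
        [{"patient_id": p, "date": start + pd.Timedelta(days=d), "event": e}
         for p, d, e in events],
        columns=["patient_id", "date", "event"],
    )
    if not len(ev):
        ev = ev.astype({"date": "datetime64[ns]"})
    treatments = treatments if treatments is not None else [
        (p["patient_id"] if isinstance(p, dict) else p, 0, 4000, "NRTI+NRTI+NNRTI")
        for p in patients
    ]
    tr = pd.DataFrame(
        [{"patient_id": p, "start": start + pd.Timedelta(days=a),
          "stop": start + pd.Timedelta(days=b), "classes": c}
         for p, a, b, c in treatments],
        columns=["patient_id", "start", "stop", "classes"],
    )
    if not len(tr):
        tr = tr.astype({"start": "datetime64[ns]", "stop": "datetime64[ns]"})
    return CohortTables(patients=pat, labs=lab, events=ev, treatments=tr)


def simulate_mixed(rng, n_groups=50, group_size=4, beta=(10.0, -40.0),
                   sigma_b=15.0, sigma_e=60.0):
    """Simple random-intercept data for fitter tests: intercept + one slope."""
    rows = n_groups * group_size
    x = rng.normal(3.0, 1.0, size=rows)
    X = np.column_stack([np.ones(rows), x])
    groups = np.repeat(np.arange(n_groups), group_size)
    b = rng.normal(0.0, sigma_b, size=n_groups)
    y = X @ np.asarray(beta) + b[groups] + rng.normal(0.0, sigma_e, size=rows)
    return y, X, groups
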