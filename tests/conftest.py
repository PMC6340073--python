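import warnings

import pytest

import lipi


@pytest.fixture
def tiny_cohort() -> lipi.Cohort:
    """Hand-built three-patient cohort covering both outcomes and drug use."""
    def visit(pid, day, th17, b, mfi, sledai=4.0, drugs=()):
        return lipi.Visit(patient_id=pid, day=day,
                          features={"th17": th17, "b_cells": b, "tlr2_mfi": mfi},
                          sledai=sledai, bilag=2.0, prednisone_mg_day=5.0,
                          drugs=frozenset(drugs))

    p1 = lipi.PatientRecord(
        patient_id="P1", infected=True, infection_day=150, severe=False,
        followup_days=365,
        visits=(visit("P1", 0, 11.0, 47.0, 1500.0, sledai=12.0,
                      drugs=("cyclophosphamide",)),
                visit("P1", 30, 14.0, 40.0, 1400.0,
                      drugs=("cyclophosphamide",)),
                visit("P1", 90, 12.0, 44.0, 1450.0,
                      drugs=("cyclophosphamide",))))
    p2 = lipi.PatientRecord(
        patient_id="P2", infected=False, followup_days=365,
        visits=(visit("P2", 0, 3.0, 157.0, 8396.0),
                visit("P2", 30, 3.5, 150.0, 8000.0),
                visit("P2", 90, 2.5, 160.0, 8200.0)))
    p3 = lipi.PatientRecord(
        patient_id="P3", infected=False, followup_days=365,
        visits=(visit("P3", 0, 4.0, 200.0, 9000.0, drugs=("azathioprine",)),
                visit("P3", 30, 5.0, 210.0, 9100.0),
                visit("P3", 90, 4.5, 205.0, 9050.0)))
    return lipi.Cohort(patients=[p1, p2, p3])


@pytest.fixture(scope="session")
def strong_cohort() -> lipi.Cohort:
    """Synthetic cohort under the strong-effect outcome model (n=2000)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lipi.generate_cohort(lipi.default_config(n_patients=2000, seed=5))


@pytest.fixture(scope="session")
def published_index() -> lipi.IndexDefinition:
    return lipi.published_lipi()
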