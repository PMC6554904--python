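"""Shared fixtures: registries, code lists, and a small reference cohort."""

import numpy as np
import pandas as pd
import pytest

import readmorbid as rm
from readmorbid.synth_codes import build_synthetic_codelist


@pytest.fixture(scope="session")
def registry():
    return rm.default_registry()


@pytest.fixture(scope="session")
def codelists():
    """Full-size synthetic code lists for both measures."""
    return {m: build_synthetic_codelist(m) for m in ("charlson", "elixhauser")}


@pytest.fixture(scope="session")
def small_codelists(registry):
    """Tiny lists (3 codes per category) for fast, readable engine tests."""
    return {
        m: build_synthetic_codelist(m, n_codes=3 * len(registry.category_ids(m)))
        for m in ("charlson", "elixhauser")
    }


@pytest.fixture(scope="session")
def small_cohort(codelists):
    """One generated case-control cohort shared by read-only tests."""
    cfg = rm.GeneratorConfig(n_cases=400, seed=20240901)
    patients, events, flags = rm.generate_cohort(cfg, codelists)
    return cfg, patients, events, flags


def make_events(patient_id, dated_codes):
    """Event table from [(date, code), ...]."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "event_date": pd.to_datetime([d for d, _ in dated_codes]),
            "code": [c for _, c in dated_codes],
        }
    )


def first_code(codelist, category):
    """Any code of the given category (deterministic: first in list order)."""
    for e in codelist.entries:
        if e.category == category:
            return e.code
    raise LookupError(category)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
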