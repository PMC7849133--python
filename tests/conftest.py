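"""Shared fixtures: hand-written micro-tables and synthetic cohorts.

Expensive objects (the synthetic cohort, the trained model) are
session-scoped so the whole suite trains at most a handful of models.
"""

import warnings

import pandas as pd
import pytest

import driversvm as dv

# a tiny grid (two configs per kernel) for tests that only need *a* model
TINY_GRID = dv.build_parameter_grid(
    nu_values=(0.1, 0.3),
    gamma_values=(2.0**-5,),
    degrees=(2,),
    coef0_values=(1.0,),
)


@pytest.fixture(scope="session")
def tiny_grid():
    return TINY_GRID


@pytest.fixture()
def tiny_mutations() -> pd.DataFrame:
    rows = [
        # S1/KRAS: two damaging missense (one a hotspot) + one truncating
        ("S1", "KRAS", "missense", True, True),
        ("S1", "KRAS", "missense", True, False),
        ("S1", "KRAS", "stop_gained", False, False),
        # S1/GENEX: synonymous only -> not damaged
        ("S1", "GENEX", "synonymous", False, False),
        # S2/TP53: truncating
        ("S2", "TP53", "frameshift", False, False),
        # S2/GENEY: benign missense -> not damaged
        ("S2", "GENEY", "missense", False, False),
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "variant_class", "damaging_flag", "hotspot_flag"])


@pytest.fixture()
def tiny_cnvs() -> pd.DataFrame:
    rows = [
        ("S1", "MYC", 8.0),     # amplified at ploidy 2
        ("S1", "GENEZ", 2.0),   # neutral
        ("S2", "CDKN2A", 0.0),  # deleted
    ]
    return pd.DataFrame(rows, columns=["sample", "gene", "copy_number"])


@pytest.fixture()
def tiny_ploidy() -> pd.DataFrame:
    return pd.DataFrame({"sample": ["S1", "S2"], "ploidy": [2.0, 2.0]})


@pytest.fixture(scope="session")
def small_cohort() -> dv.FixtureCohort:
    """A small planted-driver cohort for fast pipeline-level tests."""
    spec = dv.FixtureSpec(n_genes=300, n_driver_genes=25, n_samples=30,
                          n_candidate_genes=20, n_false_positive_genes=10, seed=5)
    return dv.generate_fixture_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort) -> pd.DataFrame:
    molecular = dv.build_molecular_features(small_cohort.mutations, small_cohort.cnvs, small_cohort.ploidy)
    features, _ = dv.join_features(molecular, small_cohort.properties)
    return features


@pytest.fixture(scope="session")
def small_model(small_features, small_cohort) -> dv.TrainedModel:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dv.train(
            small_features, small_cohort.annotation, grid=TINY_GRID, max_iterations=8, window=5, seed=13
        )


@pytest.fixture(scope="session")
def small_predictions(small_model, small_features) -> pd.DataFrame:
    return dv.score_predictions(small_model, small_features)
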