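import logging

import pytest

import vmec

logging.getLogger("vmec").setLevel(logging.ERROR)


def small_config(seed: int = 0, **overrides) -> vmec.SimulationConfig:
    """Three small cohorts: fast to simulate, still multi-batch."""
    base = dict(
        cohort_ids=("a", "b", "c"),
        cohort_sizes=(24, 40, 24),
        ec_counts=(12, 18, 12),
        n_taxa=40,
        sequencing_depth_mean=2000,
        missingness_plan={
            "a": ("age", "bmi", "ethnicity", "ph"),
            "b": ("age", "bmi", "ethnicity", "ph"),
            "c": ("age",),
        },
        held_out="a",
        seed=seed,
    )
    base.update(overrides)
    return vmec.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return vmec.simulate_multicohort(small_config(seed=42))


@pytest.fixture(scope="session")
def default_study():
    """Full five-cohort design at a modest sequencing depth."""
    return vmec.simulate_multicohort(
        vmec.SimulationConfig(seed=7, sequencing_depth_mean=5000)
    )


@pytest.fixture()
def tiny_spec():
    """One-family, one-point grid with a single CV repeat for fast fits."""
    from vmec.ensemble import ModelSpec

    def make(**overrides):
        kw = dict(
            cv_repeats=1,
            grids={"bagged_trees": [{"n_estimators": 100, "max_features": "sqrt"}]},
            seed=5,
        )
        kw.update(overrides)
        return ModelSpec(**kw)

    return make
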