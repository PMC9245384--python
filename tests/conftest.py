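import numpy as np
import pandas as pd
import pytest

from rmasca import (
    GroupFactor,
    LongitudinalDataset,
    SimulationConfig,
    build_lipoprotein_registry,
    build_metabolite_registry,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def lipo_registry():
    return build_lipoprotein_registry()


@pytest.fixture(scope="session")
def met_registry():
    return build_metabolite_registry()


@pytest.fixture(scope="session")
def five_group_factor():
    return GroupFactor("group", ("Gr1", "Gr2", "Gr3", "Gr4", "Gr5"), coding="sum")


@pytest.fixture(scope="session")
def two_group_factor():
    return GroupFactor(
        "group", ("local", "locoregional"), coding="reference", reference_level="local"
    )


@pytest.fixture(scope="session")
def small_cohort(met_registry):
    """60-patient metabolite cohort with default planted effects, full noise."""
    cfg = SimulationConfig(
        registry=met_registry, n_patients=60,
        group_names=("Gr1", "Gr2", "Gr3", "Gr4", "Gr5"), seed=11,
    )
    return simulate_cohort(cfg)


def make_noiseless(registry, group_names, n_patients=20, seed=0, retention=None, **kwargs):
    """Noiseless cohort helper: observations equal their design-cell means."""
    cfg = SimulationConfig(
        registry=registry,
        n_patients=n_patients,
        group_names=group_names,
        random_intercept_sd=0.0,
        residual_sd=0.0,
        visit_retention=retention if retention is not None else (1.0,) * 5,
        seed=seed,
        **kwargs,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_cohort(met_registry):
    cfg, ds = make_noiseless(met_registry, ("Gr1", "Gr2", "Gr3", "Gr4", "Gr5"), n_patients=20)
    return cfg, ds
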