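import numpy as np
import pandas as pd
import pytest

from sedarich.glacier import MassBalanceParams, simulate_habitat
from sedarich.synthetic import (
    ScenarioConfig,
    default_truth,
    generate_catchment_dem,
    generate_temperature_series,
)
from sedarich.tables import EXTRACTION_CONTROL, NTC, SEDIMENT, SequenceTypeTable


@pytest.fixture(scope="session")
def config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def habitat_sim(config):
    """One full glacier + habitat simulation shared across the session."""
    dem = generate_catchment_dem(config, seed=0)
    temps = generate_temperature_series(config)
    params = MassBalanceParams()
    past = simulate_habitat(dem, temps.past, params, treeline=config.treeline)
    future = simulate_habitat(dem, temps.future, params, treeline=config.treeline)
    return dem, temps, past, future


@pytest.fixture(scope="session")
def cheap_habitat(config):
    """Hand-built habitat series with the canonical shape (no ice model).

    Full ice cover during the glacial, deglaciation by the 14-13 ka
    analogue, alpine maximum in the cool post-deglacial interval, a dip in
    the warm middle of the record, and partial recovery toward present.
    """
    ages = np.round(np.arange(config.age_old, config.age_young - 0.25, -0.5), 3)
    total = 18.0
    ice = np.where(ages >= 14.0, total, np.clip((ages - 13.0) * total, 0.0, total))
    habitable = total - ice
    frac_alpine = np.interp(ages, [0.0, 3.0, 7.0, 12.0, 13.5, 18.0],
                            [0.75, 0.75, 0.55, 0.95, 1.0, 1.0])
    alpine = habitable * frac_alpine
    return pd.DataFrame(
        {
            "dT": np.zeros_like(ages),
            "ice_km2": ice,
            "habitable_km2": habitable,
            "alpine_km2": alpine,
            "forest_km2": habitable - alpine,
        },
        index=pd.Index(ages, name="age"),
    )


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=0)


def build_toy_table():
    """Tiny hand-crafted table exercising every QC rule.

    Sequence types: t1 identity 1.0 (widespread), t2 identity 0.95,
    t3 identity 0.94, t4 identity 1.0 but present in one horizon only,
    t5 a Musaceae contaminant, t6 identity 1.0 low counts only.
    """
    meta = pd.DataFrame(
        {
            "taxon": ["Kobresia", "Saussurea", "Gentiana", "Rarus", "Musa", "Faintus"],
            "family": ["Cyperaceae", "Asteraceae", "Gentianaceae", "Rosaceae",
                       "Musaceae", "Poaceae"],
            "best_identity": [1.0, 0.95, 0.94, 1.0, 1.0, 1.0],
        },
        index=pd.Index([f"t{i}" for i in range(1, 7)], name="id"),
    )
    cols = {
        ("H1", 1): [30, 100, 40, 200, 15, 9],
        ("H1", 2): [70, 50, 10, 0, 0, 5],
        ("H2", 1): [500, 20, 0, 0, 12, 3],
        ("H3", 1): [0, 0, 0, 0, 0, 0],   # empty horizon
        ("EC1", 1): [0, 0, 0, 0, 0, 0],
        ("NTC1", 1): [0, 0, 0, 0, 0, 0],
    }
    counts = pd.DataFrame(cols, index=meta.index).astype(np.int64)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample", "replicate"])
    samples = pd.DataFrame(
        {
            "age": [1.0, 5.0, 9.0, np.nan, np.nan],
            "role": [SEDIMENT, SEDIMENT, SEDIMENT, EXTRACTION_CONTROL, NTC],
        },
        index=pd.Index(["H1", "H2", "H3", "EC1", "NTC1"], name="sample"),
    )
    return SequenceTypeTable(counts=counts, metadata=meta, samples=samples)


@pytest.fixture()
def toy_table():
    return build_toy_table()


def random_table(rng, n_taxa=12, n_samples=6, depth=2000):
    """Random sediment-only table for property tests."""
    ids = [f"sq{i}" for i in range(n_taxa)]
    meta = pd.DataFrame(
        {
            "taxon": [f"Taxon{i}" for i in range(n_taxa)],
            "family": [f"Family{i % 4}" for i in range(n_taxa)],
            "best_identity": rng.choice([1.0, 0.97], size=n_taxa),
        },
        index=pd.Index(ids, name="id"),
    )
    cols = {}
    for s in range(n_samples):
        for rep in (1, 2):
            w = rng.dirichlet(np.full(n_taxa, 0.5))
            cols[(f"S{s}", rep)] = rng.multinomial(depth + rng.integers(0, depth), w)
    counts = pd.DataFrame(cols, index=meta.index).astype(np.int64)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample", "replicate"])
    samples = pd.DataFrame(
        {"age": np.linspace(10, 1, n_samples), "role": [SEDIMENT] * n_samples},
        index=pd.Index([f"S{s}" for s in range(n_samples)], name="sample"),
    )
    return SequenceTypeTable(counts=counts, metadata=meta, samples=samples)
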