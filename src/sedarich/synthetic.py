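"""Synthetic study scenarios with known ground truth.

Emulates every input of the inference chain for a glaciated mountain
catchment: a bowl-shaped catchment DEM, a deglaciation-shaped temperature
anomaly series (cold glacial, warm early-to-mid interval, late cooling,
plus a future warming leg), a sequence-type count table with PCR-replicate
structure, laboratory controls and planted contaminants, and proxy series
(zero-inflated land-use indicator, smooth Mg/Ca).

The planted ground truth is a linear richness-habitat relationship:
expected horizon richness = baseline + slope * alpine area (km²) + noise,
with taxa drawn from niche pools ("alpine" taxa require alpine habitat,
"montane" taxa require forested, i.e. ice-free non-alpine, habitat;
"ubiquitous" taxa are always eligible).  Reads are multinomial over
log-normal relative abundances.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .glacier import MassBalanceParams, simulate_habitat
from .grids import ElevationGrid
from .tables import EXTRACTION_CONTROL, NTC, SEDIMENT, SequenceTypeTable

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "TemperatureSeries",
    "ScenarioBundle",
    "DEFAULT_BLACKLIST",
    "default_truth",
    "generate_catchment_dem",
    "generate_temperature_series",
    "generate_proxy_series",
    "generate_metabarcoding_dataset",
    "simulate_scenario",
]

#: presumed contaminants: fruit/cultivar taxa and groups absent from the
#: emulated high-mountain study region
DEFAULT_BLACKLIST = ["Musaceae", "PACMAD clade", "Lycopersicon", "BOP clade", "Maleae"]

_ALPINE_FAMILIES = (
    "Asteraceae", "Saxifragaceae", "Orobanchaceae", "Ranunculaceae",
    "Polygonaceae", "Gentianaceae", "Caryophyllaceae", "Crassulaceae",
)
_MONTANE_FAMILIES = ("Pinaceae", "Betulaceae", "Ericaceae", "Rosaceae", "Salicaceae")
_UBIQ_FAMILIES = ("Poaceae", "Cyperaceae", "Brassicaceae", "Fabaceae")


class ConfigurationError(ValueError):
    """Invalid scenario configuration."""


class AlignmentError(ValueError):
    """Habitat series does not cover the requested horizon ages."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-scenario geometry, sampling design and climate forcing.

    Defaults emulate the target system: 72 sediment horizons spanning
    18-0 ka with 2 PCR replicates each (one horizon yields no reads and is
    excluded during QC), a catchment between a 4,200 m
    valley floor and 4,900 m summits, per-replicate read depths of a few
    tens of thousands, and a +2.5 degC warming reached by 2300 CE.
    """

    n_horizons: int = 72
    age_old: float = 18.0   # ka BP
    age_young: float = 0.0
    replicates_per_horizon: int = 2
    read_depth_range: tuple[int, int] = (20_000, 60_000)
    grid_n: int = 48
    cellsize: float = 90.0  # m
    floor: float = 4200.0   # m a.s.l.
    summit: float = 4900.0
    future_warming: float = 2.5    # degC by 2300 CE
    step_past_yr: float = 500.0
    step_future_yr: float = 50.0
    landuse_onset: float = 3.6     # ka BP: zero land-use signal before this
    empty_horizon: bool = True     # plant one read-free sediment horizon
    contamination_budget: int = 0  # total reads allowed in controls
    treeline: float = 4400.0

    def __post_init__(self) -> None:
        if self.n_horizons < 1 or self.replicates_per_horizon < 1:
            raise ConfigurationError("need at least one horizon and one replicate")
        if self.age_old <= self.age_young:
            raise ConfigurationError("age_old must exceed age_young")
        if not (1000.0 <= self.floor <= self.summit <= 6000.0):
            raise ConfigurationError("relief must satisfy 1000 <= floor <= summit <= 6000 m")
        if self.grid_n < 32:
            raise ConfigurationError("grid must be at least 32x32")

    @property
    def horizon_ages(self) -> np.ndarray:
        return np.linspace(self.age_old, self.age_young, self.n_horizons)


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a generated dataset."""

    taxon_pool: list[tuple[str, str, str]]  # (taxon id, family, niche)
    richness_driver_slope: float = 2.0      # taxa per km² of alpine area
    baseline_richness: float = 15.0
    noise_sd: float = 2.0                   # taxa
    contaminant_ids: list[str] = field(default_factory=list)
    fraction_exact_identity: float = 0.8    # taxa with best identity == 1
    abundance_sigma: float = 0.7            # log-normal spread of abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.richness_driver_slope) or not np.isfinite(self.noise_sd):
            raise ConfigurationError("slope and noise_sd must be finite")
        ids = [t for t, _, _ in self.taxon_pool]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate taxon ids in pool")
        for _, fam, niche in self.taxon_pool:
            if niche not in {"alpine", "montane", "ubiquitous"}:
                raise ConfigurationError(f"unknown niche {niche!r}")
            if not fam:
                raise ConfigurationError("every taxon needs a family")


def default_truth(
    seed: int = 0,
    n_alpine: int = 60,
    n_montane: int = 40,
    n_ubiquitous: int = 20,
    slope: float = 2.0,
    noise_sd: float = 2.0,
    **kwargs,
) -> SyntheticTruth:
    """Default taxon pool: alpine-dominated flora plus planted contaminants."""
    pool: list[tuple[str, str, str]] = []
    for i in range(n_alpine):
        pool.append((f"alp_{i:03d}", _ALPINE_FAMILIES[i % len(_ALPINE_FAMILIES)], "alpine"))
    for i in range(n_montane):
        pool.append((f"mon_{i:03d}", _MONTANE_FAMILIES[i % len(_MONTANE_FAMILIES)], "montane"))
    for i in range(n_ubiquitous):
        pool.append((f"ubi_{i:03d}", _UBIQ_FAMILIES[i % len(_UBIQ_FAMILIES)], "ubiquitous"))
    contaminants = [
        ("Musa", "Musaceae"), ("Lycopersicon", "Solanaceae"),
        ("Zea", "PACMAD clade"), ("Malus", "Maleae"),
    ]
    for name, fam in contaminants:
        pool.append((name, fam, "ubiquitous"))
    return SyntheticTruth(
        taxon_pool=pool,
        richness_driver_slope=slope,
        noise_sd=noise_sd,
        contaminant_ids=[name for name, _ in contaminants],
        seed=seed,
        **kwargs,
    )


def generate_catchment_dem(config: ScenarioConfig, seed: int = 0) -> ElevationGrid:
    """Bowl-shaped catchment DEM between the configured floor and summits.

    A radial bowl (single closed basin draining to the centre) plus
    smoothed correlated noise, rescaled exactly to [floor, summit].
    """
    n = config.grid_n
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    r = np.hypot(yy - c, xx - c)
    base = (r / r.max()) ** 1.2
    relief = config.summit - config.floor
    if relief == 0:
        return ElevationGrid(z=np.full((n, n), config.floor), cellsize=config.cellsize)
    noise = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
    shape = base + 0.10 * noise / max(np.abs(noise).max(), 1e-12)
    shape = (shape - shape.min()) / (shape.max() - shape.min())
    z = config.floor + relief * shape
    return ElevationGrid(z=z, cellsize=config.cellsize)


@dataclass
class TemperatureSeries:
    """Temperature anomalies: past (ka BP, descending) and future (CE)."""

    past: pd.Series
    future: pd.Series


def generate_temperature_series(config: ScenarioConfig) -> TemperatureSeries:
    """Deglaciation-shaped anomaly series plus a future warming ramp.

    The past leg (500-yr steps, anomaly 0 at 0 ka by construction) runs
    from about -6 degC in the glacial through a deglacial warming, a warm
    early-to-mid interval near +0.9 degC, and a late cooling back to
    present.  The future leg (50-yr steps, 2050-2300 CE) ramps to the
    configured warming by 2300.
    """
    n = int(round((config.age_old - config.age_young) * 1000.0 / config.step_past_yr)) + 1
    ages = config.age_old - np.arange(n) * config.step_past_yr / 1000.0

    def shape(a: np.ndarray) -> np.ndarray:
        cold = -6.0 / (1.0 + np.exp(-(a - 15.0) / 1.0))
        warm = 0.9 * np.exp(-(((a - 7.5) / 2.5) ** 2))
        return cold + warm

    anomaly = shape(ages) - shape(np.array([config.age_young]))[0]
    past = pd.Series(anomaly, index=pd.Index(ages, name="age"), name="dT")

    years = np.arange(2050.0, 2300.0 + config.step_future_yr / 2, config.step_future_yr)
    frac = (years - 2050.0) / (2300.0 - 2050.0)
    future = pd.Series(
        config.future_warming * (0.5 + 0.5 * frac),
        index=pd.Index(years, name="year"),
        name="dT",
    )
    return TemperatureSeries(past=past, future=future)


def generate_proxy_series(
    config: ScenarioConfig, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """Land-use indicator (zero-inflated) and Mg/Ca (smooth positive) series.

    The land-use series is exactly zero at every age older than the onset
    and strictly positive afterwards; Mg/Ca is a smooth positive curve on
    the same age grid as the temperature series.
    """
    rng = np.random.default_rng(seed)
    ages = generate_temperature_series(config).past.index.to_numpy()
    frac = np.clip((config.landuse_onset - ages) / max(config.landuse_onset, 1e-9), 0.0, 1.0)
    land = np.where(ages > config.landuse_onset, 0.0,
                    0.02 + 0.5 * frac ** 1.5 + 0.05 * rng.random(len(ages)))
    smooth_noise = ndimage.gaussian_filter1d(rng.standard_normal(len(ages)), sigma=3.0)
    mgca = 2.0 + 0.6 * np.cos(2 * np.pi * ages / (config.age_old - config.age_young + 1e-9))
    mgca = np.clip(mgca + 0.15 * smooth_noise, 0.1, None)
    idx = pd.Index(ages, name="age")
    return (
        pd.Series(land, index=idx, name="land_use"),
        pd.Series(mgca, index=idx, name="mgca"),
    )


def _interp_on_ages(series: pd.Series, ages: np.ndarray) -> np.ndarray:
    s = series.sort_index()
    x = s.index.to_numpy(dtype=float)
    if ages.min() < x.min() - 1e-9 or ages.max() > x.max() + 1e-9:
        raise AlignmentError("habitat series does not cover all horizon ages")
    return np.interp(ages, x, s.to_numpy(dtype=float))


def generate_metabarcoding_dataset(
    truth: SyntheticTruth,
    habitat: pd.DataFrame,
    config: ScenarioConfig,
    seed: int | None = None,
) -> SequenceTypeTable:
    """Sequence-type count table with replicate structure and controls.

    Expected richness per horizon is ``baseline + slope * alpine_km2 +
    N(0, noise_sd)``; that many taxa are drawn from the niche-eligible
    pool, given log-normal relative abundances, and reads are multinomial
    per PCR replicate at a depth drawn from the configured range.
    Contaminant taxa are injected at low counts into a few horizons, and
    near-empty control samples (one extraction control, one NTC) are
    appended.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ages = config.horizon_ages
    alpine = _interp_on_ages(habitat["alpine_km2"], ages)
    forest = _interp_on_ages(habitat["forest_km2"], ages)

    genuine = [(t, f, n) for (t, f, n) in truth.taxon_pool if t not in set(truth.contaminant_ids)]
    contam = [(t, f, n) for (t, f, n) in truth.taxon_pool if t in set(truth.contaminant_ids)]
    all_ids = [t for t, _, _ in genuine + contam]

    # per-taxon best identity: a fixed fraction are perfect reference matches
    n_exact = int(round(truth.fraction_exact_identity * len(genuine)))
    exact_ids = set(rng.choice([t for t, _, _ in genuine], size=n_exact, replace=False))
    identity = {
        t: 1.0 if t in exact_ids else float(rng.uniform(0.95, 1.0 - 1e-6))
        for t, _, _ in genuine
    }
    identity.update({t: 1.0 for t, _, _ in contam})

    sample_ids = [f"S{i+1:03d}" for i in range(len(ages))]
    empty_idx = 2 if (config.empty_horizon and len(ages) > 3) else None

    columns: dict[tuple[str, int], np.ndarray] = {}
    for h, sample in enumerate(sample_ids):
        eligible = [
            t for t, _, niche in genuine
            if niche == "ubiquitous"
            or (niche == "alpine" and alpine[h] > 0)
            or (niche == "montane" and forest[h] > 0)
        ]
        expected = truth.baseline_richness + truth.richness_driver_slope * alpine[h]
        expected += rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        r = int(np.clip(round(expected), 1, len(eligible)))
        present = rng.choice(eligible, size=r, replace=False)
        weights = rng.lognormal(mean=0.0, sigma=truth.abundance_sigma, size=r)
        p = weights / weights.sum()
        for rep in range(1, config.replicates_per_horizon + 1):
            if h == empty_idx:
                columns[(sample, rep)] = np.zeros(len(all_ids), dtype=np.int64)
                continue
            depth = int(rng.integers(config.read_depth_range[0], config.read_depth_range[1] + 1))
            reads = rng.multinomial(depth, p)
            vec = np.zeros(len(all_ids), dtype=np.int64)
            for taxon, cnt in zip(present, reads):
                vec[all_ids.index(taxon)] = cnt
            columns[(sample, rep)] = vec

    # contaminants: low counts scattered over a handful of horizons each
    for taxon, _, _ in contam:
        idx = all_ids.index(taxon)
        hit_samples = rng.choice(len(sample_ids), size=min(4, len(sample_ids)), replace=False)
        for h in hit_samples:
            if h == empty_idx:
                continue
            rep = int(rng.integers(1, config.replicates_per_horizon + 1))
            columns[(sample_ids[h], rep)][idx] += int(rng.integers(10, 60))

    # controls: near-empty (total reads bounded by the contamination budget)
    control_specs = [("ECTRL1", EXTRACTION_CONTROL), ("NTC1", NTC)]
    for cid, _ in control_specs:
        vec = np.zeros(len(all_ids), dtype=np.int64)
        budget = config.contamination_budget
        if budget > 0:
            taxon = int(rng.integers(0, len(all_ids)))
            vec[taxon] = int(rng.integers(1, budget + 1))
        columns[(cid, 1)] = vec

    counts = pd.DataFrame(columns, index=pd.Index(all_ids, name="id"))
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample", "replicate"])
    metadata = pd.DataFrame(
        {
            "taxon": all_ids,
            "family": [f for _, f, _ in genuine + contam],
            "best_identity": [identity[t] for t in all_ids],
        },
        index=pd.Index(all_ids, name="id"),
    )
    samples = pd.DataFrame(
        {
            "age": list(ages) + [np.nan, np.nan],
            "role": [SEDIMENT] * len(ages) + [role for _, role in control_specs],
        },
        index=pd.Index(sample_ids + [cid for cid, _ in control_specs], name="sample"),
    )
    return SequenceTypeTable(counts=counts, metadata=metadata, samples=samples)


@dataclass
class ScenarioBundle:
    """Everything a pipeline run needs, with its ground truth attached."""

    config: ScenarioConfig
    truth: SyntheticTruth
    dem: ElevationGrid
    temperature: TemperatureSeries
    habitat_past: pd.DataFrame
    habitat_future: pd.DataFrame
    table: SequenceTypeTable
    land_use: pd.Series
    mgca: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dem.to_ascii(outdir / "dem.asc")
        self.temperature.past.to_csv(outdir / "temperature_past.csv")
        self.temperature.future.to_csv(outdir / "temperature_future.csv")
        self.habitat_past.to_csv(outdir / "habitat_past.csv")
        self.habitat_future.to_csv(outdir / "habitat_future.csv")
        self.table.to_tsv(outdir / "counts.tsv", outdir / "samples.csv")
        self.land_use.to_csv(outdir / "land_use.csv")
        self.mgca.to_csv(outdir / "mgca.csv")


def simulate_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    params: MassBalanceParams | None = None,
    habitat_past: pd.DataFrame | None = None,
    habitat_future: pd.DataFrame | None = None,
) -> ScenarioBundle:
    """Generate a full synthetic scenario (DEM, climate, habitat, dataset).

    Precomputed habitat series may be passed in to reuse one glacier
    simulation across many dataset seeds.
    """
    config = config or ScenarioConfig()
    truth = truth or default_truth(seed=seed)
    params = params or MassBalanceParams()
    dem = generate_catchment_dem(config, seed=truth.seed)
    temps = generate_temperature_series(config)
    if habitat_past is None:
        habitat_past = simulate_habitat(dem, temps.past, params, treeline=config.treeline)
    if habitat_future is None:
        habitat_future = simulate_habitat(dem, temps.future, params, treeline=config.treeline)
    table = generate_metabarcoding_dataset(truth, habitat_past, config, seed=seed)
    land_use, mgca = generate_proxy_series(config, seed=seed)
    return ScenarioBundle(
        config=config, truth=truth, dem=dem, temperature=temps,
        habitat_past=habitat_past, habitat_future=habitat_future,
        table=table, land_use=land_use, mgca=mgca,
    )
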