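"""Glacier-cover and habitat-area simulation for a mountain catchment.

Ice flow is modelled with the shallow-ice approximation (SIA): thickness H
on the elevation grid evolves as nonlinear diffusion of the ice surface
s = z + H,

    dH/dt = b(z) + div(D grad s),   D = (2A/(n+2)) (rho g)^n H^(n+2) |grad s|^(n-1),

with Glen exponent n and softness A, no basal sliding, and no flux across
the grid boundary.  The mass balance is a capped linear profile,
b = min(gradient * (z - ELA), b_max), and the equilibrium line altitude
(ELA) shifts with temperature anomaly via the integrated lapse rate,
ELA = ELA0 + dT / lapse.

Ice extent through time is taken from steady states precomputed on a ladder
of ELA values (nearest-ELA lookup), mirroring the treatment of glacier
cover as an equilibrium response to the slowly varying temperature series.
Habitat accounting is hypsometric: ice-free catchment cells are habitable,
and those above the temperature-shifted treeline are alpine habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import ElevationGrid

__all__ = [
    "MassBalanceParams",
    "IceState",
    "StabilityError",
    "ConvergenceError",
    "mass_balance",
    "ela_from_temperature",
    "sia_step",
    "steady_ice_mask",
    "ice_extent_series",
    "habitat_series",
    "simulate_habitat",
]

SECONDS = None  # all rates are in metres per year; no unit juggling needed


@dataclass(frozen=True)
class MassBalanceParams:
    """Mass-balance and ice-flow parameters.

    ela0
        Present-day equilibrium line altitude (m a.s.l.).
    b_max
        Cap on the accumulation rate (m ice yr^-1).
    gradient
        Mass-balance gradient (m yr^-1 per m of elevation).
    lapse
        Integrated temperature lapse rate (degC per m); 0.0055 is
        0.55 degC per 100 m.
    flow_a
        Glen's-law softness A (Pa^-n yr^-1).
    glen_n
        Glen flow exponent.
    rho, g
        Ice density (kg m^-3) and gravity (m s^-2).
    h_min
        Minimum thickness (m) for a cell to count as ice-covered;
        suppresses numerically thin halos.
    """

    ela0: float = 5200.0
    b_max: float = 0.25
    gradient: float = 0.0115
    lapse: float = 0.0055
    flow_a: float = 1e-16
    glen_n: int = 3
    rho: float = 910.0
    g: float = 9.81
    h_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ela0", "b_max", "gradient", "lapse", "flow_a", "rho", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.glen_n < 1:
            raise ValueError("glen_n must be >= 1")

    @property
    def gamma(self) -> float:
        """Diffusivity prefactor 2A (rho g)^n / (n + 2)."""
        return 2.0 * self.flow_a * (self.rho * self.g) ** self.glen_n / (self.glen_n + 2)


@dataclass
class IceState:
    """Ice thickness field (m) and model time (yr)."""

    thickness: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if (self.thickness < 0).any():
            raise ValueError("negative ice thickness")


class StabilityError(RuntimeError):
    """Explicit time step exceeds the diffusion stability bound."""

    def __init__(self, dt: float, dt_max: float):
        super().__init__(
            f"dt={dt:g} yr violates the explicit stability bound; use dt <= {dt_max:g} yr"
        )
        self.suggested_dt = dt_max


class ConvergenceError(RuntimeError):
    """Steady-state iteration did not converge within the year budget."""


def mass_balance(z: np.ndarray | float, ela: float, params: MassBalanceParams) -> np.ndarray | float:
    """Capped linear mass balance b = min(gradient*(z - ELA), b_max), m yr^-1."""
    return np.minimum(params.gradient * (np.asarray(z, dtype=float) - ela), params.b_max)


def ela_from_temperature(dt_degc: float, params: MassBalanceParams) -> float:
    """ELA shifted by a temperature anomaly through the lapse rate."""
    return params.ela0 + dt_degc / params.lapse


def _face_diffusivity(H: np.ndarray, s: np.ndarray, dx: float, params: MassBalanceParams, axis: int):
    grad = np.diff(s, axis=axis) / dx
    # donor-cell thickness: the higher-surface neighbour feeds the flux, so
    # cells without ice never export mass
    h_lo = H.take(range(H.shape[axis] - 1), axis=axis)
    h_hi = H.take(range(1, H.shape[axis]), axis=axis)
    h_face = np.where(grad > 0, h_hi, h_lo)
    D = params.gamma * h_face ** (params.glen_n + 2) * np.abs(grad) ** (params.glen_n - 1)
    return D, grad


def stable_dt(state: IceState, grid: ElevationGrid, params: MassBalanceParams,
              safety: float = 0.2) -> float:
    """Largest explicit step honouring dt <= safety * dx^2 / max(D)."""
    s = grid.z + state.thickness
    dmax = 0.0
    for axis in (0, 1):
        D, _ = _face_diffusivity(state.thickness, s, grid.cellsize, params, axis)
        if D.size:
            dmax = max(dmax, float(D.max()))
    if dmax == 0.0:
        return np.inf
    return safety * grid.cellsize ** 2 / dmax


def sia_step(
    state: IceState,
    grid: ElevationGrid,
    ela: float,
    dt: float,
    params: MassBalanceParams,
    apply_balance: bool = True,
) -> IceState:
    """Advance the ice sheet one explicit step of ``dt`` years.

    Flux-form update with donor-cell face diffusivity and zero flux across
    the grid boundary; thickness is clipped at zero after the ablation
    term.  Raises :class:`StabilityError` (with a suggested step) if ``dt``
    exceeds the explicit-diffusion bound for the current state.
    """
    H = state.thickness
    dt_max = stable_dt(state, grid, params, safety=0.5)
    if dt > dt_max:
        raise StabilityError(dt, dt_max)
    s = grid.z + H
    dx = grid.cellsize
    dH = np.zeros_like(H)
    for axis in (0, 1):
        D, grad = _face_diffusivity(H, s, dx, params, axis)
        q = -D * grad  # m^2 yr^-1, positive toward increasing index
        div = np.diff(q, axis=axis) / dx
        inner = [slice(None)] * 2
        inner[axis] = slice(1, -1)
        dH[tuple(inner)] -= div
        # boundary cells: one-sided divergence (no flux through the wall)
        first = [slice(None)] * 2
        first[axis] = 0
        last = [slice(None)] * 2
        last[axis] = -1
        dH[tuple(first)] -= q.take([0], axis=axis).squeeze(axis) / dx
        dH[tuple(last)] += q.take([-1], axis=axis).squeeze(axis) / dx
    H_new = H + dt * dH
    if apply_balance:
        H_new = H_new + dt * mass_balance(grid.z, ela, params)
    H_new = np.maximum(H_new, 0.0)
    return IceState(thickness=H_new, time=state.time + dt)


def steady_ice_mask(
    grid: ElevationGrid,
    ela: float,
    params: MassBalanceParams,
    vol_tol: float = 1e-3,
    max_years: float = 10000.0,
    check_years: float = 100.0,
    mask_patience: int = 3,
    dt_cap: float = 5.0,
    initial: IceState | None = None,
) -> tuple[IceState, np.ndarray]:
    """Integrate to a steady glacier for a fixed ELA.

    Convergence when the relative volume change per ``check_years`` model
    years drops below ``vol_tol``, or when the ice mask (H > h_min) is
    unchanged over ``mask_patience`` consecutive checks (covers the
    all-accumulation regime where volume grows but extent is fixed).
    """
    state = initial if initial is not None else IceState(np.zeros_like(grid.z))
    state = IceState(state.thickness.copy(), 0.0)
    prev_vol = float(state.thickness.sum())
    prev_mask = state.thickness > params.h_min
    stable_checks = 0
    while state.time < max_years:
        t_next = state.time + check_years
        while state.time < t_next:
            dt = min(dt_cap, 0.9 * stable_dt(state, grid, params), t_next - state.time)
            state = sia_step(state, grid, ela, dt, params)
        vol = float(state.thickness.sum())
        mask = state.thickness > params.h_min
        rel = abs(vol - prev_vol) / vol if vol > 0 else 0.0
        stable_checks = stable_checks + 1 if (mask == prev_mask).all() else 0
        if rel < vol_tol or stable_checks >= mask_patience:
            return state, mask
        prev_vol, prev_mask = vol, mask
    raise ConvergenceError(
        f"no steady ice state within {max_years} model years at ELA {ela:.0f} m "
        f"(last relative volume change {rel:.2e})"
    )


def ice_extent_series(
    grid: ElevationGrid,
    temps: pd.Series,
    params: MassBalanceParams,
    ela_ladder_step: float = 50.0,
    **steady_kwargs,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Ice masks through time from steady states on an ELA ladder.

    ``temps`` maps time (index) to temperature anomaly (degC).  Steady
    states are computed once per ladder ELA, coldest first (warm-started
    from the previous, larger glacier), and each time step takes the mask
    of the nearest ladder entry.  Returns a per-step frame (dT, ELA, ice
    area) and the list of ice masks aligned with it.
    """
    elas = np.array([ela_from_temperature(t, params) for t in temps.to_numpy()])
    lo = np.floor(elas.min() / ela_ladder_step) * ela_ladder_step
    hi = np.ceil(elas.max() / ela_ladder_step) * ela_ladder_step
    ladder = np.arange(lo, hi + ela_ladder_step / 2, ela_ladder_step)
    masks_by_ela: dict[float, np.ndarray] = {}
    state: IceState | None = None
    for ela in ladder:  # cold (low ELA) -> warm, shrinking from the previous state
        state, mask = steady_ice_mask(grid, ela, params, initial=state, **steady_kwargs)
        masks_by_ela[float(ela)] = mask & grid.mask
    rows, masks = [], []
    for t, ela in zip(temps.index, elas):
        nearest = float(ladder[np.argmin(np.abs(ladder - ela))])
        mask = masks_by_ela[nearest]
        masks.append(mask)
        rows.append((float(temps.loc[t]), ela, mask.sum() * grid.cell_area_km2))
    frame = pd.DataFrame(rows, index=temps.index, columns=["dT", "ela", "ice_km2"])
    return frame, masks


def habitat_series(
    grid: ElevationGrid,
    masks: list[np.ndarray],
    temps: pd.Series,
    treeline: float = 4400.0,
    params: MassBalanceParams | None = None,
    band_lo: float = 1000.0,
    band_hi: float = 6000.0,
    band_width: float = 100.0,
) -> pd.DataFrame:
    """Hypsometric habitat accounting under shifting treeline and ice cover.

    Per step: the effective treeline is the modern treeline shifted by
    dT / lapse; habitable area is the ice-free catchment; alpine area the
    ice-free cells at or above the effective treeline; band areas partition
    the habitable area into 100-m elevation bands.  All areas in km².
    """
    params = params or MassBalanceParams()
    if len(masks) != len(temps):
        raise ValueError("ice masks and temperature series are misaligned")
    edges = np.arange(band_lo, band_hi + band_width, band_width)
    band_cols = [f"band_{int(e)}" for e in edges[:-1]]
    rows = []
    for (t, dT), ice in zip(temps.items(), masks):
        z_tl = treeline + dT / params.lapse
        free = grid.mask & ~ice
        habitable = float(free.sum()) * grid.cell_area_km2
        alpine = float((free & (grid.z >= z_tl)).sum()) * grid.cell_area_km2
        bands = grid.band_areas(band_lo, band_hi, band_width, where=free)
        rows.append(
            [dT, ela_from_temperature(dT, params), z_tl,
             float(ice[grid.mask].sum()) * grid.cell_area_km2,
             habitable, alpine, habitable - alpine, *bands]
        )
    cols = ["dT", "ela", "treeline_eff", "ice_km2", "habitable_km2", "alpine_km2",
            "forest_km2", *band_cols]
    return pd.DataFrame(rows, index=temps.index, columns=cols)


def simulate_habitat(
    grid: ElevationGrid,
    temps: pd.Series,
    params: MassBalanceParams | None = None,
    treeline: float = 4400.0,
    ela_ladder_step: float = 50.0,
    **steady_kwargs,
) -> pd.DataFrame:
    """End-to-end: temperature series -> ice masks -> habitat series."""
    params = params or MassBalanceParams()
    _, masks = ice_extent_series(grid, temps, params, ela_ladder_step, **steady_kwargs)
    return habitat_series(grid, masks, temps, treeline=treeline, params=params)
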