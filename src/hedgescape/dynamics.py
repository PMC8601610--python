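"""Coupled predator-pest reaction-diffusion dynamics over one season.

State variables (densities, saturation-level units):

* ``u`` — pest density per 2D cell (pests km^-2).  Logistic growth with
  carrying capacity ``C_it`` on crop, exponential mortality on non-crop,
  predation loss everywhere; diffuses freely across all field borders.
* ``v_field`` — predator density per 2D cell.  Mortality plus numerical
  response to pests; diffusion blocked by hedge-labelled borders (the
  predator transits hedges through the migration exchange instead).
* ``v_hedge`` — predator density per 1D hedge node (per km).  Logistic
  growth to the hedge carrying capacity, 1D diffusion continuous across
  hedge junctions.

Time stepping is operator-split within each reporting day: implicit
(backward-Euler) diffusion solves, an explicit conservative hedge-field
exchange, and exact exponential/logistic reaction maps that keep densities
nonnegative by construction.  Pesticide triggering and pest inoculations
happen on the daily grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .landscape import LandscapeAllocation, Tessellation
from .mesh import Mesh, build_mesh

__all__ = [
    "SpeciesParams",
    "PesticideConfig",
    "InoculationConfig",
    "SimState",
    "RunSummary",
    "Integrator",
    "step",
    "exchange_interface",
    "apply_pesticide_rule",
    "advance_pesticide",
    "draw_inoculation_schedule",
    "inoculate",
    "initial_state",
    "run_simulation",
]

SEASON_LENGTH = 100.0  # days in a cropping season


@dataclass
class SpeciesParams:
    """Demographic and movement parameters of predator and pest.

    Units: diffusion km^2 d^-1, rates d^-1, predation pest^-1 d^-1,
    carrying capacities are density saturation levels.  Migration is the
    hedge-field exchange: ``rho21`` (field to hedge) exceeds ``rho12``
    (hedge to field) because the predator is reluctant to leave its
    habitat.
    """

    d2v: float = 0.0063125  # predator 2D diffusion
    d1v: float = 0.012  # predator 1D diffusion along hedges
    m_v: float = 1.0 / 43.0  # predator mortality in fields
    beta: float = 0.01  # predating rate
    r_v: float = 0.015  # predator growth on hedges
    k_hedge: float = 1.0  # hedge carrying capacity
    rho12: float = 0.025  # hedge -> field migration
    rho21: float = 0.05  # field -> hedge migration
    d2u: float = 0.0063125  # pest 2D diffusion
    r_u: float = 0.015  # pest growth on crop
    k_field: float = 20.0  # crop carrying capacity for the pest
    m_u: float = 1.0 / 43.0  # pest mortality on non-crop

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.rho12 > self.rho21:
            raise ValueError(
                f"rho12 ({self.rho12}) must not exceed rho21 ({self.rho21}): "
                "hedge-to-field migration is lower than field-to-hedge"
            )


@dataclass
class PesticideConfig:
    """Threshold rule reducing the pest carrying capacity.

    An application divides the field's carrying capacity by
    ``reduction_factor`` for ``duration`` days; the default factor 200
    corresponds to a 99.5% pest reduction at saturation.
    """

    threshold: float = 0.2  # field-mean pest density triggering a spray
    reduction_factor: float = 200.0
    duration: float = 10.0  # days of efficacy

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.reduction_factor < 1:
            raise ValueError(
                f"reduction_factor must be >= 1, got {self.reduction_factor}"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def efficacy(self) -> float:
        """Fraction of the saturation pest density removed (e.g. 0.995)."""
        return 1.0 - 1.0 / self.reduction_factor


@dataclass
class InoculationConfig:
    """Random pest arrivals over the season.

    The expected number of events is ``max_mean_events`` multiplied by the
    crop area fraction.  Each event deposits a Gaussian patch of pest
    density — peak ``amount``, length scale ``spatial_spread`` — at a
    random point of a crop field picked proportionally to its area.  The
    patch is discretized mass-conservatively (total inoculum
    ``amount * 2 * pi * spatial_spread^2`` per event regardless of mesh
    resolution) and its peak stays well below the crop carrying capacity,
    so early outbreak growth is density-independent.  The default amount
    seeds a typical field at the order of the spray threshold: an arrival
    makes the threshold rule active in that field, unchecked outbreaks
    then grow towards saturation, while strong predator pressure near
    hedges can still keep fields below the trigger.
    """

    max_mean_events: float = 25.0
    amount: float = 1.5  # peak pest density of a deposited patch (pests km^-2)
    spatial_spread: float = 0.1  # Gaussian patch scale (km)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_mean_events < 0:
            raise ValueError(
                f"max_mean_events must be >= 0, got {self.max_mean_events}"
            )


@dataclass
class SimState:
    t: float
    u: np.ndarray  # pest density per cell
    v_field: np.ndarray  # predator density per cell
    v_hedge: np.ndarray  # predator density per hedge node
    C: np.ndarray  # current pest carrying capacity per polygon
    k_base: np.ndarray  # carrying capacity without pesticide per polygon
    pesticide_timers: np.ndarray  # remaining efficacy days per polygon
    clipped_mass: float = 0.0

    def copy(self) -> "SimState":
        return SimState(
            self.t,
            self.u.copy(),
            self.v_field.copy(),
            self.v_hedge.copy(),
            self.C.copy(),
            self.k_base.copy(),
            self.pesticide_timers.copy(),
            self.clipped_mass,
        )


@dataclass
class RunSummary:
    """Season-level outputs of one simulation run."""

    mean_pest: float  # space-time mean pest density over crop cells
    mean_predator: float  # space-time mean predator density over crop cells
    n_applications_total: int
    n_applications: np.ndarray  # per polygon
    application_presence: np.ndarray  # per polygon, bool
    presence_any: bool
    event_log: list  # dicts: {type, day, polygon}
    daily_pest: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    daily_predator: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    final_u: np.ndarray | None = None
    cell_mean_predator: np.ndarray | None = None


def initial_state(mesh: Mesh, params: SpeciesParams) -> SimState:
    """Season start: predators at carrying capacity in hedges, nothing else."""
    n_poly = len(mesh.poly_cells)
    return SimState(
        t=0.0,
        u=np.zeros(mesh.n_cells),
        v_field=np.zeros(mesh.n_cells),
        v_hedge=np.full(mesh.n_hedge_nodes, params.k_hedge),
        C=np.full(n_poly, params.k_field),
        k_base=np.full(n_poly, params.k_field),
        pesticide_timers=np.zeros(n_poly),
    )


def _logistic_map(x: np.ndarray, r: float, K: np.ndarray | float, dt: float):
    """Exact solution map of x' = r x (1 - x/K) over dt (K > 0)."""
    if r == 0:
        return x
    e = math.exp(r * dt)
    return K * x * e / (K + x * (e - 1.0))


class Integrator:
    """Operator-split integrator with cached implicit-diffusion factors."""

    def __init__(self, mesh: Mesh, params: SpeciesParams, dt: float):
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        self.mesh = mesh
        self.params = params
        self.dt = dt
        n = mesh.n_cells
        eye = sp.identity(n, format="csc")
        self._lu_u = splu((eye - dt * params.d2u * mesh.lap2d_pest).tocsc())
        self._lu_v = splu((eye - dt * params.d2v * mesh.lap2d_pred).tocsc())
        if mesh.n_hedge_nodes:
            eh = sp.identity(mesh.n_hedge_nodes, format="csc")
            self._lu_h = splu((eh - dt * params.d1v * mesh.lap1d).tocsc())
        else:
            self._lu_h = None
        self._frac = mesh.cell_crop_frac  # crop area fraction per cell

    def step(self, state: SimState) -> SimState:
        """Advance the state in place by one internal step of length dt."""
        mesh, p, dt = self.mesh, self.params, self.dt
        # implicit diffusion
        state.u = self._lu_u.solve(state.u)
        state.v_field = self._lu_v.solve(state.v_field)
        if self._lu_h is not None and mesh.n_hedge_nodes:
            state.v_hedge = self._lu_h.solve(state.v_hedge)
        # hedge <-> field predator exchange (conservative, explicit)
        dv_field, dv_hedge = exchange_interface(state, mesh, p, dt)
        state.v_field += dv_field
        state.v_hedge += dv_hedge
        # reactions: exact exponential / logistic maps (positivity
        # preserving); border cells blend the crop and non-crop one-step
        # maps by the cell's crop area fraction
        u, v = state.u, state.v_field
        f = self._frac
        u_before = u.copy()
        Ccell = state.C[mesh.cell_polygon]
        u_crop = _logistic_map(u, p.r_u, Ccell, dt)
        u_non = u * math.exp(-p.m_u * dt)
        state.u = u = f * u_crop + (1.0 - f) * u_non
        if p.beta:
            u *= np.exp(-p.beta * v * dt)
        v *= np.exp((p.beta * u_before - p.m_v) * dt)
        if mesh.n_hedge_nodes and p.r_v:
            state.v_hedge = _logistic_map(state.v_hedge, p.r_v, p.k_hedge, dt)
        # bookkeeping
        for arr, weight in ((state.u, mesh.cell_area), (state.v_field, mesh.cell_area)):
            neg = arr < 0
            if neg.any():
                state.clipped_mass += float(-arr[neg].sum() * weight)
                arr[neg] = 0.0
        if mesh.n_hedge_nodes:
            neg = state.v_hedge < 0
            if neg.any():
                state.clipped_mass += float(
                    -(state.v_hedge[neg] * mesh.hnode_len[neg]).sum()
                )
                state.v_hedge[neg] = 0.0
        if not (
            np.isfinite(state.u).all()
            and np.isfinite(state.v_field).all()
            and np.isfinite(state.v_hedge).all()
        ):
            raise RuntimeError(
                f"non-finite density at t={state.t + dt:.3f} "
                f"(dt={dt}, max u={np.max(state.u, initial=0.0):.3g})"
            )
        state.t += dt
        return state


def step(
    state: SimState, mesh: Mesh, params: SpeciesParams, dt_internal: float
) -> SimState:
    """Advance one internal step (convenience wrapper around Integrator)."""
    return Integrator(mesh, params, dt_internal).step(state)


def exchange_interface(
    state: SimState, mesh: Mesh, params: SpeciesParams, dt: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Predator migration increments between hedges and bordering cells.

    Per hedge node of control length l bordering a cell: the hedge gains
    ``rho21 * v_field`` per unit length and day from each bordering side,
    and loses ``rho12 * v_hedge`` split over its sides; the matching
    individual counts (density times l, resp. times cell area) are moved
    so the exchange conserves total individuals exactly.
    """
    dv_field = np.zeros_like(state.v_field)
    dv_hedge = np.zeros_like(state.v_hedge)
    if mesh.n_hedge_nodes == 0 or (params.rho12 == 0 and params.rho21 == 0):
        return dv_field, dv_hedge
    node, cell = mesh.if_node, mesh.if_cell
    nsides = np.maximum(mesh.if_nsides[node], 1)
    # linear extrapolation of the field density to the hedge line
    v_trace = np.clip(
        1.5 * state.v_field[cell] - 0.5 * state.v_field[mesh.if_cell2], 0.0, None
    )
    f2h = params.rho21 * v_trace  # per km of hedge, per day
    h2f = params.rho12 * state.v_hedge[node] / nsides
    np.add.at(dv_hedge, node, (f2h - h2f) * dt)
    np.add.at(
        dv_field,
        cell,
        (h2f - f2h) * mesh.hnode_len[node] / mesh.cell_area * dt,
    )
    return dv_field, dv_hedge


def apply_pesticide_rule(
    state: SimState, mesh: Mesh, config: PesticideConfig
) -> list[dict]:
    """Daily spray decision: trigger where the field-mean pest density
    strictly exceeds the threshold and no application is active."""
    means = mesh.polygon_means(state.u)
    trigger = (
        mesh.crop_polygon
        & (state.pesticide_timers <= 0)
        & (means > config.threshold)
    )
    events = []
    for i in np.flatnonzero(trigger):
        state.C[i] = state.k_base[i] / config.reduction_factor
        state.pesticide_timers[i] = config.duration
        events.append({"type": "pesticide", "day": state.t, "polygon": int(i)})
    return events


def advance_pesticide(
    state: SimState, config: PesticideConfig, dt: float = 1.0
) -> None:
    """Decrement efficacy timers; expired fields revert to full capacity."""
    active = state.pesticide_timers > 0
    state.pesticide_timers[active] -= dt
    expired = active & (state.pesticide_timers <= 0)
    state.C[expired] = state.k_base[expired]
    state.pesticide_timers[state.pesticide_timers < 0] = 0.0


def draw_inoculation_schedule(
    tess: Tessellation,
    alloc: LandscapeAllocation,
    config: InoculationConfig,
    season_length: float = SEASON_LENGTH,
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """Random arrival schedule: N ~ Poisson(max_mean_events * crop area
    fraction); each event gets a uniform day, a crop field drawn
    proportionally to area, and a uniform location inside it."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    areas = np.array([p.area for p in tess.polygons])
    crop = np.asarray(alloc.crop_label, dtype=bool)
    p_area = float(areas[crop].sum() / areas.sum())
    n_events = rng.poisson(config.max_mean_events * p_area)
    if n_events == 0 or not crop.any():
        return []
    crop_idx = np.flatnonzero(crop)
    probs = areas[crop_idx] / areas[crop_idx].sum()
    events = []
    for _ in range(n_events):
        day = float(rng.uniform(0.0, season_length))
        poly = int(rng.choice(crop_idx, p=probs))
        x, y = _uniform_point_in_polygon(tess.polygons[poly], rng)
        events.append({"type": "inoculation", "day": day, "polygon": poly,
                       "x": x, "y": y})
    return sorted(events, key=lambda e: e["day"])


def _uniform_point_in_polygon(poly, rng: np.random.Generator):
    from shapely.geometry import Point

    minx, miny, maxx, maxy = poly.bounds
    for _ in range(1000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.contains(Point(x, y)):
            return float(x), float(y)
    c = poly.centroid  # pragma: no cover - pathological geometry
    return float(c.x), float(c.y)


def _deposit(state: SimState, mesh: Mesh, x: float, y: float, amount: float,
             radius: float) -> None:
    """Deposit a Gaussian pest patch, conserving its total mass exactly.

    The target mass is ``amount * 2 pi radius^2`` (the integral of the
    Gaussian profile); kernel weights are renormalised on the grid so the
    deposited mass is resolution independent.
    """
    centers = mesh.cell_centroids()
    d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
    w = np.exp(-d2 / (2.0 * radius**2))
    w[d2 > (4.0 * radius) ** 2] = 0.0
    if w.sum() <= 0:  # pragma: no cover - point outside any kernel support
        w[int(np.argmin(d2))] = 1.0
    mass = amount * 2.0 * math.pi * radius**2
    state.u += mass * w / (w.sum() * mesh.cell_area)


def inoculate(
    state: SimState,
    mesh: Mesh,
    tess: Tessellation,
    alloc: LandscapeAllocation,
    config: InoculationConfig,
    season_length: float = SEASON_LENGTH,
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """Draw a season's arrival schedule and deposit every event at once."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = draw_inoculation_schedule(tess, alloc, config, season_length, rng)
    for e in events:
        _deposit(state, mesh, e["x"], e["y"], config.amount, config.spatial_spread)
    return events


def run_simulation(
    tess: Tessellation,
    alloc: LandscapeAllocation,
    params: SpeciesParams | None = None,
    pesticide: PesticideConfig | None = None,
    inoculation: InoculationConfig | None = None,
    seed: int | None = None,
    *,
    resolution: float = 0.15,
    dt_internal: float = 0.1,
    season_length: float = SEASON_LENGTH,
    mesh: Mesh | None = None,
    keep_fields: bool = False,
) -> RunSummary:
    """Integrate one cropping season and summarise it.

    Densities start at zero except predators at carrying capacity in all
    hedges.  Each reporting day: scheduled inoculations are deposited,
    the dynamics advance by ``1 / dt_internal`` internal substeps, then
    efficacy timers tick and the spray rule is evaluated per crop field.
    """
    params = params or SpeciesParams()
    pesticide = pesticide or PesticideConfig()
    inoculation = inoculation or InoculationConfig()
    if mesh is None:
        mesh = build_mesh(tess, alloc, resolution)
    rng = np.random.default_rng(seed)
    schedule = draw_inoculation_schedule(
        tess, alloc, inoculation, season_length, rng
    )
    state = initial_state(mesh, params)
    integ = Integrator(mesh, params, dt_internal)
    n_sub = max(1, int(round(1.0 / dt_internal)))

    n_days = int(round(season_length))
    n_poly = tess.n_polygons
    n_apps = np.zeros(n_poly, dtype=int)
    event_log: list[dict] = list()
    daily_pest = np.zeros(n_days)
    daily_pred = np.zeros(n_days)
    # area weights of crop cover per cell, for space averages over crop fields
    crop_rows = np.flatnonzero(mesh.crop_polygon)
    if len(crop_rows):
        w_crop = np.asarray(mesh.poly_weights[crop_rows].sum(axis=0)).ravel()
    else:
        w_crop = np.zeros(mesh.n_cells)
    w_total = w_crop.sum()
    v_accum = np.zeros(mesh.n_cells)

    ev_i = 0
    for day in range(n_days):
        while ev_i < len(schedule) and schedule[ev_i]["day"] < day + 1:
            e = schedule[ev_i]
            _deposit(state, mesh, e["x"], e["y"], inoculation.amount,
                     inoculation.spatial_spread)
            event_log.append(e)
            ev_i += 1
        for _ in range(n_sub):
            integ.step(state)
        advance_pesticide(state, pesticide, 1.0)
        events = apply_pesticide_rule(state, mesh, pesticide)
        for e in events:
            n_apps[e["polygon"]] += 1
        event_log.extend(events)
        if w_total > 0:
            daily_pest[day] = float(w_crop @ state.u) / w_total
            daily_pred[day] = float(w_crop @ state.v_field) / w_total
        v_accum += state.v_field

    return RunSummary(
        mean_pest=float(daily_pest.mean()),
        mean_predator=float(daily_pred.mean()),
        n_applications_total=int(n_apps.sum()),
        n_applications=n_apps,
        application_presence=n_apps > 0,
        presence_any=bool(n_apps.sum() > 0),
        event_log=event_log,
        daily_pest=daily_pest,
        daily_predator=daily_pred,
        final_u=state.u.copy() if keep_fields else None,
        cell_mean_predator=v_accum / n_days if keep_fields else None,
    )
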