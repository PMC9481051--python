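"""Size-structured phytoplankton-zooplankton steady states.

Each of ``n_classes`` phytoplankton size classes is paired with a
zooplankton class grazing on it; grazing pressure scales with a feeding
factor proportional to mean prey size.  Phytoplankton grow at
diffusion-supported division rates and die only by grazing (baseline);
zooplankton suffer linear and density-dependent mortality.  Steady states
are taken from the closed-form coexistence fixed point by default, with
forward-Euler integration available as a cross-check and for variants
whose outcome depends on the transient (low initial stocks plus
non-grazing mortality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffusion import TransportContext, solve_mu
from .errors import (DegenerateEquilibrium, DegenerateFit, DimensionError,
                     DomainError, NegativeStock, NonFinite)
from .size_spectrum import Group

LN2 = math.log(2.0)
FG_PER_MMOL_N = 1.4e13  # 14 mg N per mmol, in fg


@dataclass(frozen=True)
class SizeClassGrid:
    """Geometric grid of size classes with per-class feeding factors."""

    d: np.ndarray  # diameters, um
    f: np.ndarray  # feeding factors, dimensionless (= d / 1 um)
    groups: tuple[Group, ...]  # phytoplankton types per class

    @property
    def n_classes(self) -> int:
        return self.d.size

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def build_grid(n_classes: int = 25, multispecies: bool = False,
               group: Group | str = Group.non_diatom) -> SizeClassGrid:
    """Geometric size grid d_i = 0.6 * 1.25**(i-1) um.

    The feeding factor is the width of a predator's prey-size range,
    (1.5 - 0.5) * d_i / 1 um = d_i.  ``multispecies`` duplicates every
    class into a diatom and a non-diatom population sharing one grazer.
    """
    if n_classes < 1:
        raise DomainError("need at least one size class")
    d = 0.6 * 1.25 ** np.arange(n_classes)
    groups = ((Group.non_diatom, Group.diatom) if multispecies
              else (Group(group),))
    return SizeClassGrid(d=d, f=d.copy(), groups=groups)


@dataclass(frozen=True)
class EcosystemParams:
    """Grazing and integration constants (all printed defaults)."""

    g1: float = 3.24  # grazing rate, m^3 mmol^-1 d^-1
    g2: float = 0.5  # ingestion efficiency
    g3: float = 0.06  # linear zooplankton mortality, d^-1
    g4: float = 1.6  # density-dependent zooplankton mortality, m^3 mmol^-1 d^-1
    dt: float = 1.0 / 96.0  # d (~15 minutes)
    t_max: float = 1095.0  # d (3 years)
    extinct_frac: float = 1e-6  # 0.0001% biomass threshold
    p_init: float = 0.18  # mmol N m^-3
    z_init: float = 0.04  # mmol N m^-3

    def __post_init__(self):
        for name in ("g1", "g2", "g3", "g4", "dt", "t_max", "extinct_frac",
                     "p_init", "z_init"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


@dataclass(frozen=True)
class VariantOptions:
    """Deltas from the baseline loss structure."""

    m_loss: float = 0.0  # non-grazing phytoplankton mortality, d^-1
    kappa: float = 0.0  # outflow rate applied to both stocks, d^-1
    use_g4: bool = True
    per_generation_m: float = 0.0  # loss per generation (rate = m*mu/ln2)
    ward_init: bool = False  # initialize stocks at 1e-10 mmol N m^-3

    def __post_init__(self):
        if min(self.m_loss, self.kappa, self.per_generation_m) < 0:
            raise DomainError("loss rates must be non-negative")

    def phyto_loss(self, mu: np.ndarray) -> np.ndarray:
        """Total non-grazing specific loss rate on phytoplankton (d^-1)."""
        return (self.m_loss + self.kappa
                + self.per_generation_m * np.asarray(mu) / LN2)


BASELINE = VariantOptions()


@dataclass
class EcosystemState:
    """Phytoplankton (per group, per class) and zooplankton nitrogen stocks."""

    p: np.ndarray  # shape (n_groups, n_classes), mmol N m^-3
    z: np.ndarray  # shape (n_classes,), mmol N m^-3
    t: float = 0.0

    def copy(self) -> "EcosystemState":
        return EcosystemState(p=self.p.copy(), z=self.z.copy(), t=self.t)


def initial_state(grid: SizeClassGrid, params: EcosystemParams,
                  variants: VariantOptions = BASELINE) -> EcosystemState:
    p0 = 1e-10 if variants.ward_init else params.p_init
    z0 = 1e-10 if variants.ward_init else params.z_init
    return EcosystemState(
        p=np.full((grid.n_groups, grid.n_classes), p0),
        z=np.full(grid.n_classes, z0), t=0.0)


def derivatives(state: EcosystemState, mu: np.ndarray, grid: SizeClassGrid,
                params: EcosystemParams,
                variants: VariantOptions = BASELINE):
    """Time derivatives (dP, dZ) of all stocks, mmol N m^-3 d^-1.

    dP_i = mu_i P_i - g1 f_i Z_i P_i - loss_i P_i
    dZ_i = g1 g2 f_i Z_i sum_types(P_i) - g3 Z_i - g4 f_i Z_i^2 - kappa Z_i
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    p, z, f = state.p, state.z, grid.f
    if p.shape != (grid.n_groups, grid.n_classes) or mu.shape != p.shape \
            or z.shape != (grid.n_classes,):
        raise DimensionError("state/mu shapes do not match the size grid")
    loss = variants.phyto_loss(mu)
    dp = (mu - params.g1 * f * z - loss) * p
    p_tot = p.sum(axis=0)
    dz = (params.g1 * params.g2 * f * p_tot - params.g3
          - (params.g4 * f * z if variants.use_g4 else 0.0)
          - variants.kappa) * z
    return dp, dz


@dataclass(frozen=True)
class SteadyState:
    """Equilibrium stocks plus community diagnostics."""

    p_star: np.ndarray  # (n_groups, n_classes)
    z_star: np.ndarray  # (n_classes,)
    mu: np.ndarray  # (n_groups, n_classes)
    diversity: int
    method: str
    sds: float | None = None
    cells_per_ml: np.ndarray | None = None

    @property
    def total_p(self) -> float:
        return float(self.p_star.sum())


def analytic_fixed_point(mu, grid: SizeClassGrid, params: EcosystemParams,
                         variants: VariantOptions = BASELINE,
                         quotas_fg: np.ndarray | None = None) -> SteadyState:
    """Closed-form coexistence equilibrium of the grazing equations.

    Per class: Z* balances the phytoplankton equation, Z* = (mu - loss) /
    (g1 f); P* then balances the zooplankton equation.  In multispecies
    mode the shared grazer equilibrates with the faster-growing type and
    the slower type decays to zero (trophic exclusion).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if mu.shape != (grid.n_groups, grid.n_classes):
        raise DimensionError("mu shape does not match the size grid")
    pure_baseline = variants == BASELINE or (
        variants.phyto_loss(mu).max() == 0.0)
    if pure_baseline and np.any(mu <= 0):
        raise DegenerateEquilibrium(
            "non-positive division rate admits no coexistence equilibrium")

    f = grid.f
    net = mu - variants.phyto_loss(mu)  # net growth available to offset grazing
    winner = np.argmax(net, axis=0)
    idx = np.arange(grid.n_classes)
    net_w = net[winner, idx]

    z_star = np.where(net_w > 0, net_w / (params.g1 * f), 0.0)
    p_tot = np.where(
        net_w > 0,
        (params.g3 + variants.kappa
         + (params.g4 * f * z_star if variants.use_g4 else 0.0))
        / (params.g1 * params.g2 * f),
        0.0)
    p_star = np.zeros_like(mu)
    p_star[winner, idx] = p_tot

    diversity = _diversity(p_star, params.extinct_frac)
    cells = sds = None
    if quotas_fg is not None:
        cells = to_cell_abundance(p_star, quotas_fg)
        sds = size_distribution_slope(cells.sum(axis=0), grid)
    return SteadyState(p_star=p_star, z_star=z_star, mu=mu,
                       diversity=diversity, method="analytic",
                       sds=sds, cells_per_ml=cells)


def _diversity(p_star: np.ndarray, extinct_frac: float) -> int:
    total = p_star.sum()
    if total <= 0:
        raise DomainError("total phytoplankton biomass is zero")
    return int(np.count_nonzero(p_star / total >= extinct_frac))


def diversity_count(steady: SteadyState, extinct_frac: float = 1e-6) -> int:
    """Number of populations holding at least ``extinct_frac`` of biomass."""
    return _diversity(steady.p_star, extinct_frac)


@dataclass
class Trajectory:
    """Sparse record of an Euler integration."""

    times: np.ndarray
    p: np.ndarray  # (n_records, n_groups, n_classes)
    z: np.ndarray  # (n_records, n_classes)
    final: EcosystemState = field(default=None)
    converged: bool = False
    t_converged: float | None = None


def integrate(state0: EcosystemState, mu, grid: SizeClassGrid,
              params: EcosystemParams, variants: VariantOptions = BASELINE,
              record_every: float = 5.0,
              rel_tol_per_day: float = 1e-8) -> Trajectory:
    """Forward-Euler integration of the stock equations.

    Steps at ``params.dt`` until ``params.t_max`` or until the maximum
    relative change of any stock over one day falls below
    ``rel_tol_per_day``.  Raises on negative or non-finite stocks.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if params.dt <= 0:
        raise DomainError("dt must be positive")
    if np.any(state0.p < 0) or np.any(state0.z < 0):
        raise DomainError("initial stocks must be non-negative")

    state = state0.copy()
    steps_per_day = max(1, round(1.0 / params.dt))
    n_steps = int(round(params.t_max / params.dt))
    rec_stride = max(1, int(round(record_every / params.dt)))
    times, ps, zs = [state.t], [state.p.copy()], [state.z.copy()]
    day_ref_p, day_ref_z = state.p.copy(), state.z.copy()
    converged, t_conv = False, None

    for k in range(1, n_steps + 1):
        dp, dz = derivatives(state, mu, grid, params, variants)
        state.p += params.dt * dp
        state.z += params.dt * dz
        state.t = state0.t + k * params.dt
        if not (np.all(np.isfinite(state.p)) and np.all(np.isfinite(state.z))):
            raise NonFinite(f"non-finite stock at t={state.t:.3f} d")
        if np.any(state.p < 0) or np.any(state.z < 0):
            raise NegativeStock(
                f"negative stock at t={state.t:.3f} d; reduce dt")
        if k % rec_stride == 0:
            times.append(state.t)
            ps.append(state.p.copy())
            zs.append(state.z.copy())
        if k % steps_per_day == 0:
            scale = np.maximum(np.abs(day_ref_p), 1e-300)
            rel_p = np.max(np.abs(state.p - day_ref_p) / scale)
            scale_z = np.maximum(np.abs(day_ref_z), 1e-300)
            rel_z = np.max(np.abs(state.z - day_ref_z) / scale_z)
            if max(rel_p, rel_z) < rel_tol_per_day:
                converged, t_conv = True, state.t
                break
            day_ref_p, day_ref_z = state.p.copy(), state.z.copy()

    times.append(state.t)
    ps.append(state.p.copy())
    zs.append(state.z.copy())
    return Trajectory(times=np.asarray(times), p=np.asarray(ps),
                      z=np.asarray(zs), final=state,
                      converged=converged, t_converged=t_conv)


def to_cell_abundance(p_star: np.ndarray, quotas_fg: np.ndarray) -> np.ndarray:
    """Cells per ml from per-class nitrogen stocks and cell quotas.

    n = P [mmol N m^-3] * 1.4e13 [fg N mmol^-1] / Q [fg N] per m^3,
    divided by 1e6 ml per m^3.
    """
    p_star = np.asarray(p_star, dtype=float)
    quotas_fg = np.asarray(quotas_fg, dtype=float)
    if np.any(quotas_fg <= 0):
        raise DomainError("quotas must be positive")
    return p_star * FG_PER_MMOL_N / quotas_fg / 1e6


def size_distribution_slope(cells_per_ml: np.ndarray,
                            grid: SizeClassGrid) -> float:
    """Signed OLS slope of log10(n/width) against log10(diameter).

    Bin widths follow the geometric grid, delta_d = d*(1.25**0.5 -
    1.25**-0.5).  Only classes with positive abundance enter the fit.
    """
    n = np.asarray(cells_per_ml, dtype=float)
    if n.shape != grid.d.shape:
        raise DimensionError("abundance vector does not match the grid")
    mask = n > 0
    if mask.sum() < 2:
        raise DegenerateFit("need >= 2 classes with positive abundance")
    width = grid.d * (1.25**0.5 - 1.25**-0.5)
    x = np.log10(grid.d[mask])
    y = np.log10(n[mask] / width[mask])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def growth_rates(grid: SizeClassGrid, s_inf_nm: float,
                 velocity_dialect: str = "bracket_only"):
    """Per-population diffusion-supported division rates and quotas.

    Returns (mu, quotas_fg) arrays of shape (n_groups, n_classes) for
    far-field nitrogen at ``s_inf_nm`` nM.
    """
    ctx = TransportContext(s_inf=s_inf_nm, velocity_dialect=velocity_dialect)
    mu = np.zeros((grid.n_groups, grid.n_classes))
    q = np.zeros_like(mu)
    for gi, group in enumerate(grid.groups):
        for ci, d in enumerate(grid.d):
            sol = solve_mu(float(d), group, ctx)
            mu[gi, ci] = sol.mu
            q[gi, ci] = sol.q
    return mu, q


def default_nutrient_grid() -> np.ndarray:
    """Far-field nitrogen grid (nM): 7-nM steps from 1 to 35, then 200-nM
    steps up to 20 uM."""
    low = np.array([1.0, 8.0, 15.0, 22.0, 29.0, 35.0])
    high = np.arange(200.0, 20000.0 + 1.0, 200.0)
    return np.concatenate([low, high])


def steady_state(grid: SizeClassGrid, s_inf_nm: float,
                 params: EcosystemParams | None = None,
                 variants: VariantOptions = BASELINE,
                 method: str = "analytic",
                 velocity_dialect: str = "bracket_only") -> SteadyState:
    """Steady state at one far-field nutrient concentration."""
    params = params or EcosystemParams()
    mu, quotas = growth_rates(grid, s_inf_nm, velocity_dialect)
    if method == "analytic":
        return analytic_fixed_point(mu, grid, params, variants, quotas)
    if method != "integrate":
        raise DomainError(f"unknown steady-state method {method!r}")
    traj = integrate(initial_state(grid, params, variants), mu, grid,
                     params, variants)
    p_star, z_star = traj.final.p, traj.final.z
    diversity = _diversity(p_star, params.extinct_frac)
    cells = to_cell_abundance(p_star, quotas)
    cls_cells = cells.sum(axis=0)
    try:
        sds = size_distribution_slope(cls_cells, grid)
    except DegenerateFit:
        sds = None
    return SteadyState(p_star=p_star, z_star=z_star, mu=mu,
                       diversity=diversity, method="integrated",
                       sds=sds, cells_per_ml=cells)


def run_nutrient_grid(s_inf_grid=None, n_classes: int = 25,
                      group: Group | str = Group.non_diatom,
                      multispecies: bool = False,
                      params: EcosystemParams | None = None,
                      variants: VariantOptions = BASELINE,
                      method: str = "analytic",
                      velocity_dialect: str = "bracket_only") -> pd.DataFrame:
    """Steady-state diagnostics across a nutrient grid.

    Returns a DataFrame with one row per far-field concentration:
    s_inf_nm, diversity, sds, total_P.
    """
    if s_inf_grid is None:
        s_inf_grid = default_nutrient_grid()
    params = params or EcosystemParams()
    grid = build_grid(n_classes, multispecies=multispecies, group=group)
    rows = []
    for s in np.asarray(s_inf_grid, dtype=float):
        st = steady_state(grid, float(s), params, variants, method,
                          velocity_dialect)
        rows.append({"s_inf_nm": float(s), "diversity": st.diversity,
                     "sds": st.sds, "total_P": st.total_p})
    return pd.DataFrame(rows)
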