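"""Diffusion-supported, acclimated division rates for single cells.

For a cell of given diameter, group (swimming non-diatom vs sinking
diatom) and far-field nutrient concentration, the available nutrient flux
is the perfect-absorber diffusive flux enhanced by a Sherwood factor for
relative motion and a 90% capture efficiency.  Feeding that flux through
the acclimated rectangular-hyperbola response and a growth-rate-dependent
quota yields the realized division rate, found by iterating the N:C ratio
and division rate to a stable pair.

Units: lengths um, time s for transport (converted to d^-1 for rates),
nitrogen currency fg N, phosphorus currency fmol P.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ConvergenceError, DomainError
from .size_spectrum import CarbonVolumeModel, Group

SECONDS_PER_DAY = 86400.0
N_GRAMS_PER_MOL = 14.0
LN2 = math.log(2.0)

#: Quadratic envelope of maximum doublings per day is negative just below
#: the 15-um branch switch; values there are clamped to zero.
_ENVELOPE_NEGATIVE_ABOVE = 14.986


def carbon_content(d: float, group: Group | str = Group.non_diatom) -> float:
    """Cellular carbon content (pg C) for a spherical cell of diameter d."""
    return CarbonVolumeModel(group=Group(group)).carbon_pg(d)


def mu_max_envelope(d: float) -> float:
    """Size-dependent maximum division rate (d^-1).

    Quadratic in diameter below 15 um, power law at and above 15 um; both
    branches are maximum doublings per day scaled by ln(2).  The quadratic
    dips below zero just under 15 um and is clamped there.
    """
    if d <= 0:
        raise DomainError("cell diameter must be positive")
    if d < 15.0:
        doublings = -0.0555 * d**2 + 0.789 * d + 0.64
        if doublings < 0.0:
            warnings.warn(
                f"division-rate envelope negative at d={d:g} um; clamped to 0",
                RuntimeWarning, stacklevel=2)
            doublings = 0.0
    else:
        doublings = 9.29 * d ** (-0.533)
    return doublings * LN2


def nc_of_mu(mu: float) -> float:
    """Nitrogen:carbon mass ratio (fg N per fg C) at division rate ``mu``."""
    if mu < 0:
        raise DomainError("division rate must be non-negative")
    return 0.0762 * mu + 0.0389


def swimming_velocity(d: float, dialect: str = "bracket_only") -> float:
    """Characteristic swimming velocity (um s^-1) for non-diatoms.

    ``bracket_only`` (default) evaluates 93*(d/1e4)**0.26 directly in
    um s^-1; ``as_printed`` retains a trailing 1e4 factor that yields
    cm-per-second-scale speeds and is kept only for comparison.
    """
    if d <= 0:
        raise DomainError("cell diameter must be positive")
    v = 93.0 * (d / 1.0e4) ** 0.26
    if dialect == "as_printed":
        return v * 1.0e4
    if dialect != "bracket_only":
        raise DomainError(f"unknown velocity dialect {dialect!r}")
    return v


def sinking_velocity(d: float) -> float:
    """Characteristic sinking velocity (um s^-1) for diatoms; 0 below 8 um."""
    if d <= 0:
        raise DomainError("cell diameter must be positive")
    if d < 8.0:
        return 0.0
    return max(0.0, (0.0007 * math.log(d / 20000.0) + 0.0056) * 1.0e4)


def peclet(d: float, v: float, D: float) -> float:
    """Peclet number d*v/D (dimensionless)."""
    if D <= 0:
        raise DomainError("diffusion coefficient must be positive")
    if d < 0 or v < 0:
        raise DomainError("diameter and velocity must be non-negative")
    return d * v / D


def sherwood(pe: float) -> float:
    """Sherwood flux-enhancement factor, 0.5*(1 + (1 + 2*Pe)**(1/3))."""
    if pe < 0:
        raise DomainError("Peclet number must be non-negative")
    return 0.5 * (1.0 + (1.0 + 2.0 * pe) ** (1.0 / 3.0))


@dataclass(frozen=True)
class TransportContext:
    """Physical context for nutrient transport to a cell.

    ``s_inf`` is in nM of the limiting element; fluxes come out in fg N
    per day (element "N") or fmol P per day (element "P").
    """

    s_inf: float  # nM
    D: float = 1500.0  # um^2 s^-1
    s0: float = 0.0  # perfect absorber
    capture_eff: float = 0.9
    velocity_dialect: str = "bracket_only"
    element: str = "N"
    np_ratio: float = 16.0

    def __post_init__(self):
        if self.D <= 0:
            raise DomainError("diffusion coefficient must be positive")
        if self.s_inf < 0:
            raise DomainError("far-field concentration must be non-negative")
        if self.s0 != 0.0:
            raise DomainError("surface concentration is fixed at 0")
        if not 0 < self.capture_eff <= 1:
            raise DomainError("capture efficiency must lie in (0, 1]")
        if self.element not in ("N", "P"):
            raise DomainError("element must be 'N' or 'P'")

    @property
    def s_inf_per_um3(self) -> float:
        """Far-field concentration per um^3 in the element's currency.

        1 nM N = 1.4e-8 fg N um^-3; 1 nM P = 1e-9 fmol P um^-3.
        """
        if self.element == "N":
            return self.s_inf * 1e-9 * N_GRAMS_PER_MOL  # fg um^-3
        return self.s_inf * 1e-9  # fmol um^-3


def diffusive_flux(d: float, ctx: TransportContext) -> float:
    """Perfect-absorber diffusive flux 2*pi*d*D*S_inf, per day."""
    if d <= 0:
        raise DomainError("cell diameter must be positive")
    return 2.0 * math.pi * d * ctx.D * ctx.s_inf_per_um3 * SECONDS_PER_DAY


def volume_specific_flux(d: float, ctx: TransportContext) -> float:
    """Diffusive flux per unit cell volume; scales as 1/d^2."""
    return diffusive_flux(d, ctx) / (math.pi / 6.0 * d**3)


def group_velocity(d: float, group: Group | str,
                   dialect: str = "bracket_only") -> float:
    """Characteristic relative velocity for a group: swim or sink."""
    group = Group(group)
    if group is Group.non_diatom:
        return swimming_velocity(d, dialect)
    return sinking_velocity(d)


def available_flux(d: float, group: Group | str, ctx: TransportContext) -> float:
    """Potential flux available for assimilation: capture_eff * Sh * F_D."""
    v = group_velocity(d, group, ctx.velocity_dialect)
    sh = sherwood(peclet(d, v, ctx.D))
    return ctx.capture_eff * sh * diffusive_flux(d, ctx)


@dataclass(frozen=True)
class CellPhenotype:
    """One modeled size class: diameter, group and derived rate traits."""

    d: float  # um
    group: Group = Group.non_diatom
    c_pg: float = field(default=0.0)  # pg C cell^-1
    mu_max: float = field(default=0.0)  # d^-1
    nc_max: float = field(default=0.0)  # fg N per fg C at mu_max
    v_max_fg: float = field(default=0.0)  # fg N cell^-1 d^-1

    @classmethod
    def from_diameter(cls, d: float, group: Group | str = Group.non_diatom,
                      mu_max_override: float | None = None) -> "CellPhenotype":
        group = Group(group)
        c = carbon_content(d, group)
        mu_max = mu_max_override if mu_max_override is not None \
            else mu_max_envelope(d)
        if mu_max <= 0:
            raise DomainError("maximum division rate must be positive")
        nc_max = nc_of_mu(mu_max)
        # V_m is the nitrogen uptake needed to sustain mu_max: 1000 converts
        # pg C to fg C.
        v_max_fg = 1000.0 * nc_max * c * mu_max
        return cls(d=d, group=group, c_pg=c, mu_max=mu_max,
                   nc_max=nc_max, v_max_fg=v_max_fg)

    def quota_fg(self, mu: float) -> float:
        """Cellular nitrogen quota (fg N) at division rate ``mu``."""
        return nc_of_mu(mu) * 1000.0 * self.c_pg


@dataclass(frozen=True)
class GrowthSolution:
    """Converged diffusion-supported division rate with flux bookkeeping."""

    mu: float  # d^-1
    nc: float  # fg N per fg C
    q: float  # quota at realized mu (fg N, or fmol P for element P)
    f_d: float  # diffusive flux, per day
    sh: float
    pe: float
    a_f: float  # available flux, per day
    assim: float  # assimilation rate, per day
    iterations: int
    converged: bool
    phenotype: CellPhenotype


def _currency_divisor(ctx: TransportContext) -> float:
    """fg N -> context currency: 1 for N, 14*np_ratio (fg N per fmol P) for P."""
    if ctx.element == "N":
        return 1.0
    return N_GRAMS_PER_MOL * ctx.np_ratio


def solve_mu(d: float, group: Group | str, ctx: TransportContext,
             mu_max_override: float | None = None,
             tol: float = 1e-6, max_iter: int = 25) -> GrowthSolution:
    """Realized division rate under diffusion-supplied nutrient.

    The assimilation rate is the rectangular hyperbola of available flux
    and maximum uptake; the division rate then balances assimilation
    against the rate-dependent quota, ``mu * Q(mu) = assim``.  The balance
    is found by successive substitution in (N:C, mu) starting from the
    quota at mu_max, with Aitken acceleration so the pair stabilizes well
    within 25 iterations at all saturation levels.
    """
    group = Group(group)
    mu_max = mu_max_override if mu_max_override is not None \
        else mu_max_envelope(d)
    if mu_max <= 0.0:
        # inside the clamped sliver of the envelope: no growth possible
        c = carbon_content(d, group)
        pheno = CellPhenotype(d=d, group=group, c_pg=c, mu_max=0.0,
                              nc_max=nc_of_mu(0.0), v_max_fg=0.0)
        v = group_velocity(d, group, ctx.velocity_dialect)
        pe = peclet(d, v, ctx.D)
        sh = sherwood(pe)
        f_d = diffusive_flux(d, ctx)
        div0 = _currency_divisor(ctx)
        return GrowthSolution(mu=0.0, nc=nc_of_mu(0.0),
                              q=pheno.quota_fg(0.0) / div0, f_d=f_d, sh=sh,
                              pe=pe, a_f=ctx.capture_eff * sh * f_d,
                              assim=0.0, iterations=0, converged=True,
                              phenotype=pheno)
    pheno = CellPhenotype.from_diameter(d, group, mu_max)
    v = group_velocity(d, pheno.group, ctx.velocity_dialect)
    pe = peclet(d, v, ctx.D)
    sh = sherwood(pe)
    f_d = diffusive_flux(d, ctx)
    a_f = ctx.capture_eff * sh * f_d

    div = _currency_divisor(ctx)
    v_max = pheno.v_max_fg / div  # context currency per day

    if a_f + v_max <= 0 or a_f == 0:
        q0 = pheno.quota_fg(0.0) / div
        return GrowthSolution(mu=0.0, nc=nc_of_mu(0.0), q=q0, f_d=f_d,
                              sh=sh, pe=pe, a_f=a_f, assim=0.0,
                              iterations=0, converged=True, phenotype=pheno)

    assim = a_f * v_max / (a_f + v_max)

    def quota(mu: float) -> float:
        return pheno.quota_fg(mu) / div

    def step(mu: float) -> float:
        return assim / quota(mu)

    mu = assim / quota(pheno.mu_max)
    converged = False
    iterations = 0
    while iterations < max_iter:
        mu1 = step(mu)
        iterations += 1
        if abs(mu1 - mu) < tol:
            mu = mu1
            converged = True
            break
        mu2 = step(mu1)
        iterations += 1
        if abs(mu2 - mu1) < tol:
            mu = mu2
            converged = True
            break
        denom = mu2 - 2.0 * mu1 + mu
        mu = mu2 if denom == 0 else mu - (mu1 - mu) ** 2 / denom
        if mu < 0:
            mu = mu2
    if not converged:
        raise ConvergenceError(
            f"division-rate iteration not stable after {max_iter} iterations",
            last_iterate=mu)
    return GrowthSolution(mu=mu, nc=nc_of_mu(mu), q=quota(mu), f_d=f_d,
                          sh=sh, pe=pe, a_f=a_f, assim=assim,
                          iterations=iterations, converged=True,
                          phenotype=pheno)


def chemostat_prediction(d: float, mu_max: float, s_inf_list,
                         group: Group | str = Group.non_diatom,
                         np_ratio: float = 16.0,
                         velocity_dialect: str = "bracket_only") -> list[GrowthSolution]:
    """Predicted division rates for phosphate-limited chemostat cultures.

    Runs the nitrogen-calibrated machinery in phosphorus currency: the
    quota is Q_N / (14 * N:P) in fmol P and the flux is computed for the
    given far-field PO4 concentrations (nM).
    """
    if d <= 0 or mu_max <= 0:
        raise DomainError("diameter and mu_max must be positive")
    out = []
    for s in s_inf_list:
        ctx = TransportContext(s_inf=float(s), element="P", np_ratio=np_ratio,
                               velocity_dialect=velocity_dialect)
        out.append(solve_mu(d, group, ctx, mu_max_override=mu_max))
    return out
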