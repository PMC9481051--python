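"""Two-parameter production-resource curve forms and least-squares fitting.

Short-term responses (photosynthesis vs irradiance, uptake vs substrate)
follow a saturating hyperbolic tangent; acclimated responses (division
rate vs growth irradiance or substrate) follow a rectangular hyperbola.
The acclimated nutrient form is algebraically a Michaelis-Menten curve
with half-saturation ``km_cell = v_max / alpha_v``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, DomainError


@dataclass(frozen=True)
class PICurve:
    """Short-term photosynthesis-irradiance tanh curve."""

    p_max: float  # d^-1
    alpha_p: float  # m^2 (mol quanta)^-1

    def __post_init__(self):
        if self.p_max <= 0 or self.alpha_p <= 0:
            raise DomainError("PICurve parameters must be positive")

    @property
    def i_k(self) -> float:
        """Light-saturation index, p_max / alpha_p."""
        return self.p_max / self.alpha_p


@dataclass(frozen=True)
class MuIgCurve:
    """Acclimated division rate vs growth irradiance (rectangular hyperbola)."""

    mu_max: float  # d^-1
    alpha_mu: float  # m^2 (mol quanta)^-1, rate units
    i_r: float  # mol quanta m^-2 d^-1

    def __post_init__(self):
        if self.mu_max <= 0 or self.alpha_mu <= 0:
            raise DomainError("MuIgCurve maxima and slope must be positive")
        if self.i_r < 0:
            raise DomainError("compensation irradiance must be non-negative")

    @property
    def i_k(self) -> float:
        return self.mu_max / self.alpha_mu


@dataclass(frozen=True)
class UptakeCurve:
    """Short-term nutrient uptake vs far-field substrate (tanh curve)."""

    v_max: float  # mmol cell^-1 d^-1
    alpha_v: float  # dm^3 d^-1 cell^-1

    def __post_init__(self):
        if self.v_max <= 0 or self.alpha_v <= 0:
            raise DomainError("UptakeCurve parameters must be positive")

    @property
    def km_cell(self) -> float:
        """Emergent half-saturation of acclimated growth, v_max / alpha_v."""
        return self.v_max / self.alpha_v


@dataclass(frozen=True)
class MichaelisEquivalent:
    """Michaelis-Menten equivalent of the acclimated nutrient response."""

    vm_star: float  # d^-1
    km: float  # mmol m^-3
    m_loss: float = 0.0  # d^-1

    def __post_init__(self):
        if self.km <= 0:
            raise DomainError("half-saturation must be positive")

    def net_rate(self, s_inf: float) -> float:
        """Specific net growth rate at far-field concentration ``s_inf``."""
        if s_inf < 0:
            raise DomainError("substrate concentration must be non-negative")
        return self.vm_star * s_inf / (s_inf + self.km) - self.m_loss


def pi_rate(curve: PICurve, irradiance: float) -> float:
    """Short-term photosynthetic rate P = p_max * tanh(alpha_p*I/p_max)."""
    if np.any(np.asarray(irradiance) < 0):
        raise DomainError("irradiance must be non-negative")
    return curve.p_max * np.tanh(curve.alpha_p * irradiance / curve.p_max)


def mu_from_light(curve: MuIgCurve, ig: float) -> float:
    """Acclimated division rate at growth irradiance ``ig``.

    Rectangular hyperbola in the net light (ig - i_r), clamped to zero
    below the compensation point.
    """
    net = np.asarray(ig, dtype=float) - curve.i_r
    a = curve.alpha_mu * net
    mu = np.where(net > 0, a * curve.mu_max / (a + curve.mu_max), 0.0)
    return float(mu) if np.isscalar(ig) else mu


def uptake_rate(curve: UptakeCurve, s_inf: float) -> float:
    """Short-term uptake v = v_max * tanh(alpha_v*S/v_max)."""
    if np.any(np.asarray(s_inf) < 0):
        raise DomainError("substrate concentration must be non-negative")
    return curve.v_max * np.tanh(curve.alpha_v * s_inf / curve.v_max)


def mu_from_substrate(curve: UptakeCurve, q: float, s_inf: float) -> float:
    """Acclimated division rate from uptake capacity and quota.

    mu = (alpha_v*S*v_max / (alpha_v*S + v_max)) / q, identically equal to
    mu_max * S / (S + km_cell) with mu_max = v_max / q.
    """
    if q <= 0:
        raise DomainError("cell quota must be positive")
    if np.any(np.asarray(s_inf) < 0):
        raise DomainError("substrate concentration must be non-negative")
    a = curve.alpha_v * np.asarray(s_inf, dtype=float)
    out = a * curve.v_max / (a + curve.v_max) / q
    return float(out) if np.isscalar(s_inf) else out


def michaelis_equivalent(curve: UptakeCurve, q: float,
                         m_loss: float = 0.0) -> MichaelisEquivalent:
    """Recast an acclimated uptake curve plus quota in Michaelis-Menten form."""
    if q <= 0:
        raise DomainError("cell quota must be positive")
    return MichaelisEquivalent(vm_star=curve.v_max / q,
                               km=curve.km_cell, m_loss=m_loss)


# --- fitting -----------------------------------------------------------------

def _f_eq5(x, p_max, alpha):
    return p_max * np.tanh(alpha * x / p_max)


def _f_eq6(x, mu_max, alpha, i_r):
    net = np.maximum(x - i_r, 0.0)
    return alpha * net * mu_max / (alpha * net + mu_max)


def _f_eq7(x, v_max, alpha):
    return v_max * np.tanh(alpha * x / v_max)


def _f_eq8(x, mu_max, km):
    return mu_max * x / (x + km)


_MODELS = {
    "eq5": (_f_eq5, ("p_max", "alpha_p")),
    "eq6": (_f_eq6, ("mu_max", "alpha_mu", "i_r")),
    "eq7": (_f_eq7, ("v_max", "alpha_v")),
    "eq8": (_f_eq8, ("mu_max", "km_cell")),
}


@dataclass(frozen=True)
class FitResult:
    model: str
    params: dict[str, float]
    rss: float
    r_squared: float

    def predict(self, x):
        func, names = _MODELS[self.model]
        return func(np.asarray(x, dtype=float),
                    *[self.params[n] for n in names])


def curve_function(model: str):
    """Return (callable, parameter-name tuple) for a named curve form."""
    if model not in _MODELS:
        raise DomainError(f"unknown curve model {model!r}")
    return _MODELS[model]


def _start_grid(model: str, x: np.ndarray, y: np.ndarray):
    """Deterministic decade-spaced multi-start initial values."""
    ymax = max(float(np.max(y)), 1e-12)
    xpos = x[x > 0]
    xscale = float(np.median(xpos)) if xpos.size else 1.0
    max_scales = (0.5, 1.0, 2.0, 10.0)
    slope_scales = (0.1, 1.0, 10.0)
    starts = []
    for ms in max_scales:
        for ss in slope_scales:
            vmax0 = ms * ymax
            slope0 = ss * vmax0 / xscale
            if model == "eq6":
                for ir0 in (0.0, 0.1 * xscale, 0.5 * xscale):
                    starts.append((vmax0, slope0, ir0))
            elif model == "eq8":
                starts.append((vmax0, xscale * ss))
            else:
                starts.append((vmax0, slope0))
    return starts


def fit_curve(model: str, data: Sequence[tuple[float, float]]) -> FitResult:
    """Least-squares fit of a named two/three-parameter curve form.

    Uses a fixed decade-spaced grid of starting values so the result is
    deterministic for given data.  Raises ``ConvergenceError`` when fewer
    than three points are supplied or no start converges.
    """
    func, names = curve_function(model)
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ConvergenceError("at least 3 (resource, rate) points required")
    x, y = arr[:, 0], arr[:, 1]
    if np.any(x < 0):
        raise DomainError("resource values must be non-negative")

    lower = np.full(len(names), 1e-12)
    if model == "eq6":
        lower[2] = 0.0  # i_r may be zero
    best = None
    for p0 in _start_grid(model, x, y):
        try:
            popt, _ = curve_fit(func, x, y, p0=np.maximum(p0, lower),
                                bounds=(lower, np.inf), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - func(x, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise ConvergenceError("no start of the multi-start grid converged")
    popt, rss = best
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-30 else 0.0)
    return FitResult(model=model, params=dict(zip(names, map(float, popt))),
                     rss=rss, r_squared=r2)


def saturation_ratio_tanh() -> float:
    """Value of the tanh forms at their saturation index: tanh(1)."""
    return math.tanh(1.0)
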