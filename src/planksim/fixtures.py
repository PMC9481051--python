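"""Synthetic production-resource fixtures for fit-recovery testing."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .physiology import curve_function


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic noisy (resource, rate) table."""

    model: str  # eq5 | eq6 | eq7 | eq8
    true_params: dict[str, float]
    n_points: int = 30
    noise_cv: float = 0.0  # coefficient of variation of lognormal noise
    seed: int = 0
    resource_max: float | None = None  # defaults to 5x the saturation scale

    def __post_init__(self):
        curve_function(self.model)  # validates the name
        if self.n_points < 3:
            raise DomainError("need at least 3 points")
        if self.noise_cv < 0:
            raise DomainError("noise CV must be non-negative")


def _resource_grid(spec: FixtureSpec) -> np.ndarray:
    func, names = curve_function(spec.model)
    p = spec.true_params
    vmax = p[names[0]]
    if spec.resource_max is not None:
        hi = spec.resource_max
    else:
        if spec.model == "eq8":
            scale = p["km_cell"]
        else:
            scale = vmax / p[names[1]]
        hi = 5.0 * scale + p.get("i_r", 0.0)
    return np.linspace(0.0, hi, spec.n_points)


def generate_fixture(spec: FixtureSpec) -> pd.DataFrame:
    """Noisy samples of a named curve: rate = f(resource) * lognormal.

    The multiplicative lognormal noise has mean 1 and the requested
    coefficient of variation; a fixed seed gives identical tables.
    """
    func, names = curve_function(spec.model)
    x = _resource_grid(spec)
    params = [spec.true_params[n] for n in names]
    y = np.asarray(func(x, *params), dtype=float)
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        rng = np.random.default_rng(spec.seed)
        y = y * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=y.size)
    return pd.DataFrame({"resource": x, "rate": y})
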