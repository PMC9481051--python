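import numpy as np
import pytest

from planksim import size_spectrum as ss
from planksim.diffusion import TransportContext
from planksim.ecosystem import EcosystemParams, build_grid


@pytest.fixture(scope="session")
def oligotrophic_spectrum():
    """Slope-4.5 spectrum anchored at 2e4 cells/ml in the 0.6-0.8 um bin."""
    n0 = ss.calibrate_N0(2e4, (0.6, 0.8), 4.5)
    return ss.SizeSpectrum(N0=n0, xi=4.5)


@pytest.fixture(scope="session")
def eutrophic_spectrum():
    """Slope-3.3 spectrum anchored at 2e5 cells/ml in the 0.6-0.8 um bin."""
    n0 = ss.calibrate_N0(2e5, (0.6, 0.8), 3.3)
    return ss.SizeSpectrum(N0=n0, xi=3.3)


@pytest.fixture
def ctx_n_1nm():
    return TransportContext(s_inf=1.0)


@pytest.fixture(scope="session")
def grid25():
    return build_grid(25)


@pytest.fixture
def params():
    return EcosystemParams()


def spectrum_numeric_integral(spec, power=0.0, n=100_000):
    """Brute-force oracle: trapezoid on a log-spaced grid of the spectrum."""
    d = np.logspace(np.log10(spec.dmin), np.log10(spec.dmax), n)
    y = d**power * spec.density(d)
    return float(np.trapezoid(y, d))


def round_sf(x, sf=2):
    """Round to ``sf`` significant figures."""
    if x == 0:
        return 0.0
    import math
    return round(x, -int(math.floor(math.log10(abs(x)))) + sf - 1)
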