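import numpy as np
import pytest
from hypothesis import settings

from ligex import ComplexSystem
from ligex import equilibrium as eq

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

#: strong-binding constants used wherever the limiting (piecewise-linear)
#: behaviour of the designs is asserted: the indicator complex is fully
#: formed over the calibration range and displacement is quantitative
LOG_BETA_MX_STRONG = 12.0


def strong_system(n: int, **kw) -> ComplexSystem:
    """Strong-limit system of stoichiometry MLn observed at the indicator
    wavelength (MLn colorless)."""
    kw.setdefault("log_beta_MX", LOG_BETA_MX_STRONG)
    kw.setdefault("log_beta_MLn", 14.0 * n + 2.0)
    kw.setdefault("eps_MX", 1600.0)
    return ComplexSystem(n=n, **kw)


def strong_classical_system(n: int, **kw) -> ComplexSystem:
    """Strong-limit system observed at the classical wavelength (MLn colored,
    no indicator present)."""
    kw.setdefault("eps_MX", 0.0)
    kw.setdefault("eps_MLn", 2000.0)
    return strong_system(n, **kw)


@pytest.fixture
def strong_pair():
    """Zero-noise strong-limit calibration + exchange series for a 1:1 complex."""
    s = strong_system(1)
    cal = eq.simulate_calibration_design(s, eq.STANDARD_CALIBRATION_LEVELS)
    exch = eq.simulate_exchange_design(
        s, eq.STANDARD_INDICATOR_CONC, eq.STANDARD_EXCHANGE_LIGAND)
    return s, cal, exch


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
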