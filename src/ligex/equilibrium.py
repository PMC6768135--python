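"""Competitive complexation equilibria and synthetic titration data.

The chemical model is a metal M shared between two ligands: an indicator
ligand X that forms a 1:1 colored complex MX, and a test ligand L that forms
a colorless complex MLn of unknown stoichiometry n.  Both associations are
described by overall formation constants,

    M + X  <=>  MX,    beta_MX  = [MX]  / ([M][X])
    M + nL <=>  MLn,   beta_MLn = [MLn] / ([M][L]^n)

and three mass balances close the system:

    C_M = [M] + [MX] + [MLn]
    C_X = [X] + [MX]
    C_L = [L] + n [MLn]

Absorbance follows the Beer-Lambert law, additive over species.

The simulate_* functions reproduce the four experimental designs used to
determine mole ratios spectrophotometrically: a direct calibration of the
indicator complex, a ligand-exchange (displacement) series, a continuous-
variations (Job) series, and a mole-ratio (Yoe-Jones) series.  Amounts
quoted in micromoles per 10 mL convert to molarity as 1 umol/10 mL = 1e-4 M.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import SpeciationError

__all__ = [
    "ComplexSystem",
    "MixtureTotals",
    "SpeciationState",
    "TitrationSeries",
    "solve_speciation",
    "speciation_oracle",
    "absorbance",
    "simulate_calibration_design",
    "simulate_exchange_design",
    "simulate_job_design",
    "simulate_moleratio_design",
    "UMOL_PER_10ML",
    "STANDARD_CALIBRATION_LEVELS",
    "STANDARD_INDICATOR_CONC",
    "STANDARD_EXCHANGE_LIGAND",
    "STANDARD_JOB_TOTAL",
    "STANDARD_JOB_POINTS",
    "STANDARD_MOLERATIO_LIGAND",
    "STANDARD_MOLERATIO_METAL",
]

#: molar concentration of 1 umol dissolved in 10 mL
UMOL_PER_10ML = 1.0e-4

# Standard design grids of the reference bench procedure, in mol/L:
# indicator-complex calibration 0.1-0.6 mM; displacement series with 0.3 mM
# indicator complex and 0.02-0.18 mM test ligand; nine continuous-variations
# mixtures at 1 mM total; mole-ratio series with 0.5 mM ligand and
# 0.04-3 mM metal.
STANDARD_CALIBRATION_LEVELS = tuple(float(c) * 1.0e-4 for c in range(1, 7))
STANDARD_INDICATOR_CONC = 3.0e-4
STANDARD_EXCHANGE_LIGAND = tuple(float(c) * 2.0e-5 for c in range(1, 10))
STANDARD_JOB_TOTAL = 1.0e-3
STANDARD_JOB_POINTS = 9
STANDARD_MOLERATIO_LIGAND = 5.0e-4
STANDARD_MOLERATIO_METAL = tuple(
    u * UMOL_PER_10ML
    for u in (0.4, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0))

#: relative mass-balance residual demanded of a converged speciation solve
RESIDUAL_TOL = 1.0e-12

#: iteration cap for the damped Newton solver
MAX_NEWTON_ITER = 200


@dataclass(frozen=True)
class ComplexSystem:
    """Chemical definition of the competing-complex system.

    Parameters
    ----------
    n
        Stoichiometry of MLn: moles of test ligand bound per mole of metal.
    log_beta_MX
        log10 of the overall formation constant of the indicator complex MX
        (units M^-1).  MX is fixed at 1:1 stoichiometry.
    log_beta_MLn
        log10 of the overall formation constant of MLn (units M^-n).
    eps_MX, eps_MLn, eps_M, eps_L
        Molar absorptivities (M^-1 cm^-1) at the working wavelength.  The
        displacement assay assumes MLn is colorless at the indicator's
        wavelength (``eps_MLn = 0``); the classical designs instead observe
        the MLn complex directly (``eps_MLn > 0``, ``eps_MX`` irrelevant
        because no indicator ligand is present).
    path_length
        Optical path in cm.
    """

    n: int = 1
    log_beta_MX: float = 6.0
    log_beta_MLn: float = 14.0
    eps_MX: float = 1600.0
    eps_MLn: float = 0.0
    eps_M: float = 0.0
    eps_L: float = 0.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"stoichiometry n must be a positive integer, got {self.n!r}")
        for name in ("eps_MX", "eps_MLn", "eps_M", "eps_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("log_beta_MX", "log_beta_MLn"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    @property
    def beta_MX(self) -> float:
        return 10.0 ** self.log_beta_MX

    @property
    def beta_MLn(self) -> float:
        return 10.0 ** self.log_beta_MLn


@dataclass(frozen=True)
class MixtureTotals:
    """Analytical (total) concentrations of one mixture, in mol/L."""

    C_M_total: float
    C_X_total: float
    C_L_total: float

    def __post_init__(self) -> None:
        for name in ("C_M_total", "C_X_total", "C_L_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium composition of one mixture.

    ``residuals`` holds the relative mass-balance errors (M, X, L order);
    a converged state has all of them at or below 1e-9.
    """

    free_M: float
    free_X: float
    free_L: float
    conc_MX: float
    conc_MLn: float
    residuals: tuple[float, float, float]


@dataclass
class TitrationSeries:
    """An ordered set of (abscissa, absorbance) measurements.

    ``x_values`` are molar concentrations for the calibration and exchange
    designs, metal mole fractions for the Job design, and metal:ligand mole
    ratios for the mole-ratio design.  ``design`` records the fixed totals
    and which quantity varies, so a series file is self-describing.
    """

    method_kind: str
    x_values: np.ndarray
    absorbances: np.ndarray
    design: dict = field(default_factory=dict)
    seed: int | None = None
    noise_sd: float = 0.0

    _KINDS = ("exchange", "job", "mole_ratio", "calibration")

    def __post_init__(self) -> None:
        if self.method_kind not in self._KINDS:
            raise ValueError(f"method_kind must be one of {self._KINDS}, got {self.method_kind!r}")
        self.x_values = np.asarray(self.x_values, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.x_values.shape != self.absorbances.shape or self.x_values.ndim != 1:
            raise ValueError("x_values and absorbances must be 1-D arrays of equal length")
        if np.any(np.diff(self.x_values) < 0):
            raise ValueError("x_values must be sorted ascending")
        if self.method_kind == "job":
            if np.any(self.x_values < 0) or np.any(self.x_values > 1):
                raise ValueError("mole fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x_values)


# ---------------------------------------------------------------------------
# speciation solvers
# ---------------------------------------------------------------------------

def _mass_balance(system: ComplexSystem, totals: MixtureTotals,
                  m: float, x: float, l: float) -> tuple[np.ndarray, np.ndarray]:
    """Species sums per component and their relative residuals."""
    n = system.n
    mx = system.beta_MX * m * x
    ml = system.beta_MLn * m * l ** n
    sums = np.array([m + mx + ml, x + mx, l + n * ml])
    tot = np.array([totals.C_M_total, totals.C_X_total, totals.C_L_total])
    denom = np.where(tot > 0, tot, 1.0)
    res = np.abs(sums - tot) / denom
    return sums, res


def _finalize_state(system: ComplexSystem, totals: MixtureTotals,
                    m: float, x: float, l: float) -> SpeciationState:
    mx = system.beta_MX * m * x
    ml = system.beta_MLn * m * l ** system.n
    _, res = _mass_balance(system, totals, m, x, l)
    return SpeciationState(free_M=m, free_X=x, free_L=l,
                           conc_MX=mx, conc_MLn=ml,
                           residuals=tuple(float(r) for r in res))


def solve_speciation(system: ComplexSystem, totals: MixtureTotals) -> SpeciationState:
    """Solve the competitive equilibrium for one mixture.

    Damped Newton iteration on the logarithms of the free concentrations;
    the log parameterization keeps all concentrations strictly positive and
    handles formation constants spanning many orders of magnitude.  Falls
    back to nested bracketing bisection (:func:`speciation_oracle`) if the
    Newton iteration stalls.

    Raises
    ------
    SpeciationError
        If neither path reaches a maximum relative mass-balance residual
        of 1e-12 within the iteration caps.
    """
    CM, CX, CL = totals.C_M_total, totals.C_X_total, totals.C_L_total
    # components absent from the mixture are trivially zero
    active = [i for i, c in enumerate((CM, CX, CL)) if c > 0]
    if not active:
        return _finalize_state(system, totals, 0.0, 0.0, 0.0)
    if 0 not in active:  # no metal: ligands stay free
        return _finalize_state(system, totals, 0.0, CX, CL)

    n = system.n
    bmx = system.beta_MX if CX > 0 else 0.0
    bml = system.beta_MLn if CL > 0 else 0.0
    tot = np.array([CM, CX, CL])

    def residual_vec(t: np.ndarray) -> np.ndarray:
        c = np.zeros(3)
        c[active] = np.exp(t)
        m, x, l = c
        mx = bmx * m * x
        ml = bml * m * l ** n
        sums = np.array([m + mx + ml, x + mx, l + n * ml])
        return (sums[active] - tot[active]) / tot[active]

    def jacobian(t: np.ndarray) -> np.ndarray:
        c = np.zeros(3)
        c[active] = np.exp(t)
        m, x, l = c
        mx = bmx * m * x
        ml = bml * m * l ** n
        # d(species sums)/d(log c_j), full 3x3 then restricted to active set
        J = np.array([
            [m + mx + ml, mx, n * ml],
            [mx, x + mx, 0.0],
            [ml * n, 0.0, l + n * n * ml],
        ])
        return J[np.ix_(active, active)] / tot[active, None]

    # start from half-complexed guess; log space tolerates a crude start
    t = np.log(tot[active] / 2.0)
    f = residual_vec(t)
    best = np.max(np.abs(f))
    for _ in range(MAX_NEWTON_ITER):
        if best <= RESIDUAL_TOL:
            break
        try:
            step = np.linalg.solve(jacobian(t), -f)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -30.0, 30.0)
        lam, improved = 1.0, False
        for _ in range(50):
            f_new = residual_vec(t + lam * step)
            if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < best:
                t, f = t + lam * step, f_new
                best = np.max(np.abs(f))
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    if best <= RESIDUAL_TOL:
        c = np.zeros(3)
        c[active] = np.exp(t)
        return _finalize_state(system, totals, *c)
    # Newton stalled: the bracketing solve is slower but unconditionally robust
    try:
        return speciation_oracle(system, totals)
    except SpeciationError as err:
        raise SpeciationError("speciation solve failed to converge",
                              min(best, err.best_residual)) from err


def speciation_oracle(system: ComplexSystem, totals: MixtureTotals) -> SpeciationState:
    """Solve the same equilibrium by nested bracketing bisection.

    Outer bisection on free metal in [0, C_M]; for a trial free metal the
    free indicator ligand has the closed form C_X / (1 + beta_MX [M]) and the
    free test ligand is found by monotone bisection of its own mass balance.
    Used in tests as an independent check on the Newton solver, and as its
    fallback: both must find the same (unique) positive root.
    """
    CM, CX, CL = totals.C_M_total, totals.C_X_total, totals.C_L_total
    if CM == 0:
        return _finalize_state(system, totals, 0.0, CX, CL)
    n = system.n
    bmx = system.beta_MX if CX > 0 else 0.0
    bml = system.beta_MLn if CL > 0 else 0.0

    def free_L_given_m(m: float) -> float:
        if CL == 0:
            return 0.0
        k = bml * m
        if k == 0:
            return CL
        if n == 1:
            return CL / (1.0 + k)
        lo, hi = 0.0, CL  # g(l) = l + n k l^n - CL is increasing
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid + n * k * mid ** n > CL:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def metal_excess(m: float) -> float:
        x = CX / (1.0 + bmx * m) if CX > 0 else 0.0
        l = free_L_given_m(m)
        return m + bmx * m * x + bml * m * l ** n - CM

    lo, hi = 0.0, CM  # metal_excess is increasing in m, negative at 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if metal_excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    m = 0.5 * (lo + hi)
    x = CX / (1.0 + bmx * m) if CX > 0 else 0.0
    l = free_L_given_m(m)
    state = _finalize_state(system, totals, m, x, l)
    if max(state.residuals) > 1.0e-9:
        raise SpeciationError("bisection solve did not reach tolerance",
                              max(state.residuals))
    return state


def absorbance(system: ComplexSystem, state: SpeciationState) -> float:
    """Beer-Lambert absorbance of an equilibrium mixture (additive species)."""
    a = system.path_length * (system.eps_MX * state.conc_MX
                              + system.eps_MLn * state.conc_MLn
                              + system.eps_M * state.free_M
                              + system.eps_L * state.free_L)
    return float(a)


# ---------------------------------------------------------------------------
# design simulators
# ---------------------------------------------------------------------------

def _simulate(system: ComplexSystem, kind: str,
              totals_list: Sequence[MixtureTotals], x_values: np.ndarray,
              design: dict, noise_sd: float, seed: int | None) -> TitrationSeries:
    a = np.array([absorbance(system, solve_speciation(system, t)) for t in totals_list])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return TitrationSeries(method_kind=kind, x_values=np.asarray(x_values, dtype=float),
                           absorbances=a, design=design, seed=seed, noise_sd=noise_sd)


def simulate_calibration_design(system: ComplexSystem,
                                conc_levels: Sequence[float],
                                noise_sd: float = 0.0,
                                seed: int | None = None) -> TitrationSeries:
    """Direct calibration of the indicator complex: metal = indicator ligand
    at each level, no test ligand.  Abscissa is the nominal MX concentration."""
    levels = np.asarray(conc_levels, dtype=float)
    totals = [MixtureTotals(c, c, 0.0) for c in levels]
    design = {"varies": "indicator_conc", "C_L_total": 0.0}
    return _simulate(system, "calibration", totals, levels, design, noise_sd, seed)


def simulate_exchange_design(system: ComplexSystem,
                             indicator_conc: float,
                             ligand_amounts: Sequence[float],
                             noise_sd: float = 0.0,
                             seed: int | None = None) -> TitrationSeries:
    """Displacement series: fixed indicator complex, increasing test ligand.

    Each mixture has total metal = total indicator ligand = ``indicator_conc``
    and a test-ligand total from ``ligand_amounts`` (mol/L).  Abscissa is the
    test-ligand concentration.
    """
    if indicator_conc <= 0:
        raise ValueError("indicator_conc must be positive")
    cl = np.asarray(ligand_amounts, dtype=float)
    totals = [MixtureTotals(indicator_conc, indicator_conc, c) for c in cl]
    design = {"varies": "C_L_total", "indicator_conc": indicator_conc}
    return _simulate(system, "exchange", totals, cl, design, noise_sd, seed)


def simulate_job_design(system: ComplexSystem,
                        total_conc: float,
                        k_points: int = 9,
                        noise_sd: float = 0.0,
                        seed: int | None = None) -> TitrationSeries:
    """Continuous-variations series: metal + test ligand at constant total.

    The metal mole fraction runs over an equispaced interior grid
    (0.1 ... 0.9 for the default nine mixtures); no indicator ligand is
    present, so the observed signal must come from MLn (or free metal).
    """
    if k_points < 3:
        raise ValueError("a continuous-variations design needs at least 3 mixtures")
    frac = np.arange(1, k_points + 1) / (k_points + 1.0)
    totals = [MixtureTotals(f * total_conc, 0.0, (1.0 - f) * total_conc) for f in frac]
    design = {"varies": "metal_mole_fraction", "total_conc": total_conc}
    return _simulate(system, "job", totals, frac, design, noise_sd, seed)


def simulate_moleratio_design(system: ComplexSystem,
                              ligand_conc: float,
                              metal_range: Sequence[float],
                              noise_sd: float = 0.0,
                              seed: int | None = None) -> TitrationSeries:
    """Mole-ratio (Yoe-Jones) series: fixed test ligand, varying metal.

    Abscissa is the dimensionless metal:ligand mole ratio C_M / C_L.
    """
    if ligand_conc <= 0:
        raise ValueError("ligand_conc must be positive")
    cm = np.asarray(metal_range, dtype=float)
    totals = [MixtureTotals(c, 0.0, ligand_conc) for c in cm]
    ratios = cm / ligand_conc
    design = {"varies": "C_M_total", "ligand_conc": ligand_conc}
    return _simulate(system, "mole_ratio", totals, ratios, design, noise_sd, seed)
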