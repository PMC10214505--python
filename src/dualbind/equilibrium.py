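"""Exact ternary-complex (R + L + S) binding equilibrium.

A stabilizer (molecular glue) S binds a receptor R with dissociation
constant ``K_RS`` and a ligand protein L with ``K_LS``.  The ternary
association step is enhanced by a dimensionless cooperativity factor
``phi`` (phi > 1: positive cooperativity), applied identically from the
RS + L and LS + R routes so the thermodynamic cycle closes::

    R + S  <->  RS          K_RS
    L + S  <->  LS          K_LS
    RS + L <->  RLS         K_LS / phi
    LS + R <->  RLS         K_RS / phi

Because the binary complexes saturate at high stabilizer dose, the
ternary complex concentration [RLS] is a unimodal ("hook-effect")
function of the total stabilizer [S0]: it rises, peaks at an optimal
dose, and falls again.  The stabilization strength of a compound is
summarized by the effective dissociation constant of the protein pair
at the optimal dose,

    K_RL,eff = [R0][L0] / [RLS_opt]

which in the dilute limit (totals far below the binary K's) has the
closed form ``(sqrt(K_RS) + sqrt(K_LS))**2 / phi``.  This is the basis
of the dual-binding rule: the weaker of the two binary interactions
dominates the achievable stabilization.

All concentrations are molar; energies are kcal/mol; temperatures kelvin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BindingParameters",
    "TotalConcentrations",
    "SpeciesState",
    "DoseOptimum",
    "EnergyGridScan",
    "ThresholdScanResult",
    "dg_to_kd",
    "kd_to_dg",
    "solve_equilibrium",
    "rls_dilute",
    "optimal_dose",
    "titration_curve",
    "energy_grid_scan",
    "threshold_scan",
]

#: Gas constant in kcal/(mol*K); K_D = exp(ddG / (R*T)).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Standard-state temperature used when none is given, kelvin.
DEFAULT_TEMPERATURE = 298.15


def dg_to_kd(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a Gibbs binding free energy (kcal/mol) to a dissociation constant (M).

    Uses ``K_D = exp(ddG / (R T))`` with R in kcal/(mol K); more negative
    binding free energies give smaller (tighter) dissociation constants.
    """
    if not math.isfinite(ddg):
        raise ValueError(f"binding free energy must be finite, got {ddg!r}")
    if not (temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return math.exp(ddg / (GAS_CONSTANT_KCAL * temperature))


def kd_to_dg(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`dg_to_kd`: ``ddG = R T ln(K_D)`` in kcal/mol."""
    if not (kd > 0) or not math.isfinite(kd):
        raise ValueError(f"dissociation constant must be positive and finite, got {kd!r}")
    if not (temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic description of one receptor/ligand/stabilizer system.

    Parameters
    ----------
    k_rs, k_ls:
        Dissociation constants of the binary R·S and L·S complexes, molar.
    phi:
        Cooperativity factor; multiplies the ternary association constant
        (equivalently divides the ternary-step dissociation constant).
    temperature:
        Kelvin; only used when parameters are derived from free energies.
    """

    k_rs: float
    k_ls: float
    phi: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("k_rs", "k_ls", "phi", "temperature"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @classmethod
    def from_energies(
        cls,
        ddg_rs: float,
        ddg_ls: float,
        phi: float = 1.0,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "BindingParameters":
        """Build parameters from per-partner binding free energies (kcal/mol)."""
        return cls(
            k_rs=dg_to_kd(ddg_rs, temperature),
            k_ls=dg_to_kd(ddg_ls, temperature),
            phi=phi,
            temperature=temperature,
        )

    def swapped(self) -> "BindingParameters":
        """Exchange the receptor and ligand roles (K_RS <-> K_LS)."""
        return BindingParameters(self.k_ls, self.k_rs, self.phi, self.temperature)


@dataclass(frozen=True)
class TotalConcentrations:
    """Total (bound + free) concentrations of the three components, molar."""

    r0: float
    l0: float
    s0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0) or not math.isfinite(self.r0):
            raise ValueError(f"r0 must be positive and finite, got {self.r0!r}")
        if not (self.l0 > 0) or not math.isfinite(self.l0):
            raise ValueError(f"l0 must be positive and finite, got {self.l0!r}")
        if not (self.s0 >= 0) or not math.isfinite(self.s0):
            raise ValueError(f"s0 must be non-negative and finite, got {self.s0!r}")


@dataclass(frozen=True)
class SpeciesState:
    """Free and bound concentrations of all six species at equilibrium, molar."""

    r_free: float
    l_free: float
    s_free: float
    rs: float
    ls: float
    rls: float

    def totals(self) -> tuple[float, float, float]:
        """Reconstruct (r0, l0, s0) from the species."""
        return (
            self.r_free + self.rs + self.rls,
            self.l_free + self.ls + self.rls,
            self.s_free + self.rs + self.ls + self.rls,
        )

    def mass_action_residuals(self, params: BindingParameters) -> tuple[float, float, float]:
        """Absolute residuals of the three mass-action laws (binary RS, binary LS, ternary)."""
        res_rs = abs(self.r_free * self.s_free - params.k_rs * self.rs)
        res_ls = abs(self.l_free * self.s_free - params.k_ls * self.ls)
        res_ternary = abs(self.rs * self.l_free - (params.k_ls / params.phi) * self.rls)
        return res_rs, res_ls, res_ternary


@dataclass(frozen=True)
class DoseOptimum:
    """Optimal total stabilizer dose and the resulting effective K of the protein pair."""

    s0_opt: float
    rls_opt: float
    k_rl_eff: float
    flat: bool = False


@dataclass(frozen=True)
class EnergyGridScan:
    """K_RL,eff surface over a (ddG_RS, ddG_LS) energy grid."""

    ddg_rs_axis: np.ndarray
    ddg_ls_axis: np.ndarray
    k_rl_eff_surface: np.ndarray  # shape (len(ddg_rs_axis), len(ddg_ls_axis))


@dataclass(frozen=True)
class ThresholdScanResult:
    """Outcome of scanning symmetric binding energies against a K_RL,eff boundary."""

    ddg_threshold: float | None
    reached: bool
    boundary: float
    ddg_grid: np.ndarray
    k_rl_eff: np.ndarray


def _species_at_s_free(
    params: BindingParameters, r0: float, l0: float, s_free: float
) -> SpeciesState:
    """Exact species concentrations conditioned on a value of free stabilizer.

    With [S_f] fixed, R- and L-conservation close to a single quadratic in
    [L]: writing a = 1 + Sf/K_RS, b = 1 + Sf/K_LS, c = phi*Sf/(K_RS*K_LS),

        b*c*[L]^2 + (a*b + c*(r0 - l0))*[L] - a*l0 = 0

    whose positive root is evaluated in the cancellation-free form
    2*a*l0 / (B + sqrt(B^2 + 4*a*b*c*l0)).
    """
    if s_free == 0.0:
        return SpeciesState(r_free=r0, l_free=l0, s_free=0.0, rs=0.0, ls=0.0, rls=0.0)
    a = 1.0 + s_free / params.k_rs
    b = 1.0 + s_free / params.k_ls
    c = params.phi * (s_free / params.k_rs) / params.k_ls
    bq = a * b + c * (r0 - l0)
    l_free = 2.0 * a * l0 / (bq + math.sqrt(bq * bq + 4.0 * a * b * c * l0))
    r_free = r0 / (a + c * l_free)
    rls = c * r_free * l_free
    return SpeciesState(
        r_free=r_free,
        l_free=l_free,
        s_free=s_free,
        rs=r_free * s_free / params.k_rs,
        ls=l_free * s_free / params.k_ls,
        rls=rls,
    )


def solve_equilibrium(
    params: BindingParameters,
    totals: TotalConcentrations,
    rtol: float = 1e-12,
) -> SpeciesState:
    """Solve the coupled R+S / L+S / ternary mass-action system exactly.

    The system is reduced to a single monotone stabilizer-conservation
    equation in the free stabilizer concentration, bracketed on
    ``[0, s0]`` and solved by Brent's method to relative tolerance
    ``rtol``, followed by one Newton polish.  This is guaranteed to
    converge to the unique physical root for valid inputs.
    """
    r0, l0, s0 = totals.r0, totals.l0, totals.s0
    if s0 == 0.0:
        return _species_at_s_free(params, r0, l0, 0.0)

    def excess(s_free: float) -> float:
        st = _species_at_s_free(params, r0, l0, s_free)
        return (s_free + st.rs + st.ls + st.rls) - s0

    lo, hi = 0.0, s0
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo > 0 or f_hi < 0:  # cannot occur for valid inputs
        raise RuntimeError(
            "internal bracketing failure in stabilizer conservation: "
            f"f(0)={f_lo:.3e}, f(s0)={f_hi:.3e}"
        )
    s_free = brentq(excess, lo, hi, rtol=max(rtol, 4 * np.finfo(float).eps), xtol=1e-300)

    # one Newton polish on the conservation equation
    h = s_free * 1e-7
    if h > 0:
        d = (excess(s_free + h) - excess(s_free - h)) / (2 * h)
        if d > 0 and math.isfinite(d):
            step = excess(s_free) / d
            if 0 <= s_free - step <= s0:
                s_free -= step

    state = _species_at_s_free(params, r0, l0, s_free)
    tr, tl, ts = state.totals()
    for name, got, want in (("r0", tr, r0), ("l0", tl, l0), ("s0", ts, s0)):
        if abs(got - want) > 1e-6 * want:
            raise RuntimeError(
                f"equilibrium solver failed to conserve {name}: {got!r} vs {want!r}"
            )
    return state


def rls_dilute(
    params: BindingParameters, r0: float, l0: float, s_free: float
) -> float:
    """Closed-form ternary complex concentration under negligible R/L depletion.

    [RLS] = phi * r0 * l0 * Sf / ((K_RS + Sf) * (K_LS + Sf)).

    The curve vanishes at Sf = 0, peaks at Sf = sqrt(K_RS*K_LS) and
    decays as 1/Sf at large doses (the hook effect: the binary RS and LS
    complexes saturate and sequester the partners).  Agrees with
    :func:`solve_equilibrium` when r0, l0 << min(K_RS, K_LS).
    """
    if not (s_free >= 0) or not math.isfinite(s_free):
        raise ValueError(f"s_free must be non-negative and finite, got {s_free!r}")
    if s_free == 0.0:
        return 0.0
    # grouped to stay finite for very small K at moderate s_free
    return params.phi * r0 * l0 * (s_free / (params.k_rs + s_free)) / (params.k_ls + s_free)


def optimal_dose(
    params: BindingParameters, r0: float, l0: float, n_probe: int = 0
) -> DoseOptimum:
    """Find the total stabilizer dose maximizing [RLS], and K_RL,eff there.

    The exact solver is maximized over log(s0) with a bounded scalar
    search centred on the dilute-limit optimum sqrt(K_RS*K_LS) and
    widened to cover strong-depletion regimes.  In the dilute limit the
    free stabilizer at the optimum equals sqrt(K_RS*K_LS) and
    K_RL,eff = (sqrt(K_RS) + sqrt(K_LS))**2 / phi; both are verified as
    properties of this routine in the test suite rather than assumed.
    """
    s_center = math.sqrt(params.k_rs * params.k_ls) + 0.5 * (r0 + l0)
    lo, hi = math.log(s_center) - 30.0, math.log(s_center) + 30.0

    def neg_rls(log_s0: float) -> float:
        t = TotalConcentrations(r0=r0, l0=l0, s0=math.exp(log_s0))
        return -solve_equilibrium(params, t).rls

    res = minimize_scalar(neg_rls, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    s0_opt = math.exp(res.x)
    rls_opt = -res.fun

    flat = False
    probe = -neg_rls(lo)
    if rls_opt <= 0 or (probe > 0 and abs(rls_opt - probe) <= 1e-12 * rls_opt):
        flat = True
        warnings.warn("flat titration objective; returning left-most maximizer",
                      stacklevel=2)
        s0_opt, rls_opt = math.exp(lo), probe

    k_rl_eff = (r0 * l0 / rls_opt) if rls_opt > 0 else math.inf
    return DoseOptimum(s0_opt=s0_opt, rls_opt=rls_opt, k_rl_eff=k_rl_eff, flat=flat)


def titration_curve(
    params: BindingParameters,
    r0: float,
    l0: float,
    s0_grid,
) -> list[tuple[float, SpeciesState]]:
    """Solve the equilibrium along a grid of total stabilizer doses.

    The grid is emitted in input order; [RLS] along an increasing grid
    is unimodal (rises, peaks, falls) — the hook effect.
    """
    s0_grid = list(s0_grid)
    if len(s0_grid) == 0:
        raise ValueError("s0 grid must be non-empty")
    out = []
    for s0 in s0_grid:
        totals = TotalConcentrations(r0=r0, l0=l0, s0=float(s0))
        out.append((float(s0), solve_equilibrium(params, totals)))
    return out


def energy_grid_scan(
    ddg_rs_axis,
    ddg_ls_axis,
    r0: float,
    l0: float,
    phi: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnergyGridScan:
    """K_RL,eff over a 2-D grid of per-partner binding free energies.

    Cell (i, j) holds the optimal-dose effective dissociation constant for
    the system with ddG_RS = ddg_rs_axis[i] and ddG_LS = ddg_ls_axis[j].
    """
    rs_axis = np.asarray(ddg_rs_axis, dtype=float)
    ls_axis = np.asarray(ddg_ls_axis, dtype=float)
    for name, ax in (("ddg_rs_axis", rs_axis), ("ddg_ls_axis", ls_axis)):
        if ax.ndim != 1 or ax.size == 0:
            raise ValueError(f"{name} must be a non-empty 1-D array")
        if ax.size > 1:
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
    surface = np.empty((rs_axis.size, ls_axis.size))
    for i, ddg_rs in enumerate(rs_axis):
        for j, ddg_ls in enumerate(ls_axis):
            p = BindingParameters.from_energies(ddg_rs, ddg_ls, phi, temperature)
            surface[i, j] = optimal_dose(p, r0, l0).k_rl_eff
    return EnergyGridScan(ddg_rs_axis=rs_axis, ddg_ls_axis=ls_axis,
                          k_rl_eff_surface=surface)


def threshold_scan(
    r0: float,
    l0: float,
    phi: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
    ddg_grid=None,
    boundary: float = 1e-3,
) -> ThresholdScanResult:
    """Least-negative symmetric per-partner ddG reaching a K_RL,eff boundary.

    For each symmetric energy pair (ddG, ddG) on the grid, the optimal-dose
    effective dissociation constant is computed; the scan proceeds from
    the least-negative energy toward the most negative and returns the
    first grid value whose K_RL,eff <= ``boundary`` (default 1e-3 M, the
    millimolar/micromolar divide).  If no grid point reaches the boundary
    the result carries ``reached=False`` rather than raising.
    """
    if ddg_grid is None:
        ddg_grid = np.arange(-1.0, -10.0 - 1e-9, -0.5)
    grid = np.asarray(ddg_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("ddg grid must be a non-empty 1-D array")
    # least-negative first
    order = np.argsort(-grid)
    grid = grid[order]
    k_eff = np.empty_like(grid)
    hit: float | None = None
    for i, ddg in enumerate(grid):
        p = BindingParameters.from_energies(ddg, ddg, phi, temperature)
        k_eff[i] = optimal_dose(p, r0, l0).k_rl_eff
        if hit is None and k_eff[i] <= boundary:
            hit = float(ddg)
    return ThresholdScanResult(
        ddg_threshold=hit,
        reached=hit is not None,
        boundary=boundary,
        ddg_grid=grid,
        k_rl_eff=k_eff,
    )
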