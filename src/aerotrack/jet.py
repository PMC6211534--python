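"""Gas expansion and particle acceleration at the injector exit.

Helium leaving the last orifice of the aerodynamic lens expands as a
free jet into vacuum.  The centerline Mach number of the expansion is
given by the Ashkenas–Sherman far-field correlation; the local gas
temperature, pressure, density and velocity follow from the Mach number
through the isentropic relations.  Aerosol particles (four orders of
magnitude smaller than the orifice) see free-molecular flow and are
accelerated by drag, computed from the Henderson sphere correlation,
which covers the free-molecular, transition and continuum regimes as a
function of the slip Reynolds and Mach numbers.

The dimensionless parameter governing lens focusing and acceleration
is the Stokes number

    St = tau * u / (d_f / 2),     tau = C_c * rho_p * d_p^2 / (18 mu),

with u the mean flow velocity at the orifice, C_c the Cunningham slip
correction, F_m the mass flow rate and d_f the orifice diameter; u is
computed as 4 F_m / (rho_l pi d_f^2).  The orifice mass flow and gas
state come from an isentropic choked-orifice estimate with the lens
entrance pressure as stagnation pressure, using an effective orifice
diameter (a fitted fraction of the physical one) to absorb the
boundary-layer contraction at low Reynolds number.

Terminal velocities of different (diameter, pressure) conditions
normalized by the stagnation speed of sound collapse onto one curve in
the Stokes number; a pluggable three-parameter saturating model is
provided to fit that curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize

from .core import AerotrackError
from .units import R_GAS, mbar_to_pa

# Ashkenas-Sherman centerline correlation constants for a monatomic gas
# (gamma = 5/3): M = A xr^(g-1) - (g+1)/(2 (g-1) A xr^(g-1)) with
# xr = x/d - x0/d.
AS_A_MONATOMIC = 3.26
AS_X0_OVER_D_MONATOMIC = 0.075
#: Smallest x/d at which the far-field correlation is applied.
MIN_X_OVER_D = 0.5


@dataclass(frozen=True)
class GasProperties:
    """Carrier-gas properties with a power-law viscosity model."""

    species: str = "He"
    gamma: float = 5.0 / 3.0
    molar_mass_kg_mol: float = 4.002602e-3
    viscosity_ref_pa_s: float = 1.96e-5
    reference_T_K: float = 293.0
    viscosity_exponent: float = 0.7

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise AerotrackError("heat-capacity ratio must exceed 1")
        if self.viscosity_ref_pa_s <= 0:
            raise AerotrackError("viscosity must be positive")

    @classmethod
    def helium(cls) -> "GasProperties":
        return cls()

    def viscosity(self, T_K: float) -> float:
        """Dynamic viscosity at temperature T (power-law scaling)."""
        return self.viscosity_ref_pa_s * (T_K / self.reference_T_K) ** self.viscosity_exponent

    @property
    def specific_gas_constant(self) -> float:
        return R_GAS / self.molar_mass_kg_mol


@dataclass(frozen=True)
class InjectorGeometry:
    """Exit-orifice geometry of the aerodynamic lens."""

    orifice_diameter_mm: float = 1.5
    effective_diameter_ratio: float = 0.880

    def __post_init__(self) -> None:
        if not 0.0 < self.effective_diameter_ratio <= 1.0:
            raise AerotrackError("effective_diameter_ratio must be in (0, 1]")
        if self.orifice_diameter_mm <= 0:
            raise AerotrackError("orifice diameter must be positive")

    @property
    def d_f_m(self) -> float:
        return self.orifice_diameter_mm * 1e-3

    @property
    def d_eff_m(self) -> float:
        return self.d_f_m * self.effective_diameter_ratio


@dataclass(frozen=True)
class JetState:
    """Local gas state on the expansion axis."""

    x_mm: float
    mach: float
    T_K: float
    pressure_pa: float
    density_kg_m3: float
    velocity_m_s: float
    speed_of_sound_m_s: float


@dataclass(frozen=True)
class StokesInputs:
    """Inputs of the Stokes-number composition (SI units)."""

    rho_p_kg_m3: float
    d_p_m: float
    slip_correction: float
    mass_flow_kg_s: float
    gas_density_kg_m3: float
    viscosity_pa_s: float
    d_f_m: float

    def __post_init__(self) -> None:
        for name in ("rho_p_kg_m3", "d_p_m", "slip_correction",
                     "mass_flow_kg_s", "gas_density_kg_m3",
                     "viscosity_pa_s", "d_f_m"):
            if getattr(self, name) <= 0:
                raise AerotrackError(f"StokesInputs.{name} must be positive")


@dataclass
class VelocityFit:
    """Fitted terminal-velocity collapse curve parameters."""

    A: float
    B: float
    C: float
    residual_rms: float = 0.0
    model: Optional[Callable] = None


def speed_of_sound(gas: GasProperties, T_K: float) -> float:
    """Ideal-gas speed of sound sqrt(gamma R T / M); ~1008 m/s for He
    near room temperature."""
    if T_K <= 0:
        raise AerotrackError("temperature must be positive")
    return math.sqrt(gas.gamma * R_GAS * T_K / gas.molar_mass_kg_mol)


def mach_centerline(
    x_m: float,
    d_eff_m: float,
    gamma: float = 5.0 / 3.0,
    A: float = AS_A_MONATOMIC,
    x0_over_d: float = AS_X0_OVER_D_MONATOMIC,
    min_x_over_d: float = MIN_X_OVER_D,
) -> float:
    """Centerline Mach number of a free-jet expansion (far field).

    M = A xr^(γ−1) − (γ+1) / (2 (γ−1) A xr^(γ−1)),  xr = x/d − x0/d.

    Strictly increasing in x.  Raises inside the near-orifice region
    (x/d below ``min_x_over_d``), where the power-law correlation does
    not apply; start the integration downstream of that bound instead.
    """
    if d_eff_m <= 0:
        raise AerotrackError("effective orifice diameter must be positive")
    x_over_d = x_m / d_eff_m
    if x_over_d < min_x_over_d:
        raise AerotrackError(
            f"x/d = {x_over_d:.3g} is inside the near-orifice region "
            f"(< {min_x_over_d:g}); the far-field correlation does not "
            "apply there — begin propagation further downstream")
    xr = x_over_d - x0_over_d
    t = A * xr ** (gamma - 1.0)
    return t - (gamma + 1.0) / (2.0 * (gamma - 1.0) * t)


def isentropic_state(
    mach: float,
    p0_pa: float,
    T0_K: float,
    gas: GasProperties,
    x_mm: float = 0.0,
) -> JetState:
    """Local gas state from the Mach number and stagnation conditions."""
    if mach < 0:
        raise AerotrackError("Mach number must be non-negative")
    g = gas.gamma
    ratio = 1.0 + 0.5 * (g - 1.0) * mach ** 2
    T = T0_K / ratio
    p = p0_pa * ratio ** (-g / (g - 1.0))
    rho0 = p0_pa / (gas.specific_gas_constant * T0_K)
    rho = rho0 * ratio ** (-1.0 / (g - 1.0))
    a = speed_of_sound(gas, T)
    return JetState(x_mm=x_mm, mach=mach, T_K=T, pressure_pa=p,
                    density_kg_m3=rho, velocity_m_s=mach * a,
                    speed_of_sound_m_s=a)


def _henderson_cd_subsonic(M: float, Re: float, S: float,
                           tw_over_t: float) -> float:
    term1 = 24.0 / (Re + S * (4.33 + ((3.65 - 1.53 * tw_over_t)
                                      / (1.0 + 0.353 * tw_over_t))
                              * math.exp(-0.247 * Re / S)))
    sqrt_re = math.sqrt(Re)
    g = 0.03 * Re + 0.48 * sqrt_re
    term2 = math.exp(-0.5 * M / sqrt_re) * (
        (4.5 + 0.38 * g) / (1.0 + g) + 0.1 * M ** 2 + 0.2 * M ** 8)
    term3 = (1.0 - math.exp(-min(M / Re, 700.0))) * 0.6 * S
    return term1 + term2 + term3


def _henderson_cd_supersonic(M: float, Re: float, gamma: float,
                             tw_over_t: float) -> float:
    S = M * math.sqrt(gamma / 2.0)
    root = 1.86 * math.sqrt(M / Re)
    num = (0.9 + 0.34 / M ** 2
           + root * (2.0 + 2.0 / S ** 2
                     + 1.058 / S * math.sqrt(tw_over_t) - 1.0 / S ** 4))
    return num / (1.0 + root)


def henderson_drag_coefficient(M: float, Re: float, gamma: float = 5.0 / 3.0,
                               tw_over_t: float = 1.0) -> float:
    """Henderson sphere drag coefficient C_D(M, Re).

    Semi-empirical correlation covering continuum to free-molecular
    flow: a subsonic branch (M ≤ 1), a supersonic branch (M ≥ 1.75)
    and linear interpolation in Mach number between them.  ``M`` and
    ``Re`` are based on the velocity of the particle relative to the
    gas; ``tw_over_t`` is the particle-surface to gas temperature
    ratio.
    """
    if M <= 0 or Re <= 0:
        raise AerotrackError("henderson_drag_coefficient needs M, Re > 0")
    S = M * math.sqrt(gamma / 2.0)
    if M <= 1.0:
        return _henderson_cd_subsonic(M, Re, S, tw_over_t)
    cd1 = _henderson_cd_subsonic(1.0, Re, math.sqrt(gamma / 2.0), tw_over_t)
    cd175 = _henderson_cd_supersonic(1.75, Re, gamma, tw_over_t)
    if M >= 1.75:
        return _henderson_cd_supersonic(M, Re, gamma, tw_over_t)
    return cd1 + (4.0 / 3.0) * (M - 1.0) * (cd175 - cd1)


def henderson_drag(
    relative_speed_m_s: float,
    state: JetState,
    d_p_m: float,
    gas: GasProperties,
    tw_over_t: Optional[float] = None,
) -> float:
    """Drag force (N) on a sphere moving at ``relative_speed`` with
    respect to the local gas; positive when the gas pushes the particle
    forward (i.e. the sign of gas-minus-particle velocity).

    Odd in the relative velocity and zero in vacuum.
    """
    if state.density_kg_m3 <= 0.0:
        return 0.0
    v = relative_speed_m_s
    if v == 0.0:
        return 0.0
    mu = gas.viscosity(state.T_K)
    Re = state.density_kg_m3 * abs(v) * d_p_m / mu
    M = abs(v) / state.speed_of_sound_m_s
    if tw_over_t is None:
        tw_over_t = 1.0
    cd = henderson_drag_coefficient(M, Re, gas.gamma, tw_over_t)
    area = math.pi * d_p_m ** 2 / 4.0
    return math.copysign(0.5 * state.density_kg_m3 * v * v * cd * area, v)


@dataclass
class OrificeFlow:
    """Isentropic choked-flow state at the lens exit orifice."""

    mass_flow_kg_s: float
    gas_density_kg_m3: float   # at the throat (sonic state)
    mean_velocity_m_s: float   # u = 4 F_m / (rho_l pi d_f^2)
    throat_T_K: float
    throat_pressure_pa: float


def orifice_flow(
    p0_pa: float,
    T0_K: float,
    gas: GasProperties,
    geometry: InjectorGeometry,
) -> OrificeFlow:
    """Choked-orifice estimate of mass flow and orifice gas state.

    The flow area is the effective orifice (physical diameter times
    the fitted contraction ratio); the mean velocity u used in the
    Stokes number is referred to the physical diameter d_f.
    """
    if p0_pa <= 0 or T0_K <= 0:
        raise AerotrackError("stagnation conditions must be positive")
    g = gas.gamma
    sonic = 2.0 / (g + 1.0)
    T_star = T0_K * sonic
    p_star = p0_pa * sonic ** (g / (g - 1.0))
    rho0 = p0_pa / (gas.specific_gas_constant * T0_K)
    rho_star = rho0 * sonic ** (1.0 / (g - 1.0))
    a_star = speed_of_sound(gas, T_star)
    area_eff = math.pi * geometry.d_eff_m ** 2 / 4.0
    f_m = rho_star * a_star * area_eff
    u = 4.0 * f_m / (rho_star * math.pi * geometry.d_f_m ** 2)
    return OrificeFlow(mass_flow_kg_s=f_m, gas_density_kg_m3=rho_star,
                       mean_velocity_m_s=u, throat_T_K=T_star,
                       throat_pressure_pa=p_star)


class FreeJetFlow:
    """Axial gas-flow field of the free-jet expansion.

    Combines the centerline Mach correlation with the isentropic
    relations; stagnation conditions are the lens entrance pressure
    and room temperature.
    """

    def __init__(
        self,
        stagnation_pressure_mbar: float,
        stagnation_T_K: float = 293.15,
        gas: Optional[GasProperties] = None,
        geometry: Optional[InjectorGeometry] = None,
        min_x_over_d: float = MIN_X_OVER_D,
    ) -> None:
        self.gas = gas or GasProperties.helium()
        self.geometry = geometry or InjectorGeometry()
        self.p0_pa = mbar_to_pa(stagnation_pressure_mbar)
        self.T0_K = stagnation_T_K
        self.min_x_over_d = min_x_over_d

    @property
    def x_start_mm(self) -> float:
        """Smallest axial position (mm) where the flow field is defined."""
        return self.min_x_over_d * self.geometry.d_eff_m * 1e3

    def state(self, x_mm: float) -> JetState:
        m = mach_centerline(x_mm * 1e-3, self.geometry.d_eff_m,
                            self.gas.gamma,
                            min_x_over_d=self.min_x_over_d)
        return isentropic_state(m, self.p0_pa, self.T0_K, self.gas,
                                x_mm=x_mm)

    def max_gas_velocity(self, x_end_mm: float) -> float:
        return self.state(x_end_mm).velocity_m_s


@dataclass
class PropagationResult:
    """Particle velocity along the expansion axis."""

    x_mm: np.ndarray
    v_m_s: np.ndarray
    v_gas_m_s: np.ndarray
    terminal_velocity_m_s: float


def propagate_particle(
    v0_m_s: float,
    d_p_nm: float,
    rho_p_kg_m3: float,
    flow: FreeJetFlow,
    x_start_mm: Optional[float] = None,
    x_end_mm: float = 30.0,
    rtol: float = 1e-7,
    n_samples: int = 200,
) -> PropagationResult:
    """Integrate the 1-D drag equation of motion along the jet axis.

    Solves dv/dx = F_drag / (m v) with adaptive embedded Runge–Kutta
    stepping; the integration variable is the axial position, so a
    strictly positive initial velocity is required (v = 0 is a
    singular point of the change of variables).  The velocity at
    ``x_end`` is reported as the terminal velocity; by then the gas
    density has dropped enough that further change is negligible.
    """
    if v0_m_s <= 0:
        raise AerotrackError("initial velocity must be positive "
                             "(x-parameterized integration)")
    if x_start_mm is None:
        x_start_mm = flow.x_start_mm
    if x_end_mm <= x_start_mm:
        raise AerotrackError("x_end must exceed x_start")
    d_p_m = d_p_nm * 1e-9
    mass = rho_p_kg_m3 * math.pi * d_p_m ** 3 / 6.0

    def rhs(x_mm: float, y: np.ndarray) -> np.ndarray:
        v = max(float(y[0]), 1e-12)
        st = flow.state(float(x_mm))
        force = henderson_drag(st.velocity_m_s - v, st, d_p_m, flow.gas)
        # dv/dx in (m/s)/mm = F/(m v) * 1e-3
        return np.array([force / (mass * v) * 1e-3])

    xs = np.linspace(x_start_mm, x_end_mm, n_samples)
    sol = integrate.solve_ivp(rhs, (x_start_mm, x_end_mm), [v0_m_s],
                              method="RK45", t_eval=xs, rtol=rtol,
                              atol=1e-9 * max(v0_m_s, 1.0))
    if not sol.success:
        raise AerotrackError(
            f"particle propagation failed: {sol.message}")
    v = sol.y[0]
    v_gas = np.array([flow.state(float(x)).velocity_m_s for x in xs])
    return PropagationResult(x_mm=xs, v_m_s=v, v_gas_m_s=v_gas,
                             terminal_velocity_m_s=float(v[-1]))


def mean_free_path(p_pa: float, T_K: float, gas: GasProperties) -> float:
    """Gas mean free path (m) from viscosity kinetic theory."""
    if p_pa <= 0 or T_K <= 0:
        raise AerotrackError("pressure and temperature must be positive")
    mu = gas.viscosity(T_K)
    return (mu / p_pa) * math.sqrt(
        math.pi * gas.specific_gas_constant * T_K / 2.0)


def cunningham_slip(knudsen: float) -> float:
    """Cunningham slip correction 1 + Kn (1.257 + 0.4 e^(−1.1/Kn))."""
    if knudsen <= 0:
        raise AerotrackError("Knudsen number must be positive")
    return 1.0 + knudsen * (1.257 + 0.4 * math.exp(-1.1 / knudsen))


def stokes_number(inputs: StokesInputs) -> float:
    """St = τ u / (d_f/2) with τ = C_c ρ_p d_p² / (18 μ) and
    u = 4 F_m / (ρ_l π d_f²)."""
    tau = (inputs.slip_correction * inputs.rho_p_kg_m3
           * inputs.d_p_m ** 2 / (18.0 * inputs.viscosity_pa_s))
    u = 4.0 * inputs.mass_flow_kg_s / (
        inputs.gas_density_kg_m3 * math.pi * inputs.d_f_m ** 2)
    return tau * u / (inputs.d_f_m / 2.0)


def stokes_from_conditions(
    entrance_pressure_mbar: float,
    d_p_nm: float,
    rho_p_kg_m3: float = 1050.0,
    T0_K: float = 293.15,
    gas: Optional[GasProperties] = None,
    geometry: Optional[InjectorGeometry] = None,
) -> float:
    """Stokes number of a particle for given lens operating conditions.

    The orifice flow state (mass flow, density, viscosity at the
    throat temperature) comes from the choked-orifice estimate; the
    slip correction uses the particle Knudsen number 2λ/d_p at the
    throat state.
    """
    gas = gas or GasProperties.helium()
    geometry = geometry or InjectorGeometry()
    flow = orifice_flow(mbar_to_pa(entrance_pressure_mbar), T0_K,
                        gas, geometry)
    d_p_m = d_p_nm * 1e-9
    lam = mean_free_path(flow.throat_pressure_pa, flow.throat_T_K, gas)
    c_c = cunningham_slip(2.0 * lam / d_p_m)
    return stokes_number(StokesInputs(
        rho_p_kg_m3=rho_p_kg_m3, d_p_m=d_p_m, slip_correction=c_c,
        mass_flow_kg_s=flow.mass_flow_kg_s,
        gas_density_kg_m3=flow.gas_density_kg_m3,
        viscosity_pa_s=gas.viscosity(flow.throat_T_K),
        d_f_m=geometry.d_f_m))


def default_collapse_model(st: np.ndarray, A: float, B: float,
                           C: float) -> np.ndarray:
    """Default terminal-velocity collapse curve
    v/c = A (1 − exp(−C·St)) + B·St.

    Saturating rise with rate C toward plateau A plus a weak linear
    tail B capturing the residual growth at large Stokes numbers.
    Monotone non-decreasing for non-negative parameters.
    """
    st = np.asarray(st, dtype=float)
    return A * (1.0 - np.exp(-C * st)) + B * st


def fit_velocity_collapse(
    st: Sequence[float],
    v_over_c: Sequence[float],
    model: Callable = default_collapse_model,
    p0: Tuple[float, ...] = (0.5, 0.001, 0.1),
) -> VelocityFit:
    """Nonlinear least squares of the (St, v/c) collapse curve."""
    st = np.asarray(st, dtype=float)
    v = np.asarray(v_over_c, dtype=float)
    if st.size < 5:
        raise AerotrackError("collapse fit needs >= 5 points")
    if np.any(st <= 0):
        raise AerotrackError("Stokes numbers must be positive")
    try:
        popt, _ = optimize.curve_fit(model, st, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise AerotrackError(f"collapse fit did not converge: {exc}") from exc
    resid = model(st, *popt) - v
    return VelocityFit(A=float(popt[0]), B=float(popt[1]), C=float(popt[2]),
                       residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                       model=model)


def fit_entrance_parameters(
    datasets: Sequence[dict],
    gas: Optional[GasProperties] = None,
    orifice_diameter_mm: float = 1.5,
    T0_K: float = 293.15,
    ratio_bounds: Tuple[float, float] = (0.5, 1.0),
    rtol: float = 1e-6,
) -> Tuple[float, List[float], float]:
    """Jointly fit the effective-orifice ratio and per-condition
    entrance velocities to measured (distance, velocity) data.

    Each dataset is a dict with keys ``pressure_mbar``, ``d_p_nm``,
    ``rho_p_kg_m3``, ``x_mm`` (array) and ``v_m_s`` (array); at least
    two distances per condition are required.  Returns
    ``(effective_diameter_ratio, entrance_velocities, residual_rms)``.
    """
    gas = gas or GasProperties.helium()
    if len(datasets) == 0:
        raise AerotrackError("no datasets supplied")
    for ds in datasets:
        if len(ds["x_mm"]) < 2:
            raise AerotrackError(
                "each condition needs >= 2 distances (under-determined fit)")

    n_cond = len(datasets)

    def residuals(params: np.ndarray) -> np.ndarray:
        ratio = params[0]
        v0s = params[1:]
        out = []
        geom = InjectorGeometry(orifice_diameter_mm=orifice_diameter_mm,
                                effective_diameter_ratio=float(ratio))
        for ds, v0 in zip(datasets, v0s):
            flow = FreeJetFlow(ds["pressure_mbar"], T0_K, gas, geom)
            x = np.asarray(ds["x_mm"], dtype=float)
            res = propagate_particle(
                float(max(v0, 1e-3)), ds["d_p_nm"],
                ds.get("rho_p_kg_m3", 1050.0), flow,
                x_end_mm=float(x.max()), rtol=rtol,
                n_samples=64)
            v_model = np.interp(x, res.x_mm, res.v_m_s)
            out.append(v_model - np.asarray(ds["v_m_s"], dtype=float))
        return np.concatenate(out)

    x0 = np.concatenate([[0.9], np.full(n_cond, 20.0)])
    lb = np.concatenate([[ratio_bounds[0]], np.full(n_cond, 1e-3)])
    ub = np.concatenate([[ratio_bounds[1]], np.full(n_cond, 500.0)])
    sol = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                 xtol=1e-10, ftol=1e-10)
    r = residuals(sol.x)
    return (float(sol.x[0]), [float(v) for v in sol.x[1:]],
            float(np.sqrt(np.mean(r ** 2))))
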