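"""Hagen-Poiseuille flow conditions in the sampling capillaries.

Pumping a culture sample through narrow tubing exposes the bacteria to
shear; excessive shear tears off flagella (deflagellation) and destroys
the motility signal the tracker measures.  For laminar pressure-driven
pipe flow the velocity profile is the parabola

    u(y) = 2 u_m [1 - (2y/D)^2],   |y| <= D/2,

with y measured from the capillary axis, so the centreline velocity is
u_max = 2 u_m, the mean velocity is u_m = 4 Q / (pi D^2), the wall shear
rate is |du/dy| at the wall = 8 u_m / D, and the wall shear stress is
tau = eta * gamma_dot for a Newtonian fluid.  Laminarity is judged by the
Reynolds number Re = u_m D / nu < 2300.

All quantities are SI internally (m, s, Pa); the CLI converts from the
bench units (mm, ml/min, mPa s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: critical Reynolds number below which pipe flow is laminar
RE_LAMINAR = 2300.0


@dataclass
class CapillarySpec:
    """Capillary geometry and fluid properties, SI units.

    Any two of (dynamic_viscosity, kinematic_viscosity, density) determine
    the third; if all three are given they must agree to 0.1%.
    """

    diameter: float                    # m
    flow_rate: float                   # m^3/s
    length: float = 0.6                # m
    dynamic_viscosity: float | None = None    # Pa s
    kinematic_viscosity: float | None = None  # m^2/s
    density: float | None = None              # kg/m^3

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.flow_rate <= 0 or self.length <= 0:
            raise ValueError("diameter, flow_rate and length must be positive")
        eta, nu, rho = (self.dynamic_viscosity, self.kinematic_viscosity,
                        self.density)
        for name, v in (("dynamic_viscosity", eta),
                        ("kinematic_viscosity", nu), ("density", rho)):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if eta is not None and nu is not None and rho is not None:
            if abs(eta - rho * nu) > 1e-3 * eta:
                raise ValueError("eta, nu, rho inconsistent: eta != rho*nu")
        elif eta is None and nu is not None and rho is not None:
            self.dynamic_viscosity = rho * nu
        elif nu is None and eta is not None and rho is not None:
            self.kinematic_viscosity = eta / rho
        elif rho is None and eta is not None and nu is not None:
            self.density = eta / nu


@dataclass
class FlowField:
    """Derived flow quantities for one capillary configuration."""

    u_m: float            # mean velocity, m/s
    u_max: float          # centreline velocity, m/s (= 2 u_m)
    wall_shear_rate: float    # 1/s
    wall_shear_stress: float | None  # Pa; None when viscosity unknown
    reynolds: float | None    # dimensionless; None when nu unknown
    laminar: bool | None      # Re < 2300; None when Re unknown

    def to_dict(self) -> dict:
        return {"u_m_m_s": self.u_m, "u_max_m_s": self.u_max,
                "u_m_mm_s": self.u_m * 1e3, "u_max_mm_s": self.u_max * 1e3,
                "wall_shear_rate_1_s": self.wall_shear_rate,
                "wall_shear_stress_pa": self.wall_shear_stress,
                "reynolds": self.reynolds, "laminar": self.laminar}


def mean_velocity(flow_rate: float, diameter: float) -> float:
    """Cross-section averaged velocity u_m = 4 Q / (pi D^2), m/s."""
    if flow_rate < 0 or diameter <= 0:
        raise ValueError("flow_rate must be >= 0 and diameter > 0")
    return 4.0 * flow_rate / (np.pi * diameter ** 2)


def velocity_profile(u_m: float, y: float | np.ndarray,
                     diameter: float) -> float | np.ndarray:
    """Parabolic profile u(y) = 2 u_m (1 - (2y/D)^2), y from the axis."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    y = np.asarray(y, float)
    if np.any(np.abs(y) > diameter / 2.0):
        raise ValueError("|y| must not exceed the capillary radius")
    u = 2.0 * u_m * (1.0 - (2.0 * y / diameter) ** 2)
    return float(u) if u.ndim == 0 else u


def wall_shear_rate(u_m: float, diameter: float) -> float:
    """Shear-rate magnitude at the wall, 8 u_m / D (1/s)."""
    if u_m <= 0 or diameter <= 0:
        raise ValueError("u_m and diameter must be positive")
    return 8.0 * u_m / diameter


def shear_stress(eta: float, gamma_dot: float) -> float:
    """Newtonian wall shear stress tau = eta * gamma_dot (Pa)."""
    if eta < 0 or gamma_dot < 0:
        raise ValueError("eta and gamma_dot must be >= 0")
    return eta * gamma_dot


def reynolds(u_m: float, diameter: float, nu: float) -> tuple[float, bool]:
    """Reynolds number u_m D / nu and the laminar verdict (Re < 2300)."""
    if u_m <= 0 or diameter <= 0 or nu <= 0:
        raise ValueError("u_m, diameter and nu must be positive")
    re = u_m * diameter / nu
    return re, re < RE_LAMINAR


def capillary_report(spec: CapillarySpec) -> FlowField:
    """All derived flow quantities for one capillary configuration."""
    u_m = mean_velocity(spec.flow_rate, spec.diameter)
    gamma = wall_shear_rate(u_m, spec.diameter)
    tau = (shear_stress(spec.dynamic_viscosity, gamma)
           if spec.dynamic_viscosity is not None else None)
    if spec.kinematic_viscosity is not None:
        re, lam = reynolds(u_m, spec.diameter, spec.kinematic_viscosity)
    else:
        re, lam = None, None
    return FlowField(u_m=u_m, u_max=2.0 * u_m, wall_shear_rate=gamma,
                     wall_shear_stress=tau, reynolds=re, laminar=lam)
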