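"""Deterministic mechanics of a single *Utricularia* suction trap.

A trap continuously pumps water out through its porous walls. Pressure
balance between pumping and Darcy back-flow makes the inside/outside
pressure difference rise exponentially towards a saturation value
``dP_max`` with time constant ``tau``.  The trap door is an elastic shell
that buckles (fires) when the pressure difference reaches a critical value
``dP_c``; the firing interval therefore depends only on the threshold
ratio ``x = dP_c / dP_max``:

    T = -tau * ln(1 - x)        (x < 1)

For ``x >= 1`` pumping can never reach the buckling threshold and the trap
sits in a *waiting* state, represented here by the :data:`WAITING`
sentinel (a physical regime, not an error).

Units contract: times are expressed in **hours** at the API surface;
hydraulic quantities are SI (the deflation ODE runs in seconds
internally).  Conversions are centralized in :data:`HOUR`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "HOUR",
    "WAITING",
    "WaitingState",
    "TrapMechanics",
    "WallGeometry",
    "HydraulicParameters",
    "pressure_at",
    "firing_time",
    "buckling_pressure",
    "darcy_coefficient",
    "pumping_saturation_pressure",
    "deflation_tau_hours",
    "simulate_deflation_ode",
    "permeability_estimate",
    "equivalent_hole_radius",
    "reynolds_number",
]

HOUR = 3600.0
"""Seconds per hour; the single place where the units contract is encoded."""


class WaitingState:
    """Sentinel for a trap whose threshold exceeds its pumping capacity.

    Pumping saturates below the buckling pressure, so no spontaneous
    firing ever occurs.  A singleton: compare with ``is WAITING``.
    """

    __slots__ = ()
    _singleton: "WaitingState | None" = None

    def __new__(cls) -> "WaitingState":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "WAITING"


WAITING = WaitingState()


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class TrapMechanics:
    """Reduced mechanical description of one trap.

    Parameters
    ----------
    tau:
        Deflation time constant, hours.
    dP_max:
        Saturation pressure difference of the pump, Pa.
    dP_c:
        Critical buckling pressure of the door, Pa.
    """

    tau: float
    dP_max: float
    dP_c: float

    def __post_init__(self) -> None:
        _require_positive(tau=self.tau, dP_max=self.dP_max, dP_c=self.dP_c)

    @property
    def x(self) -> float:
        """Threshold ratio dP_c / dP_max (dimensionless)."""
        return self.dP_c / self.dP_max


@dataclass(frozen=True)
class WallGeometry:
    """Elastic-shell geometry of the trap door.

    ``E`` Young's modulus (Pa), ``d`` shell thickness (m), ``R`` radius of
    curvature (m), ``nu`` Poisson ratio (0.5 for an incompressible wall).
    """

    E: float
    d: float
    R: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        _require_positive(E=self.E, d=self.d, R=self.R)
        if not self.d < self.R:
            raise ValueError("shell thickness d must be smaller than radius R")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5], got {self.nu!r}")


@dataclass(frozen=True)
class HydraulicParameters:
    """Poroelastic description of the trap body (all SI).

    ``eta`` water viscosity (Pa s), ``e`` wall thickness (m), ``kappa``
    wall permeability (m^2), ``S`` trap surface area (m^2), ``V0``
    inflated volume (m^3), ``k`` effective elastic modulus linking
    pressure to relative volume change (Pa), ``q_p`` constant pumping
    flow rate (m^3/s), ``rho`` water density (kg/m^3).
    """

    eta: float = 1e-3
    e: float = 2e-5
    kappa: float = 3.5e-20
    S: float = 4e-6
    V0: float = 1e-9
    k: float = 4e4
    q_p: float = 1e-15
    rho: float = 1e3

    def __post_init__(self) -> None:
        _require_positive(
            eta=self.eta, e=self.e, kappa=self.kappa, S=self.S,
            V0=self.V0, k=self.k, rho=self.rho,
        )
        if self.q_p < 0:  # q_p = 0 is the physical no-pumping limit
            raise ValueError("pumping rate q_p must be >= 0")


def pressure_at(t, mech: TrapMechanics):
    """Pressure difference (Pa) a time ``t`` hours after the door closed.

    dP(t) = dP_max * (1 - exp(-t / tau)): strictly increasing, concave and
    bounded above by ``dP_max``.  ``t`` may be a scalar or array; negative
    times are a domain error (the pressure is reset at each firing).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative (pressure resets at firing)")
    out = mech.dP_max * -np.expm1(-t / mech.tau)
    return float(out) if out.ndim == 0 else out


def firing_time(x: float, tau: float):
    """Spontaneous firing interval (hours) for threshold ratio ``x``.

    Returns ``-tau * ln(1 - x)`` for ``0 < x < 1`` and the :data:`WAITING`
    sentinel for ``x >= 1`` (pumping saturates below threshold).
    ``x <= 0`` is a domain error.
    """
    _require_positive(tau=tau)
    if not x > 0:
        raise ValueError(f"threshold ratio x must be > 0, got {x!r}")
    if x >= 1.0:
        return WAITING
    return -tau * math.log1p(-x)


def buckling_pressure(geom: WallGeometry, prefactor: float | None = None) -> float:
    """Critical buckling pressure (Pa) of a thin spherical shell.

    Classical result 2*E*d^2 / (R^2 * sqrt(3*(1 - nu^2))); with nu = 0.5
    this reduces to (4/3)*E*d^2/R^2.  The exact prefactor is shape
    dependent, so ``prefactor`` (multiplying E*d^2/R^2) may be overridden.
    """
    if prefactor is None:
        prefactor = 2.0 / math.sqrt(3.0 * (1.0 - geom.nu**2))
    return prefactor * geom.E * geom.d**2 / geom.R**2


def darcy_coefficient(h: HydraulicParameters) -> float:
    """Hydraulic resistance K = eta*e/(kappa*S) (Pa s / m^3).

    Darcy back-flow through the porous wall is q_in = dP / K.
    """
    return h.eta * h.e / (h.kappa * h.S)


def pumping_saturation_pressure(h: HydraulicParameters) -> float:
    """Steady-state pressure difference dP_max = q_p * K (Pa)."""
    return h.q_p * darcy_coefficient(h)


def deflation_tau_hours(h: HydraulicParameters) -> float:
    """Deflation time constant tau = V0*K/k, converted to hours."""
    return h.V0 * darcy_coefficient(h) / h.k / HOUR


def simulate_deflation_ode(h: HydraulicParameters, t_grid) -> np.ndarray:
    """Numerically integrate the pumping/leak pressure balance.

    Solves d(dP)/dt = (k/V0) * (q_p - dP/K) from dP(0) = 0 on ``t_grid``
    (seconds, strictly increasing from 0) and returns dP in Pa.  The
    closed-form exponential with dP_max = q_p*K and tau = V0*K/k is the
    accuracy oracle; adaptive stepping at rtol 1e-9 keeps the relative
    deviation well below 1e-6.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a 1-d array of times")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase strictly from 0")
    K = darcy_coefficient(h)
    dP_max = h.q_p * K
    rate = h.k / (h.V0 * K)  # 1/s

    def rhs(_t, y):
        return [h.k / h.V0 * h.q_p - rate * y[0]]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [0.0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-9,
        atol=max(dP_max * 1e-12, 1e-30),
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"deflation ODE integration failed: {sol.message}")
    return sol.y[0]


def permeability_estimate(
    tau_measured: float,
    *,
    eta: float = 1e-3,
    e: float = 2e-5,
    V0: float = 1e-9,
    S: float = 4e-6,
    k: float = 4e4,
) -> float:
    """Wall permeability kappa (m^2) inferred from a measured tau (hours).

    Inverts tau = V0*K/k with K = eta*e/(kappa*S):
    kappa = eta*e*V0 / (tau * S * k).  If leaks other than wall porosity
    contribute, the true permeability is lower: this is an upper bound.
    """
    _require_positive(tau_measured=tau_measured)
    return eta * e * V0 / (tau_measured * HOUR * S * k)


def equivalent_hole_radius(kappa: float, S: float) -> float:
    """Radius (m) of the single hole hydraulically equivalent to the wall.

    A Poiseuille hole of radius R_h has resistance 8*eta*e/(pi*R_h^4);
    equating to the Darcy resistance eta*e/(kappa*S) gives
    R_h = (8*kappa*S/pi)**(1/4).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    _require_positive(S=S)
    return (8.0 * kappa * S / math.pi) ** 0.25


def reynolds_number(rho: float, q: float, R_h: float, eta: float) -> float:
    """Reynolds number of the leak flow through the equivalent hole.

    Re = rho*u*R_h/eta with mean velocity u = q/(pi*R_h^2), i.e.
    Re = rho*q/(pi*eta*R_h).  Values << 1 justify the Poiseuille model.
    """
    _require_positive(R_h=R_h, eta=eta, rho=rho)
    if q < 0:
        raise ValueError("flow rate q must be non-negative")
    return rho * q / (math.pi * eta * R_h)
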