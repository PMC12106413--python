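"""Mechanistic soil-plant pollutant kinetics.

Models the fate of a soil pollutant during phytoremediation as four coupled
pools: dissolved/sorbed soil concentration ``C``, pollutant held in plant
tissue (``M_active``), pollutant metabolized inside the plant into harmless
products (``M_metabolized``), and pollutant degraded in place by soil
biogeochemistry (``M_degraded``).  Soil loss is first order with rate
constant ``k``, root uptake is first order with rate constant ``r_p``, and
in-plant transformation drains the active tissue pool with rate constant
``k_t``:

    dC/dt            = -m(t) * (k + r_p) * C
    dM_active/dt     =  m(t) * r_p * C  -  k_t * M_active
    dM_metabolized/dt =  k_t * M_active
    dM_degraded/dt   =  m(t) * k * C

where ``m(t)`` is a dimensionless environmental rate modifier combining a
Q10 temperature response with a saturating moisture response.  The four
equations sum to zero, so the pools conserve the initial concentration
``C0`` exactly; the integrators below preserve this to machine precision.

All concentrations are in mg per kg of soil (plant pools are expressed in
soil-equivalent units so the mass balance is meaningful), time in hours and
rate constants in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "EnvDrivers",
    "RemediationTrajectory",
    "decay_closed_form",
    "rate_modifier",
    "plant_uptake_amount",
    "simulate_soil_plant",
    "mass_balance_check",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and initial condition of the soil-plant system.

    Parameters
    ----------
    C0 : float
        Initial soil pollutant concentration, mg/kg.
    k : float
        First-order soil degradation rate constant, 1/h.
    r_p : float
        First-order plant (root) uptake rate constant, 1/h.
    k_t : float
        First-order in-plant transformation rate constant, 1/h.
    """

    C0: float
    k: float
    r_p: float = 0.0
    k_t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C0", "k", "r_p", "k_t"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class EnvDrivers:
    """Environmental forcing of the soil reaction rates.

    ``temperature_c`` and ``moisture`` may be scalars (constant environment)
    or series sampled on ``time_h`` (defaults to a uniform grid spanning the
    simulation horizon).  The modifier is
    ``q10 ** ((T - t_ref) / 10) * min(moisture / moisture_opt, 1)``:
    rates double per ``10/log2(q10)`` degrees and are linearly limited by
    moisture below the optimum.
    """

    temperature_c: ArrayLike
    moisture: ArrayLike
    q10: float = 2.0
    t_ref: float = 15.0
    moisture_opt: float = 0.3
    time_h: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.q10 <= 0:
            raise ValueError(f"q10 must be > 0, got {self.q10!r}")
        if not 0 < self.moisture_opt <= 1:
            raise ValueError(
                f"moisture_opt must be in (0, 1], got {self.moisture_opt!r}"
            )
        moist = np.asarray(self.moisture, dtype=float)
        if np.any(moist < 0) or np.any(moist > 1):
            raise ValueError("moisture must lie in [0, 1]")


@dataclass
class RemediationTrajectory:
    """Time series of the four pollutant pools from one simulation."""

    time: np.ndarray
    C: np.ndarray
    M_active: np.ndarray
    M_metabolized: np.ndarray
    M_degraded: np.ndarray
    params: KineticParams = field(repr=False)

    def pool_sum(self) -> np.ndarray:
        return self.C + self.M_active + self.M_metabolized + self.M_degraded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "C_mg_per_kg": self.C,
                "M_active": self.M_active,
                "M_metabolized": self.M_metabolized,
                "M_degraded": self.M_degraded,
            }
        )


def decay_closed_form(C0: ArrayLike, k: float, t: ArrayLike) -> ArrayLike:
    """Closed-form first-order decay ``C0 * exp(-k t)``."""
    C0_a, t_a = np.asarray(C0, dtype=float), np.asarray(t, dtype=float)
    if np.any(C0_a < 0):
        raise ValueError("C0 must be >= 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    if np.any(t_a < 0):
        raise ValueError("t must be >= 0")
    out = C0_a * np.exp(-k * t_a)
    return float(out) if out.ndim == 0 else out


def rate_modifier(
    temperature_c: ArrayLike, moisture: ArrayLike, env: EnvDrivers
) -> ArrayLike:
    """Dimensionless environmental multiplier on soil reaction rates.

    Q10 temperature response times a saturating (capped linear) moisture
    response; equals 1 at the reference temperature with moisture at or
    above the optimum.
    """
    temp = np.asarray(temperature_c, dtype=float)
    moist = np.asarray(moisture, dtype=float)
    if np.any(moist < 0) or np.any(moist > 1):
        raise ValueError("moisture must lie in [0, 1]")
    out = env.q10 ** ((temp - env.t_ref) / 10.0) * np.minimum(
        moist / env.moisture_opt, 1.0
    )
    return float(out) if out.ndim == 0 else out


def plant_uptake_amount(r_p: float, C: ArrayLike) -> ArrayLike:
    """Instantaneous plant uptake ``r_p * C``.

    This is the static reading of the uptake law (an amount proportional to
    the current soil concentration).  The dynamic simulator uses the same
    product as a flux out of the soil pool; see :func:`simulate_soil_plant`.
    """
    C_a = np.asarray(C, dtype=float)
    if r_p < 0:
        raise ValueError("r_p must be >= 0")
    if np.any(C_a < 0):
        raise ValueError("C must be >= 0")
    out = r_p * C_a
    return float(out) if out.ndim == 0 else out


def _modifier_function(
    env: Optional[EnvDrivers], horizon: float
) -> Callable[[float], float]:
    if env is None:
        return lambda t: 1.0
    temp = np.asarray(env.temperature_c, dtype=float)
    moist = np.asarray(env.moisture, dtype=float)
    if temp.ndim == 0 and moist.ndim == 0:
        value = float(rate_modifier(float(temp), float(moist), env))
        return lambda t: value
    n = max(temp.size if temp.ndim else 0, moist.size if moist.ndim else 0)
    grid = env.time_h if env.time_h is not None else np.linspace(0.0, horizon, n)
    grid = np.asarray(grid, dtype=float)
    temp_series = np.broadcast_to(temp, (n,)) if temp.ndim == 0 else temp
    moist_series = np.broadcast_to(moist, (n,)) if moist.ndim == 0 else moist
    if grid.size != n:
        raise ValueError("time_h length must match the driver series length")
    modifier = np.asarray(rate_modifier(temp_series, moist_series, env))

    def m(t: float) -> float:
        return float(np.interp(t, grid, modifier))

    return m


def simulate_soil_plant(
    params: KineticParams,
    env: Optional[EnvDrivers] = None,
    horizon: float = 24.0,
    dt: float = 0.01,
    scheme: str = "rk4",
) -> RemediationTrajectory:
    """Integrate the coupled soil-plant pollutant system.

    Parameters
    ----------
    params : KineticParams
        Rate constants and initial soil concentration.
    env : EnvDrivers, optional
        Environmental forcing; ``None`` means modifier 1 throughout.
    horizon : float
        Simulated time span, h.
    dt : float
        Fixed integrator step, h.
    scheme : {"rk4", "euler"}
        Classical Runge-Kutta (default) or forward Euler (kept for
        convergence-order checks).
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon!r}")
    if dt <= 0 or dt > horizon:
        raise ValueError(f"dt must satisfy 0 < dt <= horizon, got {dt!r}")
    if scheme not in ("rk4", "euler"):
        raise ValueError(f"scheme must be 'rk4' or 'euler', got {scheme!r}")

    m = _modifier_function(env, horizon)
    k, r_p, k_t = params.k, params.r_p, params.k_t

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        C, Ma, _, _ = y
        mt = m(t)
        return np.array(
            [
                -mt * (k + r_p) * C,
                mt * r_p * C - k_t * Ma,
                k_t * Ma,
                mt * k * C,
            ]
        )

    n_steps = int(round(horizon / dt))
    time = np.linspace(0.0, n_steps * dt, n_steps + 1)
    states = np.empty((n_steps + 1, 4))
    states[0] = [params.C0, 0.0, 0.0, 0.0]
    y = states[0].copy()
    for i in range(n_steps):
        t = time[i]
        if scheme == "euler":
            y = y + dt * deriv(t, y)
        else:
            k1 = deriv(t, y)
            k2 = deriv(t + dt / 2, y + dt / 2 * k1)
            k3 = deriv(t + dt / 2, y + dt / 2 * k2)
            k4 = deriv(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        states[i + 1] = y

    return RemediationTrajectory(
        time=time,
        C=states[:, 0],
        M_active=states[:, 1],
        M_metabolized=states[:, 2],
        M_degraded=states[:, 3],
        params=params,
    )


def mass_balance_check(traj: RemediationTrajectory) -> float:
    """Maximum relative departure of the pool sum from ``C0``."""
    if traj.time.size == 0:
        raise ValueError("trajectory is empty")
    C0 = traj.params.C0
    total = traj.pool_sum()
    if C0 == 0:
        if np.any(total != 0):
            raise ValueError("C0 is zero but pools are nonzero")
        return 0.0
    return float(np.max(np.abs(total - C0)) / C0)
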