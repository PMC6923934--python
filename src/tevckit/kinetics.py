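"""Closed-form model equations for two-state charge movement and transport.

These are the shared primitives consumed by both the simulator and the
fitting routines: the Boltzmann steady-state charge distribution, the
symmetric-barrier unidirectional rate constants and their relaxation time,
the Michaelis-type dose-response current, and small derived quantities
(transport efficiency, affinity ratio, electrical-field fraction).

Units are fixed throughout the package: voltages in mV, times in ms,
currents in nA, charge in nC, concentrations in mmol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChargeMovementParams",
    "DoseResponseModel",
    "PhysicalConstants",
    "RateConstantPoint",
    "boltzmann_charge",
    "equilibrium_outer_fraction",
    "rate_constants",
    "relaxation_tau",
    "dose_response_current",
    "transport_efficiency",
    "affinity_ratio",
    "field_fraction",
]

# Exponents are clamped at +/- EXP_CLAMP before exponentiation so that
# extreme voltages degrade gracefully to the sigmoid limits instead of
# overflowing.  exp(50) ~ 5e21 is far outside any physical rate here.
EXP_CLAMP = 50.0

_BOLTZMANN_K = 1.380649e-23  # J/K
_ELEMENTARY_Q = 1.602176634e-19  # C


@dataclass(frozen=True)
class ChargeMovementParams:
    """Two-state charge-movement scenario.

    Parameters
    ----------
    Q_max:
        Maximal moveable charge, nC.
    V_half:
        Midpoint voltage of the charge distribution, mV.
    sigma:
        Slope factor of the sigmoid, mV.
    tau_peak:
        Relaxation time constant at ``V_half`` (the maximum of the
        bell-shaped tau/V relation), ms.
    """

    Q_max: float
    V_half: float
    sigma: float
    tau_peak: float

    def __post_init__(self) -> None:
        if not (self.Q_max > 0):
            raise ValueError(f"Q_max must be > 0, got {self.Q_max}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau_peak > 0):
            raise ValueError(f"tau_peak must be > 0, got {self.tau_peak}")
        if not math.isfinite(self.V_half):
            raise ValueError(f"V_half must be finite, got {self.V_half}")


@dataclass(frozen=True)
class DoseResponseModel:
    """Michaelis-type dose-response: half-saturation ``K_half`` (mmol/L)
    and maximal current ``I_max`` (nA, negative for inward current)."""

    K_half: float
    I_max: float

    def __post_init__(self) -> None:
        if not (self.K_half > 0):
            raise ValueError(f"K_half must be > 0, got {self.K_half}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal constants; temperature defaults to 22 degC room temperature."""

    temperature: float = 295.15  # K

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def thermal_voltage_mV(self) -> float:
        """kT/q in mV."""
        return _BOLTZMANN_K * self.temperature / _ELEMENTARY_Q * 1e3


@dataclass(frozen=True)
class RateConstantPoint:
    """Unidirectional rate constants (1/s) of the two-state charge
    redistribution at membrane potential ``V`` (mV)."""

    V: float
    k_out: float
    k_in: float

    def __post_init__(self) -> None:
        if self.k_out < 0 or self.k_in < 0:
            raise ValueError("rate constants must be non-negative")


def _check_voltage(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    return V


def boltzmann_charge(V, p: ChargeMovementParams):
    """Steady-state moved charge Q(V) = Q_max / (1 + exp(-(V - V_half)/sigma)).

    Strictly increasing in V, bounded in (0, Q_max).  Accepts scalars or
    arrays of voltages (mV); returns nC.
    """
    V = _check_voltage(V)
    x = np.clip(-(V - p.V_half) / p.sigma, -EXP_CLAMP, EXP_CLAMP)
    out = p.Q_max / (1.0 + np.exp(x))
    return out if out.ndim else float(out)


def equilibrium_outer_fraction(V, p: ChargeMovementParams):
    """Fraction of charge in the outer position at equilibrium, in (0, 1)."""
    q = boltzmann_charge(V, p)
    return q / p.Q_max


def rate_constants(V: float, p: ChargeMovementParams) -> RateConstantPoint:
    """Unidirectional rate constants under a symmetric barrier split.

    k_out = exp(+(V - V_half)/(2 sigma)) / (2 tau_peak),
    k_in  = exp(-(V - V_half)/(2 sigma)) / (2 tau_peak),

    with tau_peak converted to seconds so rates come out in 1/s.  By
    construction ``k_out / (k_out + k_in)`` equals
    :func:`equilibrium_outer_fraction` and ``1 / (k_out + k_in)`` equals
    :func:`relaxation_tau` (in seconds).
    """
    V = float(_check_voltage(V))
    tau_s = p.tau_peak * 1e-3
    u = np.clip((V - p.V_half) / (2.0 * p.sigma), -EXP_CLAMP, EXP_CLAMP)
    k_out = math.exp(u) / (2.0 * tau_s)
    k_in = math.exp(-u) / (2.0 * tau_s)
    return RateConstantPoint(V=V, k_out=k_out, k_in=k_in)


def relaxation_tau(V, p: ChargeMovementParams):
    """Relaxation time constant tau(V) = tau_peak / cosh((V - V_half)/(2 sigma)).

    Bell-shaped, maximal (= tau_peak) at V = V_half.  Returns ms.
    """
    V = _check_voltage(V)
    u = np.clip((V - p.V_half) / (2.0 * p.sigma), -EXP_CLAMP, EXP_CLAMP)
    out = p.tau_peak / np.cosh(u)
    return out if out.ndim else float(out)


def dose_response_current(S, m: DoseResponseModel):
    """Transport current at substrate concentration S (mmol/L).

    I(S) = I_max * S / (S + K_half) -- algebraically identical to the
    rearranged form -I_max / (1 + S/K_half) + I_max.  I(0) = 0 and
    I -> I_max as S -> infinity.  Inward currents are negative.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = m.I_max * S / (S + m.K_half)
    return out if out.ndim else float(out)


def transport_efficiency(I_max: float, K_half: float) -> float:
    """Transport efficiency |I_max| / K_half, reported as a positive
    magnitude (nA per mmol/L)."""
    if not (K_half > 0):
        raise ValueError(f"K_half must be > 0, got {K_half}")
    return abs(I_max) / K_half


def affinity_ratio(K_a: float, K_b: float) -> float:
    """Ratio of two half-saturation constants, K_a / K_b."""
    if not (K_a > 0 and K_b > 0):
        raise ValueError("affinity constants must be > 0")
    return K_a / K_b


def field_fraction(sigma: float, c: PhysicalConstants | None = None) -> float:
    """Fraction delta of the membrane electric field traversed by the moving
    charge, from the slope factor: sigma = kT/(q delta)  =>  delta = (kT/q)/sigma."""
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if c is None:
        c = PhysicalConstants()
    return c.thermal_voltage_mV / sigma
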