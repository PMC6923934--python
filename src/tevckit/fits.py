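"""Parameter estimation: Boltzmann Q/V fits, rate-constant reconstruction
from Q/V + tau/V, per-voltage logistic dose-response fits, efficiency."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .analyze import IVPoint, QVPoint, TauVPoint
from .kinetics import RateConstantPoint, transport_efficiency

__all__ = [
    "BoltzmannFitResult",
    "DoseResponseFit",
    "RateConstantCurve",
    "fit_boltzmann",
    "normalize_qv",
    "reconstruct_rate_constants",
    "fit_dose_response",
    "fit_dose_response_frame",
    "efficiency_curve",
]

SIGMA_MAX = 200.0  # mV, upper bound on the Boltzmann slope factor


@dataclass(frozen=True)
class BoltzmannFitResult:
    Q_max: float
    V_half: float
    sigma: float
    Q_0: float
    se_Q_max: float = float("nan")
    se_V_half: float = float("nan")
    se_sigma: float = float("nan")
    se_Q_0: float = float("nan")
    converged: bool = True

    def predict(self, V) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        return self.Q_0 + self.Q_max / (
            1.0 + np.exp(-(V - self.V_half) / self.sigma))

    def outer_fraction(self, V) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        return 1.0 / (1.0 + np.exp(-(V - self.V_half) / self.sigma))


@dataclass(frozen=True)
class DoseResponseFit:
    V: float
    K_half: float
    I_max: float
    se_K_half: float = float("nan")
    se_I_max: float = float("nan")
    pH: float = float("nan")
    n_points: int = 0
    saturating: bool = True
    oocyte_id: str = ""
    converged: bool = True

    @property
    def efficiency(self) -> float:
        return transport_efficiency(self.I_max, self.K_half)


@dataclass(frozen=True)
class RateConstantCurve:
    points: tuple
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))


def _boltzmann_offset(V, Q0, Qmax, Vh, sigma):
    return Q0 + Qmax / (1.0 + np.exp(-(V - Vh) / np.abs(sigma)))


def fit_boltzmann(qv) -> BoltzmannFitResult:
    """Least-squares Boltzmann fit Q(V) = Q_0 + Q_max/(1+exp(-(V-V_half)/sigma)).

    Deterministic initial guesses: Q_max = data range, V_half = voltage
    mid-range, sigma = voltage range / 6, Q_0 = minimum.  At least five
    distinct voltages are required; sigma is bounded in (0, 200] mV.
    """
    V = np.array([p.V for p in qv], dtype=float)
    Q = np.array([p.Q for p in qv], dtype=float)
    if np.unique(V).size < 5:
        raise ValueError("need at least 5 distinct voltages for a Boltzmann fit")
    q_range = float(np.ptp(Q))
    v_range = float(np.ptp(V))
    p0 = (float(np.min(Q)), q_range if q_range > 0 else 1.0,
          float((np.min(V) + np.max(V)) / 2.0),
          v_range / 6.0 if v_range > 0 else 10.0)
    bounds = ([-np.inf, 0.0, -np.inf, 1e-6],
              [np.inf, np.inf, np.inf, SIGMA_MAX])
    try:
        popt, pcov = curve_fit(_boltzmann_offset, V, Q, p0=p0, bounds=bounds,
                               maxfev=20000)
    except RuntimeError:
        return BoltzmannFitResult(Q_max=float("nan"), V_half=float("nan"),
                                  sigma=float("nan"), Q_0=float("nan"),
                                  converged=False)
    q0, qmax, vh, sigma = popt
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return BoltzmannFitResult(
        Q_max=float(qmax), V_half=float(vh), sigma=float(abs(sigma)),
        Q_0=float(q0), se_Q_0=float(se[0]), se_Q_max=float(se[1]),
        se_V_half=float(se[2]), se_sigma=float(se[3]), converged=True,
    )


def normalize_qv(qv, fit: BoltzmannFitResult):
    """Normalized charge (Q - Q_0) / Q_max for each point, nominally in [0, 1]."""
    if not fit.converged:
        raise ValueError("cannot normalize with a non-converged fit")
    return [QVPoint(V=p.V, Q=(p.Q - fit.Q_0) / fit.Q_max,
                    oocyte_id=p.oocyte_id) for p in qv]


def reconstruct_rate_constants(fit: BoltzmannFitResult, tauv) -> RateConstantCurve:
    """Unidirectional rate constants from a fitted charge distribution and
    measured relaxation times.

    At each voltage: p_out is the normalized Boltzmann value, and
    k_out = p_out / tau, k_in = (1 - p_out) / tau with tau in seconds, so
    k_out + k_in = 1/tau holds exactly by construction.
    """
    if not fit.converged:
        raise ValueError("Boltzmann fit did not converge")
    points = []
    for p in tauv:
        if not (p.tau > 0):
            raise ValueError(f"tau must be > 0 at V={p.V}")
        p_out = float(fit.outer_fraction(p.V))
        tau_s = p.tau * 1e-3
        points.append(RateConstantPoint(V=p.V, k_out=p_out / tau_s,
                                        k_in=(1.0 - p_out) / tau_s))
    points.sort(key=lambda r: r.V)
    return RateConstantCurve(points=tuple(points))


def _logistic(S, I_max, K_half):
    return I_max * S / (S + np.abs(K_half))


def _fit_one_dose(S: np.ndarray, I: np.ndarray, V: float, pH: float,
                  oocyte_id: str) -> DoseResponseFit:
    mask = S > 0
    Sp, Ip = S[mask], I[mask]
    if np.unique(Sp).size < 4:
        raise ValueError("need at least 4 non-zero concentrations per voltage")
    if np.ptp(np.log10(Sp)) < 1.0:
        raise ValueError("concentrations must span at least one decade")
    if np.allclose(Ip, 0.0):
        raise ValueError("all-zero currents cannot constrain a dose-response fit")
    i_max0 = Ip[np.argmax(Sp)]
    # concentration whose current is closest to half the largest response
    k0 = float(Sp[np.argmin(np.abs(Ip - i_max0 / 2.0))])
    try:
        popt, pcov = curve_fit(_logistic, Sp, Ip,
                               p0=(float(i_max0), max(k0, 1e-6)),
                               maxfev=20000)
    except RuntimeError:
        return DoseResponseFit(V=V, K_half=float("nan"), I_max=float("nan"),
                               pH=pH, n_points=int(Sp.size),
                               oocyte_id=oocyte_id, converged=False,
                               saturating=False)
    i_max, k_half = float(popt[0]), float(abs(popt[1]))
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return DoseResponseFit(
        V=V, K_half=k_half, I_max=i_max, se_I_max=float(se[0]),
        se_K_half=float(se[1]), pH=pH, n_points=int(Sp.size),
        saturating=bool(float(np.max(Sp)) >= k_half),
        oocyte_id=oocyte_id, converged=True,
    )


def fit_dose_response(points) -> list:
    """Per-voltage logistic fits I(S) = I_max S / (S + K_half).

    ``points`` is an iterable of IVPoint; one fit is produced per
    (voltage, oocyte) group.  The saturation flag is false when the
    largest tested concentration is below the fitted K_half (the estimate
    is then an extrapolation and typically carries a wide SE).
    """
    df = pd.DataFrame(
        [{"V": p.V, "S": p.S, "I": p.I, "pH": p.pH,
          "oocyte_id": p.oocyte_id} for p in points])
    fits = []
    for (V, oocyte), grp in df.groupby(["V", "oocyte_id"], sort=True):
        fits.append(_fit_one_dose(
            grp["S"].to_numpy(), grp["I"].to_numpy(), V=float(V),
            pH=float(grp["pH"].iloc[0]), oocyte_id=str(oocyte)))
    return fits


def fit_dose_response_frame(df: pd.DataFrame) -> list:
    """Same as :func:`fit_dose_response` but on the tidy frame written by
    the simulator (columns oocyte_id, V_mV, S_mM, I_nA, pH)."""
    points = [IVPoint(V=r.V_mV, S=r.S_mM, I=r.I_nA, pH=r.pH,
                      oocyte_id=r.oocyte_id)
              for r in df.itertuples()]
    return fit_dose_response(points)


def efficiency_curve(fits) -> pd.DataFrame:
    """Transport efficiency |I_max|/K_half per voltage (no smoothing)."""
    fits = [f for f in fits if f.converged]
    if len({f.V for f in fits}) < 2:
        raise ValueError("need fits at >= 2 voltages for an efficiency curve")
    rows = [{"V_mV": f.V, "efficiency": f.efficiency,
             "oocyte_id": f.oocyte_id, "pH": f.pH} for f in fits]
    return pd.DataFrame(rows).sort_values("V_mV", ignore_index=True)
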