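"""Raw sweep analysis: transport-current subtraction, steady-state I/V
points, double-exponential isolation of pre-steady-state transients, and
Q/V + tau/V extraction with the on/off-transient convention."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import TraceSet

__all__ = [
    "TransientFit",
    "QVPoint",
    "TauVPoint",
    "IVPoint",
    "subtract_traces",
    "steady_state_current",
    "fit_transient",
    "extract_charge",
    "build_qv_tauv",
]


@dataclass(frozen=True)
class TransientFit:
    """Double-exponential decomposition of a post-step current segment.

    Amplitudes are referenced to the step edge time, so the analytic
    integral of each component is simply A * tau.  Components are labelled
    by time constant (tau_fast < tau_slow), not by fitting order.
    """

    step_mV: float
    baseline: float
    A_fast: float
    tau_fast: float
    A_slow: float
    tau_slow: float
    residual_rms: float
    source: str  # "on" | "off"
    converged: bool = True
    separable: bool = True

    def __post_init__(self) -> None:
        if self.source not in ("on", "off"):
            raise ValueError("source must be 'on' or 'off'")
        if self.converged and not (0 < self.tau_fast <= self.tau_slow):
            raise ValueError("require 0 < tau_fast <= tau_slow")


@dataclass(frozen=True)
class QVPoint:
    V: float
    Q: float  # nC
    oocyte_id: str = ""


@dataclass(frozen=True)
class TauVPoint:
    V: float
    tau: float  # ms
    oocyte_id: str = ""

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class IVPoint:
    V: float
    S: float
    I: float
    pH: float = float("nan")
    oocyte_id: str = ""


def subtract_traces(with_sub: TraceSet, without_sub: TraceSet) -> TraceSet:
    """Transport-associated currents: (presence - absence), pointwise.

    Protocols, sample counts, and oocyte ids (when present) must match.
    """
    if with_sub.protocol != without_sub.protocol:
        raise ValueError("protocol mismatch between the two trace sets")
    if with_sub.sweeps.shape != without_sub.sweeps.shape:
        raise ValueError("sweep shape mismatch")
    id_a = with_sub.metadata.get("oocyte_id")
    id_b = without_sub.metadata.get("oocyte_id")
    if id_a is not None and id_b is not None and id_a != id_b:
        raise ValueError(f"oocyte id mismatch: {id_a!r} vs {id_b!r}")
    meta = dict(with_sub.metadata)
    meta["transport_associated"] = True
    return TraceSet(
        protocol=with_sub.protocol,
        sweeps=with_sub.sweeps - without_sub.sweeps,
        metadata=meta,
    )


def steady_state_current(trace: TraceSet, window_ms: float = 100.0) -> list:
    """Mean current over the last ``window_ms`` of each pulse segment."""
    proto = trace.protocol
    n_win = int(math.floor(window_ms * proto.sample_rate / 1000.0 + 0.5))
    if n_win < 1 or window_ms > proto.pulse_ms:
        raise ValueError(
            f"window {window_ms} ms does not fit inside the "
            f"{proto.pulse_ms} ms pulse"
        )
    i_end = proto.n_pre + proto.n_pulse
    meta = trace.metadata
    points = []
    for k, V_s in enumerate(proto.steps):
        mean_i = float(np.mean(trace.sweeps[k, i_end - n_win:i_end]))
        points.append(IVPoint(
            V=V_s, S=float(meta.get("substrate_mM", float("nan"))),
            I=mean_i, pH=float(meta.get("pH", float("nan"))),
            oocyte_id=str(meta.get("oocyte_id", "")),
        ))
    return points


def _double_exp(t, baseline, a1, tau1, a2, tau2):
    return (baseline + a1 * np.exp(-t / np.abs(tau1))
            + a2 * np.exp(-t / np.abs(tau2)))


# Deterministic restart schedule: multipliers on the two tau guesses.
_RESTARTS = ((0.5, 2.0), (2.0, 0.5), (0.3, 3.0))


def fit_transient(
    t_ms: np.ndarray,
    y_nA: np.ndarray,
    t0_ms: float,
    fit_start_ms: float | None = None,
    fit_len_ms: float | None = None,
    step_mV: float = float("nan"),
    source: str = "on",
    tau_fast_guess: float = 1.0,
    tau_slow_guess: float = 10.0,
) -> TransientFit:
    """Least-squares fit of baseline + A_f exp(-(t-t0)/tau_f)
    + A_s exp(-(t-t0)/tau_s) over [fit_start, fit_start + fit_len].

    ``fit_start_ms`` defaults to one sample after the edge; ``fit_len_ms``
    to the remainder of the segment.  Initial guesses are deterministic
    (baseline from the last decile of the window, amplitudes split 50/50
    from the first-sample residual); non-convergence triggers three fixed
    tau-perturbation restarts and is flagged, never silent.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    y_nA = np.asarray(y_nA, dtype=float)
    if t_ms.shape != y_nA.shape or t_ms.ndim != 1:
        raise ValueError("t_ms and y_nA must be matching 1-D arrays")
    dt = float(np.median(np.diff(t_ms)))
    if fit_start_ms is None:
        fit_start_ms = t0_ms + dt
    if fit_len_ms is None:
        fit_len_ms = t_ms[-1] - fit_start_ms
    mask = (t_ms >= fit_start_ms - 1e-9) & (t_ms <= fit_start_ms + fit_len_ms + 1e-9)
    tw = t_ms[mask] - t0_ms
    yw = y_nA[mask]
    if tw.size < 8:
        raise ValueError(f"only {tw.size} samples in fit window; need >= 8")

    n_tail = max(1, tw.size // 10)
    baseline0 = float(np.mean(yw[-n_tail:]))
    spread = float(np.ptp(yw))
    scale = max(abs(baseline0), spread, 1.0)
    if spread <= 1e-12 * scale:
        # flat segment: nothing to fit
        return TransientFit(
            step_mV=step_mV, baseline=baseline0, A_fast=0.0,
            tau_fast=tau_fast_guess, A_slow=0.0, tau_slow=tau_slow_guess,
            residual_rms=0.0, source=source, converged=True, separable=False,
        )

    # amplitudes referenced to the edge: back-extrapolate first residual
    r0 = float(yw[0] - baseline0)
    guesses = [(baseline0, r0 / 2, tau_fast_guess, r0 / 2, tau_slow_guess)]
    for mf, ms in _RESTARTS:
        guesses.append((baseline0, r0 / 2, tau_fast_guess * mf,
                        r0 / 2, tau_slow_guess * ms))

    popt = None
    for p0 in guesses:
        try:
            popt, _ = curve_fit(_double_exp, tw, yw, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        break
    if popt is None:
        return TransientFit(
            step_mV=step_mV, baseline=baseline0, A_fast=0.0,
            tau_fast=tau_fast_guess, A_slow=0.0, tau_slow=tau_slow_guess,
            residual_rms=float(np.std(yw - baseline0)), source=source,
            converged=False, separable=False,
        )

    baseline, a1, tau1, a2, tau2 = popt
    tau1, tau2 = abs(tau1), abs(tau2)
    if tau1 <= tau2:
        A_fast, tau_fast, A_slow, tau_slow = a1, tau1, a2, tau2
    else:
        A_fast, tau_fast, A_slow, tau_slow = a2, tau2, a1, tau1
    resid = yw - _double_exp(tw, *popt)
    separable = tau_slow >= 2.0 * tau_fast
    return TransientFit(
        step_mV=step_mV, baseline=float(baseline),
        A_fast=float(A_fast), tau_fast=float(tau_fast),
        A_slow=float(A_slow), tau_slow=float(tau_slow),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        source=source, converged=True, separable=separable,
    )


def extract_charge(fit: TransientFit) -> float:
    """Charge moved by the slow (transporter) component: the analytic
    integral A_slow * tau_slow, with nA * ms = 1e-3 nC.  The fast
    component is discarded as capacitive."""
    return fit.A_slow * fit.tau_slow * 1e-3


def _fit_sweep_transients(trace: TraceSet, k: int, blank_ms: float,
                          fit_len_ms: float | None):
    proto = trace.protocol
    t = trace.time_ms
    y = trace.sweeps[k]
    V_s = proto.steps[k]
    t_on = t[proto.n_pre]
    t_off = t[proto.n_pre + proto.n_pulse]
    on = fit_transient(
        t, y, t0_ms=t_on, fit_start_ms=t_on + blank_ms + proto.dt_ms,
        fit_len_ms=fit_len_ms if fit_len_ms is not None
        else proto.pulse_ms - blank_ms - 2 * proto.dt_ms,
        step_mV=V_s, source="on",
    )
    off = fit_transient(
        t, y, t0_ms=t_off, fit_start_ms=t_off + blank_ms + proto.dt_ms,
        fit_len_ms=fit_len_ms if fit_len_ms is not None
        else proto.post_ms - blank_ms - 2 * proto.dt_ms,
        step_mV=V_s, source="off",
    )
    return on, off


def build_qv_tauv(
    trace: TraceSet,
    blank_ms: float = 0.0,
    fit_len_ms: float | None = None,
) -> tuple:
    """Q/V and tau/V points from a no-substrate trace set.

    For every step voltage except the holding potential, charge and tau
    come from the on-transient fit.  At V == V_h no on-transient exists;
    that point uses the off transient (relaxation back to V_h) of the step
    with the largest off-response: its tau is tau(V_h) and its charge plus
    the same step's on charge measures the residual at V_h (zero up to
    noise, by charge conservation).

    Returns (qv_points, tauv_points).  Charges are relative to the holding
    potential; a Boltzmann fit's offset absorbs the reference.
    """
    if trace.metadata.get("with_substrate"):
        raise ValueError("Q/V extraction requires a no-substrate trace set")
    proto = trace.protocol
    V_h = proto.V_h
    oocyte = str(trace.metadata.get("oocyte_id", ""))
    qv, tauv = [], []
    off_fits = {}
    on_fits = {}
    for k, V_s in enumerate(proto.steps):
        on, off = _fit_sweep_transients(trace, k, blank_ms, fit_len_ms)
        on_fits[V_s], off_fits[V_s] = on, off
        if V_s != V_h:
            qv.append(QVPoint(V=V_s, Q=extract_charge(on), oocyte_id=oocyte))
            tauv.append(TauVPoint(V=V_s, tau=on.tau_slow, oocyte_id=oocyte))
    if any(v == V_h for v in proto.steps):
        candidates = {v: f for v, f in off_fits.items()
                      if v != V_h and f.converged}
        if not candidates:
            raise ValueError("no off transient available for the V_h point")
        v_star = max(candidates,
                     key=lambda v: abs(extract_charge(candidates[v])))
        off = candidates[v_star]
        q_vh = extract_charge(on_fits[v_star]) + extract_charge(off)
        qv.append(QVPoint(V=V_h, Q=q_vh, oocyte_id=oocyte))
        tauv.append(TauVPoint(V=V_h, tau=off.tau_slow, oocyte_id=oocyte))
    qv.sort(key=lambda p: p.V)
    tauv.sort(key=lambda p: p.V)
    return qv, tauv
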