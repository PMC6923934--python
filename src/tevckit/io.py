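"""File formats, run configuration, pipeline orchestration, and small
sequence utilities.

Trace sets are stored as a CSV (sweep_id, step_mV, time_ms, current_nA;
comma-separated, '.' decimal, LF, UTF-8, mandatory header) plus a JSON
sidecar carrying the protocol, metadata, tool version, seed, and a config
fingerprint.  CT tables are plain CSV with columns
(gene, stage, replicate, round, ct).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analyze import build_qv_tauv, steady_state_current, subtract_traces
from .fits import fit_boltzmann, fit_dose_response, reconstruct_rate_constants
from .simulate import TraceSet, VoltageStepProtocol

__all__ = [
    "RunConfig",
    "CodingSequenceInfo",
    "cds_protein_length",
    "write_trace_set",
    "read_trace_set",
    "write_ct_table",
    "read_ct_table",
    "run_pipeline",
]

TRACE_COLUMNS = ("sweep_id", "step_mV", "time_ms", "current_nA")


def _config_fingerprint(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end simulate/analyze/fit run."""

    scenario: str = "zfPepT1a_pH6.5"
    seed: int = 0
    out_dir: str = "."
    substrate_mM: float = 1.0
    n_oocytes: int = 5
    noise_sd_nA: float = 0.0
    expression_scatter_cv: float = 0.0
    sample_rate_Hz: float = 10000.0
    window_ms: float = 100.0
    blank_ms: float = 0.0
    log_level: str = "INFO"

    def fingerprint(self) -> str:
        return _config_fingerprint(asdict(self))


@dataclass(frozen=True)
class CodingSequenceInfo:
    """cDNA/CDS/protein length bookkeeping (lengths in bp / aa)."""

    cdna_bp: int
    cds_bp: int

    def __post_init__(self) -> None:
        if self.cds_bp > self.cdna_bp:
            raise ValueError("CDS cannot be longer than the cDNA")
        if self.cds_bp % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")

    @property
    def protein_aa(self) -> int:
        return cds_protein_length(self.cds_bp)


def cds_protein_length(cds_bp: int) -> int:
    """Protein length (aa) encoded by a CDS of ``cds_bp`` base pairs,
    excluding the terminal stop codon: cds_bp / 3 - 1."""
    if cds_bp < 6:
        raise ValueError("CDS must be at least 6 bp (one codon plus stop)")
    if cds_bp % 3 != 0:
        raise ValueError(f"CDS length {cds_bp} is not a multiple of 3")
    return cds_bp // 3 - 1


def write_trace_set(ts: TraceSet, path: str | Path) -> Path:
    """Write a trace set as ``<path>.csv`` + ``<path>.json`` sidecar.

    ``path`` is the stem (any .csv/.json suffix is stripped).  Returns the
    CSV path.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    t = ts.time_ms
    frames = []
    for k, V_s in enumerate(ts.protocol.steps):
        frames.append(pd.DataFrame({
            "sweep_id": k,
            "step_mV": V_s,
            "time_ms": t,
            "current_nA": ts.sweeps[k],
        }))
    df = pd.concat(frames, ignore_index=True)
    csv_path = stem.with_suffix(".csv")
    df.to_csv(csv_path, index=False, lineterminator="\n", encoding="utf-8")
    sidecar = {
        "format": "tevckit-traceset",
        "version": __version__,
        "protocol": ts.protocol.to_dict(),
        "metadata": ts.metadata,
        "n_sweeps": len(ts.protocol.steps),
        "n_samples": ts.protocol.n_samples,
        "fingerprint": _config_fingerprint(
            {"protocol": ts.protocol.to_dict(), "metadata": ts.metadata}),
    }
    stem.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, default=str) + "\n", encoding="utf-8")
    return csv_path


def read_trace_set(path: str | Path) -> TraceSet:
    """Read a trace set written by :func:`write_trace_set`.

    Validates the schema strictly: mandatory columns, sidecar presence,
    per-sweep sample counts, monotone time base.
    """
    stem = Path(path)
    if stem.suffix in (".csv", ".json"):
        stem = stem.with_suffix("")
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(f"trace CSV not found: {csv_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar: {json_path}")
    sidecar = json.loads(json_path.read_text(encoding="utf-8"))
    proto = VoltageStepProtocol.from_dict(sidecar["protocol"])
    df = pd.read_csv(csv_path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed trace CSV {csv_path}: missing column(s) {missing}")
    n_steps = len(proto.steps)
    sweeps = np.empty((n_steps, proto.n_samples))
    for k in range(n_steps):
        sub = df[df["sweep_id"] == k]
        if len(sub) != proto.n_samples:
            raise ValueError(
                f"sweep {k}: {len(sub)} samples, protocol says "
                f"{proto.n_samples}")
        t = sub["time_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"sweep {k}: non-monotone time base")
        sweeps[k] = sub["current_nA"].to_numpy()
    return TraceSet(protocol=proto, sweeps=sweeps,
                    metadata=sidecar.get("metadata", {}))


def write_ct_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CT table not found: {path}")
    df = pd.read_csv(path)
    required = ("gene", "stage", "replicate", "round", "ct")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"malformed CT table {path}: missing {missing}")
    return df


def _json_sanitize(obj):
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> analyze -> fit -> report, end to end.

    Simulates a multi-oocyte experiment for the configured scenario,
    extracts Q/V + tau/V from the no-substrate sweeps and steady-state
    transport currents from the subtracted pairs, fits the Boltzmann
    charge distribution per oocyte, reconstructs rate constants, and
    writes a JSON report plus per-oocyte CSV tables under ``out_dir``.

    Fully deterministic under ``config.seed``; every artifact embeds the
    tool version, seed, and config fingerprint.
    """
    from .simulate import CellParams, paper_protocol, scenario_presets, \
        simulate_experiment

    presets = scenario_presets()
    if config.scenario not in presets:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; "
            f"available: {sorted(presets)}")
    transport, charge = presets[config.scenario]
    protocol = paper_protocol(sample_rate=config.sample_rate_Hz)
    cell = CellParams()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        pairs = simulate_experiment(
            protocol, cell, charge, transport, S=config.substrate_mM,
            n_oocytes=config.n_oocytes,
            expression_scatter_cv=config.expression_scatter_cv,
            noise_sd=config.noise_sd_nA, seed=config.seed,
        )

        stage = "analyze"
        boltzmann_rows, iv_rows, rate_rows = [], [], []
        for with_sub, without in pairs:
            oocyte = with_sub.metadata["oocyte_id"]
            diff = subtract_traces(with_sub, without)
            for p in steady_state_current(diff, window_ms=config.window_ms):
                iv_rows.append({"oocyte_id": oocyte, "V_mV": p.V,
                                "S_mM": p.S, "I_nA": p.I})
            qv, tauv = build_qv_tauv(without, blank_ms=config.blank_ms)

            stage = "fit"
            bfit = fit_boltzmann(qv)
            boltzmann_rows.append({
                "oocyte_id": oocyte, "Q_max_nC": bfit.Q_max,
                "V_half_mV": bfit.V_half, "sigma_mV": bfit.sigma,
                "Q_0_nC": bfit.Q_0, "converged": bfit.converged,
            })
            if bfit.converged:
                curve = reconstruct_rate_constants(bfit, tauv)
                for r in curve.points:
                    rate_rows.append({"oocyte_id": oocyte, "V_mV": r.V,
                                      "k_out_per_s": r.k_out,
                                      "k_in_per_s": r.k_in})
            stage = "analyze"
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    stage = "report"
    boltz_df = pd.DataFrame(boltzmann_rows)
    iv_df = pd.DataFrame(iv_rows)
    rate_df = pd.DataFrame(rate_rows)
    boltz_df.to_csv(out_dir / "boltzmann_fits.csv", index=False,
                    lineterminator="\n")
    iv_df.to_csv(out_dir / "iv_points.csv", index=False, lineterminator="\n")
    rate_df.to_csv(out_dir / "rate_constants.csv", index=False,
                   lineterminator="\n")
    ok = boltz_df["converged"].all() if len(boltz_df) else False
    report = {
        "tool": "tevckit",
        "version": __version__,
        "seed": config.seed,
        "config_fingerprint": config.fingerprint(),
        "scenario": config.scenario,
        "n_oocytes": config.n_oocytes,
        "all_converged": bool(ok),
        "boltzmann_mean": {
            "Q_max_nC": float(boltz_df["Q_max_nC"].mean()),
            "V_half_mV": float(boltz_df["V_half_mV"].mean()),
            "sigma_mV": float(boltz_df["sigma_mV"].mean()),
        },
        "files": ["boltzmann_fits.csv", "iv_points.csv",
                  "rate_constants.csv"],
    }
    report = _json_sanitize(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2) + "\n", encoding="utf-8")
    summary = (
        f"tevckit {__version__} | scenario {config.scenario} | seed "
        f"{config.seed} | {config.n_oocytes} oocytes\n"
        f"mean Boltzmann fit: Q_max={report['boltzmann_mean']['Q_max_nC']:.2f} nC, "
        f"V_half={report['boltzmann_mean']['V_half_mV']:.1f} mV, "
        f"sigma={report['boltzmann_mean']['sigma_mV']:.1f} mV\n"
        f"all fits converged: {ok}\n"
    )
    (out_dir / "summary.txt").write_text(summary, encoding="utf-8")
    return report
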