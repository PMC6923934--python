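"""Comparative-CT qPCR analytics.

Primer efficiency from dilution series, relative expression by the
2^-dCT method (dCT = target CT - reference CT), fold-change versus a
control stage, and per-stage paralogue expression ratios.

Aggregation contract: 2^-dCT is computed per (replicate, round), averaged
over rounds within each biological replicate, then mean +/- SD over
replicates.  Fold-changes divide stage means by the control-stage mean,
so the control maps to exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrimerEfficiencyResult",
    "ExpressionResult",
    "primer_efficiency",
    "validate_ct_table",
    "expression_2dct",
    "fold_change",
    "gene_ratio",
    "stage_anova",
]

CT_COLUMNS = ("gene", "stage", "replicate", "round", "ct")


@dataclass(frozen=True)
class PrimerEfficiencyResult:
    """Slope of CT vs log10(relative template amount), and the implied
    amplification efficiency E = 10^(-1/m) (E = 2 for perfect doubling)."""

    slope: float
    efficiency: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ExpressionResult:
    """Per-stage relative expression of one target gene.

    ``per_replicate`` holds the round-averaged 2^-dCT per (stage,
    replicate); ``summary`` holds mean and SD over replicates, plus the
    fold-change column once :func:`fold_change` has been applied.
    """

    gene: str
    reference_gene: str
    per_replicate: pd.DataFrame  # columns: stage, replicate, expr_2dct
    summary: pd.DataFrame        # columns: stage, mean_2dct, sd_2dct[, fold_change]
    control_stage: str | None = None

    def stage_mean(self, stage) -> float:
        row = self.summary.loc[self.summary["stage"] == stage]
        if row.empty:
            raise KeyError(f"stage {stage!r} not present")
        return float(row["mean_2dct"].iloc[0])


def primer_efficiency(dilutions, cts) -> PrimerEfficiencyResult:
    """OLS line of CT vs log10(relative template amount).

    ``dilutions`` are relative template amounts (1, 0.1, 0.01 for a
    tenfold series); at least three distinct dilutions are required.
    Efficiency inverts m = -(1/log10 E):  E = 10^(-1/m).
    """
    d = np.asarray(list(dilutions), dtype=float)
    y = np.asarray(list(cts), dtype=float)
    if d.shape != y.shape:
        raise ValueError("dilutions and cts must have equal length")
    if np.any(d <= 0):
        raise ValueError("dilution factors must be positive")
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct dilutions")
    x = np.log10(d)
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("zero slope: dilution series carries no signal")
    eff = 10.0 ** (-1.0 / res.slope)
    return PrimerEfficiencyResult(
        slope=float(res.slope), efficiency=float(eff),
        r_squared=float(res.rvalue**2), n_points=int(d.size),
    )


def validate_ct_table(table: pd.DataFrame, reference: str) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CT table is missing column(s): {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive cycles")
    ref = table[table["gene"] == reference]
    if ref.empty:
        raise ValueError(f"reference gene {reference!r} absent from table")


def expression_2dct(table: pd.DataFrame, target: str,
                    reference: str = "28S",
                    geometric: bool = False) -> ExpressionResult:
    """Relative expression 2^-(CT_target - CT_reference).

    Computed per (stage, replicate, round), averaged over rounds within
    replicate, then mean +/- SD over replicates per stage.  With
    ``geometric=True`` the round/replicate averaging is geometric
    (equivalent to averaging dCT before exponentiation) instead of the
    default arithmetic mean of 2^-dCT values.
    """
    validate_ct_table(table, reference)
    tgt = table[table["gene"] == target]
    if tgt.empty:
        raise ValueError(f"target gene {target!r} absent from table")
    ref = table[table["gene"] == reference]
    keys = ["stage", "replicate", "round"]
    merged = tgt.merge(ref, on=keys, suffixes=("_t", "_r"), how="left")
    if merged["ct_r"].isna().any():
        bad = merged.loc[merged["ct_r"].isna(), keys].iloc[0].to_dict()
        raise ValueError(f"no reference CT for {bad}")
    merged["expr_2dct"] = 2.0 ** (-(merged["ct_t"] - merged["ct_r"]))

    if geometric:
        agg_rounds = (merged.groupby(["stage", "replicate"], sort=False)
                      ["expr_2dct"].apply(lambda v: float(stats.gmean(v))))
    else:
        agg_rounds = (merged.groupby(["stage", "replicate"], sort=False)
                      ["expr_2dct"].mean())
    per_rep = agg_rounds.reset_index()
    summary = (per_rep.groupby("stage", sort=False)["expr_2dct"]
               .agg(mean_2dct="mean", sd_2dct="std").reset_index())
    return ExpressionResult(gene=target, reference_gene=reference,
                            per_replicate=per_rep, summary=summary)


def fold_change(expr: ExpressionResult, control_stage) -> ExpressionResult:
    """Fold-change of each stage's mean 2^-dCT versus the control stage.

    The control maps to exactly 1; stages below the control give ratios in
    (0, 1) (some sources display these with a sign-flipped "negative
    fold-change" convention -- stored values are always plain ratios).
    """
    control = expr.summary.loc[expr.summary["stage"] == control_stage]
    if control.empty:
        raise ValueError(f"control stage {control_stage!r} not in results")
    c = float(control["mean_2dct"].iloc[0])
    summary = expr.summary.copy()
    summary["fold_change"] = summary["mean_2dct"] / c
    return ExpressionResult(
        gene=expr.gene, reference_gene=expr.reference_gene,
        per_replicate=expr.per_replicate, summary=summary,
        control_stage=control_stage,
    )


def gene_ratio(expr_a: ExpressionResult, expr_b: ExpressionResult) -> pd.DataFrame:
    """Per-stage ratio of mean 2^-dCT of gene a over gene b, with a
    boolean ``above_one`` indicator."""
    stages_a = list(expr_a.summary["stage"])
    stages_b = list(expr_b.summary["stage"])
    if stages_a != stages_b:
        raise ValueError(
            f"stage mismatch: {stages_a} vs {stages_b}")
    ratio = (expr_a.summary["mean_2dct"].to_numpy()
             / expr_b.summary["mean_2dct"].to_numpy())
    return pd.DataFrame({
        "stage": stages_a,
        "ratio": ratio,
        "above_one": ratio > 1.0,
    })


def stage_anova(expr: ExpressionResult) -> dict:
    """One-way ANOVA across stages on per-replicate 2^-dCT values
    (delegated to scipy); returns the F statistic and p-value."""
    groups = [g["expr_2dct"].to_numpy()
              for _, g in expr.per_replicate.groupby("stage", sort=False)]
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p_value": float(p), "n_groups": len(groups)}
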