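# tevckit

Simulation and analysis toolkit for two-electrode voltage clamp (TEVC)
studies of electrogenic membrane transporters expressed in *Xenopus*
oocytes, plus a comparative-CT (2^-ΔCT) qPCR expression pipeline.

The package covers the full analysis chain of a transporter
characterization study:

* **`tevckit.kinetics`** — closed-form model equations: Boltzmann
  steady-state charge distribution Q(V), symmetric two-state
  unidirectional rate constants k_out/k_in and their bell-shaped
  relaxation time τ(V), Michaelis-type dose-response current
  I(S) = I_max·S/(S+K_0.5), transport efficiency |I_max|/K_0.5, affinity
  ratios, and the electrical-field fraction δ = (kT/q)/σ.
* **`tevckit.simulate`** — synthetic-data generation: voltage-step
  protocols, full current sweeps (leak + capacitive transient +
  transporter pre-steady-state transient + steady transport current +
  Gaussian noise), multi-oocyte experiments with shared lognormal
  expression scatter, direct dose-response point simulation, named
  transporter×pH scenario presets, and qPCR CT tables with
  stage-dependent expression ratios. Bit-identical under a seed.
* **`tevckit.analyze`** — trace analysis: transport-current subtraction
  (presence − absence), steady-state I/V windows, double-exponential
  isolation of pre-steady-state transients from the capacitive
  component, charge extraction (Q = A_slow·τ_slow), and Q/V + τ/V
  construction with the on/off-transient convention (the holding-potential
  point comes from an off transient).
* **`tevckit.fits`** — estimation: Boltzmann fits of Q/V with offset,
  Q/V normalization, rate-constant reconstruction from Q/V + τ/V
  (k_out = p_out/τ, k_in = (1−p_out)/τ), per-voltage logistic
  dose-response fits with saturation flagging, and efficiency curves.
* **`tevckit.qpcr`** — primer efficiency from dilution series
  (E = 10^(−1/m)), 2^-ΔCT relative expression with the
  rounds-then-replicates aggregation contract, fold-change versus a
  control stage, paralogue expression ratios, and a delegated one-way
  ANOVA helper.
* **`tevckit.io`** — CSV + JSON-sidecar trace format, CT-table I/O,
  run configuration with seed/version/fingerprint embedding, CDS→protein
  length bookkeeping, and the end-to-end pipeline orchestrator.

Units are fixed package-wide: mV, ms, nA, nC, mmol/L, µS, nF.

## CLI

The console script `tevckit` exposes the pipeline:

```sh
# simulate with/without-substrate sweep pairs for a named scenario
tevckit simulate-tevc --scenario zfPepT1a_pH6.5 --substrate-mM 1.0 \
    --n-oocytes 5 --seed 42 --out sim/

# pre-steady-state analysis: Q/V and tau/V tables
tevckit analyze-pss sim/ --out pss/

# steady-state transport-associated I/V points
tevckit analyze-iv sim/ --window-ms 100 --out iv/

# fits
tevckit fit-boltzmann pss/qv.csv --out boltzmann.csv
tevckit fit-dose iv.csv --per-oocyte --out dose.csv

# qPCR
tevckit qpcr-efficiency series.csv
tevckit qpcr-foldchange ct.csv --target slc15a1a --reference 28S \
    --control-stage 1dpf

# one-shot simulate -> analyze -> fit -> report
tevckit run-pipeline --scenario zfPepT1a_pH6.5 --seed 42 --out run/

# emit a small synthetic fixture suite
tevckit make-fixtures --seed 1 --out fixtures/
```

Exit codes: 0 success, 2 validation error, 3 fit non-convergence
(partial outputs still written).

Scenario presets (`zfPepT1a_pH6.5`, `zfPepT1a_pH7.6`, `zfPepT1b_pH6.5`,
`zfPepT1b_pH7.6`) bundle published per-voltage dose-response anchors
(K_0.5, I_max at −60/−120/−140 mV) with Boltzmann charge-movement
parameters (Q_max, V_0.5, σ); K_0.5(V) is interpolated log-linearly and
I_max(V) linearly between anchors.

## Notes on conventions

* Inward (substrate-evoked) currents are negative; transport efficiency
  is reported as a positive magnitude.
* The capacitive (fast) and transporter (slow) transient components are
  assigned purely by τ ordering; fits with τ ratio < 2 are flagged
  `separable=False` rather than trusted.
* Fold-changes below the control stage are stored as ratios in (0, 1);
  any sign-flipped "negative fold-change" display is a reporting
  convention only.
* The default temperature for the field-fraction calculation is
  295.15 K (22 °C), configurable via `PhysicalConstants`.
* Default sampling for simulation-based analyses is 10 kHz so the
  0.8 ms capacitive transient is resolvable; 1 kHz acquisition can be
  simulated but triggers an "unresolvable transient" warning.
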