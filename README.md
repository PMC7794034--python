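# autoregkit

Cerebral autoregulation (CA) is the vasoconstriction/vasodilation mechanism
that holds cerebral blood flow (CBF) approximately constant while cerebral
perfusion pressure (CPP = MAP − ICP) varies. Assessing whether CA is intact
matters for managing traumatic brain injury, hydrocephalus and stroke, but
the field uses several partly disagreeing measurement families.
`autoregkit` implements the three canonical ones as one tested pipeline, for
researchers working with multimodal neuromonitoring recordings (arterial
blood pressure, intracranial pressure, and a diffuse-correlation-
spectroscopy blood-flow index):

* **Static CA — Lassen's curve.** Quality-controlled 10-s flow means are
  averaged within 1-mmHg CPP bins, normalized per subject
  (v → (v − m)/m), and group-averaged. A three-segment piecewise-linear fit
  (rising / flat / rising) estimates the lower and upper limits of
  autoregulation (LLA, ULA); an intact bed shows a flat plateau, a
  pressure-passive bed a degenerate fit.
* **Pseudo-dynamic CA — pressure reactivity index (PRx).** Pearson
  correlation of 0.1 Hz (10-s mean) MAP and ICP in moving 5-minute windows,
  sorted into 150 CPP groups over 0–180 mmHg and averaged on the Fisher-Z
  scale: PRx = tanh(mean(atanh r)). Negative PRx ⇒ intact reactivity
  (pressure rise → constriction → smaller blood volume → ICP falls);
  PRx ≳ 0.3 ⇒ pressure-passive.
* **Dynamic CA — ABP–ICP phase lag.** During induced oscillations
  (reservoir-driven ICP, or PEEP-driven ABP at 0.009–0.059 Hz) both
  channels pass through the same narrowband linear-phase FIR
  (Parks–McClellan), the analytic signal is formed with the Hilbert
  transform, and the delay φ_ABP − φ_ICP is circularly averaged. Intact CA
  below the ~0.03 Hz cutoff shows ≈180°; a passive bed shows ≈0°.

Because the underlying animal recordings are not public, the package ships
a seeded lumped-parameter cerebrovascular simulator
(`autoregkit.synthetic_data`) with a tunable autoregulation state
(`ca_gain` ∈ [0, 1]), the full oscillation protocol (five frequencies, ICP
baseline staircase, PEEP modulation), DCS noise/artifact models, vitals and
anesthesia logs. Every pipeline stage is validated against it.

## Worked example

Simulate a small two-group study (two subjects per anesthesia group, one
induced frequency, two ICP baselines) and run all three pipelines:

```yaml
# study.yaml
seed: 11
output_dir: out
simulate:
  n_fentanyl: 2       # intact CA (ca_gain = 1)
  n_isoflurane: 2     # pressure-passive (ca_gain = 0)
  frequencies: [0.059]
  icp_baselines: [6, 12]
  duration_per_baseline: 600.0
```

```bash
autoregkit run --config study.yaml
autoregkit report --out out
```

prints

```
autoregkit 0.1.0 study (seed 11)
  sim_fentanyl_11000 [fentanyl] prx_windows=27 phase_segments=4
  sim_fentanyl_11001 [fentanyl] prx_windows=27 phase_segments=4
  sim_isoflurane_11500 [isoflurane] prx_windows=27 phase_segments=4
  sim_isoflurane_11501 [isoflurane] prx_windows=27 phase_segments=4
```

and `out/phase.tsv` contains (abridged):

| modality | freq_hz | group | mean_delay_deg | mean_icp_magnitude_mmhg |
|----------|---------|-------|----------------|--------------------------|
| abp_osc  | 0.059   | fentanyl   | −86.0 | 4.2 |
| abp_osc  | 0.059   | isoflurane | +1.2  | 0.6 |
| icp_osc  | 0.059   | fentanyl   | +0.3  | 2.7 |
| icp_osc  | 0.059   | isoflurane | −6.4  | 2.3 |

Reading it: 0.059 Hz lies *above* the autoregulatory cutoff, so even the
intact group cannot fully counter-regulate — its ABP-oscillation delay sits
near 90° (the transition value) instead of 180°, while the passive group
transmits pressure directly (≈0°). The first rows of `out/prx_profile.tsv`
show the same separation in the PRx domain: the isoflurane group's
Fisher-Z-averaged PRx is ≈ +0.65 across its CPP groups (pressure-passive),
the fentanyl group's is strongly negative. Intact-vs-passive contrast at
frequencies *below* the cutoff (0.009, 0.017 Hz) and full Lassen-plateau
recovery need longer recordings; see `scripts/acceptance.py`.

The report bundle also contains `lassen.tsv` (group Lassen curve ± SD),
`histograms.tsv` (1-mmHg pooled CPP/MAP/ICP histograms), `vitals.tsv`
(per-subject ETCO2/heart-rate summaries) and `qc_report.json` (every
threshold, Mann–Whitney group tests, plateau fits, and counts of every
rejected sample and window).

## Library layout

| module | contents |
|--------|----------|
| `recording_io` | data model, TSV/CSV round-trip I/O, beat-pressure → MAP, CPP, ΔCBF, 5 Hz alignment, 10-s binning, β and CBF z-score QC masks |
| `static_ca` | subject/group Lassen curves, plateau (LLA/ULA) fit, Mann–Whitney rank-sum (exact for small n), pressure histograms |
| `pseudo_dynamic_ca` | 0.1 Hz down-sampling, windowed PRx, Fisher-Z averaging, CPP-group profile |
| `dynamic_ca` | narrowband equiripple filter design, analytic-signal phase/envelope, per-segment delay, circular statistics |
| `synthetic_data` | protocol builder and the seeded coupled hemodynamics model |
| `pipeline_cli` | study configuration, orchestration, report bundle, `autoregkit` CLI |

See `docs/methods.md` for the model equations, parameter defaults and the
design decisions behind them.
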