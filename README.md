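# erpvar

Trial-to-trial ERP variability analysis for two-channel prefrontal
(Fp1/Fp2) auditory-oddball EEG, with a statistics layer relating the
variability measures to mild-cognitive-impairment (MCI) status.

The core quantity is the **response variance curve (RVC)**: the unbiased
across-trial variance of single-trial epoch amplitudes at each time point,
i.e. the instability of trials around the average ERP. From the RVC, four
measures are extracted in two component windows (P2: 150–300 ms,
P3: 300–600 ms) for target and standard responses:

| measure | meaning | units |
|---------|---------|-------|
| AMPV | peak of the variance curve in the window | µV² |
| LATV | latency of that peak (earliest on ties) | ms |
| FALV | 50% fractional-area latency (linear interpolation on the cumulative trapezoid) | ms |
| AUCV | trapezoidal area under the curve | µV²·ms |

Per-channel measures feed the normalized hemispheric asymmetry index
`(Fp2 − Fp1) / (Fp2 + Fp1)`; channel-averaged measures feed group
comparisons (Student/Welch t, Pearson χ²) and three nested logistic
regression tiers (crude; + age, sex, education; + MMSE).

## Package layout

- `erpvar.synthetic` — seeded synthetic cohorts: demographics /
  neuropsychological scores plus simulated epoch sets (Gaussian P2/P3-like
  bumps with trial-level amplitude/latency jitter, white noise,
  super-threshold artifact trials, behavioural errors, and a right-channel
  jitter scale for controlled asymmetry).
- `erpvar.preprocess` — segmentation ([−200, 800) ms at 250 Hz), baseline
  correction ([−200, 0) ms), correct-trial selection, ±100 µV artifact
  rejection, 9-point moving-average smoothing, and the subject-inclusion
  decision (any condition/channel with zero clean trials, or a clean
  fraction < 50%, excludes the subject).
- `erpvar.rvc` — variance curves, window measures, peak-discernibility
  check, channel averaging, and the Tukey-fence extreme-value screen.
- `erpvar.asymmetry` — asymmetry indices and the per-subject asymmetry table.
- `erpvar.stats` — t-tests (raw vectors or summary triples), Pearson χ²,
  and the tiered logistic models (Wald CIs; z-scored predictors by default,
  raw units by flag).
- `erpvar.pipeline` — end-to-end orchestration with an exhaustive,
  mutually exclusive per-subject exclusion ledger.
- `erpvar.io` / `erpvar.edf` — fixture CSV epoch files (bit-exact
  round-trip) and a minimal EDF+C reader/writer with annotation-based
  events.
- `erpvar.cli` — the `erpvar` command.

## CLI

```sh
# synthetic cohort as fixture CSVs + metadata table
erpvar simulate --n-cn 20 --n-mci 20 --seed 1 --outdir cohort/

# per-subject cleaning / measures / statistics
erpvar preprocess cohort/S0001.csv --out clean.csv
erpvar measures cohort/S*.csv --out measures.csv --asym-out asym.csv
erpvar stats measures.csv cohort/metadata.csv --out stats.json

# everything in one go (writes measures.csv, asymmetry.csv, stats.json,
# run_report.json, run.log into --outdir)
erpvar run --mode synthetic --n-cn 50 --n-mci 50 --seed 1 --outdir out/
erpvar run --config run.yaml
```

A YAML config can set any `RunConfig` field (flags override), e.g.

```yaml
mode: synthetic
seed: 7
outdir: out
windows: {P2: [150, 300], P3: [300, 600]}
t_variant: welch
scaling: z_scored
generator: {n_cn: 100, n_mci: 100}
```

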