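# gshmrs — edited-MRS glutathione quantification pipeline

`gshmrs` is an end-to-end, fully synthetic test bench for measuring brain
glutathione (GSH) by difference-edited proton magnetic-resonance
spectroscopy, modelled on an intranasal-GSH time-course experiment: 15
subjects scanned at baseline and serially (~every 12 min) after
administration, with the group GSH/creatine ratio rising from 0.0170 at
baseline to 0.0457 by ~45 minutes.

The package contains the complete forward and inverse problem:

- **Forward simulation** (`gshmrs.simulate`, `gshmrs.cohort`) — free
  induction decays as sums of damped complex exponentials (Lorentzian
  lines); MEGA-PRESS editing by amplitude bookkeeping (edited resonances
  survive the OFF−ON difference at `efficiency × amplitude`, everything
  else cancels); co-edited contaminants and a macromolecular background;
  thermal noise, frequency/phase jitter; a 15-subject longitudinal cohort
  with known ground truth, six undetectable baselines and one corrupted
  acquisition (70 spectra total).
- **Preprocessing** (`gshmrs.preprocess`) — exponential line broadening,
  zero-filling, time-domain spectral registration (frequency/phase
  alignment), Hankel-SVD residual-water removal.
- **Edited quantification** (`gshmrs.edited`) — 5-Gaussian + linear
  baseline fit of the difference spectrum over 2.6–3.3 p.p.m., a Gaussian
  creatine reference from the editing-OFF spectrum, a matched-filter limit
  of detection, fit-error and sensitivity quality control, and the
  concentration-scale GSH/Cr ratio.
- **Absolute quantification** (`gshmrs.press`) — short-echo PRESS
  linear-combination fitting with Cramér–Rao lower bounds, water
  referencing with T2 correction, and CSF partial-volume correction.
- **Longitudinal statistics** (`gshmrs.stats`) — baseline imputation for
  undetectable scans, per-time-bin summaries, a general-linear-model
  repeated-measures ANOVA with Holm–Šidák post-dose-versus-baseline
  comparisons, and percent change.
- **I/O and CLI** (`gshmrs.io`, `gshmrs.cli`) — a self-describing JSON
  spectral container with bit-exact round trips, delimited tables, and the
  `gshmrs` command line (`simulate`, `quantify`, `stats`, `run-all`).

See [docs/methods.md](docs/methods.md) for the signal model, every default
parameter with its rationale, and known limitations.

## Worked example

Simulate the default cohort at full fidelity (every FID synthesised and
processed through the complete spectral chain), quantify and analyse:

```python
from gshmrs.cohort import simulate_cohort
from gshmrs.pipeline import quantify_cohort, analyze_cohort

dataset = simulate_cohort(seed=1, mode="transients")
table = quantify_cohort(dataset)          # ~30 s: 70 spectral fits
print(table.flag.value_counts().to_dict())
res = analyze_cohort(table)
an = res["anova"]
print(f"RM-ANOVA time effect: F({an.df_num},{an.df_den}) = "
      f"{an.f_statistic:.2f}, p = {an.p_value:.3g}")
```

Actual output:

```text
{'ok': 63, 'undetectable': 6, 'insufficient_quality': 1}
RM-ANOVA time effect: F(4,49) = 9.49, p = 9.26e-06
```

70 spectra are acquired and 63 analysed: the six undetectable baselines
are excluded (and later imputed at the lowest measured ratio divided by
two) and the one corrupted scan fails quality control. The per-bin summary
and the Holm–Šidák comparisons for this seed:

```text
 time_bin  time_mean_min  n     mean      sem
        0       0.000000 15 0.016982 0.002643
        1       7.500000 15 0.024014 0.002368
        2      19.931930 14 0.036226 0.005450
        3      31.980025 15 0.035862 0.006142
        4      44.780164  9 0.033041 0.003694

 time_bin  mean_diff  p_adjusted  significant
        1   0.007031    0.067467        False
        2   0.019323    0.000028         True
        3   0.018880    0.000028         True
        4   0.014540    0.004206         True
```

The qualitative pattern of the modelled study reproduces: a strongly
significant omnibus time effect, a non-significant 7.5-minute comparison,
and significant elevations at the later time points.

The same pipeline is available from the command line:

```bash
gshmrs run-all --out results/run1 --seed 1
```

which writes the per-scan table, the summary, the ANOVA report and plots,
and logs every exclusion with its rule. Monte-Carlo studies of the
inference use the fast `quantified` fidelity, which replaces the spectral
chain with a measurement model calibrated once against it:

```python
dataset = simulate_cohort(seed=1, mode="quantified")   # milliseconds
```

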