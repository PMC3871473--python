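# cardiopower

Beat-by-beat cardiac energy analysis: per-cycle left-ventricular stroke
work (the pressure–volume loop area, SW) compared against the per-cycle
time integral of aortic hydraulic power (the PWR integral), across six
loading/contractility conditions. Because no real recordings ship with
the package, a lumped-parameter hemodynamic simulator (time-varying
elastance ventricle + 3-element Windkessel) generates the five measured
channels — ECG, aortic pressure, aortic flow, LV pressure, LV volume —
at 1 kHz, including a conductance-catheter measurement model (volume
gain/offset + channel noise) so the per-animal alpha calibration is
exercised end to end.

## Modules

- `cardiopower.hemo_sim` — synthetic animals, the six conditions
  (baseline, reduced preload, increased afterload, dobutamine,
  nitroprusside, metoprolol), RK4 integration, measurement model.
- `cardiopower.signal_io` — waveform/beat-table CSV I/O with JSON
  sidecars; clinical-unit ↔ SI conversions (energies in J, power in W).
- `cardiopower.beat_metrics` — R-peak detection, R-to-R cycle
  segmentation, power curve, per-cycle power integral, shoelace
  stroke work, alpha calibration, CO/MAP/CPO summaries, oscillatory
  power fraction.
- `cardiopower.agreement_stats` — through-origin regression with
  uncentered R², Bland–Altman limits of agreement, and a no-intercept
  random-slope mixed model (per-condition fixed slopes, per-animal
  random slope) fitted by profiled REML with closed-form rank-one
  covariance inversion.
- `cardiopower.pipeline` / `cardiopower.cli` — full-protocol
  orchestration (6 animals × 60 measurements × 10 cycles by default)
  and the `simulate` / `analyze` / `report` commands.

## CLI

```sh
# simulate a (reduced) synthetic dataset
cardiopower simulate --out data/ --seed 1 --animals 2 --sets 2 \
    --drug-measurements 2 --cycles 10

# run the agreement analysis: beat table, per-animal slopes/R²,
# Bland–Altman points, mixed-model condition slopes
cardiopower analyze --in data/ --out analysis/

# scatter + Bland–Altman figures
cardiopower report --in analysis/ --out figures/
```

`analyze` writes `beat_table.csv`, `per_animal.csv`, `conditions.csv`,
`bland_altman.csv` and `run_log.txt`. The regression direction defaults
to power-integral-on-SW (`--direction sw_on_pwr` flips it) and the mixed
model uses REML (`--method ml` switches).

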