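# tvv — continuous T-vector-velocity effect profiles from 12-lead ECGs

`tvv` quantifies drug effects on ventricular repolarization from annotated
10-second 12-lead resting ECGs. It implements:

1. **ECG I/O and preprocessing** (`tvv.ecg_io`) — WFDB-style, HL7-aECG-style
   and CSV readers/writers; isoelectric baseline correction (PQ-median nodes
   joined by a natural cubic spline) and a bidirectional 36 Hz 4-pole Bessel
   low-pass.
2. **Vectorcardiography** (`tvv.vcg`) — inverse Dower reconstruction of the
   XYZ heart vector and trajectory time-quantiles `Tr(p)`: the time (ms) to
   cover p% of the T-vector trajectory arc length between J-point + 20 ms
   and T-end, averaged over beats per ECG.
3. **Heart-rate correction** (`tvv.hr_correction`) — per-p exponents
   `alpha_p` from log–log mixed models on drug-free data;
   `Tr(p)c = Tr(p) / RR^alpha_p`.
4. **Effect models** (`tvv.effect_models`) — replicate averaging, change from
   baseline, placebo correction, and the pointwise mixed models for the
   three supported study designs (A: crossover exposure–response,
   B: crossover phase means, C: parallel with treatment/concentration/
   nominal-time/baseline terms).
5. **Functional model** (`tvv.functional_model`) — all 100 per-p models
   joined into a single mixed model whose p-dependent coefficients are cubic
   B-splines (8/16/12 equidistant knots by design), fit by a fast custom
   REML engine (`tvv._lmm`) with analytic gradients.
6. **Bootstrap** (`tvv.bootstrap`) — two-step nonparametric bootstrap
   (subjects, then replicate ECGs within subject × timepoint) yielding the
   median profile and 5%/95% confidence band.
7. **p_zero** (`tvv.pzero`) — the largest p where the effect profile turns
   from negative (accelerated repolarization) to non-negative (delayed);
   threshold classification of hERG-predominant vs multichannel blockers.
8. **Synthetic data** (`tvv.synthetic`) — signal-level ECG studies built
   from an XYZ dipole with a *prescribed* repolarization time course
   (ground-truth `Tr(p)`, RR power law and concentration-proportional warps
   hold by construction), plus cheap quantile-level study generators for
   statistical experiments.

## CLI

```sh
tvv simulate --design A --seed 7 --out study/ --subjects 4 --timepoints 0,1,2,4
tvv extract study/ --format wfdb --out quantiles.csv
tvv alpha --quantiles quantiles.csv --out alpha.csv
tvv correct --quantiles quantiles.csv --alpha alpha.csv --out corrected.csv
tvv profile --design A --quantiles corrected.csv --pk study/pk.csv \
    --conc 1000 --knots 8 --bootstrap 200 --seed 1 --out profile.csv
tvv pzero --profile profile.csv
tvv classify --samples pzero_samples.csv --threshold 43 --out report.json
```

`tvv profile --pointwise` writes the 100 independent per-p fits instead of
the functional profile (useful as a cross-check).

## Data conventions

- Quantile tables are CSVs with columns
  `subject,treatment,timepoint,replicate,RR_s,Tr_1..Tr_100`
  (plus `Trc_1..Trc_100` after correction).
- PK tables: `subject,treatment,timepoint,drug,conc_ng_ml`.
- Timepoints are hours post-dose; rows with `timepoint <= 0` are baseline.
- All sample indices are 0-based; annotations are half-open in
  `[0, n_samples)`.
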