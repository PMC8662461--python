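# ovitrack

Radar-based tracking and behavioural phenotyping of sheep in the standard
arena (pen) test.

Applied ethologists and breeding programmes need movement phenotypes for
many animals, without tags, cameras sensitive to lighting, or manual
scoring. A millimetre-wave FMCW radar placed behind one short wall of a
2 m × 7 m test pen can recover an untagged animal's 2D trajectory at 50
fixes per second. `ovitrack` implements that measurement chain and the
behavioural estimators built on top of it, end to end, with a synthetic
session generator so every stage is testable without hardware:

1. **Radar simulation** — FMCW beat signals (or map-level shortcuts) for a
   point-reflector sheep moving through a static clutter scene, with
   configurable 77 GHz indoor / 24 GHz outdoor radar parameters.
2. **Clutter-normalized detection** — per-cell background statistics from
   animal-absent recordings standardize each range–azimuth map:

   `D(t, r, θ) = (S(t, r, θ) − mean(r, θ)) / std(r, θ)`

   The animal is the supra-threshold global maximum of `D`; sub-bin
   parabolic refinement and constant-velocity gap filling yield the track.
3. **Behavioural estimators** —
   * 1-s window features (speed, sinuosity, path length, lateral and
     longitudinal speed) classified by a Gaussian mixture whose class
     count k ∈ 1…15 is chosen by minimum AIC;
   * movement-change counts from Ricker ("Mexican hat") wavelet filtering
     of each position coordinate across time scales, counting local maxima
     of the coefficient field;
   * occupancy scores on an 80-zone grid (16 × 5; a zone counts when the
     sheep remains in it longer than 200 ms), plus proximity and
     area-crossing scores on the seven 1-m virtual areas;
   * per-sheep eight-feature phenotypes (four estimators × two test
     phases) reduced by correlation-matrix PCA with Kaiser–Guttman
     retention (eigenvalue > 1) and regressed on docility/sociability
     covariates.

## Worked example

Simulate a 58-sheep cohort (three phases of 15/60/60 s at 50 Hz, planted
phase-3 movement suppression and a positive sociability→activity
coupling), assemble phenotypes, and run the PCA:

```
$ ovitrack cohort --n-sheep 58 --seed 7 --out-dir demo
n=58 sheep; retained 3 PCs; eigenvalues [2.327, 1.865, 1.1, 0.936, 0.886, 0.615, 0.17, 0.102]
```

The run writes `phenotypes.csv` (one row per sheep: covariates, the eight
features, PC scores), `pca_summary.json`, and
`covariate_associations.csv`. In this cohort the mean fast-movement
proportion falls from 0.357 (phase 2, isolation) to 0.170 (phase 3, human
present), the longitudinal wavelet count from 13.7 to 9.5, and the
heatmap score from 35.0 to 24.2 — the planted "sheep move less with a
human present" effect. The first principal component (general movement)
is positively associated with sociability (slope 0.738 ± 0.180,
p = 1.3 × 10⁻⁴), recovering the planted coupling direction.

Single sessions run the same way:

```
ovitrack simulate --seed 1 --frames map --out session.h5
ovitrack track --session session.h5 --threshold 5 --out track.csv
ovitrack features --track track.csv --out-dir feats
```

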