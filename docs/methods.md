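# Methods

## Setting

The package models the standard arena test for sheep social motivation: a
2 m × 7 m pen with three conspecifics behind a grid barrier at one short
end, three protocol phases (15 s exploration with visual contact, 60 s of
social isolation behind an opaque panel, 60 s with the conspecifics
visible again and a motionless human present), seven 1-m "virtual areas"
along the pen length delimited by infrared beams, and an FMCW radar
behind the entrance-side wall. Analyses use phases 2 and 3.

Coordinates: `y` runs along the pen length (0 at the entrance wall), `x`
across the width centred on the radar boresight; the radar phase centre
sits 1 m behind the entrance wall at `(0, −1)`. Azimuth is measured from
boresight, positive toward +x.

## Radar model

The indoor radar defaults follow the 77 GHz device: 3 GHz modulation
bandwidth, 256 µs ramps, 4 Tx × 8 Rx giving 32 virtual channels at
half-wavelength spacing, 100 mW, 50° field of view. A 24 GHz outdoor
variant (800 MHz, 1 ms ramps) is provided as `RadarConfig.outdoor()`.
The frame rate defaults to 50 Hz (the device's measure rate; its chirp
repetition interval would imply a lower rate — the rate is configurable
and the discrepancy is noted here rather than resolved).

Each reflector at range r and azimuth θ contributes a complex tone of
beat frequency `f_b = 2 B r / (c T_ramp)` along fast-time and the phase
ramp `2π d sin θ / λ` across the virtual array, with the deterministic
two-way propagation phase `−4π r / λ`. Range–azimuth maps are magnitudes
of a Hann-windowed 2D FFT (fast-time → range, one bin = `c/2B` = 5 cm at
3 GHz; channels, zero-padded to 64 bins → sin-azimuth). The sheep is one
point reflector: no micro-Doppler, body extent, or pose.

A map-level shortcut (`synthesize_map`) places a separable Gaussian
point-spread (σ ≈ 0.6 bins) directly on the polar grid with the same
propagation phase, bypassing the FFTs. The two levels agree on the argmax
cell for a noiseless target (tested over 20 arena positions) and the
map level makes thousand-frame clutter experiments cheap.

Clutter is strictly static: wall scatterers every 25 cm with amplitudes
drawn once per scene. Noise is circular complex Gaussian added per frame
(per-component sd `noise_sigma/√2`, default `noise_sigma = 0.5` against a
target amplitude of 5 — a strong, plainly visible echo, as in the real
device at these ranges). Echo amplitude is range-independent; across a
7-m pen the spread in free-space loss is modest and the clutter
normalization removes static gain structure anyway.

## Clutter normalization and tracking

With per-cell background mean and standard deviation estimated from ≥ 2
animal-absent frames (120 by default; the sd uses ddof = 1),

    D(t, r, θ) = (S(t, r, θ) − mean(r, θ)) / max(std(r, θ), ε)

with ε = 10⁻¹² guarding zero-variance cells. On held-out background the
standardized ensemble has grand mean ≈ 0 and sd ≈ 1 (checked at n = 1000
frames). Detection takes the global argmax of D when it exceeds a
threshold (default D ≥ 5; on pure background with ~11 000 cells this
yields a non-trivial per-frame false-alarm rate, which only matters when
the animal is outside the beam — the threshold is exposed on the CLI).
Ties break toward the smaller range bin, then the smaller angle bin.
3-point parabolic interpolation along each axis refines the peak to
sub-bin precision; recovery error for a noiseless target is well under
half a bin in both axes. Tracks convert polar fixes to arena coordinates;
runs of invalid frames are filled by constant-velocity interpolation
between flanking fixes (leading/trailing gaps hold the nearest fix), and
out-of-arena fixes are clamped to the walls.

`range_resolution(B) = c/2B` and
`free_space_gain(f_h, f_l) = 20 log₁₀(f_h/f_l)` are exposed as closed
forms (5 cm at 3 GHz; 10.13 dB for 77 → 24 GHz).

## Movement simulator

Ground truth is a correlated random walk switching among movement modes.
Each mode has a truncated-normal step speed and a per-second von Mises
turning concentration κ (κ → ∞ is straight-line motion). The default
four modes mirror the canonical repertoire: slow (0.06 ± 0.03 m/s,
κ = 30), fast (0.80 ± 0.20, κ = 30), fast tortuous (0.60 ± 0.20,
κ = 0.5), slow tortuous (0.10 ± 0.05, κ = 0.3), with stationary weights
(0.513, 0.355, 0.102, 0.030) matching the occupancy split reported for
real sheep. Transitions use a "redraw from the stationary law with
probability `switch_prob`" matrix (default 0.02/step ≈ 1 s mean dwell at
50 Hz), which makes the stationary distribution exact by construction.
Walls are reflective (positions fold specularly).

Covariates: docility and sociability are standard-normal z-scores. The
coupling is log-linear on the active-mode stationary weights and on the
switching rate: sociability multiplies activity by `exp(0.35·z)` and
switching by `exp(0.25·z)` (positive direction — sociable sheep move and
change more, the direction of the reported wavelet-Y and PC1 effects);
docility multiplies activity by `exp(−0.15·z)`. Phase 3 multiplies the
active-mode weight by 0.30 and the switching rate by 0.55 for every
sheep, producing the "all sheep move less with the human present"
suppression; the sizes were chosen once to give a clear but not
caricatured contrast (roughly halving the mean speed and space use, in
line with the ~2.4× reported drop in space coverage).

What the generator does **not** emulate: real posture/gait, multi-animal
interactions, bleats, radar shadowing or multipath, attention to the
conspecific end (the walk has no spatial bias along y). Passing tests
therefore show that the estimators recover *planted* kinematic structure
through the full measurement chain, not that real sheep behave this way.

## Behavioural estimators

**Windows and features.** Trajectories are cut into contiguous 1-s
windows (a trailing fragment shorter than 0.5 s is dropped). Each window
yields: mean speed (path length / duration), sinuosity (path length /
net displacement, floored: net displacements under one range bin, 5 cm,
are treated as unmeasurable, stationary windows get sinuosity 1, and the
ratio is clipped to ≥ 1), path length, and the mean |dx|/dt and |dy|/dt
speed components.

**Mixture classes.** Full-covariance Gaussian mixtures are fitted to the
standardized features for k = 1…15 with 10 random restarts each;
the k minimising AIC = 2p − 2 log L is kept. Two numerical choices
matter: `reg_covar = 10⁻²` (a mild ridge on standardized-feature
covariances; with many restarts the default 10⁻⁶ lets near-singular
high-k solutions win the AIC, e.g. selecting k = 14 on a clean 2-mode
simulation) and semantic labelling of components. Components are named
slow/fast × plain/tortuous from their means: speed splits midway between
the slowest and fastest component means (0.3 m/s when a single component
leaves no spread); sinuosity splits at the absolute, scale-free value
1.5. Pooled medians are deliberately not used — with one dominant class
the median falls inside a cluster and misnames it. The fast-movement
proportion is fast/(slow + fast) occupancy, ignoring tortuous classes.
Per-lamb fitting is the default; cohort phenotyping pools all windows
into one mixture (standardized over the pool, k = 1…6, 3 restarts) so
labels are comparable across animals and the cohort run stays fast.

**Wavelet transitions.** Each position coordinate is convolved
(reflect-padded, same-length) with L2-normalized Ricker kernels
ψ(t) ∝ (1 − (t/a)²)e^(−t²/2a²) on 8 geometric scales from 0.2 s to
2.0 s (support 8a, exact zero mean on the truncated support). The
transition count is the number of strict 8-neighbour local maxima of
|coefficients| in the (scale × time) field that reach 0.1 × the field
maximum, excluding columns within half a kernel support of the signal
ends per scale (margin cells are also barred from suppressing valid
neighbours — otherwise a change near the boundary of a coarse scale
would silently erase its own maximum at finer scales). An absolute floor
of 10⁻⁹ on the field maximum keeps numerical noise on a flat signal from
counting. The scale ladder stops at 2 s because an 8a support at 6 s
(48 s) leaves almost no margin-free interior in a 60-s phase and merges
changes spaced a few seconds apart; with the 2-s top the estimator
recovers 5 planted velocity switches within ±1 and increases strictly
when the switches double, across all tested seeds. Counts are taken
inside per-phase time masks on a single whole-signal transform, so phase
boundaries add no edge artefacts.

**Occupancy.** The 16 × 5 grid tiles the pen exactly (0.4375 m × 0.40 m
cells — the footprint of a small lamb). Cells and 1-m areas are
half-open, closed at the far (conspecific) edge. A *visit* is a maximal
run of consecutive samples in one cell, split at phase boundaries; the
heatmap score counts zones with at least one continuous visit longer
than 200 ms ("remained in" read as continuity — a cumulative-time mode
and the 1-s threshold variant are flags). The proximity score is
Σ weightₐ × timeₐ with linear weights 1…7 increasing toward the
conspecific end (the direction is fixed, the values configurable); the
crossing rate counts area-boundary transitions (a k-boundary jump counts
k). Infrared beams at y = 1…6 m emit an event per crossing with linearly
interpolated times; the reconstructed crossing count equals the
trajectory-derived one exactly.

**Phenotypes.** Each sheep contributes eight features (fast proportion,
wavelet X, wavelet Y, heatmap × phases 2 and 3). The cohort matrix is
z-scored (features have incommensurate units) and the correlation matrix
eigendecomposed; eigenvalues sum to the feature count, loadings are
sign-fixed so each component's largest-magnitude loading is positive,
rank deficiency shows up as zero eigenvalues. Kaiser–Guttman retention
keeps eigenvalues strictly greater than 1 (exactly 1.0 is not retained).
Component scores are regressed on each covariate by OLS; mixed-model
fitting across phases is deliberately left to downstream tools, which
consume the tidy tables this package writes.

## Validation problem sizes

The test and acceptance runs use: 20 noiseless positions for end-to-end
recovery; 1000 + 1000 map-level frames for the background statistics;
20 seeded replicates of 400-window planted mixtures for k ∈ {2, 4}
(occupancies compared after merging components by quadrant label, so an
occasional k overshoot does not corrupt the comparison — the modal
selected k still equals the planted k); 20 seeded planted-switch tracks
(5 vs 10 switches, 60 s); and 20 seeded cohorts of 58 sheep with the
full 15/60/60-s protocol at 50 Hz. The phase-3 sign test is evaluated on
per-sheep phase differences pooled over the 20 cohorts; on single
cohorts it holds in ~17/20 seeds, the marginal feature always being
wavelet X — the lateral effect is genuinely the weaker one, as in the
real data.

## Known limitations

* Single target only: no data association, CFAR, or Doppler; a second
  mover (e.g. a handler) would capture the argmax on frames where it
  reflects more strongly.
* The 50° beam does not cover the pen corners nearest the radar; there
  the simulated animal is simply not illuminated and the track falls
  back to gap filling, which is realistic but inflates position error
  near the entrance.
* Wavelet counts depend on the scale ladder and relative threshold;
  absolute counts are not comparable across settings, only contrasts
  (phases, animals) under a fixed configuration.
* The azimuth resolution of the real device (~6°) is aperture-limited;
  no closed form for it is exposed, only the sin-space bin width of the
  simulated array.
* Eigenvalue-based retention on small cohorts is noisy; with 58 sheep
  the third eigenvalue hovers near 1 and retention can be 2 or 3.
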