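# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Repeat screen

A cluster is a set of non-overlapping k-mer occurrences (k = 20 nt by
default) within one transcript whose pairwise Hamming distances are all at
most `max_mismatch` (default 1). Matching is on the sense strand only,
because dCas13 binds the mRNA; U and T are interchangeable; N never matches.
Candidate pairs are enumerated by pigeonhole seeding (a k-mer is split into
`max_mismatch + 1` chunks; two k-mers within the distance budget must share
one chunk exactly), which is exact and avoids the O(n²) scan; the test suite
checks equality with a brute-force all-pairs oracle. Clusters are grown
greedily left to right, the canonical motif is the first occurrence's
sequence, and overlap ties resolve to the smaller start.

Two points were genuinely open and are both implemented behind flags:

* *Mismatch topology.* "All fragments match exactly or have only one
  mismatch" can mean pairwise distance ≤ 1 (stricter) or distance ≤ 1 from
  a hub occurrence (star). Default `pairwise`; `--mismatch-topology star`
  switches.
* *Cross-gene removal.* A cluster whose repeat unit recurs in another
  gene's cluster is discarded (both sides are). Default matching is
  mismatch-tolerant (within Hamming 1); `tolerant=False` requires exact
  identity. Same-gene isoforms never collide.

A consequence of repeat structure worth knowing: wherever a motif occurs at
a constant spacing, k-mers shifted by one or two bases into the flanks also
form (smaller) clusters, because they differ only at flank positions. These
"satellite" clusters are genuine repeats and are reported; candidate
selection uses the largest cluster per transcript, so they do not affect
candidate calls.

`expression_summary` scales each cell's counts to the median library size
before averaging within cell types. Processing of real single-cell count
matrices is deliberately out of scope; the function is a hook for annotating
screen results with expression.

## Transcription-trace quantification

Activity is `(ROI1_max − ROI2_mean) / ROI2_mean`, ROI-2 being the annulus at
three times ROI-1's radius with ROI-1 excluded. The ratio is invariant to
any positive gain applied jointly to signal and background, which is exactly
how photobleaching enters; the property is tested both algebraically and on
rendered bleaching movies (< 1% drift). An unidentified puncta is assigned
the local background, i.e. activity 0.

Initiation is the first time the trace exceeds a threshold for two
consecutive points (the debounce suppresses single-frame speckles). The
original analysis scored traces manually; as a self-calibrating default the
threshold is 3 × 1.4826 × MAD of the pre-cycle baseline, with an absolute
override (the synthetic studies use 0.15, about seven baseline noise SDs and
7.5% of the plateau amplitude). Detection time is monotone in the threshold
(property-tested).

Activation patterns: *none*, *one_allele*, *same_time* (|Δt| ≤ window),
*sequential*. No numeric window is published for "at the same time"; the
default is one sampling interval (2 or 5 min depending on acquisition), and
the window is an explicit parameter everywhere so sensitivity can be
reported.

Plateau time is the first point at which the 3-point moving average reaches
90% of its maximum — a rule chosen because published plateau times come
without one; for a linear ramp it returns 0.9 × (rise time), which the tests
account for.

Memory statistics summarize |Δt| between allele initiation times per cycle
class and compare classes with an unpaired two-tailed t test.

## Noise decomposition

Cumulative output is the plain sum of normalized intensities over the
cycle's uniform time grid (a Δt-weighted option exists; on a uniform grid
the two differ by a constant factor). Pearson r, Spearman ρ, the slope of
output₂ on output₁, and the two-tailed p are reported per cohort. The
random-pair control re-pairs allele 1 of cell i with allele 2 of a seeded
derangement (no self-pairs). Per-timepoint correlation series are compared
between cycles by a t test on the raw r values — deliberately reproducing
the published procedure; a Fisher-z option exists but is off by default.

## Single-particle tracking

Tracks shorter than 20 consecutive frames are discarded. The time-averaged
MSD uses all overlapping pairs per lag and equals a brute-force double loop
exactly (tested). Model fits are weighted least squares with σ ∝ t^1.5,
because the variance of the time-averaged MSD estimator grows roughly as t³
for lags short relative to the track; the weighting anchors the fit to the
well-estimated early lags. This matters quantitatively: the confined
model's derived D = L²/(12τ) is the initial-slope/plateau combination, and
early-lag anchoring is what makes it recover the generating D within ~1% on
synthetic cohorts.

Classification decisions, in order:

1. *Directed*: gyration-radius ratio < 10⁻³ and span > 2 µm. The ratio is
   of radii (square roots of the covariance eigenvalues); a flag can switch
   to eigenvalues. Speed comes from the closed-form least-squares fit of
   MSD = (vt)²; the power-law fit is also reported (α → 2 for ballistic
   motion).
2. Otherwise the power-law and confined models compete on weighted rss over
   the first 10% of lags (4–100). Both have two free parameters, so rss
   ranking and AIC ranking coincide. During classification τ is bounded
   above by half the fit window: confinement is only declared when
   equilibration is actually observable, which prevents the confined model
   from collapsing onto its τ → ∞ linear limit and shadowing genuine
   diffusion.
3. *Stationary* override: span < 0.4 µm and fitted D < 0.03 µm²/s. The D
   used is the power-law fit's: the confined model's L²/(12τ) diverges as
   τ → 0 on flat MSD curves, which would defeat the override exactly where
   it is needed.

Export events: the nucleus is a closed polygon; dock is the first frame of
the final nuclear-side dwell within 0.2 µm (the NPC length scale: basket
~75 nm, central framework ~70 nm, cytoplasmic filaments ~50 nm) of the
edge before the inside→outside crossing; release is the first cytoplasmic
frame from which the distance to the edge increases for two consecutive
frames. Transit < 1 s is *fast*, otherwise *slow*; a near-linear
dock-to-release sub-track is *directed*. The directed transit estimate is
simply NPC length / speed.

## Synthetic data

Trajectories: diffusive motion is a Gaussian random walk with per-axis step
variance 2 D Δt; directed adds a constant drift in a seeded random
direction; stationary is a fixed point; localization noise of SD σ_loc is
added to every reported coordinate. **Corralled motion defaults to a
harmonic tether** — a discrete Ornstein–Uhlenbeck process parameterized by
(D, L) with stationary per-axis SD L/√12 and relaxation τ = L²/(12 D) —
because its MSD *is* the confined model exactly, including the plateau L²/3
and the derived-D identity. A literal reflecting square box of side L is
available (`corral_model="box"`) and shares the plateau and the stationary
variance, but its true MSD is a multi-exponential series; fitting the
single-exponential confined model to it understates L²/(12τ) by 12–16% at
any fit window (verified on the exact theory curve), so the box is the
wrong generator when the point is to invert the confined model.

Classification benchmarks run diffusive/corralled/stationary tracks for
1000 frames (10 s at the 10-ms frame interval) so that several confinement
times fit inside the classification window; directed tracks are simulated
ballistic (D = 0, σ_loc = 0, 100 frames) because the near-linearity gate
(ratio < 10⁻³) admits only tracks with negligible transverse spread — at
the measured nuclear D and v, transverse diffusion alone pushes the ratio
to ~0.1.

Allelic traces: each cell draws a shared log-normal extrinsic multiplier
exp(N(0, σ_ext²)) and per-allele intrinsic multipliers; allele 1 initiates
at a gamma time (default mean 20, SD 8 min), allele 2 after a gamma offset
parameterized by mean/SD (SD 0 is a point mass; gamma keeps offsets
non-negative, matching a mean ± SD specification); a configurable fraction
of second alleles stays silent. Traces ramp linearly to plateau over
`plateau_time` minutes from initiation and then fluctuate multiplicatively
(SD 5%). Raw ROI tables are emitted with signal *and* background multiplied
by exp(−t/bleach_tau), plus additive measurement noise (SD 2 a.u. on a
100 a.u. background), so normalization genuinely has bleaching to cancel.
No telegraph (burst) kinetics are modelled: the ramp-plateau form is a
stand-in sufficient for initiation timing, output correlation, and plateau
statistics, and the package makes no claim about burst-frequency or
burst-size inference.

Spot movies are sums of 2-D Gaussians over a constant background with
Gaussian read noise — no PSF engine, no shot noise. Transcriptomes embed
motif copies at fixed spacing inside random sequence with recorded
positions and planted substitutions.

What passing tests on these generators shows: the estimators invert the
stated generative models at realistic parameter scales. What it does not
show: robustness to segmentation errors, tracking linkage errors, nuclear
movement, or background structure present in real movies.

## Denoising

The objective ‖f − H⊗g‖₂² + λ‖g‖₁ + μ‖∇g‖₂² uses reflective boundaries for
both the convolution and the forward-difference gradient. The solver is
ISTA with step 1/(2 + 16μ) (a Lipschitz bound from ‖H‖₁ = 1 and ‖∇ᵀ∇‖ ≤ 8);
its objective is non-increasing every iteration, asserted to 10⁻¹⁰. FISTA
acceleration is available but not monotone. The PSF and weights are not
published for the original system; defaults are a Gaussian PSF of SD 1.3 px
and λ = 0.01, μ = 0.1 in image units — these are tuning knobs, and any
comparison to the original reconstructions is qualitative only. An 8×8
optimality check against a quasi-Newton oracle on a smoothed-|x| surrogate
agrees to 0.1%.

## Dosage arithmetic

Molecules per embryo = concentration × volume × N_A, reported to two
significant figures; per-cell dose after n synchronous divisions divides by
2ⁿ and reports one significant figure — matching how such numbers are
quoted.

## Problem sizes

Cohort sizes used by the tests and the acceptance script: 200 tracks × 100
frames for parameter-recovery fits (1000 tracks in the acceptance script,
where ensemble-fit noise of ~1% is wanted), 100 tracks per class for
classification recall, and 55 / 36 allele pairs for the de novo /
re-activation memory cohorts — the published cohort sizes. The acceptance
script averages the recovered memory statistic over 11 replicate cohorts so
its report reflects the detection pipeline rather than the sampling noise
of one gamma draw.

## Known limitations

* No particle detection or linking: tracks are consumed, not produced.
* 2-D only; no 3-D NPC geometry for export events.
* No burst-kinetics (k_on/k_off) inference and no dual-reporter variance
  decomposition formulas — noise is characterized via correlations, as in
  the source analysis.
* The export-event dock/release rules automate a procedure that was
  originally scored manually; boundary annotation quality dominates their
  accuracy on real data.
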