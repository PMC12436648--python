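# Methods

This note documents the models, estimators and numerical choices behind
`smtrack`, and what the synthetic generators do and do not emulate.

## The measurement problem

A reporter mRNA tethered to the plasma membrane is imaged by TIRF in up
to three channels: the mRNA itself (coat-protein label), its translation
site (nascent-peptide epitope array bound by a fluorescent antibody
fragment), and a tagged protein factor. The analysis asks four
questions: (i) what fraction of mRNAs ever carry the factor during an
observation window; (ii) how long individual binding events last;
(iii) how many factor molecules sit on one mRNA (stoichiometry against a
single-binding-site calibration standard); and (iv) how fast ribosomes
clear an mRNA after translation initiation is blocked, summarized as a
survival curve of translation-site lifetimes. A fixed-cell smFISH-IF
branch counts nascent peptides per translation site.

## Synthetic cohorts

Real movies for assays of this kind are not generally redistributable,
so every stage is validated against simulated cohorts whose ground truth
is the set of values the assays are known to produce. The presets encode:
a 3.6-s exponential mean residence time for the single-site coat-protein
standard; per-mRNA engagement fractions of 0.50 / 0.80 / 0.95 for the
1x/3x/12x binding-site ladder; recruitment fractions of 0.8 (stalling
reporter) and 0.1 (no-insert control) for the collision-sensing ligase;
a transient-recruitment mean duration of 3.5 min inside 5-min movies
with one third of recruitments persisting past the window; a 1.5-fold
clearance-rate increase under ligase overexpression; a 10%
runoff-resistant subpopulation of which half carries ligase signal; and
right-skewed nascent-peptide counts with mean 40.3 (48.1 after UV).

Design choices that were genuinely open:

- **Tethered-mRNA motion.** Confined diffusion in a harmonic well,
  implemented as an Ornstein–Uhlenbeck process around a fixed anchor
  (stationary SD 0.6 px ≈ 100 nm, relaxation 10 s). This keeps spots
  trackable but non-stationary, which is the regime membrane tethering
  produces.
- **Two kinds of binding preset.** The *kinetics* preset
  (`pbs_1x_kinetics`) draws a per-site alternating renewal process —
  exponential on-times (mean 3.6 s), exponential off-times (mean 90 s) —
  and is used wherever dwell times are the measurand. The *engagement*
  presets (`pbs_1x/3x/12x`, `polya_znf`, `no_insert_znf`) define
  `p_engaged` as the fraction of mRNAs that show at least one
  qualifying colocalization event in the window, because that is what
  the emulated assay reports; an engaged mRNA therefore receives one
  episode guaranteed to be long enough to qualify (a memoryless
  `min_qualify + Exp(mean_on)` duration) placed so it fits inside the
  window, plus ordinary renewal episodes. Separating the two avoids
  coupling the dwell-time measurement to the duty-cycle calibration.
- **Transient recruitment durations.** The observed mean duration of
  ligase recruitments that end inside a 5-min movie is 3.5 min. No
  window-truncated exponential can average 3.5 min on (0, 5 min) — the
  conditional mean of a truncated exponential is bounded by half the
  window — so the generator treats the observed value itself as ground
  truth and draws transient durations from a scaled Beta on (0, window)
  with mean `transient_mean_min` (concentration 4, i.e. SD ≈ 1 min).
  Transient episodes are placed clear of the first/last frame; episodes
  drawn longer than the window minus margins run to the window end and
  are censored.
- **Cohort fractions are balanced, not Bernoulli.** The damaged and
  ligase-positive fractions of a runoff cohort are observed cohort
  fractions in the emulated experiment, so the generator assigns
  `round(frac·n)` molecules (randomly placed) rather than flipping an
  independent coin per molecule. The pipeline still has to *measure*
  the fractions through detection, clearance extraction and
  colocalization; balancing only removes generator-side binomial noise
  from the ground truth.
- **Runoff decay.** Translation-site intensity decays as a linear ramp
  (uniform ribosome flux off a loaded message gives a linear decay),
  parameterized so the trace crosses 10% of its plateau exactly at the
  true clearance time. Baseline clearance times are lognormal: median
  600 s, σ = 0.3 for the stalling reporter; median 180 s, σ = 0.4 for
  the no-insert control. The no-insert spread keeps the damaged
  (persistent) subpopulation separable from the slow tail of normal
  runoff, matching the observed bimodality (≈90% cleared within
  10 min).
- **Imaging model.** Spots are rendered as pixel-integrated Gaussians
  (separable in z for 3D), so total expected photons equal
  intensity × `photons_per_unit` at any sub-pixel position; noise is
  Poisson shot noise plus additive Gaussian read noise. Defaults
  (160 nm pixels, 2-s frames steady-state / 10-s frames runoff, PSF
  σ = 1.3 px, 2000 photons per intensity unit on background 100) are
  declared calibration constants, not values inferred from data.

What the generators do **not** emulate: dye photophysics (blinking,
photobleaching), chromatic offsets and registration error, uneven TIRF
illumination depth, cell-shape realism, and out-of-focus or diffusing
background molecules. Passing tests therefore demonstrate correctness of
the estimators under the stated imaging model, not robustness to every
artifact of real microscopy.

Reproducibility: every generator draws from per-molecule child streams
of one `SeedSequence`, so identical (preset, config, seed) give
bit-identical cohorts, and truncating the window of a renewal-preset
cohort reproduces a prefix of the longer window's episode list.
(Engagement and mixture presets define their ground truth relative to
the observation window, so their draws are window-dependent by design.)

## Detection and fitting

Candidate spots are maxima of a scale-normalized Laplacian-of-Gaussian
band-pass above `k` robust (MAD-based) standard deviations of the
filtered image (k = 3 for 2D movies, 4 for large 3D volumes, where the
greater voxel count otherwise admits noise maxima). Each candidate is
refined by unweighted least squares against an offset plus
pixel-integrated elliptical Gaussian, solved by Levenberg–Marquardt with
an analytic Jacobian. Fits are rejected with a machine-readable reason
when they fail to converge, go negative, leave the window, or land
outside the accepted width band (0.6–2.0 × the nominal PSF σ by
default) — the width band is what separates true spots from sharp noise
excursions that survive the candidate threshold. An optional post-fit
amplitude gate (`amp_threshold_k` × the raw image's robust noise SD)
serves the same purpose for dim channels. Windows touching the image
border are shrunk and the spot flagged `edge`. Localization accuracy is
checked against the information limit: at peak SNR 5 the Monte-Carlo
median radial error matches the background-corrected Cramér–Rao
prediction (~0.2 px); noiseless spots re-fit to < 0.02 px and < 1%
integrated intensity.

## Tracking

Frame-to-frame linking solves a gated linear assignment on squared
displacement with per-spot birth/death alternatives priced at the gate
(3 px default at 2-s frames for tethered mRNAs). Gap closing joins track
ends to later starts across ≤ `max_gap_frames` missed frames within a
radius scaled by √(gap+1); temporally overlapping tracks are never
merged. Filters implement the analysis rules: mRNA tracks shorter than
25 frames and protein tracks shorter than 4 frames are discarded
(5 frames for both in runoff/UV mode); mRNA tracks must span ≥ 2 min;
mRNA tracks approaching another within 2×PSF σ (2.6 px default — the
crossing criterion is not published, so it is a declared parameter) are
discarded as crossings. "Shorter than N discarded" is read strictly: a
track of exactly N frames is kept.

## Colocalization

A protein or translation-site track joins an mRNA track if their
per-frame distance is ≤ 1.5 px (≈240 nm; the original assays curated
overlap manually, so the radius is an explicit parameter here) for at
least 4 overlapping frames (2 in runoff/UV mode); each candidate track
goes to the mRNA with the smallest time-averaged distance, ties to the
lower id, so no track is counted twice. An mRNA is *colocalized* when
some run of consecutive within-radius frames reaches 5 (steady state,
~10 s) or 2 (runoff/UV at 10-s frames), evaluated within the first
5 min in steady-state mode. An mRNA is *translating* iff a
translation-site track is linked to it. Cell eligibility supports both
published rules — more than 15 mRNAs (calibration assays) or more than
10 translating mRNAs (ligase assays) — selected per run.

## Bound states and residence times

Two bound-state definitions are implemented and the selection is logged
per run:

1. **Colocalization runs** (default): each maximal run of consecutive
   frames during which one linked protein track stays within the
   association radius is a bound state; runs shorter than 8 s (4 frames
   at 2-s intervals; stored in seconds so other intervals scale) are
   dropped, and runs touching the observation boundary are flagged
   censored. This is the natural definition when the binder is only
   detectable while bound, and it is robust for episodes as short as
   one frame.
2. **Change-point segmentation**: recursive binary splitting of an
   intensity trace at the position of the maximal two-sample pooled-t
   statistic, gated at α = 0.01 with Bonferroni correction over each
   segment's candidate split positions; zero-variance splits (noiseless
   steps) are taken as infinitely significant. Above-threshold segments
   lasting ≥ 8 s become bound states. Binary segmentation has full power
   for step-like level changes (it matches exhaustive least-squares
   segmentation on 1–2-step traces to ±1 frame ≥90% of the time, and
   splits null traces with probability ≤ α) but, like any global
   mean-shift statistic, it cannot resolve one-frame spikes inside long
   traces — which is why definition 1 is the default for dwell-time
   work and definition 2 serves level analysis (multi-binder steps,
   stoichiometry).

Residence-time summaries exclude censored episodes. Two policies exist:
the arithmetic mean of observed durations (default), and a
discretization-corrected exponential MLE used whenever the dwell time is
comparable to the frame interval. The correction is exact for the
generator's sampling model: an exponential dwell of mean τ observed at
frame instants yields a frame count that is geometric with
`p = 1 − exp(−Δt/τ)` conditioned on `n ≥ 1`, so
`τ̂ = −Δt / ln(1 − 1/n̄)`; conditioning on `n ≥ 1` exactly accounts for
sub-frame episodes that are never observed (the raw mean overestimates a
3.6-s dwell by ~30% at 2-s frames).

Stoichiometry samples are integrated intensities divided by the mean
bound-state intensity of the single-site calibration standard, which
makes them scale-invariant by construction. Distribution comparisons use
the exact two-sample KS statistic with asymptotic p-values, or the
pooled-variance two-tailed t test.

## Runoff survival

For each record the clearance time is the time from the
translation-site maximum to the first frame strictly below 10% of that
maximum, on the raw (unsmoothed) trace. Records are excluded when the
mean of the first four frames is below 10% of maximum (not translating
at treatment) or when the mRNA- and translation-site crossings coincide
within ≤ 3 frames (signal loss for reasons other than ribosome
clearance); translation-site signal persisting after mRNA loss is kept,
and never-crossing traces are right-censored at the window end. The
treatment clock starts at the first post-treatment frame; the
acquisition dead time after drug addition is metadata, not added to
clearance times. On noisy flat-top traces the observed maximum can land
a frame or two late, which shortens measured clearance times by a few
percent — an intrinsic property of the published rule that affects both
cohorts of a comparison proportionally.

The survival curve is the Kaplan–Meier product-limit estimator over
event times, censored records reducing the risk set without events;
variance is Greenwood's formula
`Var Ŝ(t) = Ŝ(t)² Σ_{t_i ≤ t} d_i/(n_i(n_i−d_i))` with linear 95%
bounds clipped to [0, 1] (a log–log variant is deliberately out of
scope; the linear form is what the emulated analysis names). Cohorts are
compared by the ratio of KM medians (first event time with S ≤ 0.5),
with the reciprocal reported as a rate ratio; undefined medians are
flagged rather than guessed.

## smFISH-IF quantification

mRNA spots are detected in 3D inside per-cell masks; protein-channel
fits within 2 px laterally and 1 z-plane of an mRNA spot (declared
defaults — the published thresholds are unstated) are translation sites,
each linked to its nearest mRNA. Single proteins are protein-channel
detections outside every translation-site ROI (an ellipsoid of 3 fitted
σ); a cell needs ≥ 5 single-protein detections for a defined unit
intensity, else it is dropped with a reason. NAP counts divide each
site's integrated intensity by its own cell's unit mean — never another
cell's. Distribution comparisons square-root-transform the counts before
the two-tailed equal-variance t test.

## Problem sizes

The validation suite and the reproduction script run the cohorts at the
sizes the analyses are specified at: 2000 mRNAs for residence-time
recovery, 30 cells × 30 mRNAs per engagement condition, 150 mRNAs per
runoff arm, 300 for the damaged-subpopulation cohort, and 200
translation sites (10 fields of 20, with 30 single proteins each) for
the smFISH branch; the end-to-end movie-rendering path is exercised on
smaller fields (≈10 molecules, ≤ 100 frames, 64–128 px), chosen as the
smallest sizes at which the per-stage estimators are testable against
their statistical tolerances.

## Known limitations

- The colocalization radius and the crossing radius replace manual
  curation steps of the emulated workflow; their values are declared,
  not reconstructed.
- The geometric dwell-time correction assumes exponential on-times and
  point sampling; for strongly non-exponential dwell distributions only
  the arithmetic-mean policy is meaningful.
- Change-point segmentation is blind to sub-frame and one-frame events
  inside long traces (see above).
- The imaging model omits photobleaching; residence-time estimates on
  real data should be checked for illumination-power independence
  before being read as binding kinetics.
- Greenwood confidence bounds are pointwise, not simultaneous.
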