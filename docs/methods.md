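# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the toolkit, in the order the pipeline runs them.

## Signal model and beat detection

An extracellular cardiomyocyte field potential is modeled as a sharp
biphasic R-complex (dominant lobe usually negative-going) followed by a
slower, smaller T wave. Detection is peak finding on each electrode trace
with two user-facing parameters:

- `min_height` (default **100 µV**): minimum peak amplitude. The default
  suits healthy cultures whose R peaks are several hundred µV; noisy or
  weak preparations should raise the detection filter rather than lower
  this threshold.
- `min_distance` (default **250 ms**): minimum peak separation,
  corresponding to a 240 bpm ceiling.

Polarity is resolved per electrode (`auto`): peaks are searched on both the
raw and negated trace and the orientation with the larger median peak
amplitude wins. This handles arrays where individual electrodes record
inverted deflections. All derivative-based metrics then operate on the
*oriented* trace (negated where polarity is negative) so "upstroke" and
"downstroke" are consistent.

Optional zero-phase (forward–backward) Butterworth filtering (order 4)
precedes detection; zero-phase filtering is essential because every spatial
metric depends on unbiased peak *times*. White broadband noise crosses any
fixed amplitude threshold occasionally at kHz rates, so for noisy inputs a
low-pass at ~100 Hz (well above the R-complex bandwidth) is the recommended
first resort. When a filter is configured, the property maps are computed
on the same filtered trace the detector saw.

Peak times are refined to sub-sample precision by a parabolic fit through
the three samples surrounding each detected peak (and likewise for the
LAT's derivative extremum). This matters because time lags across a 2 mm
array at physiological conduction speeds span only a few milliseconds: at
1 kHz sampling, integer-sample times would quantize the lag surface at the
same order as the signal. `refine=False` restores plain sample-index times.

## Electrode curation

The dataset beat count is the **mode** of per-electrode beat counts;
electrodes deviating from the mode are excluded automatically (faulty
electrodes, partial coverage). When several counts tie for modal frequency
the larger count wins, preserving the most active electrodes. Manual
silencing removes named electrodes outright, takes precedence over
inclusion, recomputes the mode over the remainder, and is exactly
reversible. The result is a rectangular beats × electrodes problem: every
included electrode has exactly the modal number of beats.

## Property maps

- **Time lag**: per-beat R-peak time minus the per-beat minimum. The minimum
  is exactly 0 by construction.
- **LAT**: the maximal negative derivative after the R peak, searched within
  min(150 ms, half the minimum beat interval) — a window that excludes both
  the T wave (whose downslope is an order of magnitude gentler than the
  R downstroke) and the next beat. Normalized per beat like the time lag.
  Beats whose window is truncated by the recording end, or that lack any
  negative post-peak derivative, are flagged missing (NaN).
- **dV/dt_max**: maximum backward finite difference within 50 ms before the
  peak, at the native sample rate, no smoothing.
- **Amplitude**: max minus min of the raw trace within ±25 ms of the R peak
  (equivalently, positive plus negative excursion). Invariant to constant
  voltage offsets.
- **Beat intervals**: successive differences of per-electrode event times
  (raw LAT times, falling back to peak times where LAT is missing). The
  dataset-level series is the pacemaker-referenced one (per-beat earliest
  event), which also defines the beat rate.
- **CV**: distance from the per-beat reference electrode divided by the LAT
  difference. The reference is the zero-LAT electrode; when several
  electrodes tie at zero, the one nearest their centroid (channel order
  breaks exact ties) is chosen — a deterministic, symmetric rule. The
  reference itself and any zero-ΔLAT electrode are flagged undefined rather
  than infinite. Values are µm/ms (numerically equal to mm/s; divide by
  1000 for m/s).

## Pacemaker origin

The normalized lag map is interpolated piecewise-linearly on the electrode
grid (no smoothing, so contour vertices are reproducible) and contour
polylines are extracted at the deciles of the per-beat lag distribution.
The level whose polyline carries the most vertices is taken as the
wavefront sample — the richest isochrone. A circle is then fit by bounded
nonlinear least squares, minimizing Σ(‖p_i − (h,k)‖ − r)², with the center
constrained to the array bounding box and the radius to (0, array
diagonal]. Both center and radius are bounded: a wavefront that is almost
straight (planar wave) would otherwise send the center to infinity; instead
it is clamped to the boundary and flagged `at_bounds`. Initialization is
deterministic (wavefront centroid pulled halfway toward the minimum-lag
electrode; r₀ = mean distance to it), so repeated runs agree exactly.

On noiseless circular data the fit is exact to machine precision and agrees
with the closed-form circumcircle on any non-collinear 3-point input; both
facts are enforced by tests.

## Field potential duration

T-peak search window: **120–500 ms after the R peak**, truncated 50 ms
before the next beat; the most prominent deflection from the window median,
of either sign, above `min_t_amplitude` (default 20 µV) is the T peak.
Negative T waves are mirrored. The endpoint then maximizes the trapezoid
area A(x_i) = ½(y_m − y_i)(2x_r − x_i − x_m) with the proximal fixed point
at the maximum-downslope sample after the T peak and the distal point at a
configurable offset in [50, 200] ms past the T peak (default **150 ms**,
mid-range). The area is affine in voltage, so the endpoint is invariant
under scaling and offset; the candidate set is the finite set of samples
between the fixed points, so the implementation *is* an exhaustive scan and
is checked against an independent re-implementation in tests.

The T limb is smoothed before landmark extraction with a Savitzky–Golay
filter (quadratic, default window **41 ms**). The window is sized to the
T-wave timescale (tens of ms): on clean data it leaves the endpoint
unchanged (verified in tests), while on noisy data it suppresses the
noise-induced late bias of the area argmax. Residual bias at S/N ≈ 10 is a
few ms, within the ±5 ms recovery contract.

## Translocations and quiescent periods

The per-beat pacemaker location is the centroid of the electrodes attaining
the per-beat minimum lag. A translocation is a **strictly** greater-than-
500 µm displacement between *consecutive-beat* locations (not against a
period anchor, so sub-threshold drift never triggers; an anchor-based
variant exists behind a flag for exploration). Runs between translocations
are quiescent periods, reported in beats and seconds (pacemaker event-time
difference between the run's first and last beat). Censoring: the first
closed period is dropped (its true start precedes the recording) and the
trailing open period never counts (its end is unobserved). The scan is
verified against an independent brute-force state machine on 1,000 random
paths.

## Property–distance regression

Per beat, each electrode contributes (distance from the fitted origin,
property value). Time lag, LAT and dV/dt_max are fit by OLS; CV by the
saturating exponential y = c(1 − e^(−x/λ)) + y₀ — CV versus distance
flattens away from the origin, and the model choice is isolated behind one
interface (`kind="linear"` is selectable). R² = 1 − SS_res/SS_tot per beat;
beats with fewer than 4 retained points or a non-converging fit are
skipped. The sigma-based outlier pass (default 3 SD) runs once per property
across all beats, with mean and SD from the full sample — a deliberate
single pass, not an iterative trim.

## Heavy-tail fitting and comparison

Continuous-support distributions throughout: quiescent durations in seconds
are continuous, and beat counts are treated as a continuous approximation.
The lower cutoff x_min minimizes the KS distance of the fitted power-law
tail over all observed candidate cutoffs (candidates leaving < 10 tail
points are skipped); rival families are fit above the **same** cutoff so
log-likelihoods are comparable. Power-law and exponential MLEs are closed
form; log-normal, stretched-exponential (≡ Weibull; one implementation, two
accepted names) and doubly truncated power-law MLEs are numerical
(Nelder–Mead), with the truncated power law's normalizing constant
∫_{x_min}^∞ x^(−α) e^(−λx) dx evaluated by adaptive quadrature with
exponential rescaling for stability.

Comparisons use the normalized log-likelihood ratio R/(σ√n) (σ = SD of the
per-point log-likelihood differences) with a two-sided normal p-value;
positive favors the first family, and the statistic is antisymmetric by
construction. Exponents are reported as positive α in P(x) ∝ x^(−α).
Sturges' rule (⌈1 + log₂ n⌉) provides the default histogram bin count for
qualitative export.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions every estimator is tested
under: a template placed at each electrode with delay
‖coords(e) − origin(b)‖ / speed (radial propagation at constant speed), a
scripted per-beat origin path, constant beat rate, additive white Gaussian
noise (S/N defined as R-peak magnitude over noise σ), and faulty electrodes
emitting noise only. Defaults: R lobes +120/−300 µV (σ 3 ms), T wave
150 µV (σ 40 ms) at 250 ms latency, 40 bpm, 1 kHz sampling, conduction
speeds 100–500 µm/ms — magnitudes typical of healthy hESC-CM monolayer
recordings. Template landmarks (true peak, upstroke, LAT offset, T endpoint)
are computed once on a 0.01 ms reference grid, so ground truth is
independent of the recording's sampling and noise.

What the generator does **not** emulate: waveform heterogeneity across the
culture, beat-rate variability, drifting baselines, line interference,
correlated noise, re-entrant or planar-with-curvature propagation, and
electrode-specific gain differences. Passing the recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every pathology of real recordings — the parameter controls
(thresholds, filters, silencing) exist precisely because real data departs
from this model.

Simulation sizes in the test-suite and acceptance harness (8–10 beats,
10 simulations, 5,000-point tail samples, 100 comparison replicates) were
chosen as the smallest sizes at which the recovery contracts are
statistically meaningful.

## Numerical choices and degenerate inputs

- Sampling step uniformity is enforced to 1 part in 10⁴; the time column
  may be fractional ms (rates above 1 kHz).
- Zero peaks on an electrode is valid (the mode pass excludes it); an
  all-zero modal count raises an analysis error.
- A flat lag surface (all lags equal) has no wavefront: origin estimation
  returns a missing estimate for that beat and downstream statistics skip it.
- Circle-fit tolerances are set to machine precision (xtol/ftol/gtol
  1e-15); collinear points are clamped by the bounds and reported with
  their residual rather than rejected.
- Workbook and ASCII round trips preserve 6 significant figures (ASCII
  written at 10).

## Known limitations

- The channel order of the 120-electrode layout beyond "channel 1 = F7" is
  a package convention recorded in the layout table, not a vendor-verified
  map; recordings exported with a different channel order need an edited
  layout CSV.
- CV is the two-point distance/ΔLAT estimator; no vector-field or
  polynomial-surface methods.
- The saturating-exponential CV–distance model is a pragmatic default, not
  a mechanistic claim.
- Heavy-tail families assume continuous support; heavily tied beat-count
  samples (many repeated small integers) weaken the KS-based cutoff choice.
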