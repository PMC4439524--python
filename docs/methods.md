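# Methods

This note documents the models implemented in `itdfreq`, the defaults and
units that matter, the synthetic data the package is validated on, and
the numerical choices made where the design was genuinely open.

## Circular statistics of beat responses (`circstats`)

Spikes recorded under a binaural beat are reduced to phases of the beat
period (cycles in [0, 1)). The vector strength VS is the modulus and the
best phase BP the angle (in cycles, wrapped to [−0.5, 0.5)) of the mean
resultant of the spike phases; BP and VS are computed from raw phases —
the period histogram (default 64 bins) is display-only. Sync-rate
SR = rate × VS is the downstream regression weight. IPD sensitivity at
each tone frequency is screened with a Rayleigh test at p < 0.001, using
the large-sample approximation with Zar's finite-n correction,
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·VS. Its empirical
type-I rate is verified by simulation in the test suite.

Conventions chosen once and used everywhere: positive BP means
contralateral-leading; recordings made with the opposite beat direction
(`beat_sign = −1`) are sign-flipped before pooling; repetitions are
pooled by concatenating phases. Discarding the first beat cycle (onset
suppression) is exposed as a flag, default off — no quantitative
criterion for "strong onset" exists, so the decision is left to the user.

## Circular-linear CP/CD regression (`cpcd`)

BP(f) ≈ CP + CD·f is fit by minimizing Σ_f SR(f)·d(BP(f), CP + CD·f)
with d(x,y) = ½[1 − cos 2π(x−y)]. Because the objective is 1-periodic in
CP and multimodal in CD, the fit is exhaustive-then-local:

- grid scan, CP ∈ [−0.5, 0.5] cycles step 0.02, CD ∈ [−2, 2] ms step
  0.02 (51 × 201 nodes); ties broken toward smaller |CD| then |CP|;
- damped Newton descent from the best node, using the closed-form 2×2
  Hessian with Levenberg-style damping, internally scaling CD in ms and
  f in kHz so both parameters are O(1); terminates on gradient norm
  < 1e-10 or objective improvement < 1e-14, and never returns a point
  worse than the grid optimum. The refined CD may step slightly outside
  [−2, 2] ms and is reported as found (no clamp).

The fit is equivariant under phase offsets (CP shifts, CD fixed) and
pure delays (CD shifts, CP fixed); both are verified to 1e-6 in tests
and to 1e-3 at study scale. Against a brute-force 1e-3 × 1e-3 ms grid
the two-stage fit agrees to within two fine-grid cells.

Fit quality uses the unweighted residual (mean circular distance,
0 = perfect, 1 = antiphase). Linearity is tested against surrogates: a
surrogate curve draws the same number of BPs uniformly on [−0.5, 0.5),
is fit the same way, and its residual recorded; p = (1 + #{r_s ≤ r_obs})
/ (N + 1), resolution 1/(N+1), default N = 9999. The null residual
distribution depends essentially only on the number of points, so
surrogates use a fixed 300–3000 Hz span and a per-n bank of surrogate
residuals can be shared across cells — this is what makes the 2000-cell
calibration run affordable (one 9999-surrogate bank instead of 2000).
Calibration is confirmed empirically: the null rejection rate at p<0.05
is 0.052 (suite) / 0.054 (acceptance script, seed 1).

Best ITD at each frequency maps BP to the delay candidate (BP + k)/f of
minimal |ITD| (a cell-level CD hint can override the branch choice); the
best-ITD range is max − min over frequencies whose SR reaches 80% of the
maximum.

## Population statistics (`population`)

CP and CD come from a single regression, so their estimates covary
within a cell; a negative across-cell correlation must be shown not to
be that artifact. Per-cell estimate covariance is obtained by a
frequency bootstrap: resample n frequency points with replacement, refit,
recenter each bootstrap CP to within half a cycle of the point estimate,
and take the 2×2 covariance (resamples with fewer than two distinct
frequencies are redrawn). The independence test then builds surrogate
populations: CP and CD drawn independently with replacement from the
observed marginals, each surrogate point perturbed by Gaussian noise
with the covariance of a bootstrap model drawn uniformly with
replacement (the parametric family and the model-to-point assignment are
package choices; the noise is small relative to the marginal spread, so
the choice is not load-bearing). p is the fraction of surrogate Spearman
ρ at or below the observed ρ; default 10⁴ iterations (p resolution
1e-4), configurable upward. Self-calibration (uniform p under the null)
is verified over 1000 replicated experiments of 50 cells each; the
Kolmogorov–Smirnov statistic against U(0,1) stays below 0.05 — 1000
replicates are used because the KS statistic of a perfectly uniform
200-sample set already sits near 0.06 on average, so a 200-replicate run
cannot resolve calibration at that level.

Center frequencies are sampled from a Gaussian KDE of measured CFs on
log-frequency (Silverman bandwidth), truncated to [300, 3000] Hz by
rejection. Azimuth priors: uniform over the contralateral hemifield
(default), front quadrant only, side-biased (1 + cos(θ − 90°))⁴,
center-biased — implemented as (1 + cos θ)⁴ restricted to the
contralateral hemifield, an interpretation of the owl-literature prior
whose exact form is not published with a formula — and the empirical
best-azimuth distribution.

## Spherical-head acoustics (`acoustics`)

The head is a rigid sphere, diameter 7.3 cm (cat), ears antipodal at
±90° on the horizontal great circle (placement is a package choice).
The pressure at a surface point for a point source is the partial-wave
series Σ (2m+1) P_m(cos θ) h_m(kr)/h_m′(ka) (spherical Hankel functions,
e^{−iωt} convention), truncated adaptively: summation stops when three
consecutive orders fall below 1e-6 of the partial sum (reached far below
the max order 120 for all ka ≤ 2.7 used here); non-convergence raises.
The 1/r spreading and travel phase live in h_m(kr), so direct and
reflected waves can be summed coherently. Checks: ITD_p at 100 Hz and
90° equals the diffraction limit 3a/c within 0.2%; IPD is exactly
antisymmetric in azimuth and zero on the midline; the ipsilateral ear
gain exceeds the contralateral at 3 kHz (head shadow).

The ground reflection uses an image source below the ground plane
(default: head and source 0.2 m high, 1.5 m apart → extra delay 153 µs).
The reflected ray passes through the sphere solution at the image
elevation and distance (a free-field mode exists for comb-filter tests),
scaled by a plane-wave reflection coefficient from the one-parameter
Delany–Bazley impedance, ζ = 1 + 0.0571 X^(−0.754) + 0.087i X^(−0.732),
X = ρ₀f/σ, at the geometric incidence angle. Flow resistivity σ is in
SI Pa·s·m⁻² (grass ≈ 1e5, sand ≈ 1e6; default 5e5); σ → ∞ recovers the
rigid ground, R → 1. Spherical-wave corrections to R are not included.

IPD spectra are computed on a dense grid (default 2 Hz, 100–4000 Hz —
the top extends to 4 kHz so that the band analysis below fits inside the
grid for CFs up to 3 kHz) as unwrapped phase differences (conventional
half-cycle jump rule), positive = contralateral lag. Delay metrics per
frequency: ITD_g is the slope of a circular-linear regression of IPD on
a window of width f/4 centered at f (initialized from unwrapped
least squares and refined by Newton descent on the circular objective —
the full grid scan is redundant for these smooth windows); ITD_p is
unwrapped IPD over f; IDI = f(ITD_p − ITD_g) by definition, which makes
the identity exact, while the regression intercept is retained and
cross-checked against IDI mod 1 (agreement ~1e-3 cycles). Band-wise
acoustical CP/CD uses windows of bandwidth BW(F) = F/Q(F), Q(F) = 1.04 +
3.8e-4·F (the cell-derived quality factor), fit with the same grid +
descent regression as cells, uniform weights.

Best azimuth of a cell minimizes Σ_f d(BP(f), IPD(f; θ)) over the
available spectra, taking the nearest grid frequency per cell frequency;
ties break toward the smaller azimuth.

With these defaults the bare sphere gives |acoustical CP| < 0.004 below
500 Hz, while adding the ground drives |CP| beyond 0.1 cycles at some
(azimuth, CF) — the core acoustical contrast — and 200 samples of
(azimuth from the contralateral-uniform prior, CF from the KDE) give
Spearman ρ(CP, CD) ≈ −0.17. A note on scale: the reflection arrives from
nearly the same azimuth as the direct ray, so it perturbs the two ears
almost equally; the IPD distortion is second-order and band-local
(strongest toward the first interference null near 1/(2·153 µs) ≈
3.3 kHz), which is why the contrast shows in band-wise CP rather than in
the residual of one global linear fit.

## Pseudobinaural coincidence analysis (`coincidence`)

Coincidences are counted on continuous spike times: pair (t_a, t_b)
coincides at internal delay d when |t_a − (t_b + d)| ≤ bin/2 (default
bin 50 µs) — window coincidence equals histogram counting in expectation
and is shift-invariant. Repetitions pair same-index only (a shuffled
mode is deliberately absent by default). The delay grid spans ±2 ms in
bin-width steps. The sorted-sweep implementation is verified against the
O(n²) pairwise oracle exactly.

Best phase of a coincidence curve is the count-weighted circular mean of
delay × tone frequency, after trimming the delay window to a whole
number of stimulus periods (a partial period biases the mean); an argmax
mode exists. Flat curves (resultant below 2% of the total count) are
undefined. Before the pair fit, tone frequencies whose curve shows no
significant modulation are discarded by a Rayleigh-style screen on the
count resultant (α = 0.001) — the direct analog of the Rayleigh screen
on cell data points; without it, shot noise in unmodulated curves at
weakly locked frequencies corrupts the weighted fit. The retained
(f, BP) points are fit with the cell regression, weighted by total
coincidence count. Sign convention: positive internal delay shifts
fiber B later, so delaying B by τ fits CD = −τ.

Population analysis filters pairs to |ΔCF| ≤ 0.1 octave and CF <
3.3 kHz and, when symmetrized, represents each pair as (CP, CD) and
(−CP, −CD) interleaved — modeling random assignment of the mistuned
fiber to either ear — which makes the symmetrized means exactly zero by
construction.

## Synthetic data (`synthetic`)

**Model cells.** BP(f) = wrap(CP + CD·f) is the generative rule. Spikes
are a von Mises-modulated Poisson process locked to the beat period: the
spike count per repetition is Poisson(rate × duration), each spike phase
von Mises with concentration solved numerically so the resultant length
equals the requested VS (capped at κ = 500), assigned to a uniformly
chosen beat cycle. Defaults: 9 tones log-spaced 100–3000 Hz, 5 s beats
(1 Hz beat), 10 repetitions, a log-frequency Gaussian rate profile
(peak 60 sp/s, 1.5-octave SD) and a logistic phase-locking rolloff
above ~1.8 kHz. The tone span matters: the CP estimate extrapolates to
f = 0, and its standard error scales with σ·√((1 + (f̄/σ_f)²)/n), so a
narrow span (e.g. 400–1200 Hz) makes 0.05-cycle recovery impossible at
0.05-cycle noise for any estimator; the default spans the full
phase-locked beat-testing range. A curve-level generator (wrapped-normal
BP noise, unit weights) supports estimator calibration without spikes.

**Model fibers.** The cochlear phase function is a traveling wave with
accelerating lag, φ(f; cf) = −N·(f/cf)^γ cycles, N = 3 cycles at CF,
γ = 2. This gives the two physiological ingredients the mechanism needs:
at fixed f the lower-CF (apical) fiber lags, and the lag accelerates
with frequency, so a mistuned pair's phase difference is curved in f —
which is what produces nonzero CP with the opposite sign to CD (a
4th-order gammatone's phase alone cannot do this: its accumulated phase
at CF always dominates its group-delay difference for ERB-scaled
bandwidths, which would put per-pair CP and CD in the same quadrant).
The exponent and cycle count are modeling choices, not fits to data;
they place the example mistuned pair (CFs 1092/1133 Hz) at CP ≈ +0.22
cycles, CD ≈ −0.4 ms — the observed order of magnitude. Excitation
breadth uses a rounded-exponential weight (1 + pg)e^{−pg},
g = |f − cf|/cf, with p = 6 (broad, suprathreshold drive; sharper
threshold-like p starves off-CF tones of coincidences), peak rate
150 sp/s, spont 10 sp/s, and nerve-like phase locking rolling off above
~2.8 kHz. Study conditions for pair analyses: 9 tones log-spaced ±0.75
octave around the pair's geometric-mean CF (clipped at 3.4 kHz), 5 s ×
10 repetitions — comparable to the 400–2200 Hz span used for a ~1.1 kHz
pair in real recordings; matched-control precision (|CP| < 0.02) again
requires this breadth for the intercept to be well conditioned.

**Model IPD sets.** Affine (CP + CD·f, exact), pure delay, and the
sphere/sphere+ground models over requested azimuths.

What the generators do *not* emulate: adaptation and onset dynamics,
rate-level nonlinearities, refractoriness, across-fiber correlation,
efferent effects, and any fitted correspondence to a particular animal's
cochlear map. Passing tests therefore validate the *analysis chain* —
estimator correctness, calibration, and the qualitative population
structure implied by the stated generative assumptions — not the
biological parameter values themselves.

## Problem sizes and determinism

All random generation flows through `numpy.random.default_rng` with
explicit seeds; every generator is bit-reproducible. The packaged
study sizes are: 500 cells for recovery, 2000 null cells × 9999 shared
surrogates for linearity calibration, 1000 replicates × 10⁴ iterations
(50 cells each) for independence-test calibration, 36 azimuths × 1951
grid frequencies for the acoustics bank with 200 (azimuth, CF) samples,
and 73 mistuned pairs plus 10 matched controls (CFs log-spaced
400–1600 Hz, the strongly phase-locked range where the control bound is
well conditioned) for the coincidence population. The full suite runs in
a few minutes on one CPU; `scripts/acceptance.py` in about one minute.

## Known limitations

- The sphere model omits pinna, torso and elevation cues; the ground
  model uses a plane-wave reflection coefficient without spherical-wave
  correction.
- The linearity surrogate bank assumes the null residual distribution
  depends only on the number of frequency points; the dependence on the
  exact frequency set is weak but nonzero.
- The independence test adds bootstrap noise to marginals that already
  contain estimation noise (as in the original procedure); with
  realistic noise magnitudes the miscalibration is far below the KS
  sensitivity used.
- Spearman ρ treats CP as a linear variable; CP is circular, but its
  observed range (well within ±0.5) makes rank correlation meaningful.
- The cochlear phase surrogate's slope parameters are free; only the
  qualitative structure (apical lag, accelerating phase) is asserted.
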