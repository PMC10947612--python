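# Methods

This note documents the models, estimators, numerical choices and known
limitations of `swdisp`, in the spirit of a model-documentation page for a
scientific library.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and conventions

The universal input is a real particle-velocity field v(x, t) on uniform
lateral (step dx) and temporal (step dt) grids — the output of ultrafast
ultrasound motion tracking of an ARF-induced shear wave, after any axial
averaging.  Wavenumbers are cyclic (units 1/m) throughout; the phase
velocity conversion is c = f/ξ, identical to c = 2πf/k for angular k.

A rightward (increasing x) wave is cos(2π(ft − ξx)) with f, ξ > 0.  Under
the forward DFT kernels e^(−i2πft), e^(−i2πkx) its energy occupies the two
f-k quadrants with opposite signs of f and k.  The slant spectral
amplitude is evaluated as the forward spatial transform at −k, so that
rightward components appear at positive wavenumber and c = f/ξ is
positive; a dedicated unit test pins the convention.

## Generalized S-transform slant f-k estimator (GST-SFK)

1. **Generalized S-transform.**  For each lateral position,
   S(τ, f) = Σ_t v(t) · w_f(τ − t) · e^(−i2πft) · dt with the Gaussian
   window w_f(s) = (f/√(2πβ)) exp(−f²s²/2β).  The window has unit
   continuous area at every analysis frequency, and β (default 1, the
   standard S-transform) trades time against frequency resolution: the
   temporal standard deviation is √β/f.  The implementation is a dense
   windowed matrix product per frequency and is tested to ≤ 1e−8 against
   the literal double-sum discretization and to ≤ 1e−3 against numerical
   quadrature of the continuous transform for a pure tone.
2. **Time-distance maps.**  At one analysis frequency, the τ-slices of all
   positions form a complex map V(x, τ).
3. **Slant-phase functions.**  V is read along τ = x/u for steering group
   velocities u, with linear interpolation between τ nodes and zero
   outside the record; x is the propagation distance from the wave origin
   (the first lateral sample for a left-edge push).  Reading along the
   wave trajectory acts as a matched filter: record samples that contain
   only noise are never summed.  It also self-corrects spectral leakage:
   content at a neighbouring frequency f′ that leaks through the Gaussian
   window enters P(x) with effective wavenumber ξ(f′) − (f′ − f)/u, which
   returns ≈ ξ(f) when u matches the propagation speed — the mechanism by
   which the estimator keeps its accuracy where the source spectrum rolls
   off.
4. **Slant amplitude and collapse.**  |Λ(u, f, k)| is the direct (not
   FFT-bin-restricted) spatial Fourier magnitude of P on an arbitrary
   wavenumber grid, and K(f, k) = max_u |Λ|.  The default steering set is
   64 velocities, linearly spaced on [0.5, 10] m/s (uniform-slowness
   spacing is available), covering physiological shear speeds with margin.
5. **Peak extraction.**  Each frequency is treated independently: the
   global k-maximum (ties toward smaller k, i.e. the lower-velocity
   branch), refined by a three-point parabola on log-amplitude clamped to
   half a bin, gives c(f) = f/k.  No smoothing or extrapolation across
   frequency is applied.  Frequencies whose peak is below `min_quality`
   times the largest per-frequency peak are reported missing rather than
   guessed; the gate defaults to 0.1 for exploratory use, and the
   validation pipelines run with `min_quality=0` because on controlled
   synthetic inputs every frequency row of the band is genuinely
   informative (noiseless) or deliberately evaluated (CV studies, where
   scatter at weak frequencies is precisely the quantity being measured).

Default analysis grids: frequencies every 25 Hz from 100 Hz to 0.9 ×
Nyquist; 700 wavenumbers linearly spanning 2–1200 1/m (c ≥ 0.9 m/s at the
highest kidney-grid frequency).  The whole pipeline is linear in the
field, and a small-instance brute-force triple loop over (u, f, k)
reproduces it to ≤ 1e−9.

## 2D-FT baseline

The magnitude of the 2-D DFT (physical scaling dx·dt, Parseval-tested) on
the full signed f-k plane.  Peak picking uses the rightward quadrant.
Candidates are strict local maxima over k (plateau fallback: first
argmax); the mode is seeded at the frequency row with the greatest peak
and followed outward, accepting at each row the candidate whose refined
velocity is closest to the previously accepted one — this keeps the
extractor on one mode where a bare per-row argmax would jump between
crossing modes (tested by construction).

Padding: the wavenumber axis defaults to 4× zero padding because sub-bin
peak position there maps directly to velocity accuracy; the frequency axis
defaults to native resolution.  Evaluating between temporal bins
(pad_t > 1) only sinc-interpolates neighbouring-bin content with different
wavenumbers and can bias high-frequency velocities by several percent on
band-limited records, while curves are resampled onto the analysis
frequency grid downstream anyway.  Windowing (`tukey`, α = 0.1) is
available but off by default.

## Rheological models and fitting

Zener (standard linear solid): springs E1, E2 and dashpot η, complex
Young's modulus E* = E1(1 + iωτ_e)/(1 + iωτ_σ) with τ_σ = η/E2 ≤
τ_e = η/E1 + η/E2.  Phase velocity (ω = 2πf, A = ηωE2², B = E1E2² +
η²ω²(E1+E2), density ρ):

c(ω) = √( 2(A² + B²) / (3ρ (E2² + η²ω²)(B + √(A² + B²))) )

which equals the complex-modulus route c = √(2|G*|²/(ρ(Re G* + |G*|))),
G* = E*/3 — the two routes are cross-checked to 1e−9 in the tests.  At
f = 0 it reduces to √(E1/3ρ) exactly; as E2 → ∞ it converges to the
Kelvin-Voigt form (E1 parallel to η), tested as a monotone limit over
E2 = 10⁶ … 10⁹ Pa.  The factor 3 converts Young's to shear modulus for an
incompressible solid.  ρ defaults to 1000 kg/m³ (soft-tissue convention)
and is always explicit in reports.

Fitting minimizes Σ_f (c_model − ĉ)² over non-missing points in a closed
band (missing points skipped, never interpolated).  The objective is
non-convex and E2 is weakly identified on narrow bands, so optimization
runs in log-parameter space with bounds E1 ∈ [0.1, 10³] kPa,
E2 ∈ [0.1, 10⁶] kPa, η ∈ [0.01, 100] Pa·s, from 16 seeded Latin-hypercube
starts (best local optimum kept; the multistart result is never worse
than any single start, tested).  The minimized sum is the norm of
residuals (NoR, m²/s²); fits with NoR > 1 m²/s² carry
`reliable_flag=False`.

**Convergence analysis** fits on [f_lo, end] for end = 300, 325, … Hz and
reports the smallest window end from which every parameter stays within
`plateau_tol` (default 5%) of its final-window value with reliable NoR.
A deliberate +1 m/s step in the curve drives NoR above 1 m²/s² once two or
more contaminated points enter the window; the single boundary window that
contains exactly one contaminated point optimizes to NoR slightly below 1
(the least-squares optimum is bounded by the 1.0 m²/s² residual of the
uncontaminated-truth parameters, and fit leverage reduces it further) —
an intrinsic property of a 3-parameter smooth model absorbing one outlier,
documented in the tests.

## Ensemble statistics

Per-frequency mean and sample SD (n−1 denominator; the package's choice,
as either convention is defensible) over non-missing acquisitions;
CV = SD/mean·100%; frequencies with fewer than two valid values are
missing.  The usable bandwidth is the last frequency of the unbroken
CV < threshold run from the start frequency (default threshold 30%); a
pointwise, non-contiguous variant is available behind a flag.  Box-plot
summaries use quartiles with 1.5-IQR whiskers and the standard outlier
rule.

## Synthetic data generator

The generator emulates the two acquisition settings the package targets —
a phantom-like linear-array scan (0–30 mm aperture, dx = 0.154 mm,
4.167 kHz frame rate, 128 frames) and a kidney-like curved-array scan
(0–21.3 mm, dx = 0.2396 mm, 2.412 kHz, 96 frames) — by frequency-domain
synthesis: v(x, t) = Re Σ_f A(f) e^(i2πft) e^(−i2πk*(f)d), where d is the
distance from the push and k*(f) = f/c(f) − iα(f)/2π derives from the same
complex shear modulus as the phase velocity, keeping the medium causally
self-consistent (α = 0 exactly for lossless media).  The source magnitude
A(f) is Gaussian, centred at 400 Hz with 1600 Hz FWHM — an impulsive
ARF-push-like pulse that retains real spectral content (≈ 12% of peak at
1.8 kHz) across the full analysis band of both grids; a narrowband source
would make high-frequency rows leakage-dominated and unmeasurable by any
estimator.  There is no phase dispersion at the push location.  Fields are
peak-normalized to 10 mm/s; white Gaussian noise is added at the requested
SNR measured against pre-noise signal power (realized within 0.5 dB,
tested).  Counter-propagating components enter as a mirrored wave from the
right edge with amplitude fraction 1 − direction_mix.

The reference medium `ZENER_REFERENCE` (E1 = 12 kPa, E2 = 30 kPa,
η = 0.6 Pa·s, ρ = 1000 kg/m³) is a tissue-mimicking-phantom-like solid:
dispersive (c rising from about 2.0 to 2.9 m/s over 150–1800 Hz) yet
transmissive enough (decay length above 2 mm at 1.8 kHz) that the wave is
measurable over the full aperture, as a usable elastography phantom must
be.  Considerably more viscous parameter sets (η of a few Pa·s at these
stiffnesses) attenuate the wave within ~1 mm above 1 kHz, making
high-frequency dispersion physically unmeasurable on these apertures
regardless of estimator.

Cohorts derive child seeds deterministically as SeedSequence((base_seed,
index)) and jitter each medium parameter independently and log-normally
with relative SD `jitter`.  Note that a relative SD j on E1 propagates to
≈ j/2 on the static velocity √(E1/3ρ).

**What the generator does not emulate:** speckle-correlated tracking
noise (noise is white in x and t), probe geometry and beamforming,
near-field diffraction of the push, cylindrical wave spreading, tissue
motion between acquisitions, and reflections from boundaries.  Passing
tests therefore demonstrate correctness of the estimators on plane-ish
dispersive attenuating wave packets under additive noise — not
performance on raw clinical data.

## Validation problem sizes

Oracle comparisons run on 64-sample signals and 16×64 fields with coarse
(u, f, k) grids, where literal double/triple loops are exact and fast.
Full-pipeline studies use one phantom-grid field (195×128) per medium for
recovery and a 15-acquisition kidney-grid cohort (89×96 each) at 10 dB SNR
for the robustness comparison — sizes chosen to match the emulated
acquisition geometries exactly while keeping the complete validation suite
in the minutes range on one CPU.

## Known limitations

- Single dominant mode only; no multi-mode extraction or 2-D local
  phase-velocity imaging.
- The slant trajectories are anchored at the record origin, so the
  *amplitudes* of K(f, k) are sensitive at the few-percent level to a
  bulk time shift of the record even though extracted velocities are
  stable well below 1% (tested); records should start near the push
  instant.
- The quality gate is a simple relative-amplitude floor; it does not
  attempt statistical detection of signal presence.
- Group-velocity estimation, inferential statistics across subject
  groups, and upstream acquisition processing (beamforming, IQ
  autocorrelation) are out of scope.
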