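# Methods

This note records the models, parameter choices and numerical decisions
behind `mpus`, and what the synthetic-data validation does and does not
establish about real scanner data.

## H-scan reconstruction

The Gaussian-weighted Hermite kernel of order n is
GHₙ(t) = Hₙ(t/σ)·exp(−t²/(2σ²)) with Hₙ the physicists' Hermite
polynomial, sampled over ±6σ.  Its energy Eₙ = ∫GHₙ² dt (for σ = 1,
Eₙ = 2ⁿ n! √π, which the implementation matches to better than 0.1%) is
used to normalize the matched-filter outputs, so the red (GH₂) and blue
(GH₈) channels are comparable and the B/(R+B) intensity is invariant to a
global RF gain.

*Kernel time scale.* A single shared σ is used for both orders, chosen so
that the geometric mean of the GH₂ and GH₈ spectral peaks equals the
transducer center frequency (15 MHz default).  With the peak ratio
√(17/5) ≈ 1.84 this places the peaks at ≈ 10.0 and ≈ 22.7 MHz; the GH₈
peak therefore sits above the 18 MHz edge of the analysis band, but both
kernels' −6 dB passbands overlap the band, which is the property the
channel contrast relies on.  The σ a given scanner effectively uses is not
derivable from image data alone, so reported H-scan intensities are
device-relative.

*Processing chain.* Per RF line: convolution with the kernel taps (mode
"same"), division by √Eₙ (equivalent to normalizing the taps, since
convolution is linear), zero-phase 4th-order Butterworth bandpass
(forward–backward, preserving co-registration), Hilbert envelope.  The
B-scan branch is the envelope of the original unfiltered RF.  Samples
within one kernel half-length of the frame top/bottom are flagged invalid,
as are pixels whose channel energy R+B is more than 40 dB below the frame
maximum — such pixels carry no usable spectral information and their
B/(R+B) ratio is numerical noise.  ROI metrics average the B-scan envelope
over the whole ROI and the intensity map over its defined pixels.

*Attenuation correction* multiplies each sample by
10^(coeff · f_c[MHz] · 2z[cm] / 20) (two-way path), a single global bulk
gain at the center frequency rather than a per-frequency correction; the
default coefficient is 0.3 dB/cm/MHz.  A metadata flag prevents double
application.

## Shear wave speed and attenuation

The displacement estimator is the classical lag-1 slow-time
autocorrelator on complex baseband data, averaged over a sliding axial
window (default 8 samples), cumulatively summed to displacement.  It is
unbiased for inter-frame shifts below λ/8 at the demodulation frequency;
phases approaching ±π set an aliasing flag.

The f–k analysis mean-removes and tapers u(x, t) at one depth row with a
separable Tukey(0.25) window, takes the 2-D DFT, and reads the speed from
the sub-bin (3-point parabolic, on log power) wavenumber peak at the
temporal frequency of the global spectral maximum.  Attenuation is the
half-width at half-maximum of a least-squares Lorentzian fit to the
squared-magnitude wavenumber profile — exact for an exponentially damped
sinusoid.  The taper/aperture broadening is measured once per grid by
pushing an undamped wave (worst-case half-bin wavenumber offset) through
the identical transform-and-fit path and is removed in quadrature; on the
default grids this effective broadening is below one wavenumber bin, so
the subtraction is a small correction and attenuations below one bin
(2π/aperture) should be read as "unresolved", not as zero.  Multi-row
analysis aggregates per-row estimates with the median over five central
depth rows, for robustness to occasional poor rows.

*Validation conditions.* Parameter recovery is verified on a
3 × 3 grid — speeds {1.0, 1.5, 2.0} m/s × attenuations {50, 100, 150}
Np/m — at 25 dB IQ SNR, 20 seeds each, with median speed bias ≤ 5% and
attenuation bias ≤ 10% (measured ≤ 0.7% and ≤ 7.7% respectively).  The
synthetic wave is a single-frequency (200 Hz) damped plane wave, which
makes the truth exact and the estimator's bias measurable; real push-pulse
shear waves are broadband and dispersive, so these numbers bound estimator
error, not physiological variability.  Grid sizes: lateral aperture
6/α (capped at 40–120 mm) at 0.3 mm pitch, PRF 2 kHz, record covering the
transit plus 12 wave periods — chosen so the wave decays by e⁻⁶ across the
aperture and the f–k ridge is well resolved.

## CEUS perfusion

The bolus model is the lognormal time-intensity curve
I(t) = A·exp(−(ln τ − μ)²/(2σ²))/τ, τ = t − t₀.  Its peak
(τ_pk = e^(μ−σ²), value A·e^(σ²/2−μ)) and maximum wash-in slope (at the
rising inflection, 1 + y = −q with q = (1+√(1+4/σ²))/2) have closed forms,
so the generator can hit any requested (PE, WIR) pair exactly and the
fitting oracles are analytic.

`fit_tic` fits (t₀, μ, σ, A) by nonlinear least squares to the samples
from bolus arrival through the first post-peak sample only (wash-in
restriction, suppressing recirculation); the peak index is located on a
~1 s moving-average smoothing of the trace so noise on the flat top cannot
truncate the window before the true peak.  Bolus arrival is the first
frame exceeding the 1 s pre-injection baseline by 3 SD; the onset t₀ is
constrained not to precede the record.  PE is reported
baseline-subtracted.  The fit falls back to model-free estimates (max of
the smoothed curve; max finite-difference slope), with a flag, when the
optimizer fails, the relative RMSE exceeds 15%, or the record never washes
out after its maximum — a plateau is outside the first-pass bolus regime,
and the fallback reproduces e.g. a linear ramp's slope exactly.

Normalization by the IVC (PE-nLP = PE_liver/PE_IVC, likewise WIR) makes
the parameters invariant to global gain and injected dose; both
invariances are tested.  Recovery at 20 dB ROI-trace SNR is within 5%
median over 20 seeds for PE and WIR.  The generator's ROIs (liver band,
IVC and aorta discs) are geometric conveniences; spatial heterogeneity of
real perfusion is not modelled.

## Histology fat fraction

The generator places non-overlapping white ellipses (radius 15 ± 4 µm by
default) on an eosin-pink background until the white-area fraction is
within 0.2 percentage points of the request, recording the realized
fraction as truth.  Segmentation excludes border-connected near-white
slide background, then selects bright, weakly saturated pixels inside
tissue; the brightness threshold is the midpoint between the tissue's
median value and its 99.9th percentile and the saturation threshold is
min(Otsu, 0.6 × median tissue saturation), both self-scaling so the result
is invariant to ±10% uniform illumination and a vacuole-free section
yields 0%.  Opening-then-closing with a 3 px disc and a 50 µm² minimum
component area remove speckle.  The fraction is fat area over tissue area
(not image area).  Recovery is within 2 percentage points over
{0, 5, 10, 20, 40}% and monotone in the truth.  Real H&E sections add
nuclei, sinusoids, tears and staining gradients that this phantom does not
contain; the validation establishes the morphological pipeline, not
robustness to slide artifacts.

## Classification and statistics

Z-scoring uses the sample SD (n−1); standardization parameters are
retained and applied to held-out rows, never refitted on them.

PCA contributions use eigenvalue-weighted squared loadings over the K
retained components: contribution_j = 100·Σ_{k≤K} λ_k w²_jk / Σ_{k≤K} λ_k.
With all six components retained this is exactly 100/6 per feature on
standardized data (each feature's full unit variance is captured), so
feature rankings must be read from a truncated decomposition (K = 3 by
default).  Two structural caveats, both consequences of standardization,
are worth knowing: any single feature's contribution is bounded above by
100/Σ_{k≤3} λ_k ≤ 33.3%, and when the between-feature correlation
structure is weak or highly symmetric the per-feature split of the
retained subspace is nearly degenerate, so small sampling fluctuations can
reorder features with similar contributions.  The implementation is
verified against a direct eigendecomposition of the sample covariance to
1e-8.

The SVM uses an RBF kernel with C ∈ 10^{−1..3} and γ ∈ 10^{−3..1} selected
by 5-fold cross-validation on the training split of a stratified, seeded
80/20 split; multiclass is one-vs-one.  Three accuracies are reported and
kept distinct: training-split, held-out test, and "overall" (every row,
including training rows, through the fitted model) — headline accuracies
in the literature are often the overall figure, so all three are exposed.

Mann–Whitney U follows the U = min(U_x, U_y) convention with midrank ties.
The two-sided p-value is exact — the fraction of labelings whose min-U is
at most the observed one, computed from the Gaussian-binomial recurrence —
when n_x·n_y ≤ 400 and there are no ties, and otherwise a normal
approximation with tie and continuity corrections.  The exact path is
verified against full enumeration for all n_x, n_y ≤ 8.

## Study pipeline

`run_study` synthesizes and measures every subject-timepoint.  The
group × week ground-truth maps (speed/attenuation, spectral shift,
echogenicity gain, perfusion) are this package's own settings: the study
the pipeline emulates reports group values only as boxplots, so the maps
were chosen to follow the established directions of steatosis (speed down,
attenuation up, echogenicity and H-scan blue shift up, perfusion down)
with effects absent at week 0, mild at week 2 and strong at week 6.
Subject-level biology is a 2% multiplicative jitter on each truth value.
Per-stage seeds are SHA-256 hashes of (master seed, subject, week, stage),
so the study is bit-reproducible and any subject can be regenerated in
isolation.  Default problem sizes (48 RF lines, ~200-line shear movies,
32 × 32 CEUS frames, 256² histology images) keep a full 63-row study under
half a minute while leaving every estimator inside its validated regime.

## Known limitations

- No acoustic field simulation: no diffraction, beam profiles, or push
  physics; RF speckle statistics are controlled spectrally, not
  geometrically.
- The shear-wave truth is monochromatic and non-dispersive.
- CEUS recirculation is handled only by the wash-in restriction.
- PCA "contribution" is one of several definitions in use; see the bounds
  above before comparing absolute percentages across studies.
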