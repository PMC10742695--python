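# Methods

`entroscan` implements kernel-density-estimation (KDE)-based ultrasound
Shannon entropy imaging, alongside the conventional histogram-based
estimator, from raw backscattered radiofrequency (RF) frames to parametric
images and diagnostic statistics, with a synthetic speckle phantom standing
in for clinical data.

## Entropy estimators

Both estimators operate on the values of a gated (windowed) patch of the
**uncompressed** envelope image; B-mode log compression is display-only.

**Histogram estimator (bits).** The discrete Shannon entropy
`E_hist = -Σ p_i log2 p_i` with `p_i = count_i / N` over 40 equal-width bins
spanning the window's own `[min, max]` (a fixed-limits option exists for
cross-subject comparability). Bins are left-closed/right-open with the last
bin closed, matching `numpy.histogram`. `E_hist ∈ [0, log2 40 ≈ 5.32]`,
attaining the maximum iff all bins are equally filled and 0 for a constant
window. Because the limits track the data, the estimator is invariant to
window gain — it sees only the *shape* of the envelope distribution
relative to its range. This is also why its dynamic range is limited.

**KDE estimator (nats).** The differential Shannon entropy by
resubstitution: `E_KDE = -(1/N) Σ_i ln f(Z_i)` where
`f(z) = (1/(N h)) Σ_i K((z - Z_i)/h)` with the Gaussian kernel
`K(v) = exp(-v²/2)/√(2π)` (Epanechnikov available). The bandwidth is fully
data-adaptive: Scott's rule with the mean absolute deviation as the spread
coefficient, `h = β (4/(3N))^{1/5}`, `β = mean|S - mean S|` (d = 1). `f` is
evaluated **exactly at the sample points**, not on an approximation grid.
The self-term is included by default (the estimator as printed); a
leave-one-out flag removes it, which strictly increases the estimate and
reduces its small-sample downward bias. Because `β` is absolutely
homogeneous and shift-invariant, the estimator satisfies
`E(aS) = E(S) + ln a` and `E(S + c) = E(S)` *exactly* (to float round-off)
— so, unlike the histogram estimator, it tracks local signal power on a
log scale. That power sensitivity, plus its unbounded range, is the source
of its larger parametric-imaging dynamic range.

Numerical notes: a zero-spread sample makes `h = 0` and is rejected
(`ZeroSpreadError`) at the estimator level; inside a parametric map such
windows become sentinels (0 bits / NaN) with a warning instead of aborting
the frame. With the Gaussian kernel and resubstitution, `f(Z_i) > 0` always;
a defensive clamp to the smallest positive float covers compact kernels
with leave-one-out.

Verified against closed forms: `E[N(0,1)] = ½ ln 2πe ≈ 1.4189` nats and
`E[Rayleigh(σ)] = 1 + ln(σ/√2) + γ/2` (γ the Euler–Mascheroni constant),
both recovered within 0.05 at N = 10,000, and against a direct O(N²)
kernel-sum oracle to 1e-10.

## Parametric imaging

The gating window is 1 pulse length × 1 pulse length (2.3 mm × 2.3 mm) with
90% × 90% overlap. Window size in samples is round-half-up from mm using
`depth_per_sample = c / (2 f_s)` axially and the scanline pitch at the
transducer face laterally (beam divergence is ignored for window sizing, as
is standard sliding-window practice); stride is
`max(1, round(window × (1 - overlap)))`; partial windows at the frame edge
are dropped. At the reference acquisition (12 MHz sampling, 1540 m/s,
0.3 mm pitch) the window is 36 × 8 samples with strides 4 × 1.

Per-window entropies form the entropy map. The parallelization contract is
deliberately stronger than any particular block-processing scheme: any
chunking of the window grid across workers must produce results
bit-identical to the serial sliding window. The implementation chunks grid
rows across a thread pool; each window's reduction is independent, so the
contract holds by construction and is asserted in tests.

The map is resized to the RF grid by bilinear interpolation anchored at the
window centers (values at centers preserved exactly; edge pixels
replicated, so the image never leaves the map's range; bicubic would not
preserve the range). Scan conversion resamples to display geometry: linear
arrays to square pixels; convex arrays by polar-to-Cartesian mapping about
the virtual apex with out-of-sector pixels set to NaN (rendered
transparent). B-mode (20 log10, 40 dB dynamic range, mapped to [0, 255])
and parametric images pass through the same scan conversion, which is what
keeps them pixel-registered. Color mapping uses a perceptually uniform
colormap with per-image [min, max] scaling by default and a fixed-range
option.

ROI statistics (mean, Emax, Emin, DR = Emax − Emin) are taken over finite
pixels of the interpolated value image inside the mask; the pipelines
default to a centered rectangle covering 70% of each axis.

## Synthetic phantom

The simulator is a 2-D point-scatterer convolution model: scatterers at
continuous axial positions deposit a Gaussian-modulated cosine at the
carrier (3 MHz at 12 MHz sampling) whose −6 dB envelope width equals the
pulse length (2.3 mm); evaluating the pulse at each scatterer's sub-sample
offset gives the envelope continuous phase statistics. The resolution cell
for density accounting is 1 PL × 2 scanline pitches. Scatterer counts are
Poisson at the stated density; amplitudes constant, uniform, or lognormal.
A dense random field (≥ 10 scatterers/cell, constant amplitudes) reproduces
fully developed speckle — envelope SNR (mean/std) within 10% of
`√(π/(4−π)) ≈ 1.91` — and sparse fields (0.5/cell) are pre-Rayleigh
(SNR < 1.91). These two regimes are the simulation oracle for the engine.

**Liver stand-in.** Normal parenchyma is modeled on the standard acoustic
picture of liver: the effective scatterers (lobules) are quasi-regularly
distributed, so their echoes sum coherently. Concretely: a phase-coherent
lattice (nodes at one carrier wavelength spacing, 0.5% jitter, total
strength 6/cell), weak diffuse scattering (10/cell at gain 0.5), and sparse
brighter structural echoes (vessel walls, portal tracts; 1/cell at gain
2.5), under 4 dB/cm round-trip attenuation (≈ 0.67 dB/cm/MHz at 3 MHz) and
a log-normal parenchymal echogenicity texture (σ = 0.45, 4 mm correlation,
macroscopic relative to the window). Steatosis adds randomly distributed
sub-resolution fat scatterers at density 12 × coverage per cell (gain 1.4),
with coverage following the Brunt hepatocyte-percentage cutoffs
(G0/G1/G2/G3 → 0/0.05/0.33/0.66) as a mnemonic.

This composition produces the clinical directions through explicit
mechanisms rather than assertion:

* the growing diffuse floor degrades the coherent component
  (Rician → Rayleigh), and the fixed structural outliers lose prominence
  against it — both raise the range-normalized histogram entropy
  (the sonographic "smoothing" of fatty liver);
* backscattered power rises with fat density, which the scale-equivariant
  KDE entropy tracks as + ln(power)/2 — so `E_KDE` rises and B-mode
  brightens;
* attenuation and echogenicity texture vary power *across* windows, which
  inflates the KDE map's within-ROI dynamic range but leaves the
  range-normalized histogram map untouched — the mechanism behind the
  dynamic-range gap between the two estimators.

An important empirical caveat discovered during design: with per-window
data-range histogram limits, simply adding random scatterers to a random
background *lowers* `E_hist` (the Rayleigh shape is range-concentrated), so
a phantom without the coherent/structural components cannot reproduce the
joint rise of both estimators with grade. The coherent-lattice model is
therefore not decorative; it is what makes the histogram estimator's grade
response physical.

**Cohorts.** Graded cohorts default to the 80/70/36/18 class sizes;
continuous-severity cohorts draw 72 fat fractions log-uniformly over
0.25–44.66% (coverage = severity/100). Per-subject biological/instrumental
variability is applied as lognormal multipliers: overall gain σ = 0.08
(scanner and body-wall coupling; affects only the KDE estimator — one
reason its subject-level discrimination trails the histogram estimator's),
diffuse gain σ = 0.20, structural density σ = 0.10. Subject seeds derive
from the cohort seed by a counter scheme
(`SeedSequence((cohort_seed, index))`), so cohorts are bit-reproducible and
resumable. Cohort frames are 384 × 32 samples (≈ 24.6 mm × 9.6 mm), a size
chosen so the full 204-subject rehearsal runs at desk scale; the ROI then
holds ≈ 3,700 window positions.

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: diffraction and depth-dependent beam width, a
lateral point-spread function (off by default), frequency-dependent
attenuation and dispersion, reverberation/shadowing artifacts, vendor
processing, and real biological heterogeneity beyond the three variability
knobs. Synthetic correlations and AUCs are therefore in-model quantities;
only their directions and orderings, not their magnitudes, are meaningful
points of comparison with clinical reports.

## Diagnostics

Group-style analyses: Pearson r between ROI-mean entropy and
log10(severity) (two-sided t-test p); ROC per grade split (≥G1, ≥G2, ≥G3)
with empirical curves over all observed thresholds, trapezoidal AUC, and a
DeLong (midrank) 95% CI — cross-checked against R's pROC; bootstrap is
deliberately not the default since DeLong is closed-form and seedless. The
operating cutoff maximizes Youden's J with ties broken toward higher
sensitivity; sensitivity, specificity, LR±, PPV and NPV are recomputed from
the confusion matrix at that cutoff (prediction rule: score ≥ cutoff), so
the defining identities hold to 1e-12. Predictive values use the cohort's
own prevalence, not a population adjustment. Scores are used as-is (higher
entropy ⇒ more severe); no auto-orientation. The dynamic-range comparison
is a paired t-test; a zero-variance nonzero difference reports p → 0 with a
warning.

## Degenerate inputs and edge behavior

* Constant sample: `E_hist = 0`; KDE rejects (zero bandwidth).
* All-zero envelope: B-mode rendering rejects ("empty envelope").
* Zero-spread windows inside a frame: sentinel values, warning, run
  continues (robustness to dead elements).
* Degenerate ROC split (one class empty): error at the operation level;
  cohort pipelines record the split as missing and continue.
* Convex geometry without radius/sector: configuration error at metadata
  construction.

## Known limitations

* The resubstitution estimator is biased low at small N; the window size
  (≈ 288 samples) keeps this bias stable across windows rather than small.
  Leave-one-out is provided but not default, to match the printed method.
* Scan conversion uses bilinear resampling; no speckle-preserving
  interpolation.
* The per-window data-range histogram convention makes `E_hist`
  sensitive to single outliers in a window (range stretch); this is a
  property of the convention, not a bug, and the fixed-limits option is the
  remedy when comparability matters.
* On graded synthetic cohorts the KDE-vs-histogram dynamic-range gap is
  positive on average with very high confidence, but individual subjects
  can overlap (within-ROI max−min is an extreme statistic); the per-subject
  separation is reliably observed on the continuous-severity cohort design.
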