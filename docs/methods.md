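# Methods

## Problem and data model

A multispectral cube is an H×W×19 stack of reflectance images taken at the
narrow LED bands 395, 435, 450, 470, 505, 525, 570, 590, 630, 645, 660,
700, 850, 870, 890, 910, 940, 950 and 970 nm.  Reflectance is a
dimensionless fraction, nominally in [0, 1] with specular excess tolerated
up to 1.2.  Reflectance and absorbance are related by the standard
spectrophotometric convention R = 10^(−A).  Chemical reference values are
astaxanthin concentrations (µg per g fish) determined in duplicate; the
working value is the replicate mean.

Cubes travel as multi-page 16-bit TIFFs with a JSON sidecar
(`wavelengths_nm`, `scale`); the scale factor is `max(1, data.max())` so
ordinary reflectances round-trip within 1/65535 while specular excess
survives.  Masks are 0/255 PNGs; reference tables are CSV.

## Synthetic fillet phantoms

No real cubes are distributed, so the pipeline is validated on phantoms
that reproduce the statistical structure the analysis depends on.  A flesh
pixel carrying local concentration c follows Beer–Lambert attenuation of a
flesh baseline:

    R(λ) = brightness · flesh_base(λ) · 10^(−c·ε(λ)) + noise

with defaults:

* `flesh_base(λ) = 0.30 + 0.55·sigmoid((λ−620)/80)` — monotonically
  brighter toward the NIR, as fillet images show;
* `ε(λ) = 0.12·exp(−((λ−500)/55)²/2)` per (µg/g) — an absorption band
  confined to ~420–600 nm peaking near 500 nm, matching astaxanthin's
  known absorption and giving attenuation factors between 0.95 (c = 0.2)
  and 0.30 (c = 4.3) at the peak;
* fat/collagen stripes (six diagonal myocommata-like bands, width 2 px)
  rendered with `fat = flesh_base + 0.42·exp(−((λ−450)/120)²)`: brighter
  than flesh only in the blue/green and converging to the flesh curve in
  the red/NIR, so fat contrast is confined to 395–570 nm;
* a flat mid-gray background (0.50) standing in for the petri dish;
* i.i.d. additive Gaussian pixel noise, default SD 0.01 reflectance,
  clipped to [0, 1.2];
* a smooth multiplicative within-fillet concentration gradient
  (default ±30 %) renormalized so the fillet mean equals the sample's
  reference concentration exactly;
* per-sample brightness jitter (lognormal, SD 0.05) emulating the overall
  scaling differences between fillets that autoscaling is meant to remove.

Cohort concentrations follow a normal distribution truncated to
[0.20, 4.34] µg/g.  Because truncation shifts moments, the parent (µ, σ)
are solved numerically (least squares on the analytic truncated moments)
so the *realized* distribution has mean 1.69 and SD 0.95 µg/g; a naive
normal(1.69, 0.95) truncated to that window would realize ≈1.80/0.83
instead.  Duplicate "chemical" replicates are symmetric about the true
value (half-difference SD 0.02 µg/g), so their mean equals the truth.

What the phantoms do **not** model: optical scattering (Kubelka–Munk),
illumination non-uniformity, specular highlights, instrument spectral
response, or biologically realistic fat geometry.  Passing tests therefore
demonstrate correctness of the algorithms under a known forward model, not
field performance on real fillets; the real-data error levels will be far
higher than the phantom numbers.

## Segmentation

* **MNF**: noise covariance Σ_N = cov(Δ)/2 from horizontally adjacent pixel
  differences (offset configurable); generalized eigenproblem
  Σ_N v = λ Σ v solved with `scipy.linalg.eigh`; components ordered by
  increasing noise fraction λ.  With single-offset shift differences this
  coincides with the maximum autocorrelation factor (MAF) transform; one
  implementation carries both names.  If even the smoothest component has
  λ > 0.5 the image is declared structureless (background only) — on
  phantoms, object images give λ₁ ≈ 0.03 and pure-noise images ≈ 0.8, so
  the decision boundary is far from both.
* **Fillet**: Otsu threshold on MNF component 1; the side holding the
  majority of image-border pixels is background; the foreground keeps its
  largest connected component and fills holes.
* **Fat**: two-class CDA trained on seed regions (ground-truth masks on
  phantoms; user-supplied on real data), Otsu on the canonical variate
  within the fillet, fat side chosen by seed-class means.  Two guards make
  the near-null case sensible: if the seed classes are not separable on
  the variate (Cohen's d < 2) no fat is declared, and fat pixels must also
  lie on the fat side of the midpoint between the seed-class means (Otsu
  on unimodal data would otherwise split the meat itself).
* **Otsu**: between-class variance maximized over a 256-bin histogram.
  The objective is invariant under affine maps of the values, so the
  computation runs in bin-index units where all sums are exact integers in
  float64 — thresholds are then bit-for-bit reproducible and tie-breaking
  (toward the lower cut) is deterministic.

## Chemometrics

* Autoscaling uses the sample SD (n−1 denominator) everywhere; constant
  columns are an error naming the offending band.
* PLSR is univariate-y NIPALS with X-deflation; the regression vector
  b = W(PᵀW)⁻¹q reproduces training predictions alone, which is what the
  pixel-wise mapping applies.  At A = min(p, n−1) on full-rank data the
  model reproduces OLS (verified against the normal equations in tests,
  and against scikit-learn's PLSRegression as an independent reference).
* LOOCV refits the autoscaling *inside* every fold (no leakage); RMSECV
  ties resolve to the smallest component count; `a_max` is capped at
  min(p, n−2) with a warning.  Default `a_max` = 10.
* Metrics: RMSEP = √(mean squared error), R² = 1 − SS_res/SS_tot, and the
  residual standard error sd(residuals)/√n.
* Outlier screening is automated (score-plot inspection is not
  reproducible): Hotelling's T² on the first 2 autoscaled PCA scores
  against the exact F-based null quantile (default α = 0.975).  In the
  default experiment flagged samples are removed from the *training pool
  only*, keeping the independent test set intact.

## Colorimetry

The 12 visible bands (395–700 nm) are interpolated to the 5 nm grid
380–780 nm by monotone piecewise-cubic (PCHIP) interpolation with constant
extension outside [395, 700] and clipping at zero — a deliberately
assumption-free reconstruction operator, since training-based
reconstruction would require basis spectra that are not available.
XYZ integration follows X = k·ΣR·S·x̄ with k = 100/ΣS·ȳ.

The CIE 1931 2° color-matching functions are generated from the published
multi-lobe Gaussian analytic fits (Wyman, Sloan & Shirley, *JCGT* 2013),
accurate to about 1 %; the illuminant is a 6504 K Planckian spectrum
standing in for D65.  After construction, the x̄ and z̄ columns are
rescaled once so the perfect diffuser maps *exactly* to the nominal D65
white point (95.047, 100, 108.883) — "white-point anchoring".  This makes
every neutral-axis identity exact (R ≡ 1 → (255, 255, 255); R ≡ 0.5 →
neutral mid-gray) regardless of the residual CMF/SPD approximation error,
which then only perturbs the hue of strongly non-flat spectra at the
percent level.  sRGB uses the standard D65 matrix and piecewise gamma,
with out-of-gamut values clipped before 8-bit quantization.

## Mapping

Each ROI pixel is autoscaled with the *training* parameters and pushed
through the regression vector; non-ROI pixels are NaN.  Because the whole
chain is affine, the ROI mean of the map equals the scalar prediction of
the ROI mean spectrum (to 1e−8; asserted in tests).  Maps are rendered on
a blue→red colormap over [0, 4.5] µg/g with transparent background.
Pixel-level accuracy is not validated against chemistry — maps are
visualization, exactly as the underlying method intends.

## Experiment driver and problem sizes

The default experiment uses 59 phantoms of 90×120 px (20 train / 39 test),
noise SD 0.01, `a_max` 10, and completes in a few seconds; the test suite
uses smaller cohorts (8–30 samples, 60×80 px) chosen so the whole suite
runs in well under a minute while leaving every statistical conclusion
unchanged.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence`, making reports bit-for-bit reproducible.

## Known limitations

* The linear PLS model can only approximate the nonlinear Beer–Lambert
  response; in the noiseless limit the residual approximation error is
  ~1e−7 µg/g with 20 training samples, but with few samples or few
  components it dominates over noise.
* Pixel-wise maps amplify per-pixel noise (the autoscaling SDs come from
  nearly noise-free ROI *means*), so maps are substantially noisier than
  scalar predictions — another reason they are qualitative.
* The CDA seed-region workflow requires labelled seed pixels; on real
  images without them, fat removal is skipped and the ROI equals the
  fillet.
* Real-data performance claims cannot be established from phantoms; only
  algorithmic correctness and the multispectral-vs-RGB ordering are.
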