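# Methods

## The spatial-period pipeline

The quantity of interest is the spatial period of high/low expression
microclusters along the dorsoventral (DV) axis of a neuroepithelium, read
from a calibrated single-channel fluorescence image. The pipeline, applied
per rectangular ROI (default 15 µm wide, one side of the ventricle, one
z-slice):

1. **Gaussian blur**, isotropic, σ = 3 µm, reflective boundaries, applied to
   the 2D ROI raster *before* row averaging. A sinusoid of period T is
   attenuated by the Gaussian transfer factor exp(−2π²σ²/T²): 0.17 at
   T = 10 µm (the internuclear spacing) versus 0.89 at T = 40 µm, so the
   nuclei-scale signal is suppressed ~30-fold in power relative to the
   cluster-scale signal.
2. **Row mean**: one value per DV row (mean across the apicobasal columns),
   giving a profile sampled at the pixel size.
3. **Detrend**: least-squares polynomial of order 4, fitted against position
   in µm centred on the ROI midpoint (centring plus the rescaled-domain fit
   keep the quartic design matrix well conditioned). This removes the smooth
   domain-edge expression trend; the pipeline is insensitive to any added
   trend of order ≤ 4 by construction.
4. **FFT estimate**: periodogram I_k = |X_k|²/n at k = 1..⌊n/2⌋, no zero
   padding, periods nΔ/k. The reported period is the maximum-power ordinate
   among periods ≤ span/3 (fewer than three observed cycles cannot be
   distinguished from residual trend; this also subsumes the half-span
   guard); ties resolve to the largest period. Significance is Fisher's
   exact g-test, g = max I_k / Σ I_k, with
   p = Σ_{j=1}^{⌊1/g⌋} (−1)^{j−1} C(m,j)(1−jg)^{m−1} (clamped to [0,1]),
   computed in log space. For even n the Nyquist ordinate enters the sum
   with half weight (it is χ²₁ rather than exponential under the null; the
   half weight matches its mean, and Monte-Carlo calibration confirms the
   type-I rate stays within ±1.5 points of α = 0.05). The test targets a
   white-noise null, so it is applied to the detrended profile; the period
   is reported even when non-significant, with the flag carried.
5. **ACF estimate**: biased normalised autocorrelation (divide by n, then by
   lag 0), lags restricted to ≤ n/2 samples to limit edge noise. The
   significance envelope is a permutation bootstrap: profile values are
   shuffled without replacement, the ACF recomputed (default 1000
   resamples), and the per-lag upper (1−α) quantile taken — pointwise, not
   family-wise, mirroring the envelope depiction this procedure reproduces.
   Peaks are strict local maxima over a 3-sample neighbourhood above the
   envelope; the period is the mean spacing, counting lag 0 → first peak
   and then successive peak-to-peak gaps (equivalently, last peak lag /
   number of peaks). No peak above the envelope ⇒ no period reported.

Each ROI (each z-depth, each side) is treated as an independent observation
in group comparisons, as in the analysis this package re-implements. This is
pseudo-replication — ROIs from the same slice share biology and optics — and
is documented rather than corrected.

**Group comparison.** Two-tailed Mann–Whitney U test: exact enumeration of
all C(n, n₁) group assignments (ties at 0.5 weight) when the combined sample
is ≤ 20, otherwise scipy's tie-corrected normal approximation.

### A note on the g-test after blurring

Blurring colours the spectrum: on a blurred pure-noise profile the
low-frequency ordinates dominate and Fisher's g (which is scale-free) will
often reject even though no tissue-scale periodicity exists; likewise a
perfectly regular internuclear lattice retains a coherent, attenuated 10 µm
line that the test correctly detects. The operational meaning of the blur is
therefore *which period dominates*, not whether g rejects: without blur the
10 µm internuclear ordinate wins; with σ = 3 µm the cluster period wins. The
calibration suite verifies the g-test's type-I rate on white noise (its
null), and the flip of the dominant period on synthetic tissue.

## Synthetic data

`gen_tissue_image` emulates the structure the pipeline assumes, with ground
truth: nuclei as isotropic Gaussian bumps (sd 2.5 µm — only their ~10 µm DV
spacing matters), at exact `internuclear_um` spacing (default 10 µm, 24
cells ⇒ 240 µm span); a raised-cosine microcluster envelope of period
`cluster_period_cells × internuclear_um` (default 4 × 10 = 40 µm) evaluated
at nucleus centres, with `cluster_amplitude` (default 1.0, i.e. high cells
twice as bright as low cells) setting the contrast; a smooth order-2
polynomial trend (default 0.3x² + 0.1x on the rescaled DV coordinate,
relative to unit nucleus amplitude — the detrend is order 4, so recovery
must not depend on this choice); and i.i.d. Gaussian pixel noise (default
sd 0.1 of the nucleus peak, a typical contrast-to-noise for a confocal
reporter slice). Deliberately absent: PSF anisotropy, z-blur, nuclear shape
and position jitter, bleaching, autofluorescence structure. Passing
recovery tests therefore shows the estimators are correct and calibrated on
data with the assumed structure — not that real tissue meets those
assumptions.

Protrusion maximum lengths and lifetimes are log-normal — the field's
standard choice for a strictly positive, right-skewed size distribution —
parameterised by median and i.q.r. through the quantile function, which has
the closed form σ = asinh(iqr/(2·median))/z₀.₇₅, µ = ln median (defaults:
length 6.5 ± 3.6 µm, lifetime 4 ± 7 min). Tracks sample a triangular
extend-retract length profile at 2 min intervals, with the lifetime rounded
to a whole number of frames (minimum one), so the generated ground truth
obeys the same lifetime convention the measurement uses.

All generators draw from `numpy.random.default_rng(seed)` with an explicit
per-call seed; no global state.

## Morphometry conventions

- **Lifetime** = frames observed × frame interval: a protrusion seen in a
  single 2 min frame has lifetime 2 min (the convention is not externally
  fixed; this one is consistent with a 4 min median at 2 min sampling).
  Tracks truncated by the movie boundaries can be flagged censored and are
  retained by default; the configurable cap (default 100 min) excludes
  outlier lifetimes, logging each exclusion.
- **Angle** uses the base→tip chord, not the tip tangent: atan2 of the
  signed basal component over the magnitude of the in-plane remainder, in
  [−90°, +90°], with the apical sense defined per side ("towards the
  ventricle"), so mirror-image traces on opposite sides of the ventricle map
  to the same angle. Length classes for angle histograms are [0,5), [5,10),
  [10,∞) µm.
- **Quantiles** use linear interpolation between order statistics
  (numpy default); i.q.r. = Q3 − Q1.
- **Puncta**: strict local maxima above background median + k·MAD (k = 3,
  MAD unscaled) separated by ≥ 1 µm (closer maxima merge, brightest kept);
  both thresholds configurable — they operationalise "above background and
  well separated".

## Packing model

Equal-width apical endfeet in hexagonal close packing (the default; square
and linear layouts for comparison) give coordination 6/4/2 independent of
the widths. Required reach is the width of the single intervening structure
(endfoot origin → endfoot width; process origin → body width), with strict
inequality for "longer than"; cells are assumed straight, neither curved nor
intercalated, so neighbour identity is set entirely at the apical surface.
No pseudostratified 3D packing or probabilistic origin model is attempted.

## Problem sizes and numerics

Default synthetic images are 240 × 15 px at 1 µm/px (24 cells); recovery
suites use 50 seeded replicates, calibration suites 2000 white-noise
profiles (g-test) and 150 profiles × 300 permutations (ACF envelope), sizes
at which the binomial uncertainty of the measured rates sits comfortably
inside the asserted bands. The Fisher p-value series is evaluated with
log-gamma binomial coefficients; all-zero spectra and zero-variance profiles
raise distinct errors rather than returning numbers. ROI bounds are µm,
half-open, 0-based after rounding to the pixel grid.

## Known limitations

- The FFT period grid is harmonic (nΔ/k), so resolution is coarse at long
  periods; estimates near span/3 are bin-limited.
- The bootstrap envelope is pointwise; with ~n/2 lags inspected, some
  above-envelope excursions are expected under the null (calibrated ~5% per
  lag), which is why the ACF period uses peak *structure*, not a single
  exceedance.
- Treating ROIs as independent overstates effective sample size in group
  comparisons (see above).
- The synthetic generator's regular nucleus lattice makes the internuclear
  spectral line sharper than in tissue; conclusions about sub-10 µm signal
  suppression transfer to real images only through the transfer-function
  calibration, not literally.
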