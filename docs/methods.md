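# Methods

This note documents the models, conventions and numerical choices behind
`netstab`, in the order the pipeline runs.

## Preprocessing

The pipeline assumes spatially aligned 4D BOLD input (slice timing,
realignment, distortion correction and segmentation are upstream of this
package; masks and motion parameters are inputs). Temporal processing per
subject-session:

1. **Drop initial volumes** (default 10 of 300): scanner equilibration.
   Motion tables are truncated identically.
2. **Nuisance regression**: ordinary least squares of every voxel series
   on an intercept plus the Friston-24 motion expansion (6 realignment
   parameters, their one-volume-lagged copies with the first lagged row
   zero-filled — any constant fill is absorbed by the intercept — and the
   squares of both sets) and the WM and CSF mean series. The intercept is
   always included so residuals are mean-centred consistently. Rank
   deficiency is rejected with the offending column named rather than
   silently pseudo-inverted.
3. **Framewise displacement** uses the Power convention: the sum of
   absolute backward differences of the three translations (mm) plus 50 mm
   times the same for the three rotations (radians), FD[0] = 0. This is
   the de-facto convention behind the 0.2 mm scrubbing threshold. The
   formula choice matters only through that threshold.
4. **Gross-motion screen**: subjects with any |translation| > 1.5 mm or
   |rotation| > 1.5° (motion files store radians; conversion happens in
   the screen) are excluded from the study with a logged frame list. The
   run aborts only if no subject survives.
5. **Scrubbing**: volumes with FD > 0.2 mm are dropped. Kept frames are
   concatenated in time order; nothing is interpolated or imputed.
6. **Band-pass 0.01–0.1 Hz** (ReHo/DC/connectivity branch only): a
   zero-phase frequency-domain mask with unit gain on bins
   `low ≤ f ≤ high` and zero elsewhere, including DC. Exact band edges,
   no filter-order choice, output exactly mean-free. Scrub gaps are
   treated as contiguous time — see "Scrubbing and spectra" below.

## Voxel metrics

* **Amplitude convention.** The one-sided amplitude spectrum is the DFT
  modulus scaled by 2/n (Nyquist bin of an even-length series by 1/n), so
  a pure on-bin sinusoid of amplitude A contributes a single bin of height
  A and ALFF of a pure tone equals the tone amplitude. Any fixed scaling
  cancels in fALFF and in z-scored maps.
* **ALFF** sums amplitudes over bins in [0.01, 0.1] Hz, on the
  nuisance-regressed *unfiltered* branch (band-passing first would be
  circular). At least 32 kept frames are required for a usable spectrum.
* **fALFF** divides the in-band sum by the sum over all positive bins up
  to Nyquist. The zero bin is excluded: demeaning removes it, and its
  inclusion would make the ratio depend on an arbitrary offset. Zero
  total power flags the voxel with the NaN sentinel.
* **ReHo** is Kendall's W over each voxel's in-mask 3×3×3 neighbourhood
  (27, 19 and 7-voxel variants available), computed on time ranks with
  average-rank tie handling and no tie-correction term in the denominator
  — exact ties have measure zero on band-passed real-valued data. Edge
  voxels use only in-mask neighbours (K < 27 allowed, K ≥ 2 required;
  padding would fabricate data). The implementation is a convolution over
  rank fields and is tested voxel-for-voxel against a direct per-cluster
  computation.
* **DC** counts strict exceedances r > 0.25 of the voxel's Pearson
  correlations to all other in-mask voxels (ties at the threshold are
  excluded, self-correlation excluded). The conventional joint criterion
  "(r > .25, p ≤ .001)" reduces to the r-clause for the frame counts this
  pipeline sees (~280 kept frames: r = 0.25 has p ≈ 2e-5); a stricter
  operating point can be had by raising `r_threshold`. Zero-variance
  voxels contribute zero correlations and are flagged.
* **Finishing**: maps are z-scored over the valid gray-matter mask
  (subtract in-mask mean, divide by in-mask population SD) and then
  smoothed with a 3 mm FWHM Gaussian (σ_axis = FWHM / (voxel_size ·
  2√(2 ln 2))) in that order, following the processing order of the
  emulated study. Smoothing is a normalized convolution — the map (with
  sentinels as zero mass) and the valid-mask indicator are convolved with
  the same kernel and the ratio taken — so constants pass unchanged and
  no mass bleeds across the mask edge; kernels are truncated at 6σ.
  Whether the concordance analysis uses smoothed (default) or unsmoothed
  standardized maps is a config switch, since either order is defensible.

## Connectivity and stability

ROI mean series are unweighted means over each ROI's voxels of the
band-passed residuals (resting-state connectivity is defined on the
0.01–0.1 Hz band). The 15×15 Pearson matrix gets a Fisher transform with
|r| clipped at 1−1e−12 so degenerate r = ±1 stays finite.

**Lin's CCC** is computed with population (1/n) moments; the sample
counterpart built from n−1 statistics is kept as a second code path and
tested to agree to 1e−10 (the normalization cancels identically). The
confidence interval uses Lin's (1989) asymptotic variance of atanh(r_c),
back-transformed, at a Bonferroni-adjusted α (default .05/192, the family
of 16 subjects × 4 metrics × 3 networks; the CI method is recorded in the
report provenance since reference implementations vary). Degenerate
inputs: both vectors constant is undefined and rejected; one constant
yields ρc = 0.

**Internetwork stability** is Spearman's rank correlation between the two
sessions' cross-network Fisher-z blocks, two-sided p by the
t-approximation (an exact permutation p is available for n ≤ 10, where
the t reference is dubious). Spearman is invariant to the monotone atanh
map, so raw-r blocks give the identical ρ. The block family is
FDR-corrected (Benjamini–Hochberg, q = .01).

**Labels** follow the Dancey–Reidy scale applied to the magnitude after
half-even rounding to the 2 decimals the scale is defined on; negative
estimates keep their sign in the report and are labelled by magnitude.
**Aggregation** is mean / SD (n−1) / min / max per network×metric or
pair, at full precision, with rounding only at report time.

## The synthetic generator

The generator emulates the target acquisition — two sessions of 300
volumes at TR 3 s, 16 subjects — on a 16×16×10 desk-scale grid (full
pipeline in seconds, ≥ 27 voxels per ROI). Components, per subject:

* **Geometry**: the brain fills the grid; WM and CSF are slabs at the x
  extremes (the masks are pipeline inputs, so only their topology
  matters); 15 disjoint 27-voxel spherical ROIs (DMN 4, CEN 4, SN 7,
  named after the standard network-atlas labels) sit on a spacing-3
  lattice in the gray slab, so ReHo neighbourhoods straddle region
  boundaries as in real cortex.
* **Latent signals** are synthesized directly on the DFT frequency comb
  inside 0.01–0.1 Hz (exact band control, no filter edge effects) with
  complex-Gaussian bins — Rayleigh amplitudes, uniform phases — so
  realized spectra vary between draws the way real BOLD spectra do; a
  deterministic-amplitude comb would pin every realization's amplitude
  sums to the same value and erase the session-to-session spectral
  variation the stability analysis is supposed to measure. A `flat` vs
  `one_over_f` comb weighting is a config option; the analysis band is
  narrow enough that the choice is second-order, and flat is the default.
* **Connectivity**: the 15 ROI latents are mixed through a Cholesky
  factor (1e−8 diagonal jitter for borderline-PSD inputs) of a prescribed
  correlation matrix; the default has r = 0.5 within networks and 0.2
  across, a provably PSD block structure. Each ROI voxel couples to its
  ROI latent with a stable per-voxel coupling drawn from U(0.6, 0.95)
  (the rest of its in-band variance is a voxel-unique latent): perfect
  within-region synchrony would make Kendall's W essentially
  deterministic and session-invariant. Non-ROI gray voxels carry
  independent in-band latents.
* **Stable subject fingerprints**: per-voxel amplitudes from
  U(0.5, 1.5) and out-of-band nuisance loadings from U(0.02, 0.11), drawn
  once per subject and reused in both sessions. The loading ceiling keeps
  noise-free gray voxels ≥ 95% band-limited in power even at the
  amplitude floor (0.11²/0.5² ≈ 0.05); the WM/CSF compartments are
  nuisance-dominated by design and exempt from that property.
* **Nuisance**: three out-of-band (0.11–0.16 Hz) signals — a global
  physiological component loading weakly on gray matter, plus WM- and
  CSF-specific components. Distinct tissue components keep the two
  tissue-mean regressors linearly independent even with zero noise.
* **Motion**: slow random-walk drifts (0.01 mm / 1e−4 rad per step) plus
  one-frame spikes at `motion_spike_rate` (translation 0.3–0.6 mm or
  rotation 0.006–0.012 rad — comfortably above the 0.2 mm FD threshold,
  comfortably below the 1.5 mm/1.5° exclusion screen).
* **Session fidelity** f ∈ [0, 1]: every session-specific process
  (latents, nuisance, motion) is √f·shared + √(1−f)·unique, renormalized
  to unit variance for signals — without renormalization the shared-unique
  cross term inflates session energy by up to 2√(f(1−f))·corr(shared,
  unique), a spurious fidelity-dependent jitter maximal at f = 0.5.
  f = 1 with zero noise makes the two sessions bit-identical, giving the
  exact perfect-stability limit (all CCC = 1). Defaults: f = 0.9,
  noise SD 0.4, spike rate 0.03, chosen so the default run lands the
  group stabilities in the ordering and approximate ranges seen in real
  two-session data (amplitude and connectivity metrics strong, fALFF
  moderate, internetwork Spearman ~0.7).
* **Randomness**: one global integer seed; per-subject / per-purpose /
  per-session streams are derived deterministically and do not depend on
  the fidelity value, so runs at different fidelities with the same seed
  are paired draw-for-draw — which is what makes "mean stability strictly
  increases with fidelity" a sharp, testable property rather than a
  statistical tendency.

### What the generator does not emulate

Scanner physics (field inhomogeneity, distortion, drift), physiological
waveforms (cardiac/respiratory quasi-periodicity), spatially correlated
noise, hemodynamic response shape, motion-induced signal artifacts (motion
affects the data only through regression and scrubbing), anatomical
variability, and slow state changes between visits. Consequently
synthetic ReHo stability (~0.99 at fidelity 0.9) exceeds empirically
reported values (~0.84): with no within-session state drift, Kendall's W
over ~280 frames is close to its population value in both sessions.
Passing tests therefore demonstrate correctness of the computations and
the expected qualitative behaviour of the statistics, not that real data
would produce these numbers.

## Scrubbing and spectra

Published descriptions are generally silent on how spectral metrics treat
the non-contiguous series scrubbing leaves behind. This package
concatenates kept frames for all metrics (no imputation), which slightly
blurs the frequency grid when frames are dropped; `scrub_spectral_metrics
= False` computes ALFF/fALFF on the unscrubbed residuals instead. A
Lomb–Scargle periodogram would be the principled alternative but is not
implemented.

## Problem sizes

Tests and the acceptance script run the full pipeline at the study's
temporal size (300 volumes, 290 analyzed) and subject count (16) on the
16×16×10 grid; oracle comparisons use a 12×12×6×120 volume where the
brute-force references are exact and fast. Long-horizon parameter
recovery (connectivity within ±0.1) uses 2048 volumes on the same grid.
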