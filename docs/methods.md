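# Methods

## Overview

`alpaca_cwas` implements a connectome-wide association analysis for
native-space resting-state fMRI in children: per-subject functional
connectomes over an anatomical parcellation, built with two complementary
edge definitions, regressed edge-by-edge on age, sex, and a behavioral
covariate, with a family-wise threshold based on the effective number of
independent tests. Because suitable cohort data cannot be redistributed, the
package ships a synthetic cohort generator that reproduces the *structure*
of such a study — ages 6–10 years, ~balanced sex, 160 volumes at TR = 2 s,
motion spikes, global nuisance signals, and planted connectivity effects —
so that every stage is testable end to end with known ground truth.

## Connectivity definitions

For regions A and B with in-mask voxel time series
$\{x_i(t)\}_{i \in A}$, $\{y_j(t)\}_{j \in B}$:

- **MeanTS** — the Pearson correlation of the voxel-averaged series,
  $r_{AB} = \mathrm{corr}(\bar x, \bar y)$. Sensitive to connectivity that
  is homogeneous over the pair; averaging dilutes focal signal.
- **ALPACA** — the peak voxel-pair correlation
  $r_{AB} = \max_{i \in A, j \in B} \mathrm{corr}(x_i, y_j)$, with the
  argmax pair retained. Sensitive to connectivity confined to small
  subregions. Implemented as one matrix product of standardized series;
  an exhaustive double-loop implementation is kept as an independent oracle
  and the two are required to agree to 1e-10 (values and argmax). Ties
  resolve to the smallest voxel pair in scan order. Zero-variance voxels
  are dropped from ALPACA candidates but kept in the MeanTS average (they
  shift the mean without carrying signal).

Edge weights are Fisher-transformed, $z = \operatorname{arctanh}(r)$, with
$r$ clamped to $\pm(1 - 10^{-5})$ first, so noise-free synthetic edges at
$r = 1$ stay finite.

## Preprocessing chain

Fixed order: trim → high-pass → nuisance regression → scrubbing → spatial
median filter. Defaults follow common pediatric rs-fMRI practice:

| step | parameter | default |
|---|---|---|
| truncate series | `max_volumes` | 160 |
| drop initial volumes | `drop_first` | 4 (so 160 → 156) |
| high-pass cutoff | `hp_cutoff_hz` | 0.01 Hz |
| scrub threshold | `scrub_threshold_mm` | 0.5 mm relative RMS |
| exclusion floor | `min_volumes` | 125 kept volumes |
| ROI mask overlap | `overlap_threshold` | 0.90 mean across subjects |

Numerical choices:

- **High-pass** is regression on a discrete cosine drift basis (intercept
  plus all DCT-II components below the cutoff). This removes the mean
  exactly, has no ringing, and makes the passband/stopband directly
  verifiable by FFT.
- **Nuisance regression** projects each voxel series onto the orthogonal
  complement of [intercept, 6 motion parameters, mean WM, mean CSF];
  collinear columns are dropped greedily (earlier columns protected) with a
  warning, never silently inverted.
- **Relative displacement**: a precomputed per-volume value is accepted
  when present (the generator writes one); otherwise it is derived from the
  six parameters as translation Euclidean distance plus rotation arc length
  on a 50 mm sphere between consecutive volumes — the common convention.
  Scrubbing removes only the flagged volume (neighbor removal is available
  as an explicit option upstream of the threshold rule, default off).
- **Median filter**: per volume, each in-mask voxel takes the median of its
  3×3×3 neighborhood restricted to in-grid, in-mask voxels; out-of-mask
  voxels pass through. At (3.4, 3.4, 4.0) mm voxels the full kernel covers
  27 × 46.24 ≈ 1,248 mm³. `scipy.ndimage.median_filter` is not used because
  it cannot restrict the neighborhood to the brain mask.
- **ROI exclusion**: per subject, overlap = |ROI ∩ mask| / |ROI|; regions
  with mean overlap < 0.90, or on the manual exclusion list (six cortical
  regions routinely affected by susceptibility artifacts: entorhinal
  cortex, frontal pole, inferior temporal gyrus, lateral and medial
  orbitofrontal cortex, temporal pole), are removed; surviving regions
  contribute only ROI ∩ mask voxels.

## Edgewise statistics

Per edge and per connectivity definition, OLS (statsmodels):

$$ z_e = \beta_0 + \beta_{age}\,\mathrm{age} + \beta_{sex}\,\mathrm{sex}
        + \beta_{cbcl}\,\mathrm{cbcl} (+ \beta_{a\times s}\,\mathrm{age}{\cdot}\mathrm{sex}) + \varepsilon $$

with two-sided t-tests; sex is coded female = 0, male = 1 so positive
$\beta_{sex}$ means male > female. The behavioral covariate is the square
root of a summed item score (right-skewed, nonnegative).

Multiple testing: with $M$ edges the effective number of independent tests
is estimated from the eigenvalues $\lambda_i$ of the $M \times M$ inter-edge
correlation matrix (computed on the subjects × edges z matrix, per method,
after subject exclusions):

$$ M_{eff} = \sum_i \left[ \mathbb{1}(\lambda_i \ge 1)
            + (\lambda_i - \lfloor \lambda_i \rfloor) \right] $$

This fractional-eigenvalue estimator satisfies the boundary identities that
pin the family down (independent edges → $M$; rank-one correlation → 1;
two edges at $r = 0.5$ → eigenvalues (1.5, 0.5) → 2.0); a simpler
eigenvalue-count variant (`kaiser`) is available behind a switch.
Eigenvalues are rounded at 1e-8 before the floor/indicator because both are
discontinuous at integers (a rank-one matrix yields $\lambda = M -
\epsilon$ in floating point). The per-test threshold is the Sidak
correction $\alpha_{corr} = 1 - (1-\alpha)^{1/M_{eff}}$ with $\alpha =
0.05$; it is never more conservative than Bonferroni at the same count.
Edges degenerate in any subject are dropped from both $M$ and $M_{eff}$.

Significant edge sets are summarized two ways: hemispheric symmetry per
hemisphere-stripped region pair (intra: left–left and right–right both
significant; inter: both crossed edges significant), and tallies by
anatomical group pair × sign × location (Left / Right / Between), which
partition the significant set exactly.

## Synthetic cohort generator

Every region owns a unit-variance Gaussian latent series; voxels add i.i.d.
noise with SD `noise_sd` (default 0.5 in latent-SD units — small enough to
keep both edge definitions calibratable over the full planted range, large
enough that voxel series are visibly distinct); WM and CSF series are mixed
into all voxels with weight 0.2 each; motion spike volumes (probability
0.02/volume) exceed the 0.5 mm scrub threshold and add a global intensity
offset of 3, so they are exactly the volumes scrubbing removes.

A planted edge introduces a shared latent with mixing weight $w$ solved in
closed form so that the **expected value of the statistic the edge is
scored with** equals the target: for homogeneous edges the MeanTS
correlation (accounting for voxel-noise dilution $\sigma^2/V$ and the
shared nuisance variance $\nu$), for focal edges the peak voxel-pair
correlation. Covariate effects act on the Fisher-z scale:
$r(\mathrm{age}, \mathrm{sex}) = \tanh(\operatorname{arctanh}(r_0) +
\beta_{age}(\mathrm{age} - \bar{\mathrm{age}}) + \beta_{sex}\,\mathrm{sex})$,
clamped to (0, 0.99). Planting on the z scale makes the downstream linear
model exactly correctly specified, so a planted $\beta_{age}$ *is* the
slope the regression should recover, in z units per year. A consequence of
unit-variance mixing worth noting: at zero voxel noise an edge's
correlation equals its calibrated target (not 1), because the two regions
retain independent latent components; only at the 0.99 calibration ceiling
does the edge saturate.

Focal mode gives only a contiguous corner block of `hotspot_fraction` of
each region's voxels the shared latent, and the hotspot behaves as one
coherent locus (its voxels share a single noise draw). This choice keeps
the peak statistic an *unbiased* estimate of the planted target — a max
over independently-noisy pairs is biased upward by selection — and makes
the argmax location reproducible. MeanTS on a focal edge is attenuated by
roughly the product of the hotspot fractions (~100× for 10% hotspots),
which is the mechanism behind the focal/homogeneous detection dissociation.

Each region may appear in at most one planted effect, keeping the
closed-form calibration exact. Determinism: all randomness derives from
`SeedSequence` children of the cohort seed; identical specs give
bit-identical cohorts.

What the generator does **not** emulate: hemodynamic response convolution
and physiological noise spectra, EPI susceptibility distortion, spatial
autocorrelation of noise, multi-peak focal architecture, and realistic
motion-parameter covariance. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not effect sizes or error
rates expected on real developmental cohorts.

## Reference simulation studies

`alpaca_cwas.experiments` fixes three seeded studies on a compact phantom
(10 mirrored 27-voxel block regions, one per anatomical group per
hemisphere, on a 16×12×8 grid — sized so the Monte-Carlo suites run on one
CPU in minutes):

1. **Parameter recovery** — 100 cohorts, n = 200, three disjoint planted
   edges at $\beta_{age} = 0.05$ z/year: mean slope bias is required under
   10% and every planted edge must clear the per-cohort Sidak threshold
   (the analytic power at these settings is ≈ 1: residual z noise
   ~$1/\sqrt{T-3} \approx 0.08$, so the slope's t-statistic is ≈ 10 against
   a critical value ≈ 3.3).
2. **Family-wise error** — 100 null cohorts, n = 100: the proportion with
   any significant age edge must stay ≤ 0.10 (binomial slack around the
   nominal 0.05).
3. **Focal dissociation** — 50 cohorts, n = 60, one focal edge with a 10%
   hotspot at $\beta_{age} = 0.1$ z/year: the planted edge's detection rate
   under the peak statistic must exceed the region-mean rate.

These studies run on raw generator output (no motion spikes, connectomes
computed directly), isolating the statistical stage; the preprocessing
chain is integration-tested separately through the full pipeline at small
cohort sizes.

## Visualization

Layout computation is pure/deterministic and separated from matplotlib
rendering. Connectograms: left-hemisphere regions on the left half-circle,
grouped by cluster, alphabetical within; red = positive association (male >
female for sex), blue = negative; edge intensity linear in $-\log_{10} p$,
saturating at $p = \alpha_{corr}/10^4$; node opacity proportional to the
node's significant-edge count with a 0.2 floor so unconnected regions stay
legible (the transfer functions are cosmetic configuration — any monotone
choice preserves the documented ordering guarantees). Worm plots: lanes are
group pairs ordered by mean signed association in the ALPACA table; each
method's y values are scaled by $C / (-\log_{10} \alpha_{corr}^{(m)})$ with
$C = -\log_{10} \alpha_{corr}^{(\mathrm{ALPACA})}$, so one pair of dashed
lines at $\pm C$ marks significance for every method; within-lane ordering
is per method.

## Known limitations

- The generator's noise is temporally and spatially white; empirical
  autocorrelation would widen edgewise sampling noise and the effective
  $M_{eff}$ on real data.
- ALPACA peak locations are only guaranteed stable across subjects under
  the single-hotspot generative model; real regions may carry several peaks.
- The displacement fallback formula is one of several conventions; when a
  precomputed displacement column is supplied it always wins.
- Group-level inference is mass-univariate OLS only; permutation or
  network-based alternatives are out of scope.
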