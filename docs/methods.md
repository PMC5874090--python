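# Methods

## Problem and model

Breathing displaces the pancreas quasi-rigidly, predominantly along the
latero-lateral (LL) and superior-inferior (SI) axes, by a few
millimetres under typical immobilization. For gated particle therapy
the quantities of interest are (i) which respiratory phase is most
stable (the gating reference), (ii) the per-phase centre-of-mass (COM)
displacement of the gland and of its head/body/tail segments relative
to that reference, and (iii) whether displacement patterns differ
between patient setups (position, immobilization device) or between
segments. `pancmotion` computes all three from a 6-phase 4D
reconstruction of a dynamic, free-breathing, interleaved multi-slice MR
acquisition.

Axis convention throughout: array axis 0 = LL (positive patient-left),
1 = AP, 2 = SI (positive superior); phases are labelled 1..6 with
phase 1 = end inhalation. All COM coordinates are voxel-centre mm.

## Digital breathing phantom

The phantom stands in for patient scans that cannot be shipped with the
package; it defines the study conditions of every end-to-end test.

* **Anatomy.** Three separated ellipsoidal lobes along LL (head 24 cc,
  body 10 cc, tail 8 cc; ~42 cc total, within the 20–80 cc range of
  adult glands) on a 128 × 64 × 25 grid at 1.17 × 1.17 × 4 mm. Lobe
  separation makes the k-means optimum unique, which the partition
  tests exploit.
* **Motion.** Each lobe is displaced rigidly by
  `amplitude × waveform[phase]`; the displacement moves the continuous
  ellipsoid centre *before* voxelisation, so masks stay binary and the
  analytic COM is exact ground truth. Default peak-to-trough amplitudes
  (LL, AP, SI): head (2.0, 0.8, 2.4) mm, body (2.5, 1.0, 3.0) mm, tail
  (3.0, 1.2, 3.6) mm — LL/SI exceed AP and the tail moves 1.5× the
  head, the qualitative pattern reported for pancreatic breathing
  motion. The default waveform (1.0, 0.20, 0.06, 0.10, 0.30, 0.55) has
  the two canonical features of relaxed breathing: a long flat exhale
  plateau (making phase 3 the unique stability minimum and hence the
  reference) and a short, sharp inhale peak (making end inhalation the
  isolated extreme state — the feature the phase-anchoring step
  identifies). A raised cosine was rejected because, sampled at six
  phases, it ties the stability minimum between phases 1 and 4 and has
  no identifiable inhale anchor.
* **Intensity.** Gland contrast 1.5 over a breathing background of
  fixed Gaussian blobs plus band-limited tissue texture (σ ≈ 1.8 mm in
  plane, 8 mm across slices). The texture is sharp in plane so that
  millimetre shifts decorrelate it (giving the MI surrogate its
  respiratory sensitivity) and smooth across slices so adjacent slice
  positions share structure (keeping the reference chain on one
  respiratory state). Background geometry is fixed by an internal seed:
  user seeds change only the additive Gaussian noise (default
  sd = 0.05, SNR ≈ 30 w.r.t. gland contrast).
* **Acquisition.** 30 measurements of 25 interleaved axial slices at
  216.97 ms per image (~163 s); breathing period 4.8 s, so consecutive
  measurements of one slice position advance the cycle by ≈ 0.13 — the
  per-position surrogate sweeps the cycle with an apparent period of
  ≈ 7.7 samples, giving 3–4 cycle landmarks per position. Each 2D image
  is drawn from the phase volume active at its timestamp (continuous
  phase quantised to the nearest of the 6 states) with fresh noise.
* **What the phantom does not model:** deformation beyond per-segment
  rigid shifts, MR sequence physics, coil profiles, through-plane
  partial volume, hysteresis, or cycle-to-cycle breathing variability.
  Passing tests therefore demonstrate correctness of the analysis chain
  under quasi-rigid periodic motion, not robustness to irregular
  breathing.

## Retrospective sorting choices

* **Reference volume.** Greedy chain: exhaustive MI argmax over the
  central adjacent pair of slice positions, then outward extension by
  per-position argmax against the chosen neighbour. Candidates are
  first restricted to the *typical* half of each position's
  measurements (median MI against the other measurements at the same
  position, computed on 2× downsampled images). Without this filter
  the seed pair is effectively a lottery among respiratory states and
  the chain can drift mid-stack; the filter locks the reference onto
  the exhale plateau, the densest state of relaxed breathing.
* **Phase anchor.** Because the reference sits on the plateau, the
  surrogate *minimum* of each slice-position group marks the state most
  dissimilar from it — end inhalation. Landmark prominence is scaled by
  the inner 10–90 percentile range so the reference measurement's
  self-match spike cannot mask the respiratory oscillation. Cycle
  fractions interpolate linearly between successive landmarks
  (nearest-interval extrapolation outside) and are binned into six
  equal bins centred on the landmark.
* **Gap filling.** Empty (phase, slice) cells borrow the cyclically
  nearest populated phase, ties to the earlier phase, each fill logged.
* **MI estimator.** Joint histogram on 64 × 64 bins after independent
  min–max scaling, base-2 logs; constant images have zero entropy and
  return 0 by construction.

## Analysis conventions

* **Stability (cyclic).** Phase 1 neighbours phases 6 and 2; a
  truncated variant (single neighbour at the ends) is available for
  sensitivity checks and differs only at phases 1 and P. Per-direction
  stability averages absolute component differences; 3D stability
  averages the Euclidean norms of the two adjacent difference vectors.
  Ties in the argmin resolve to the lower phase with a warning.
* **Profile registration.** Integer shift = COM offset rounded
  half-away-from-zero; correlations are computed on the cropped common
  support of each pair (zero-padding would deflate them spuriously).
  The per-phase Pearson scalar is the median of that phase's pairwise
  correlations; summaries are median and IQR across phases.
* **Quartiles.** Type-6 (Weibull plotting positions) everywhere, the
  common box-plot convention: quartiles of {−1, 0, 1, 2, 3} are −0.5
  and 2.5 (IQR 3). Box-plot outlier fences (1.5 × IQR) are flagged for
  plotting only, never excluded from statistics.
* **Friedman/Conover.** Mid-ranks with the tie-corrected chi-square
  statistic; exact permutation p by exhaustive enumeration for small
  designs. Conover's pairwise t statistics use (b−1)(k−1) degrees of
  freedom and are run only when the omnibus test is significant
  (Fisher-LSD protection). Because all pairs share one critical
  difference, homogeneous groups are maximal intervals of treatments
  sorted by rank sum; each interval receives one symbol, and a blank
  column in the rendered table means no significant differences.
* **Blocking.** The repeated observations available per setup are the
  five non-reference phases, so blocks are phase crossed with the
  setup factors not under test (devices × phases for prone/supine,
  positions × phases for devices, positions × devices × phases for
  structures; the dataset id joins the blocks in pooled analyses).
  Incomplete blocks are dropped and counted. LL/AP/SI comparisons use
  signed displacements, 3D uses magnitudes.

## Synthetic cohorts for the statistics

`pancmotion.pipeline.cohort_motion_records` emulates a multi-patient
setup study: per dataset a lognormal amplitude scale (sd 0.15), per
acquisition a uniform sub-voxel repositioning offset (decorrelating
voxelisation error between scans), optional prone-vs-supine SI
amplitude ratio and head→tail SI gradient, and contouring jitter of
0.3 mm sd added independently to every non-reference displacement. The
jitter is applied to displacements rather than trajectories because a
shared reference-phase error would correlate all blocks of an
acquisition and invalidate the phases-as-blocks design; the reference
phase itself is fixed at the noise-free stability optimum, as a study
would fix its gating phase. Under these conditions a doubled effect
(position or segment) is detected in SI essentially always, while
unaffected directions reject at the nominal ~5% rate.

## Numerical and degenerate-input choices

* Empty k-means clusters are re-seeded at the mask voxel farthest from
  the remaining centroids (logged); iteration stops when assignments
  fix (≤ 100 rounds); the within-cluster sum of squares is asserted
  non-increasing.
* Cluster anatomy is assigned by sorting centroids along LL (head =
  most patient-right); the axis is configurable.
* Zero-variance profiles yield NaN correlations with a warning; empty
  structures, non-binary masks, inconsistent geometries, flat
  surrogates and too-few landmarks raise errors naming the offender.
* Threshold segmentation places the cut midway between the pooled
  99.5th percentile (gland interior) and the median (background), then
  removes components below 64 voxels.

## Problem sizes

Default test and acceptance runs use the full 25 × 30 acquisition
(750 slices of 128 × 64), 6 phases, 5-dataset cohorts (30 phantom
acquisitions per cohort), and 1000 null replicates of a 30 × 4 block
design for the Friedman calibration; the complete pipeline runs in
well under a minute on one CPU.

## Known limitations

* Phase labels are recovered up to the landmark precision of one
  sample (~0.13 cycle); ~1 in 4 slices lands in an adjacent bin at the
  default noise level, which phase-averaging tolerates (COM recovery
  stays well under half a voxel) but which would bias amplitude-based
  rebinning schemes (not implemented).
* The typicality filter assumes the acquisition dwells longest near one
  respiratory state; strongly irregular breathing violates this.
* The exact permutation test enumerates (k!)^b orderings and is
  restricted to small designs (≤ 2·10⁶ permutations).
* Friedman blocks built from phases assume exchangeable per-phase
  errors; temporally correlated segmentation errors would inflate the
  type-I error, which is why the cohort noise model is phase-wise
  independent.
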