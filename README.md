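# pancmotion

Quantification of breathing-induced pancreas motion from retrospectively
sorted 4D MRI.

Gated particle therapy of pancreatic lesions needs to know how far the
gland moves with breathing under a given patient setup (prone/supine
position, vacuum cushion / thermoplastic mask / compressor belt
immobilization), and which respiratory phase is stable enough to serve
as the treatment gate. `pancmotion` implements the full analysis chain
for that question, together with a digital breathing phantom so that
every stage is testable end-to-end without patient data:

1. **Retrospective 4D reconstruction** (`pancmotion.recon`). A dynamic
   free-breathing acquisition images each axial slice position
   repeatedly. A reference volume is assembled by greedily chaining, per
   slice position, the measurement with closest mutual information (MI)
   to its already-chosen neighbour; the MI of every acquired slice
   against its same-position reference slice is an internal respiratory
   surrogate; cycle landmarks on the surrogate give each slice a phase
   bin (6 phases, phase 1 = end inhalation); member slices are averaged
   into per-phase volumes.
2. **Gland partition** (`pancmotion.partition`). K-means (k = 3, Lloyd
   iterations on voxel mm coordinates) splits each phase's binary
   pancreas map into head, body and tail; each phase is initialised from
   the previous phase's centroids, and phase 1 is re-run from the last
   phase's centroids to cancel the random initialisation.
3. **Segmentation reliability** (`pancmotion.metrics`). Integral map
   profiles — 1D marginals `profile_i = Σ_j Σ_k segmentation(i,j,k)` —
   are COM-registered across phases and correlated pairwise (Pearson);
   volume consistency is the per-phase deficit `100·(V_max − V_p)/V_max`.
4. **Motion quantification** (`pancmotion.motion`). The COM stability of
   phase *ph* is `(|COM_{ph−1} − COM_ph| + |COM_{ph+1} − COM_ph|)/2`
   (cyclic adjacency); its minimiser is the reference (gating) phase,
   and motion is the signed per-phase COM displacement relative to it,
   summarised as median ± IQR along LL/AP/SI.
5. **Setup comparison** (`pancmotion.stats`). Friedman tests (tie
   corrected, phases as repeated measures within setup blocks) with
   Conover's Fisher-LSD-protected post-hoc, rendered as
   homogeneous-group symbol tables.

The phantom (`pancmotion.phantom`) is a three-lobed ellipsoidal gland
(~40 cc at 1.17 × 1.17 × 4 mm voxels) in a breathing abdominal
background, moving quasi-rigidly over a 6-phase cycle with larger LL/SI
than AP amplitudes and a tail that moves 1.5× the head; the simulator
emits the interleaved dynamic acquisition (25 slice positions × 30
measurements) with known ground-truth phase labels and COM trajectories.

## Worked example

```python
from pancmotion import (
    PhantomConfig, AcqConfig, generate_phantom, simulate_dynamic_acquisition,
    build_reference_volume, extract_surrogate, assign_phases, reconstruct_4d,
    com_trajectory, com_stability, com_displacement,
)
from pancmotion.pipeline import segment_by_threshold

phantom = generate_phantom(PhantomConfig(seed=1))
series = simulate_dynamic_acquisition(phantom, AcqConfig(seed=1))   # 750 slices
ref = build_reference_volume(series)
sig = extract_surrogate(series, ref)
labels = assign_phases(sig, 6)
vol4d = reconstruct_4d(series, labels, 6)
masks = segment_by_threshold(vol4d)
stab = com_stability(com_trajectory(masks))
print("reference phase:", stab.reference_phase)
disp, mag = com_displacement(com_trajectory(masks), stab.reference_phase)
print("phase-1 displacement (LL, AP, SI) mm:", disp[0].round(2))
```

prints

```
reference phase: 3
phase-1 displacement (LL, AP, SI) mm: [2.11 0.86 2.48]
```

i.e. the flat-exhale phase 3 is selected as the gating reference, and at
end inhalation the gland COM sits ≈2.1 mm latero-laterally, 0.9 mm
antero-posteriorly and 2.5 mm superior-inferiorly away from it —
recovering the phantom's built-in motion (truth at phase 1:
2.18 / 0.87 / 2.61 mm) to well under half a voxel.

The same chain is available from the shell:

```sh
pancmotion run --out demo --seed 1          # full pipeline
pancmotion simulate --out sim --seed 1      # or stage by stage
pancmotion reconstruct --series sim --out rec
```

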