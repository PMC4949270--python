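# walkfuse

Label fusion for multi-atlas segmentation that refines the voxels the
atlases disagree on, instead of re-weighting the atlases.

## The problem

Multi-atlas pipelines segment a structure (the motivating case is the
hippocampus in T1-weighted MRI) by registering several expert-labeled
atlases to a target image and propagating their labels, producing J
candidate binary segmentations `L^j` of the same target. Fusing those
candidates by majority vote works well in the core of the structure, where
the votes are near-unanimous, but poorly on the surface, where
registration error splits the votes — and with small atlas libraries
(J < 10) the split regions are large. `walkfuse` implements a fusion
method that mimics how a manual rater works: freeze what is certain,
then refine the uncertain boundary region-by-region, moving from
high-confidence voxels toward low-confidence ones while reading intensity
statistics off the target image itself.

## The method

1. **Vote map.** `v(x) = Σ_j w^j L^j(x) / Σ_j w^j`, interpreted as
   `P(L(x)=1)`.
2. **Confidence partition.** `S_H` = voxels with `v(x) > LT1` (confident
   structure) or `1−v(x) > LT0` (confident background); everything else
   is `S_L`. Defaults `(LT0, LT1) = (0.8, 0.6)`; at `(0.5, 0.5)` the
   output degenerates exactly to majority vote.
3. **Patches.** `S_L` voxels are ranked by the number of `S_H` voxels
   among their 26 neighbors; voxels with at least
   `ceil(mixing_ratio · L_patch³)` such neighbors (10, at the defaults
   `0.0075` and `L_patch = 11`) seed cubic patches of side `L_patch`.
   Overlaps resolve to the nearest seed; uncovered `S_L` voxels keep the
   majority-vote label.
4. **Patch MRF.** Each patch carries a binary Markov random field whose
   singleton potential is the Gaussian negative log-likelihood
   `½·log(2πσ_y²) + (f−μ_y)²/(2σ_y²)` — with `(μ_y, σ_y)` fitted from the
   patch's own `S_H` voxels of class `y` — and whose pairwise potential on
   6-adjacent voxels is `−λ` for equal labels, `+λ` otherwise
   (default `λ = 0.2`).
5. **Walk.** The patch's `S_L` voxels, with edge weights `(f_i − f_j)²`
   on 6-adjacent pairs, are spanned by a Prim minimum spanning tree
   rooted at the seed. One sequential pass in insertion order replaces
   each voxel's label by the argmin of its conditional energy given the
   current configuration — a non-iterative inference in which confidence
   propagates outward from the seed, by construction of the ordering.

The whole pipeline is deterministic: same inputs, same output, always.

## Worked example

```python
from walkfuse import (WalkFusion, MajorityVoteFusion, PhantomSpec,
                      CandidateSpec, make_phantom, make_candidates, dice)

image, truth = make_phantom(PhantomSpec(seed=42))          # 64^3 phantom
candidates = make_candidates(truth, CandidateSpec(seed=43))  # 9 noisy atlases

mv = MajorityVoteFusion().fit(image, candidates)
wf = WalkFusion().fit(image, candidates)

print(f"majority vote   DSC = {dice(mv.labels_, truth):.4f}")
print(f"walk fusion     DSC = {dice(wf.labels_, truth):.4f}")
rep = wf.report_
print(f"|S_H| = {rep['high_bg'] + rep['high_fg']}, |S_L| = {rep['low']}, "
      f"rho = {rep['rho']:.3f}, patches = {rep['n_patches']}, "
      f"coverage = {rep['coverage']:.3f}")
```

prints

```
majority vote   DSC = 0.8989
walk fusion     DSC = 0.9314
|S_H| = 258821, |S_L| = 3323, rho = 0.996, patches = 27, coverage = 1.000
```

The phantom is a smoothly deformed ellipsoid with T1-like two-class
intensities; the nine candidates are the ground truth warped by smooth
random displacement fields (≈2 voxels) near the surface. Majority vote
already gets the core right (Dice 0.90); the walk refinement recovers
most of the contested surface (Dice 0.93). `rho = |S_L| / |structure|` is
the threshold-screening ratio — values in (0.5, 1) indicate a useful
amount of refinable uncertainty — and coverage is the fraction of `S_L`
reached by patches.

Estimators follow scikit-learn conventions (`get_params` / `set_params`,
fitted attributes `labels_`, `report_`, `vote_map_`, `partition_`), and a
`neonate` preset (`WalkFusion.from_preset("neonate")`) sets the symmetric
thresholds `(0.7, 0.7)` used for reversed-contrast, low-consensus data.

## Command line

```sh
walkfuse phantom --out-dir ph --shape 64 --n-candidates 9 --perturb 2 --seed 1
walkfuse vote  --labels ph/cand_*.nii.gz --out mv.nii.gz
walkfuse fuse  --image ph/image.nii.gz --labels ph/cand_*.nii.gz \
               --out fused.nii.gz --report report.json
walkfuse dice  --a fused.nii.gz --b ph/truth.nii.gz
```

All volumes are NIfTI-1 (`.nii` / `.nii.gz`); candidate labels must
already be resampled to the target grid.

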