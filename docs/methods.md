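# Methods

This note records the model behind `cryoshell`, the numerical conventions it
fixes, the parameters that matter, what the synthetic fixtures do and do not
emulate, and the design choices made where more than one reasonable option
existed.

## Ensemble-to-density model

The object being assessed is a *cryo-ensemble*: a set of up to 1000 atomic
models of an RNA with surrounding waters and ions whose **averaged density**
is compared to an experimental map, rather than any single fitted structure.

Rigid global drift of the RNA between frames would smear the solvent signal,
so averaging is done in locally aligned frames:

1. **Standardization.** Residue names map to species: recognized
   ribonucleotide codes → RNA; HOH/WAT/H2O → water; MG/NA/CL/K → the four
   ion species; *any other residue code is assigned as water*. The mapping
   is a configurable table. All distance computations use heavy atoms only
   (element ≠ H/D): at ~2 Å map resolution hydrogens contribute no usable
   signal, and submissions vary in protonation.
2. **Trimming.** Non-RNA atoms farther than 5.0 Å (inclusive) from the RNA
   are discarded. The distance is measured against *the same model's* RNA,
   not the reference: predictors trim their own frames, and a frame with
   global drift would otherwise lose its solvent. Waters are kept or removed
   as whole residues, keyed on their oxygen, so hydrogens never orphan.
3. **Neighborhoods.** On the reference structure, residue *j* belongs to the
   neighborhood of residue *i* iff their minimum heavy-atom distance is
   ≤ radius (default 10 Å; 6/12/20 Å supported). The relation is symmetric
   and monotone in the radius.
4. **Local superposition.** Per (frame, neighborhood), the model RNA is
   superposed on the reference by the Kabsch algorithm (SVD with sign
   correction, so reflections are excluded; unweighted, as no basis exists
   for per-atom weights). Atom correspondence is the intersection of
   (residue index, atom name) pairs present on both sides; unmatched atoms
   are dropped silently with a log line. Selections: all heavy atoms
   (default), a configurable backbone set (P, OP1, OP2, O5', C5', C4', C3',
   O3', C2', C1', O4', O2' — the full sugar-phosphate set, since no
   canonical list exists), a 5-atom set (P, C4', C2, plus N9/C6 for purines
   or N1/C4 for pyrimidines) and a 3-atom set (P, C4', plus N9 or N1).
   Fewer than 3 common atoms, or a collinear configuration, makes the
   region's alignment impossible for that frame: the region is skipped and
   recorded in the run report, never fatal.
5. **Solvent capture.** Solvent within 5.0 Å (inclusive) of the
   neighborhood's RNA, measured in the *model* frame before the transform,
   is carried through the fitted transform. A solvent atom may enter several
   neighborhoods; the stitching weights arbitrate.
6. **Rendering.** Two interchangeable renderers on a 0.82 Å cubic voxel
   lattice:
   * *scattering* — each atom adds
     ρ(r) = Σᵢ aᵢ (4π/bᵢ)^{3/2} · exp(−4π² r² / bᵢ),
     the real-space Fourier transform of the 5-Gaussian electron scattering
     factor f(s) = Σ aᵢ exp(−bᵢ s²). Coefficients are taken at import time
     from gemmi's bundled International Tables C table 4.3.2.2
     parameterization (neutral atoms). The profile is hard-truncated at
     4.0 Å (the value exactly at 4.0 Å is included; no taper). Any other
     self-consistent Gaussian convention would cancel in the comparisons,
     since predicted and reference fixture maps go through the same
     renderer; the physical convention is fixed here once and documented.
   * *probability* — each atom increments the voxel containing it.
   Values are divided by the number of frames, so ensembles of different
   depth are comparable; correlation metrics are scale-invariant, so this
   choice only affects σ-thresholds, which are defined on the compared
   vectors themselves. B-factors are carried through I/O but never read by
   any renderer.
7. **Stitching.** Each neighborhood renders onto a sub-lattice of the output
   lattice (its member residues' bounding box padded by capture radius +
   scattering cutoff). The final map is the per-voxel weighted average over
   all regions whose sub-lattice contains the voxel, with weight 1/r to the
   nearest atom of the region's *center* residue, floored at one voxel
   spacing (0.82 Å) so a voxel inside the center residue cannot dominate.
   Containment is by bounding box. Uncovered voxels are 0. Species are
   rendered separately with the *same* weight field, so the species maps
   sum to the total exactly.

The output lattice is axis-aligned with origin at the reference bounding box
minus a pad, snapped to the spacing; when a reference map is supplied its
lattice is adopted verbatim, which is what every scoring path does.

## Comparison model

The assessment shell is the set of voxels whose distance to the nearest
reference RNA heavy atom lies in [1.8, 3.2) Å. Bands are half-open to keep
sliding windows disjoint where they should be. Each voxel is labeled with
its nearest residue (ties → lowest residue index, resolved exactly); voxels
nearest to an excluded residue are dropped, not reassigned — the exclusion
list addresses poorly resolved map regions, configurable as ranges like
`63-88,229-245`. Distances always use the reference structure, never model
frames, because the mask addresses the experimental map. Localization
variants: growing shells [1.8, 1.9) … [1.8, 5.0) in 0.1 Å steps (32 masks,
nested), 1 Å windows [1.8, 2.8) … [4.0, 5.0) (23 masks), and the partition
of the default shell by nearest residue.

Metrics on the masked vectors x (predicted) and x₀ (reference):

* **CC** — Pearson correlation, the cryo-EM real-space cross-correlation.
* **ρ** — Pearson correlation of midrank vectors.
* **MI** — k-nearest-neighbor mutual information with k = 6, estimated with
  scikit-learn's `mutual_info_regression` (the continuous kNN estimator);
  exact ties are broken by the estimator's internal seeded noise at 1e-10 of
  the value scale. Regions with fewer than `min_voxels_mi` voxels (default
  50; the estimator itself needs > k+1) skip MI with a reason code.
* **AUC-PR** — reference voxels with value > 3σ are the positive class,
  where σ is the population standard deviation of the reference values
  *within the compared mask* (the comparison universe; whole-map σ is a
  config option). No mean subtraction is applied — the rule is literally
  value > 3σ. Thresholds sweep the distinct predicted values in descending
  order; AUC is the right-continuous step sum Σ (Rᵢ − Rᵢ₋₁) Pᵢ, which is
  invariant under strictly monotone transforms of the prediction (so
  sweeping raw rather than standardized predicted values is immaterial).
  Under a random ranking the expected AUC-PR equals the positive-class
  prevalence.

A metric that cannot be computed (constant vector, empty positive class,
too few voxels) carries a typed reason code and is never silently zero.

References: the **floor** permutes the masked reference values and scores
the permutation against the ordered vector; the **ceiling** resamples an
independent experimental map onto the reference lattice by trilinear
interpolation and scores it like any prediction. **Bootstrap**: frames are
resampled with replacement to the original depth, the full density and
scoring path is rerun (default 5 replicates), and the per-metric standard
deviation estimates the score's sampling variance. **Ranking**: per metric,
Z = (score − mean)/sd across ensembles with population sd (ddof 0);
ensembles missing a metric are excluded from that metric's mean/sd and
receive 0 for it; negative Z is clipped to 0 so below-average performance on
one metric is not penalized; the clipped Z are summed. Per-residue Z
matrices apply the same standardization per residue region.

Determinism: one global seed fans out to per-task seeds through
`SeedSequence(seed, spawn_key=path)` counters; reports are serialized with
sorted keys and fixed float precision, so identical inputs give
byte-identical reports.

## Synthetic fixtures

The generator produces desk-scale inputs with the statistical structure the
assessment assumes, with known ground truth and full seeding:

* **Toy RNA** — an idealized A-form-like helix (rise 2.81 Å, twist 32.7°,
  phosphate radius 9.4 Å) with the full backbone atom set and purine or
  pyrimidine base skeletons, so every alignment selection is resolvable.
  Consecutive P–P distances are ≈ 6 Å, as in A-form RNA.
* **Planted sites** — points 2–3 Å from a random RNA heavy atom (hence
  inside the default shell), ≥ 2 Å apart, with species drawn from a
  composition dominated by water with Mg²⁺ and Na⁺ the most common ions
  (weights 0.70/0.12/0.10/0.05/0.03 for water/Mg²⁺/Na⁺/Cl⁻/K⁺), occupancy
  uniform in [0.55, 1] and isotropic Gaussian thermal spread 0.6 Å.
* **Frames** — per frame each site is present with probability = occupancy,
  displaced by its Gaussian spread; bulk waters (default ~1.3 per residue)
  are placed uniformly in the 1.8–5 Å zone; optional per-frame global rigid
  motion and a hinge rotation of the helix's second half emulate ensemble
  drift.
* **Maps** — the ground-truth ensemble (default 150 frames) is rendered
  through the *same* pipeline; seeded voxel Gaussian noise at 12% of the
  in-shell standard deviation gives the pseudo-experimental reference map,
  and a second seed gives the independent map for the ceiling.
* **Degradation suite** — ensembles whose site positions carry additional
  error of 0, 0.5, 1 and 2 Å, folded into the thermal spread in quadrature
  (replacing the spread outright would make the 0.5 Å level *closer* to the
  truth than the 0 Å level and destroy the a-priori fidelity order).

Defaults were chosen so that the designed contracts hold by construction:
the ceiling dominates every degraded score on all four metrics, all metrics
decrease along the suite in the large majority of seeds, and the positive
class stays sparse. Two calibration facts are worth recording. First, with
Gaussian point sites and the literal > 3σ rule, the fraction of shell voxels
above 3σ saturates near 2–3% regardless of site count or spread (σ itself
scales with the planted signal); the fixtures therefore operate at ≈ 3%
prevalence — sparse-peak class imbalance, which is the regime that motivates
AUC-PR over AU-ROC. Second, Spearman's ρ is nearly blind to the first
degradation step (effective spread 0.6 → 0.78 Å, both below one voxel): rank
structure over a background-dominated mask barely moves under sub-voxel
blur, so ρ orders the first pair only in a modest majority of seeds while
CC, MI and AUC-PR order all pairs essentially always. This is a genuine
property of rank correlation on sparse-peak fields, not an implementation
artifact.

What the fixtures do **not** emulate: real solvent physics (no coordination
geometry, no correlated hydration networks), experimental map artifacts
(sharpening, anisotropy, masking edge effects), RNA conformational
heterogeneity beyond rigid/hinge motion, and molecular-identity ambiguity
of density peaks. Passing the designed tests shows the pipeline measures
what it claims on data with known truth; it does not certify accuracy
claims about any particular real-world predictor.

## Problem sizes and numerical choices

Test and acceptance runs use a 12-residue helix (≈ 5800 shell voxels at
0.82 Å), 25-frame ensembles and a 150-frame truth ensemble; the shuffle-null
check uses a 24-residue helix (≥ 10⁴ shell voxels) with a 60-frame truth
ensemble, since the permutation null is insensitive to truth depth. These
are the package's fixture scales, chosen so the whole designed experiment
replicates across 20 seeds comfortably on one CPU.

* Maps are written as MRC2014/CCP4 mode 2 (32-bit float) via gemmi, with
  the lattice origin in the ORIGIN header words; values round-trip
  bit-exactly at float32.
* Trilinear interpolation is the exact 8-corner blend; points outside the
  hull of voxel centers are an error for the point API and 0 (with a count
  logged) for lattice resampling.
* Kabsch rejects n < 3 and configurations whose second singular value is
  ≤ 1e-8 of scale (collinear).
* Internal grids are float64; the 1/r stitch weights make every output
  voxel a convex combination of its contributing patches, so stitched
  values are bounded by the contributing local values.
* Alternate locations: highest occupancy wins, ties to the first
  encountered. Insertion codes are rejected with an error rather than
  silently renumbered.

## Known limitations

* No Fourier-space operations: no sharpening, B-factor blurring, or
  resolution filtering of either map. Map sharpening is known to affect
  shell-level agreement and is deliberately out of scope.
* Scattering factors are neutral-atom; charged-species factors (relevant
  for ions at very low resolution) are not used.
* Correspondence assumes shared residue numbering between prediction and
  reference; there is no sequence alignment and no insertion-code support.
* MI estimates are biased upward for small regions even with the voxel
  minimum; per-residue MI should be compared across ensembles, not read as
  absolute information content.
* The CLI's multi-ensemble `assess` holds one density map in memory at a
  time but scores sequentially; very large batches are better scripted
  against the library API.
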