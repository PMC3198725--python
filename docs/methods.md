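# Methods

`synapsedetect` detects and segments asymmetric (presumed excitatory)
synapses in nearly isotropic serial EM volumes, such as FIB/SEM stacks of
cortical neuropil acquired at ~5×5×9 nm voxels. Rather than implementing
the morphological criteria a human expert uses (postsynaptic density,
visible cleft, nearby vesicle cluster) as explicit rules, it learns to
imitate the expert's decisions from a handful of brush-stroke voxel labels.
This note describes the model, its parameters and defaults, the numerical
choices, what the synthetic scenes do and do not establish, and known
limitations.

## Pipeline

1. **Feature bank.** For every voxel, 38 geometric features of its 3D
   neighborhood are computed as Gaussian scale-space responses:

   | filter | σ (voxels) | channels |
   |---|---|---|
   | Hessian eigenvalues | 1, 1.6, 3.5, 5 | 3 each |
   | structure-tensor eigenvalues | 1, 1.6, 3.5, 5 | 3 each |
   | Gaussian-smoothed intensity | 0.7, 1, 1.6, 3.5, 5 | 1 each |
   | Gaussian gradient magnitude | 1.6, 3.5, 5 | 1 each |
   | Laplacian of Gaussian | 1.6, 3.5, 5 | 1 each |
   | difference of Gaussians | 1.6, 3.5, 5 | 1 each |

   The structure tensor uses the listed σ as its integration (outer) scale
   and σ/2 as the gradient (inner) scale, following the standard
   inner < outer convention; the DoG subtracts the smoothing at 0.66·σ.
   Eigenvalue triples characterise local dimensionality — for a dark sheet
   (synaptic density, membrane) one dominant Hessian eigenvalue, for a tube
   two, for a blob (vesicle, mitochondrion) three — which is what lets a
   voxel classifier separate synapses from other stained structures using
   intensity plus geometry alone, independently of orientation.

2. **Voxel classification.** A Random Forest (default 100 trees,
   ⌊√38⌋ = 6 features per split, fixed seed) is trained on the feature
   vectors of the labeled voxels. Three classes — synapse / membrane /
   rest — work better than a binary setup because membranes are the
   nearest confusers and deserve their own class. Prediction yields a
   per-voxel class probability map (tree-averaged, summing to 1). An
   out-of-bag accuracy estimate is stored with the model. Whole volumes
   can be predicted blockwise with a filter halo (⌈truncate·σ_max⌉ voxels)
   so block interiors are exactly equal to the whole-volume computation.

3. **Post-processing.** The synapse-class probability is smoothed with a
   Gaussian of σ = 5 voxels (suppressing voxel-wise prediction noise),
   thresholded strictly at the core threshold, and connected components
   (26-connectivity by default) with fewer than 1000 voxels are discarded —
   1000 voxels being roughly the volume of two vesicles at 5×5×9 nm; the
   helper `suggested_min_size` rescales this bound by voxel volume for
   other resolutions. Surviving cores are grown by hysteresis: every
   connected voxel with smoothed probability ≥ 0.5 joins the segment.
   Cores that would grow into one another are separated by assigning
   contested voxels to the Euclidean-nearest core (ties to the lower core
   id). Boundary semantics are deliberate and tested: core threshold
   strict (>), relaxation inclusive (≥), size filter applied to the core
   before growth while the reported candidate size is the grown segment.

4. **Evaluation.** Ground truth is a list of ball markers (center +
   radius, voxel units). Balls touching the left/top image borders or the
   last slice, or centered in the first slice, are excluded — feature
   responses there are boundary-dominated. Matching is one-to-one with
   removal: candidates are visited largest-first, each claims its
   nearest-centroid overlapping unclaimed ball (overlap = at least one
   segment voxel within the ball radius, inclusive), and matched pairs
   leave the pool. Recall = tp / (gold synapses), precision =
   tp / (candidates). With zero candidates the 0/0 precision is reported
   as 1.0 with an explicit `precision_defined=False` flag so PR curves
   stay plottable. Unmatched candidate/ball pairs with centroid distance
   below twice the ball radius are flagged as near misses for manual
   review, since expert disagreement on position can mimic a detection
   error.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| feature σ set | table above | voxels | multi-scale neighborhood sizes; rescale to data resolution |
| n_trees | 100 | — | forest is robust to this; 100 is a safe standard |
| mtry | √(channels) | — | classic Random Forest default |
| smoothing σ | 5 | voxels | suppresses salt-and-pepper prediction noise |
| core threshold | 0.98 default; swept in evaluation | probability | operating point; pick from the PR curve |
| min core size | 1000 | voxels | ≈ two vesicles at 5×5×9 nm |
| relax threshold | 0.5 | probability | majority vote boundary for segmentation |
| connectivity | 26 | — | most permissive; diagonal contacts merge |

Sigmas are interpreted in voxel units, identically on all axes: at ~5×5×9
nm the data is near-isotropic enough to treat as one 3D volume, which is
precisely what makes detection orientation-independent.

The threshold sweep used by `pr_curve` defaults to a grid that is dense
below 0.5: after σ = 5 smoothing, a sheet a few voxels thick retains a
peak probability well below 1 (for an ideal thickness-t plateau the peak
is erf(t/(2√2·5))), so useful operating points sit at low thresholds when
the synapse-probability region is thin. Thicker probability regions move
the best threshold up; the sweep covers both regimes.

## Numerical choices

- All convolutions use reflective boundary handling. Kernels are truncated
  at 5σ: at 4σ the sampled derivative kernels lose ~0.07 % of their second
  moment, which shows up as ~1e-3 relative bias in gradient/Laplacian
  responses; 5σ keeps discretization error below 1e-4 at ~25 % extra cost.
- Eigenvalues are sorted descending by signed value (not magnitude);
  consistent ordering is required for stable feature semantics.
- Filters compute in float32 for whole volumes (feature stacks are the
  memory bottleneck: 38 channels × volume) but keep float64 inputs in
  float64 for analysis use.
- Smoothing with σ = 0 is the identity; smoothed probabilities are clipped
  to [0, 1].
- Duplicate identical training labels are deduplicated (overlapping brush
  strokes); the same voxel labeled with two classes is an error, never a
  silent overwrite.
- Determinism: scenes, labels, forests and predictions are pure functions
  of their seeds; detection is deterministic.

## Synthetic scenes

The generator builds a bright-background (dark = stained) volume
containing: Voronoi-cell membranes 1–2 voxels thick; synapses as dark
discs (thickness 3–5, radius 8–15 voxels) at controlled orientation, each
on a wider co-planar membrane patch with a 3–10 sphere vesicle cluster
(radius 2–3) on one side; mitochondria as striated ellipsoids;
myelin-like triple-layered extra-dark sheets; Gaussian noise (σ = 10 gray
levels). Defaults: 128×256×256 voxels, 20 synapses, 8 mitochondria, 3
myelin sheets, 60 Voronoi cells — a scene dense enough that every synapse
has membranes and distractors nearby, sparse enough that gold balls are
unambiguous. Each synapse contributes a gold ball at the disc centroid
with the disc radius.

Training labels emulate sparse brush strokes: per class, a handful of
~15-voxel compact strokes (default 10 per class, ≈450 voxels, far under
0.01 % of the volume). The background class deliberately samples its full
variability — plain cytosol, vesicles, and mitochondria with stroke starts
biased to the dark striations, because dark internal lines are exactly
what a sheet detector confuses with synaptic densities; a training set
that never labels them produces mitochondrial false positives, mirroring
the known failure mode on real tissue. Myelin-like sheets are labeled as
membrane (they are membranes).

What passing on these scenes shows: the pipeline recovers planted
geometry from contrast and local shape at realistic sparsity of
supervision, independent of synapse orientation, with the detection
reduced from ~8×10⁶ voxels to a few dozen candidates. What it does not
show: performance on real neuropil, which is far more crowded, textured
and ambiguous than any of these scenes; the generator makes no attempt at
electron-optics realism (no charging, curtaining, depth blur or stain
gradients), and real annotator variability is absent.

## Problem sizes

The bundled end-to-end experiment uses the default 128×256×256 scene
(8.4 M voxels): feature bank ≈ 2 min, training < 1 s, whole-volume
prediction ≈ 0.5 min, threshold sweep ≈ 0.5 min on one CPU core, with the
feature stack (38 × 8.4 M float32 ≈ 1.3 GB) the peak memory consumer.
Larger volumes should use `predict_blockwise`, which bounds memory by
block size while remaining exactly equal to the whole-volume path.

## Known limitations

- The detector finds asymmetric-synapse-like dark sheets; it assigns no
  polarity (pre/post side) and does not split perforated synapses.
- Candidates merged with large dark distractors (myelin) can be removed
  by the size filter together with the synapse they absorbed — the
  optional `max_size_vox` upper bound mitigates but cannot fully cure
  this.
- Feature responses within one kernel radius of the volume faces are
  reflection-distorted; the evaluation protocol's border exclusions exist
  for this reason, but candidates near faces are still reported.
- Ball radii are isotropic in voxel units; converting annotations made in
  physical units at anisotropic spacing is the user's responsibility.
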