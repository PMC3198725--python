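# synapsedetect

Automated detection and voxel-level segmentation of asymmetric (presumed
excitatory) synapses in nearly isotropic serial electron-microscopy
volumes, e.g. FIB/SEM stacks of cortical neuropil at ~5×5×9 nm voxels.

Counting and measuring synapses in EM volumes by hand is slow and
error-prone, especially for synapses whose cleft lies at a low angle to
the imaging plane. `synapsedetect` is aimed at neuroscientists who have a
registered 3D stack and a few minutes to scribble training labels: it
learns to imitate the annotator from sparse brush strokes and then
classifies every voxel in the volume, reducing millions of voxels to a few
dozen reviewable candidates.

## Method

For every voxel a 38-channel bank of 3D geometric features is computed:
eigenvalues of the Hessian ∇∇(G_σ ∗ I) and of the structure tensor
G_σ ∗ (∇G_{σ/2} I)(∇G_{σ/2} I)ᵀ at σ ∈ {1, 1.6, 3.5, 5}, Gaussian-smoothed
intensity at σ ∈ {0.7, 1, 1.6, 3.5, 5}, and gradient magnitude, Laplacian
of Gaussian and difference of Gaussians (second σ = 0.66 σ) at
σ ∈ {1.6, 3.5, 5}. A Random Forest trained on sparse three-class labels
(synapse / membrane / rest) predicts a per-voxel synapse probability
p(x). Detection is deterministic post-processing:

1. smooth p with a Gaussian, σ = 5 voxels;
2. synaptic cores = connected components of {p > θ} with ≥ 1000 voxels
   (≈ the volume of two vesicles at 5×5×9 nm);
3. segmentation by hysteresis: relax the threshold to 0.5 for all voxels
   connected to a core.

Detections are scored against expert "ball" annotations (center + radius)
by one-to-one overlap matching with removal semantics; recall =
tp / (gold synapses), precision = tp / (candidates). A seeded synthetic
EM-scene generator (membranes, oriented synaptic discs with vesicle
clusters, striated mitochondria, myelin-like sheets) provides ground truth
so the entire pipeline is testable without external data. See
`docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

```python
import synapsedetect as sd
from synapsedetect.evaluate import best_operating_point, pr_curve

# synthetic ground-truth scene: 128x256x256 voxels, 20 synapses at random
# 3D orientations, mitochondria and myelin-like distractors
scene = sd.generate_scene(sd.SceneConfig(seed=11))
labels = sd.make_training_labels(scene, strokes_per_class=10, seed=11)
print(labels.counts_per_class())
# {'synapse': 150, 'membrane': 150, 'rest': 150}

stack = sd.compute_feature_stack(scene.volume)   # (38, 128, 256, 256)
model = sd.train(stack, labels, sd.ForestConfig(seed=0))
print(round(model.metadata["oob_accuracy"], 3))
# 1.0
prob = sd.predict(model, stack)

curve = pr_curve(prob, scene.gold_balls)
threshold, best = best_operating_point(curve)
print(threshold, best.tp, best.fp, best.fn, best.recall, round(best.precision, 3))
# 0.15 20 1 0 1.0 0.952
```

The 450 labeled voxels (0.005 % of the volume) suffice to recover all 20
planted synapses; at the best threshold on the precision–recall sweep one
mitochondrion is falsely detected and no synapse is missed. Candidates
carry voxel masks, sizes, centroids and probability statistics and can be
exported as CSV, a label volume, ball-style annotations, or an HTML
proofreading report with orthogonal slice thumbnails per candidate
(`synapsedetect.report.render_report`).

The same stages are available from the shell:

```sh
synapsedetect simulate --out-dir scene --seed 11
synapsedetect train --volume scene/volume.h5 --labels scene/training_labels.csv \
    --model-out model.joblib
synapsedetect predict --volume scene/volume.h5 --model model.joblib --out prob.h5
synapsedetect detect --prob prob.h5 --out candidates.csv
synapsedetect evaluate --prob prob.h5 --balls scene/gold_balls.csv --out-prefix eval
```

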