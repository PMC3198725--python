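"""Seeded synthetic EM-like volumes with known synapse ground truth.

The generator emulates the appearance of heavy-metal-stained cortical
neuropil in nearly isotropic FIB/SEM data, at the level needed to exercise
a geometric feature bank and a voxel classifier:

* a Voronoi partition of the volume into "cells" whose boundaries are dark
  membrane surfaces 1–2 voxels thick;
* synapses as thickened dark discs (postsynaptic-density-like sheets) at
  controlled 3D orientation, each sitting on a larger co-planar membrane
  patch and flanked on one side by a cluster of small dark spheres
  (vesicles);
* mitochondria as ellipsoidal blobs with dark internal striations, and
  optional myelin-like multi-layered extra-dark sheets — the classic
  false-positive sources for sheet detectors;
* additive Gaussian noise on a bright, mildly textured background
  (dark = stained convention).

Every scene carries its ground truth: a gold "ball" per synapse at the
disc centroid with the disc radius, a dense synapse mask, and a distractor
mask.  Scenes are deterministic functions of the config seed.

What this is not: a physical simulation of electron optics.  There is no
charging, curtaining, depth blur or stain gradient, and real neuropil is
far more crowded; passing on these scenes shows the pipeline recovers
geometry from contrast, not that it matches any instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .volume import (
    BallAnnotation,
    SparseLabels,
    Volume3D,
    write_balls,
    write_volume,
    read_volume,
    read_balls,
)


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.  Intensities are 8-bit grayscale
    (0 dark / stained, 255 bright); geometry is in voxel units."""

    shape: tuple[int, int, int] = (128, 256, 256)
    n_synapses: int = 20
    n_mitochondria: int = 8
    n_myelin: int = 3
    membrane_density: int = 60  # Voronoi seed (cell) count
    synapse_thickness_vox: tuple[float, float] = (3.0, 5.0)
    synapse_radius_vox: tuple[float, float] = (8.0, 15.0)
    vesicle_count_range: tuple[int, int] = (3, 10)
    vesicle_radius_vox: tuple[float, float] = (2.0, 3.0)
    background_mean: float = 200.0
    background_texture_sigma: float = 8.0
    membrane_gray: float = 90.0
    myelin_gray: float = 55.0
    synapse_gray: float = 40.0
    vesicle_gray: float = 75.0
    mito_gray: float = 120.0
    mito_stripe_gray: float = 70.0
    noise_sigma: float = 10.0
    orientation: str = "random"  # "random" | "axis" | "mixed"
    min_synapse_separation_vox: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(c < 0 for c in (self.n_synapses, self.n_mitochondria, self.n_myelin)):
            raise ValueError("object counts must be >= 0")
        if self.orientation not in ("random", "axis", "mixed"):
            raise ValueError("orientation must be 'random', 'axis' or 'mixed'")
        margin = self.synapse_radius_vox[1] + self.synapse_thickness_vox[1]
        if min(self.shape) <= 2 * margin:
            raise ValueError(
                f"shape {self.shape} too small for synapse radius up to "
                f"{self.synapse_radius_vox[1]}"
            )
        for g in (self.membrane_gray, self.myelin_gray, self.synapse_gray,
                  self.vesicle_gray, self.mito_gray, self.mito_stripe_gray,
                  self.background_mean):
            if not 0 <= g <= 255:
                raise ValueError("gray levels must lie in [0, 255]")


@dataclass
class SyntheticScene:
    volume: Volume3D
    gold_balls: list[BallAnnotation]
    synapse_mask: np.ndarray  # bool, synapse (PSD disc) voxels
    distractor_mask: np.ndarray  # bool, mitochondria + myelin voxels
    myelin_mask: np.ndarray  # bool, myelin-like sheet voxels only
    membrane_mask: np.ndarray  # bool, membrane surfaces (incl. synapse patches)
    vesicle_mask: np.ndarray  # bool, vesicle voxels
    synapse_table: pd.DataFrame  # per-synapse geometry: center, radius, normal, oblique
    config: SceneConfig


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-8:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _local_grid(center, extent, shape):
    """Integer coordinate grids for a clipped box around ``center``."""
    lo = np.maximum(np.floor(np.asarray(center) - extent).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + extent).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    return lo, hi, zz, yy, xx


def _disc_mask(center, normal, radius, thickness, shape):
    """Boolean mask (in a local box) of a thickened disc; returns (lo, hi, mask)."""
    extent = radius + thickness
    lo, hi, zz, yy, xx = _local_grid(center, extent, shape)
    d = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1).astype(np.float64)
    axial = d @ normal
    radial2 = (d * d).sum(axis=-1) - axial**2
    mask = (np.abs(axial) <= thickness / 2.0) & (radial2 <= radius**2)
    return lo, hi, mask


def _sphere_mask(center, radius, shape):
    lo, hi, zz, yy, xx = _local_grid(center, radius, shape)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return lo, hi, d2 <= radius**2


def _paint(canvas, lo, hi, mask, gray):
    """Darken (min-compose) a region of the canvas; dark stain dominates."""
    box = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.minimum(box, np.where(mask, gray, box), out=box)


def _set(maskvol, lo, hi, mask):
    maskvol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= mask


def _voronoi_membranes(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Dark membrane surfaces as Voronoi-cell boundaries (1–2 voxels thick)."""
    shape = cfg.shape
    n = max(cfg.membrane_density, 2)
    seeds = np.column_stack([rng.integers(0, s, n) for s in shape])
    seed_vol = np.zeros(shape, dtype=bool)
    seed_vol[seeds[:, 0], seeds[:, 1], seeds[:, 2]] = True
    _, idx = ndimage.distance_transform_edt(~seed_vol, return_indices=True)
    key = (idx[0].astype(np.int64) * shape[1] + idx[1]) * shape[2] + idx[2]
    boundary = np.zeros(shape, dtype=bool)
    for axis in range(3):
        a = np.swapaxes(key, 0, axis)
        b = np.swapaxes(boundary, 0, axis)
        diff = a[1:] != a[:-1]
        b[1:] |= diff
        b[:-1] |= diff
    return boundary


def generate_scene(cfg: SceneConfig | None = None) -> SyntheticScene:
    """Generate a deterministic synthetic scene from ``cfg``.

    Synapse placement retries are bounded; if the volume cannot host the
    requested count at the required separation, the scene is returned with
    fewer synapses and a warning (the gold list stays consistent).
    """
    if cfg is None:
        cfg = SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape

    canvas = np.full(shape, cfg.background_mean, dtype=np.float32)
    if cfg.background_texture_sigma > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal(shape).astype(np.float32), 3.0, mode="reflect"
        )
        tex *= cfg.background_texture_sigma / max(tex.std(), 1e-6)
        canvas += tex

    membrane_mask = _voronoi_membranes(cfg, rng)
    canvas[membrane_mask] = np.minimum(canvas[membrane_mask], cfg.membrane_gray)

    synapse_mask = np.zeros(shape, dtype=bool)
    vesicle_mask = np.zeros(shape, dtype=bool)
    distractor_mask = np.zeros(shape, dtype=bool)
    myelin_mask = np.zeros(shape, dtype=bool)

    # --- synapses: PSD disc on a membrane patch, vesicles on one side
    gold: list[BallAnnotation] = []
    rows = []
    centers: list[np.ndarray] = []
    margin = cfg.synapse_radius_vox[1] + cfg.synapse_thickness_vox[1] + 4
    placed = 0
    for i in range(cfg.n_synapses):
        ok = False
        for _ in range(100):
            c = np.array([rng.uniform(margin, s - margin) for s in shape])
            if all(np.linalg.norm(c - p) >= cfg.min_synapse_separation_vox for p in centers):
                ok = True
                break
        if not ok:
            warnings.warn(
                f"placed only {placed} of {cfg.n_synapses} synapses at the "
                "required separation", stacklevel=2,
            )
            break
        if cfg.orientation == "axis":
            oblique = False
        elif cfg.orientation == "random":
            oblique = True
        else:  # mixed: alternate axis-aligned and oblique
            oblique = i % 2 == 1
        normal = _unit_vector(rng) if oblique else np.array([1.0, 0.0, 0.0])
        if not oblique:
            _unit_vector(rng)  # keep the random stream aligned across modes
        radius = rng.uniform(*cfg.synapse_radius_vox)
        thickness = rng.uniform(*cfg.synapse_thickness_vox)

        # supporting membrane patch, co-planar and wider than the density
        lo, hi, patch = _disc_mask(c, normal, radius * 2.2, 2.0, shape)
        _paint(canvas, lo, hi, patch, cfg.membrane_gray)
        _set(membrane_mask, lo, hi, patch)

        lo, hi, disc = _disc_mask(c, normal, radius, thickness, shape)
        _paint(canvas, lo, hi, disc, cfg.synapse_gray)
        _set(synapse_mask, lo, hi, disc)

        # vesicle cluster offset to the presynaptic side
        n_ves = int(rng.integers(cfg.vesicle_count_range[0], cfg.vesicle_count_range[1] + 1))
        # lateral frame orthogonal to the normal
        t1 = np.cross(normal, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(normal, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(normal, t1)
        for _ in range(n_ves):
            rv = rng.uniform(*cfg.vesicle_radius_vox)
            axial_off = thickness / 2.0 + rng.uniform(2.0, 7.0)
            lat = rng.uniform(-0.7, 0.7, size=2) * radius
            vc = c + normal * axial_off + t1 * lat[0] + t2 * lat[1]
            vc = np.clip(vc, 1, np.asarray(shape) - 2)
            lo, hi, sph = _sphere_mask(vc, rv, shape)
            _paint(canvas, lo, hi, sph, cfg.vesicle_gray)
            _set(vesicle_mask, lo, hi, sph)

        gold.append(BallAnnotation(tuple(c), radius))
        rows.append(
            {"id": placed + 1, "z": c[0], "y": c[1], "x": c[2], "radius_vox": radius,
             "thickness_vox": thickness, "nz": normal[0], "ny": normal[1],
             "nx": normal[2], "oblique": oblique}
        )
        centers.append(c)
        placed += 1

    # --- mitochondria: striated ellipsoids, kept away from synapses
    max_semi = min(shape) / 2.0 - 4.0  # must fit the volume
    for _ in range(cfg.n_mitochondria):
        semi = rng.uniform(6.0, 14.0, size=3)
        semi[np.argmax(semi)] *= 1.6  # elongated
        semi = np.minimum(semi, max_semi)
        for _ in range(100):
            c = np.array([rng.uniform(semi.max() + 2, s - semi.max() - 2) for s in shape])
            if all(np.linalg.norm(c - p) >= 25 + semi.max() for p in centers):
                break
        else:
            continue
        axis_dir = _unit_vector(rng)
        lo, hi, zz, yy, xx = _local_grid(c, semi.max(), shape)
        d = np.stack([zz - c[0], yy - c[1], xx - c[2]], axis=-1).astype(np.float64)
        inside = ((d / semi) ** 2).sum(axis=-1) <= 1.0
        proj = d @ axis_dir
        stripes = inside & (np.sin(proj * (2 * np.pi / 6.0)) > 0.35)
        _paint(canvas, lo, hi, inside, cfg.mito_gray)
        _paint(canvas, lo, hi, stripes, cfg.mito_stripe_gray)
        _set(distractor_mask, lo, hi, inside)

    # --- myelin: multi-layered extra-dark sheets, away from synapses
    for _ in range(cfg.n_myelin):
        radius = min(rng.uniform(18.0, 28.0), min(shape) / 2.0 - 8.0)
        for _ in range(100):
            c = np.array([rng.uniform(radius + 6, s - radius - 6) for s in shape])
            if all(np.linalg.norm(c - p) >= 45 + radius for p in centers):
                break
        else:
            continue
        normal = _unit_vector(rng)
        for layer in (-3.0, 0.0, 3.0):
            lc = c + normal * layer
            lo, hi, sheet = _disc_mask(lc, normal, radius, 1.6, shape)
            _paint(canvas, lo, hi, sheet, cfg.myelin_gray)
            _set(distractor_mask, lo, hi, sheet)
            _set(myelin_mask, lo, hi, sheet)

    if cfg.noise_sigma > 0:
        canvas += rng.normal(0.0, cfg.noise_sigma, size=shape).astype(np.float32)
    np.clip(canvas, 0, 255, out=canvas)

    return SyntheticScene(
        volume=Volume3D(canvas.astype(np.uint8)),
        gold_balls=gold,
        synapse_mask=synapse_mask,
        distractor_mask=distractor_mask,
        myelin_mask=myelin_mask,
        membrane_mask=membrane_mask,
        vesicle_mask=vesicle_mask,
        synapse_table=pd.DataFrame(
            rows,
            columns=["id", "z", "y", "x", "radius_vox", "thickness_vox",
                     "nz", "ny", "nx", "oblique"],
        ),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# sparse stroke labels


def _sample_stroke(
    mask: np.ndarray,
    rng: np.random.Generator,
    length: int,
    start_pool: np.ndarray | None = None,
) -> np.ndarray | None:
    """A compact ``length``-voxel "brush stroke" inside ``mask``: a random
    start voxel plus its nearest in-mask neighbours.  ``start_pool``
    restricts where strokes begin (the stroke itself may leave the pool)."""
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return None
    pool = np.argwhere(start_pool) if start_pool is not None and start_pool.any() else coords
    start = pool[rng.integers(len(pool))]
    d2 = ((coords - start) ** 2).sum(axis=1)
    take = min(length, len(coords))
    nearest = np.argpartition(d2, take - 1)[:take]
    return coords[nearest]


def make_training_labels(
    scene: SyntheticScene,
    strokes_per_class: int = 10,
    seed: int = 0,
    stroke_length: int = 15,
) -> SparseLabels:
    """Sample sparse brush-stroke labels for the three classes.

    Class 1 strokes lie inside the synapse mask; class 2 on membranes
    (including myelin-like sheets, which are membranes); class 3 samples
    the rest — plain background, mitochondria and vesicle clusters — so the
    background class represents its full variability.  Total labeled
    voxels stay well under 1% of the volume.
    """
    if scene.synapse_mask.sum() == 0:
        raise ValueError("scene has no synapse voxels to sample class 1 from")
    rng = np.random.default_rng(seed)
    shape = scene.volume.shape
    myelin = scene.myelin_mask
    mito = scene.distractor_mask & ~scene.myelin_mask
    structures = scene.membrane_mask | scene.distractor_mask | scene.synapse_mask | scene.vesicle_mask
    background = ~structures

    coords_all = []
    ids_all = []

    def add(mask, class_id, n_strokes, start_pool=None):
        for _ in range(n_strokes):
            s = _sample_stroke(mask, rng, stroke_length, start_pool)
            if s is not None:
                coords_all.append(s)
                ids_all.append(np.full(len(s), class_id, dtype=np.int64))

    # class 1: synapse
    add(scene.synapse_mask, 1, strokes_per_class)
    # class 2: membranes, with some strokes on myelin-like dark sheets
    n_my = max(1, strokes_per_class // 3) if myelin.any() else 0
    add(scene.membrane_mask & ~scene.synapse_mask, 2, strokes_per_class - n_my)
    if n_my:
        add(myelin, 2, n_my)
    # class 3: the rest — background, mitochondria, vesicles.  Mitochondria
    # strokes start on the darkest (striation) voxels: the dark internal
    # lines are the structures a sheet detector confuses with synaptic
    # densities, so a representative training set must label them.
    n_mito = max(1, strokes_per_class // 3) if mito.any() else 0
    n_ves = max(1, strokes_per_class // 4) if scene.vesicle_mask.any() else 0
    add(background, 3, strokes_per_class - n_mito - n_ves)
    if n_mito:
        vals = scene.volume.data[mito]
        dark = np.zeros_like(mito)
        dark[mito] = vals <= np.quantile(vals, 0.3)
        add(mito, 3, n_mito, start_pool=dark)
    if n_ves:
        add(scene.vesicle_mask, 3, n_ves)

    coords = np.concatenate(coords_all, axis=0)
    ids = np.concatenate(ids_all, axis=0)
    # deduplicate; on collisions the first-written class wins (strokes of
    # different classes never overlap by construction of the masks)
    key = np.ravel_multi_index(coords.T, shape)
    _, first = np.unique(key, return_index=True)
    first.sort()
    labels = SparseLabels(coords[first], ids[first])
    labels.validate_against(shape)
    return labels


# ---------------------------------------------------------------------------
# persistence


def save_scene(scene: SyntheticScene, out_dir) -> None:
    """Persist a scene as a directory: volume.h5, gold_balls.csv,
    synapse_mask.h5, distractor_mask.h5, synapses.csv, config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(scene.volume, out / "volume.h5")
    write_balls(scene.gold_balls, out / "gold_balls.csv")
    write_volume(Volume3D(scene.synapse_mask.astype(np.uint8)), out / "synapse_mask.h5")
    write_volume(Volume3D(scene.distractor_mask.astype(np.uint8)), out / "distractor_mask.h5")
    scene.synapse_table.to_csv(out / "synapses.csv", index=False)
    cfg = asdict(scene.config)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)


def load_scene_config(path) -> SceneConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    for k in ("shape", "synapse_thickness_vox", "synapse_radius_vox",
              "vesicle_count_range", "vesicle_radius_vox"):
        if k in raw and raw[k] is not None:
            raw[k] = tuple(raw[k])
    return SceneConfig(**raw)
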