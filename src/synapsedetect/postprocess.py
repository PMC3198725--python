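"""Deterministic post-processing of the synapse probability map.

The chain is: Gaussian smoothing of the synapse-class probability (sigma 5
voxels, suppressing voxel-wise prediction noise) -> strict thresholding at
a high core threshold -> connected components -> size filter (cores below
1000 voxels, roughly the volume of two vesicles at 5x5x9 nm, are rejected)
-> hysteresis growth of each surviving core to every connected voxel with
probability >= 0.5, turning detection cores into full segmentations.

Boundary semantics, fixed here because they matter at exact values: the
core threshold is strict (value > threshold); the relaxation threshold is
inclusive (value >= 0.5).  The minimum-size filter applies to the core,
before growth; the reported candidate size is the grown segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import ProbabilityMap
from .volume import BallAnnotation, Volume3D

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class PostprocessConfig:
    smoothing_sigma_vox: float = 5.0
    core_threshold: float = 0.98
    min_size_vox: int = 1000
    max_size_vox: int | None = None
    relax_threshold: float = 0.5
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0 < self.relax_threshold <= self.core_threshold < 1):
            raise ValueError(
                f"need 0 < relax_threshold <= core_threshold < 1, got "
                f"{self.relax_threshold}, {self.core_threshold}"
            )
        if self.min_size_vox < 1:
            raise ValueError("min_size_vox must be >= 1")
        if self.max_size_vox is not None and self.max_size_vox <= self.min_size_vox:
            raise ValueError("max_size_vox must exceed min_size_vox")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.smoothing_sigma_vox < 0:
            raise ValueError("smoothing_sigma_vox must be >= 0")


def suggested_min_size(spacing_nm: Sequence[float]) -> int:
    """Scale the 1000-voxel minimum (two vesicles at 5x5x9 nm) to another
    resolution by voxel-volume ratio."""
    sz, sy, sx = spacing_nm
    return max(1, int(round(1000 * (5.0 * 5.0 * 9.0) / (sx * sy * sz))))


@dataclass
class SynapseCandidate:
    """One detected object: a high-probability core grown to a segment."""

    id: int
    core_voxels: np.ndarray  # (n, 3) int (z, y, x)
    segment_voxels: np.ndarray  # (m, 3) int, superset of core
    size_vox: int
    centroid: tuple[float, float, float]
    bbox: tuple[tuple[int, int, int], tuple[int, int, int]]  # (min, max) inclusive
    mean_prob: float
    max_prob: float


def smooth_probability(prob: ProbabilityMap, class_name: str = "synapse", sigma: float = 5.0) -> Volume3D:
    """Gaussian-smooth one class's probability map; values clipped to [0, 1].

    ``sigma == 0`` skips smoothing (identity).
    """
    pm = prob.class_map(class_name).astype(np.float32)
    if sigma > 0:
        pm = ndimage.gaussian_filter(pm, sigma, mode="reflect", truncate=4.0)
        np.clip(pm, 0.0, 1.0, out=pm)
    return Volume3D(pm)


def _label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=_STRUCTURES[connectivity])


def extract_cores(smoothed: Volume3D, cfg: PostprocessConfig) -> list[np.ndarray]:
    """Connected components of {value > core_threshold}, filtered by size.

    Returns a list of (n, 3) voxel-coordinate arrays in component-label
    order (deterministic scan order).
    """
    mask = smoothed.data > cfg.core_threshold
    lab, n = _label(mask, cfg.connectivity)
    if n == 0:
        return []
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    keep = np.flatnonzero(sizes[1:] >= cfg.min_size_vox) + 1
    if cfg.max_size_vox is not None:
        keep = keep[sizes[keep] <= cfg.max_size_vox]
    if len(keep) == 0:
        return []
    objs = ndimage.find_objects(lab)
    cores = []
    for lbl in keep:
        sl = objs[lbl - 1]
        local = np.argwhere(lab[sl] == lbl)
        local += np.array([s.start for s in sl])
        cores.append(local)
    return cores


def _split_by_nearest_core(
    comp_mask: np.ndarray, core_ids: list[int], core_masks: list[np.ndarray]
) -> np.ndarray:
    """Assign every voxel of a multi-core component to its Euclidean-nearest
    core; ties go to the lower core id.  Returns an int array over
    ``comp_mask``'s grid with the winning core id (+1-free; ids as given)."""
    assign = np.full(comp_mask.shape, -1, dtype=np.int32)
    best = np.full(comp_mask.shape, np.inf, dtype=np.float64)
    for cid, cmask in zip(core_ids, core_masks):
        d = ndimage.distance_transform_edt(~cmask)
        better = comp_mask & (d < best)
        assign[better] = cid
        best[better] = d[better]
    return assign


def grow_segments(
    cores: list[np.ndarray], smoothed: Volume3D, cfg: PostprocessConfig
) -> list[SynapseCandidate]:
    """Hysteresis growth: each core expands to all voxels with value >=
    relax_threshold that are connected to it (transitive flood fill).

    Segments that would grow into each other are separated by assigning
    contested voxels to the nearest core.  Candidate statistics (size,
    centroid, bbox, mean/max probability) are computed over the grown
    segment from the smoothed map.
    """
    if not cores:
        return []
    shape = smoothed.data.shape
    core_label = np.zeros(shape, dtype=np.int32)
    for i, core in enumerate(cores):
        sel = core_label[core[:, 0], core[:, 1], core[:, 2]]
        if (sel != 0).any():
            raise ValueError("cores must be disjoint")
        core_label[core[:, 0], core[:, 1], core[:, 2]] = i + 1

    low_mask = smoothed.data >= cfg.relax_threshold
    low_mask |= core_label > 0  # cores always belong to their own segment
    low_lab, n_low = _label(low_mask, cfg.connectivity)

    # which low components contain which cores
    comp_of_core = ndimage.labeled_comprehension(
        low_lab, core_label, np.arange(1, len(cores) + 1), lambda v: v[0], np.int64, 0
    )
    comp_to_cores: dict[int, list[int]] = {}
    for core_idx, comp in enumerate(np.atleast_1d(comp_of_core)):
        comp_to_cores.setdefault(int(comp), []).append(core_idx)

    objs = ndimage.find_objects(low_lab)
    seg_coords: dict[int, np.ndarray] = {}
    for comp, core_idxs in comp_to_cores.items():
        sl = objs[comp - 1]
        offset = np.array([s.start for s in sl])
        comp_mask = low_lab[sl] == comp
        if len(core_idxs) == 1:
            coords = np.argwhere(comp_mask) + offset
            seg_coords[core_idxs[0]] = coords
        else:
            core_masks = [comp_mask & (core_label[sl] == i + 1) for i in core_idxs]
            assign = _split_by_nearest_core(comp_mask, core_idxs, core_masks)
            for i in core_idxs:
                coords = np.argwhere(assign == i) + offset
                seg_coords[i] = coords

    sm = smoothed.data
    out = []
    for i, core in enumerate(cores):
        seg = seg_coords[i]
        vals = sm[seg[:, 0], seg[:, 1], seg[:, 2]]
        out.append(
            SynapseCandidate(
                id=i + 1,
                core_voxels=core,
                segment_voxels=seg,
                size_vox=int(len(seg)),
                centroid=tuple(float(c) for c in seg.mean(axis=0)),
                bbox=(
                    tuple(int(c) for c in seg.min(axis=0)),
                    tuple(int(c) for c in seg.max(axis=0)),
                ),
                mean_prob=float(vals.mean()),
                max_prob=float(vals.max()),
            )
        )
    return out


def detect(
    prob: ProbabilityMap,
    cfg: PostprocessConfig | None = None,
    class_name: str = "synapse",
    smoothed: Volume3D | None = None,
) -> list[SynapseCandidate]:
    """Full post-processing chain: smooth -> threshold -> components ->
    size filter -> hysteresis growth.

    Candidates are sorted by descending segment size and re-numbered 1..n.
    A precomputed ``smoothed`` map may be passed to share work across
    thresholds (as in a precision-recall sweep).
    """
    if cfg is None:
        cfg = PostprocessConfig()
    if smoothed is None:
        smoothed = smooth_probability(prob, class_name, cfg.smoothing_sigma_vox)
    cores = extract_cores(smoothed, cfg)
    cands = grow_segments(cores, smoothed, cfg)
    cands.sort(key=lambda c: (-c.size_vox, c.id))
    for new_id, c in enumerate(cands, start=1):
        c.id = new_id
    return cands


# ---------------------------------------------------------------------------
# exports


def candidates_to_dataframe(cands: Sequence[SynapseCandidate]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append(
            {
                "id": c.id,
                "size_vox": c.size_vox,
                "centroid_z": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_x": c.centroid[2],
                "bbox_zmin": c.bbox[0][0],
                "bbox_ymin": c.bbox[0][1],
                "bbox_xmin": c.bbox[0][2],
                "bbox_zmax": c.bbox[1][0],
                "bbox_ymax": c.bbox[1][1],
                "bbox_xmax": c.bbox[1][2],
                "mean_prob": c.mean_prob,
                "max_prob": c.max_prob,
            }
        )
    cols = [
        "id", "size_vox", "centroid_z", "centroid_y", "centroid_x",
        "bbox_zmin", "bbox_ymin", "bbox_xmin", "bbox_zmax", "bbox_ymax", "bbox_xmax",
        "mean_prob", "max_prob",
    ]
    return pd.DataFrame(rows, columns=cols)


def candidates_to_csv(cands: Sequence[SynapseCandidate], path) -> None:
    candidates_to_dataframe(cands).to_csv(path, index=False)


def candidates_to_label_volume(
    cands: Sequence[SynapseCandidate], shape: tuple[int, int, int]
) -> Volume3D:
    """Render candidates as a label volume (0 background, candidate id elsewhere)."""
    lab = np.zeros(shape, dtype=np.int32)
    for c in cands:
        s = c.segment_voxels
        lab[s[:, 0], s[:, 1], s[:, 2]] = c.id
    return Volume3D(lab)


def candidates_to_balls(cands: Sequence[SynapseCandidate]) -> list[BallAnnotation]:
    """Ball-style export: centroid plus equivalent-sphere radius, for
    cross-evaluation against expert ball annotations."""
    out = []
    for c in cands:
        r = (3.0 * c.size_vox / (4.0 * np.pi)) ** (1.0 / 3.0)
        out.append(BallAnnotation(c.centroid, max(r, 1e-6)))
    return out
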