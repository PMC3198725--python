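"""HTML summary report for proofreading detected synapse candidates.

One page lists every candidate with its id, size, centroid and probability
statistics, plus three orthogonal 128x128 slice thumbnails through the
centroid with the segment outlined — enough context for a human to accept
or reject each detection in seconds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from jinja2 import Template

from .postprocess import SynapseCandidate
from .volume import Volume3D

THUMB_SIZE = 128

_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Synapse detection summary</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 4px 8px; text-align: center; }
img { image-rendering: pixelated; width: 128px; height: 128px; }
.near-miss { background: #fff3cd; }
</style>
</head>
<body>
<h1>Synapse detection summary</h1>
<p>{{ n }} candidate{{ '' if n == 1 else 's' }} detected
in a volume of shape {{ shape }}.</p>
{% if n == 0 %}
<p><strong>Zero detections.</strong></p>
{% else %}
<table>
<tr><th>id</th><th>size (vox)</th><th>centroid (z, y, x)</th>
<th>mean prob</th><th>max prob</th><th>xy</th><th>xz</th><th>yz</th></tr>
{% for c in cands %}
<tr>
<td>{{ c.id }}</td>
<td>{{ c.size_vox }}</td>
<td>({{ '%.1f'|format(c.centroid[0]) }}, {{ '%.1f'|format(c.centroid[1]) }}, {{ '%.1f'|format(c.centroid[2]) }})</td>
<td>{{ '%.3f'|format(c.mean_prob) }}</td>
<td>{{ '%.3f'|format(c.max_prob) }}</td>
<td><img src="thumbs/cand{{ c.id }}_xy.png"></td>
<td><img src="thumbs/cand{{ c.id }}_xz.png"></td>
<td><img src="thumbs/cand{{ c.id }}_yz.png"></td>
</tr>
{% endfor %}
</table>
{% endif %}
{% if near_misses %}
<h2>Near misses (manual review suggested)</h2>
<table>
<tr><th>candidate id</th><th>ball index</th><th>centroid distance (vox)</th></tr>
{% for cid, bi, d in near_misses %}
<tr class="near-miss"><td>{{ cid }}</td><td>{{ bi }}</td><td>{{ '%.1f'|format(d) }}</td></tr>
{% endfor %}
</table>
{% endif %}
</body>
</html>
"""
)


def _crop_plane(data2d: np.ndarray, cy: int, cx: int, size: int) -> tuple[np.ndarray, int, int]:
    """Fixed-size crop centered at (cy, cx), zero-padded at volume borders.
    Returns the crop and the (y, x) offset of its origin in image coords."""
    half = size // 2
    out = np.zeros((size, size), dtype=data2d.dtype)
    y0, x0 = cy - half, cx - half
    ys = slice(max(0, y0), min(data2d.shape[0], y0 + size))
    xs = slice(max(0, x0), min(data2d.shape[1], x0 + size))
    out[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0] = data2d[ys, xs]
    return out, y0, x0


def _thumbnail(
    vol: Volume3D, cand: SynapseCandidate, plane: str, path: Path
) -> None:
    """Grayscale crop through the candidate centroid with the segment
    outlined in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.image as mpimg
    from skimage.segmentation import find_boundaries

    cz, cy, cx = (int(round(c)) for c in cand.centroid)
    cz = int(np.clip(cz, 0, vol.shape[0] - 1))
    cy = int(np.clip(cy, 0, vol.shape[1] - 1))
    cx = int(np.clip(cx, 0, vol.shape[2] - 1))
    seg = cand.segment_voxels
    if plane == "xy":
        img2d = vol.data[cz]
        in_plane = seg[seg[:, 0] == cz][:, 1:]
        c0, c1 = cy, cx
        plane_shape = vol.shape[1:]
    elif plane == "xz":
        img2d = vol.data[:, cy, :]
        sel = seg[seg[:, 1] == cy]
        in_plane = sel[:, [0, 2]]
        c0, c1 = cz, cx
        plane_shape = (vol.shape[0], vol.shape[2])
    else:  # yz
        img2d = vol.data[:, :, cx]
        sel = seg[seg[:, 2] == cx]
        in_plane = sel[:, [0, 1]]
        c0, c1 = cz, cy
        plane_shape = (vol.shape[0], vol.shape[1])

    crop, o0, o1 = _crop_plane(np.asarray(img2d, dtype=np.float32), c0, c1, THUMB_SIZE)
    lo, hi = float(vol.data.min()), float(vol.data.max())
    crop = (crop - lo) / max(hi - lo, 1e-6)
    rgb = np.stack([crop] * 3, axis=-1)

    segmask = np.zeros(plane_shape, dtype=bool)
    if len(in_plane):
        segmask[in_plane[:, 0], in_plane[:, 1]] = True
    segcrop, _, _ = _crop_plane(segmask.astype(np.uint8), c0, c1, THUMB_SIZE)
    edge = find_boundaries(segcrop.astype(bool), mode="inner")
    rgb[edge] = (1.0, 0.1, 0.1)
    mpimg.imsave(path, np.clip(rgb, 0, 1))


def render_report(
    cands: Sequence[SynapseCandidate],
    vol: Volume3D,
    out_dir,
    near_misses: Sequence[tuple[int, int, float]] | None = None,
) -> Path:
    """Write ``report.html`` (plus PNG thumbnails) under ``out_dir``.

    Candidates are listed in id order; ``near_misses`` entries from the
    evaluation module, when given, are appended as a review table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise IOError(f"not a writable directory: {out}")
    thumbs = out / "thumbs"
    thumbs.mkdir(exist_ok=True)
    cands = sorted(cands, key=lambda c: c.id)
    for c in cands:
        for plane in ("xy", "xz", "yz"):
            _thumbnail(vol, c, plane, thumbs / f"cand{c.id}_{plane}.png")
    html = _TEMPLATE.render(
        n=len(cands),
        cands=cands,
        shape=tuple(vol.shape),
        near_misses=list(near_misses) if near_misses else [],
    )
    path = out / "report.html"
    path.write_text(html)
    return path
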