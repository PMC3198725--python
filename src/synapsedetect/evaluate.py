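"""Detection evaluation against expert ball annotations.

Ground truth is a set of "ball" markers (center + radius) placed on each
synapse.  A candidate counts as a true positive if its segmented shape
overlaps a gold ball; once matched, both the ball and the candidate are
removed from the pool, so a second candidate on the same synapse is a
false positive and every unclaimed ball a false negative.  Recall is
tp / (number of gold synapses) and precision tp / (number of candidates).

Balls whose sphere touches the left (x=0) or top (y=0) image border or the
last slice, and balls centered in the first slice, are excluded before
matching — feature responses there are dominated by boundary effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ProbabilityMap
from .postprocess import PostprocessConfig, SynapseCandidate, detect, smooth_probability
from .volume import BallAnnotation


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    matches: list[tuple[int, int]]  # (candidate id, ball index)
    unmatched_candidates: list[int]
    unmatched_balls: list[int]
    precision_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "precision_defined": self.precision_defined,
            "matches": [list(m) for m in self.matches],
            "unmatched_candidates": list(self.unmatched_candidates),
            "unmatched_balls": list(self.unmatched_balls),
        }


def exclude_border(balls: Sequence[BallAnnotation], shape: tuple[int, int, int]) -> list[BallAnnotation]:
    """Remove balls touching the left/top borders or the last slice, and
    balls whose center lies in the first slice."""
    kept = []
    zmax = shape[0] - 1
    for b in balls:
        cz, cy, cx = b.center
        r = b.radius_vox
        if cx - r <= 0 or cy - r <= 0:  # touches left or top border
            continue
        if cz + r >= zmax:  # touches the last slice
            continue
        if int(round(cz)) == 0:  # center in the first slice
            continue
        kept.append(b)
    return kept


def ball_overlaps_candidate(ball: BallAnnotation, cand: SynapseCandidate) -> bool:
    """True iff any voxel of the candidate's segment lies within
    ``radius_vox`` (inclusive) of the ball center."""
    seg = cand.segment_voxels
    if len(seg) == 0:
        return False
    d2 = ((seg - np.asarray(ball.center)) ** 2).sum(axis=1)
    return bool(d2.min() <= ball.radius_vox**2)


def _centroid_dist(cand: SynapseCandidate, ball: BallAnnotation) -> float:
    return float(np.linalg.norm(np.asarray(cand.centroid) - np.asarray(ball.center)))


def match(cands: Sequence[SynapseCandidate], balls: Sequence[BallAnnotation]) -> EvalResult:
    """One-to-one greedy matching with removal semantics.

    Candidates are visited in descending segment size; each claims its
    nearest-centroid overlapping ball that is still unclaimed (ties broken
    toward the lower ball index).  Matched pairs are true positives;
    leftover candidates are false positives and leftover balls false
    negatives.  With zero candidates precision is the 0/0 case, reported
    as 1.0 with ``precision_defined=False``.
    """
    order = sorted(range(len(cands)), key=lambda i: (-cands[i].size_vox, cands[i].id))
    claimed = [False] * len(balls)
    matches: list[tuple[int, int]] = []
    unmatched_c: list[int] = []
    for ci in order:
        cand = cands[ci]
        best = None
        best_d = np.inf
        for bi, ball in enumerate(balls):
            if claimed[bi]:
                continue
            if ball_overlaps_candidate(ball, cand):
                d = _centroid_dist(cand, ball)
                if d < best_d:
                    best, best_d = bi, d
        if best is None:
            unmatched_c.append(cand.id)
        else:
            claimed[best] = True
            matches.append((cand.id, best))
    tp = len(matches)
    fp = len(unmatched_c)
    fn = claimed.count(False)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fp > 0:
        precision, pdef = tp / (tp + fp), True
    else:
        precision, pdef = 1.0, False
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        matches=matches,
        unmatched_candidates=sorted(unmatched_c),
        unmatched_balls=[i for i, c in enumerate(claimed) if not c],
        precision_defined=pdef,
    )


def near_misses(
    cands: Sequence[SynapseCandidate],
    balls: Sequence[BallAnnotation],
    result: EvalResult,
) -> list[tuple[int, int, float]]:
    """Flag unmatched candidate/ball pairs whose centroid distance is below
    twice the ball radius without overlapping — likely geometric
    disagreements worth manual review.  Returns (cand id, ball index, dist)."""
    unmatched_ball_set = set(result.unmatched_balls)
    unmatched_cand_set = set(result.unmatched_candidates)
    flagged = []
    for cand in cands:
        if cand.id not in unmatched_cand_set:
            continue
        for bi in unmatched_ball_set:
            ball = balls[bi]
            d = _centroid_dist(cand, ball)
            if d < 2 * ball.radius_vox and not ball_overlaps_candidate(ball, cand):
                flagged.append((cand.id, bi, d))
    return flagged


def pr_curve(
    prob: ProbabilityMap,
    balls: Sequence[BallAnnotation],
    cfg: PostprocessConfig | None = None,
    thresholds: Sequence[float] | None = None,
) -> list[tuple[float, EvalResult]]:
    """Detect + match at a sweep of core thresholds.

    The smoothed probability map is computed once and shared; only the
    thresholding, component and growth stages rerun per threshold.  Border
    exclusion is applied to the balls before matching.
    """
    if cfg is None:
        cfg = PostprocessConfig()
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    for t in thresholds:
        if not 0 < t < 1:
            raise ValueError(f"thresholds must lie in (0, 1), got {t}")
    smoothed = smooth_probability(prob, "synapse", cfg.smoothing_sigma_vox)
    kept = exclude_border(balls, prob.shape)
    out = []
    from dataclasses import replace

    for t in thresholds:
        c = replace(cfg, core_threshold=t, relax_threshold=min(cfg.relax_threshold, t))
        cands = detect(prob, c, smoothed=smoothed)
        out.append((float(t), match(cands, kept)))
    return out


# dense at the low end where smoothing leaves thin-sheet probability peaks
DEFAULT_THRESHOLDS = (
    0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98,
)


def best_operating_point(curve: Sequence[tuple[float, EvalResult]]) -> tuple[float, EvalResult]:
    """Operating point maximising F1 (ties toward higher threshold)."""
    def f1(r: EvalResult) -> float:
        if r.precision + r.recall == 0:
            return 0.0
        return 2 * r.precision * r.recall / (r.precision + r.recall)

    return max(curve, key=lambda tr: (f1(tr[1]), tr[0]))


def curve_to_dataframe(curve: Sequence[tuple[float, EvalResult]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": t,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "precision": r.precision,
                "recall": r.recall,
            }
            for t, r in curve
        ]
    )


def curve_to_csv(curve, path) -> None:
    curve_to_dataframe(curve).to_csv(path, index=False)


def result_to_json(result: EvalResult, path) -> None:
    with open(path, "w") as f:
        json.dump(result.to_dict(), f, indent=2)


def plot_pr_curve(curve: Sequence[tuple[float, EvalResult]], path) -> None:
    """Plot precision vs recall with threshold annotations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    rec = [r.recall for _, r in curve]
    prec = [r.precision for _, r in curve]
    ax.plot(rec, prec, "o-")
    for (t, r) in curve:
        ax.annotate(f"{t:g}", (r.recall, r.precision), fontsize=8,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.05)
    ax.set_ylim(0, 1.05)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
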