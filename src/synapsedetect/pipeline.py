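"""End-to-end pipeline: features -> forest prediction -> detection -> report.

A :class:`PipelineConfig` bundles the sub-configurations and I/O paths into
one YAML-serializable document; :func:`run_pipeline` executes the chain and
writes the candidate CSV, label volume, HTML report and a machine-readable
run summary with a provenance block (config echo, seed, version).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .classify import (
    ForestConfig,
    TrainedModel,
    load_model,
    predict_blockwise,
    save_model,
    train,
)
from .features import FeatureSpec, compute_feature_stack
from .postprocess import (
    PostprocessConfig,
    candidates_to_csv,
    candidates_to_label_volume,
)
from .volume import read_labels, read_volume, write_volume

log = logging.getLogger("synapsedetect")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    volume_path: str | None = None
    dataset_name: str | None = None
    labels_path: str | None = None
    model_path: str | None = None  # load if exists and no labels, else save here
    out_dir: str = "synapsedetect_out"
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    forest: ForestConfig = field(default_factory=ForestConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    block_shape: tuple[int, int, int] = (64, 128, 128)

    def to_yaml(self, path) -> None:
        doc = {
            "volume_path": self.volume_path,
            "dataset_name": self.dataset_name,
            "labels_path": self.labels_path,
            "model_path": self.model_path,
            "out_dir": self.out_dir,
            "feature_spec": self.feature_spec.to_records(),
            "forest": asdict(self.forest),
            "postprocess": asdict(self.postprocess),
            "block_shape": list(self.block_shape),
        }
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f)
        kwargs = dict(doc)
        if "feature_spec" in doc and doc["feature_spec"] is not None:
            kwargs["feature_spec"] = FeatureSpec.from_records(doc["feature_spec"])
        if "forest" in doc and doc["forest"] is not None:
            kwargs["forest"] = ForestConfig(**doc["forest"])
        if "postprocess" in doc and doc["postprocess"] is not None:
            kwargs["postprocess"] = PostprocessConfig(**doc["postprocess"])
        if "block_shape" in doc and doc["block_shape"] is not None:
            kwargs["block_shape"] = tuple(doc["block_shape"])
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return out, time.perf_counter() - t0
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig, write_report: bool = True):
    """Run the full detection chain described by ``cfg``.

    Requires either a trained model on disk (``model_path``) or sparse
    training labels (``labels_path``).  Returns the candidate list; all
    artifacts are written under ``cfg.out_dir``.
    """
    if cfg.volume_path is None:
        raise PipelineError("stage 'validate' failed: config field 'volume_path' is missing")
    model_exists = cfg.model_path is not None and Path(cfg.model_path).exists()
    if not model_exists and cfg.labels_path is None:
        raise PipelineError(
            "stage 'validate' failed: neither a trained model ('model_path') "
            "nor training labels ('labels_path') were provided"
        )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    vol, timings["read"] = _stage("read")(read_volume)(cfg.volume_path, cfg.dataset_name)

    if model_exists:
        model, timings["load_model"] = _stage("load_model")(load_model)(cfg.model_path)
    else:
        def _train():
            labels = read_labels(cfg.labels_path)
            stack = compute_feature_stack(vol, cfg.feature_spec)
            return train(stack, labels, cfg.forest)

        model, timings["train"] = _stage("train")(_train)()
        if cfg.model_path is not None:
            save_model(model, cfg.model_path)

    prob, timings["predict"] = _stage("predict")(predict_blockwise)(
        model, vol, cfg.feature_spec, cfg.block_shape
    )

    from .postprocess import detect

    cands, timings["detect"] = _stage("detect")(detect)(prob, cfg.postprocess)

    def _export():
        candidates_to_csv(cands, out_dir / "candidates.csv")
        write_volume(candidates_to_label_volume(cands, vol.shape), out_dir / "label_volume.h5")
        if write_report:
            from .report import render_report

            render_report(cands, vol, out_dir)

    _, timings["export"] = _stage("export")(_export)()

    summary = {
        "version": __version__,
        "n_candidates": len(cands),
        "volume_shape": list(vol.shape),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "model_metadata": dict(model.metadata),
        "config": {
            "volume_path": cfg.volume_path,
            "labels_path": cfg.labels_path,
            "model_path": cfg.model_path,
            "feature_spec": cfg.feature_spec.to_records(),
            "forest": asdict(cfg.forest),
            "postprocess": asdict(cfg.postprocess),
            "block_shape": list(cfg.block_shape),
        },
    }
    with open(out_dir / "run_summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    cfg.to_yaml(out_dir / "config_echo.yaml")
    return cands, prob
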