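"""End-to-end orchestration: preprocess -> segment -> post-process ->
features -> export, as one reproducible, manifest-tracked run.

The hand-off between segmentation and feature extraction is the GeoJSON
polygon file rather than label masks: polygons are orders of magnitude
smaller than per-pixel masks at slide scale, and every downstream consumer
(feature extraction, interactive viewers) reads them directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import io_formats, morphometrics, preprocess
from .flow_postprocess import (
    FlowField,
    assign_types,
    cluster_terminals,
    follow_flows,
    remove_small,
)
from .model import NetworkOutput, SegModel, load_checkpoint, predict_image
from .synthetic import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "segment_output", "segment_image", "run"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; the seed and config are recorded
    in the output manifest so the run is reproducible."""

    input_path: str | Path
    output_dir: str | Path
    checkpoint: str | Path | None = None
    patch_size: int = preprocess.DEFAULT_PATCH_SIZE
    min_tissue_fraction: float = preprocess.DEFAULT_MIN_TISSUE_FRACTION
    min_std: float = preprocess.DEFAULT_MIN_STD
    inference_margin: int = 8
    fg_threshold: float = 0.5
    min_instance_area: int = 10
    flow_steps: int = 200
    flow_step_size: float = 1.0
    merge_radius: int = 2
    microns_per_pixel: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise ValueError(f"input path does not exist: {self.input_path}")
        if self.checkpoint is not None and not Path(self.checkpoint).exists():
            raise ValueError(f"checkpoint does not exist: {self.checkpoint}")


def segment_output(
    output: NetworkOutput,
    fg_threshold: float = 0.5,
    flow_steps: int = 200,
    flow_step_size: float = 1.0,
    merge_radius: int = 2,
    min_instance_area: int = 10,
) -> tuple[np.ndarray, dict[int, int]]:
    """Instances + classes from raw network outputs.

    Foreground is thresholded, the predicted flow is re-normalised to unit
    length on foreground, pixels are advected along it and clustered into
    sinks, small specks are removed, and each instance is typed by the
    summed class probabilities of its pixels.
    """
    fg = output.foreground > fg_threshold
    flow = output.flow.copy()
    norm = np.hypot(flow[0], flow[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        flow = np.where(norm > 1e-6, flow / norm, 0.0)
    flow[:, ~fg] = 0.0
    field = FlowField(dist=np.maximum(output.dist, 0.0), flow=flow)
    terminals = follow_flows(field, fg, n_steps=flow_steps, step_size=flow_step_size)
    instances = cluster_terminals(terminals, fg, merge_radius=merge_radius)
    instances = remove_small(instances, min_area=min_instance_area)
    classes = assign_types(instances, output.class_probs)
    return instances, classes


def segment_image(
    model: SegModel,
    image: np.ndarray,
    margin: int = 8,
    **post_kwargs,
) -> tuple[np.ndarray, dict[int, int], NetworkOutput]:
    """Tiled inference followed by flow post-processing."""
    out = predict_image(model, image, margin=margin)
    instances, classes = segment_output(out, **post_kwargs)
    return instances, classes, out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline on one image; returns the run manifest.

    Stages: tile + filter patches, tiled network inference, flow
    post-processing, GeoJSON export, per-nucleus morphometrics CSV, and a
    composition summary (class percentages + Shannon index).  Every output
    file is referenced in the returned manifest, which is also written as
    ``manifest.json``.  Outputs are pure functions of (inputs, config,
    seed); only the manifest timestamp varies between identical runs.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()},
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed on {config.input_path}") from exc

    try:
        image = iio.imread(config.input_path)
    except Exception as exc:  # pragma: no cover - I/O failure path
        fail("load", exc)
    logger.info("loaded %s: %s", config.input_path, image.shape)

    # --- preprocess -------------------------------------------------------
    try:
        grid = preprocess.tile_image(image, patch_size=config.patch_size)
        grid = preprocess.filter_patches(
            grid, image, config.min_tissue_fraction, config.min_std
        )
    except Exception as exc:
        fail("preprocess", exc)
    kept = grid.kept
    manifest["stages"]["preprocess"] = {
        "patches_total": len(grid.origins),
        "patches_kept": len(kept),
    }
    rows = ["row\tcol\tkept\treason"]
    for o in grid.origins:
        reasons = grid.reasons.get(o, ())
        rows.append(f"{o[0]}\t{o[1]}\t{not reasons}\t{','.join(reasons)}")
    (out_dir / "patches.tsv").write_text("\n".join(rows) + "\n")
    manifest["outputs"].append("patches.tsv")
    logger.info("preprocess: kept %d/%d patches", len(kept), len(grid.origins))

    # --- segmentation -----------------------------------------------------
    # Predicted fields from all kept patches are stitched into canvas-sized
    # arrays and post-processed once, so nuclei straddling patch borders are
    # recovered as single instances rather than per-patch fragments.
    instances = np.zeros(image.shape[:2], dtype=np.int32)
    classes: dict[int, int] = {}
    if kept and config.checkpoint is not None:
        try:
            model = load_checkpoint(config.checkpoint)
            h, w = image.shape[:2]
            fields = NetworkOutput(
                foreground=np.zeros((h, w)),
                class_probs=np.zeros((6, h, w)),
                dist=np.zeros((h, w)),
                flow=np.zeros((2, h, w)),
            )
            fields.class_probs[0] = 1.0  # background where nothing was predicted
            for origin in kept:
                patch = preprocess.extract_patch(image, grid, origin)
                out = predict_image(model, patch, margin=config.inference_margin)
                r, c = origin
                ph, pw = out.foreground.shape
                fields.foreground[r : r + ph, c : c + pw] = out.foreground
                fields.class_probs[:, r : r + ph, c : c + pw] = out.class_probs
                fields.dist[r : r + ph, c : c + pw] = out.dist
                fields.flow[:, r : r + ph, c : c + pw] = out.flow
            instances, classes = segment_output(
                fields,
                fg_threshold=config.fg_threshold,
                flow_steps=config.flow_steps,
                flow_step_size=config.flow_step_size,
                merge_radius=config.merge_radius,
                min_instance_area=config.min_instance_area,
            )
        except Exception as exc:
            fail("segment", exc)
    manifest["stages"]["segment"] = {"nuclei": len(classes)}
    logger.info("segment: %d nuclei", len(classes))

    # --- export + features ------------------------------------------------
    try:
        collection = io_formats.instances_to_geojson(instances, classes)
        (out_dir / "nuclei.geojson").write_text(json.dumps(collection))
        manifest["outputs"].append("nuclei.geojson")

        feat_rows = []
        from scipy import ndimage as _ndi

        slices = _ndi.find_objects(instances)
        for lab, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            mask = instances[sl] == lab
            feats = morphometrics.extract_features(
                mask, microns_per_pixel=config.microns_per_pixel
            )
            feat_rows.append(
                {
                    "nucleus_id": lab,
                    "class": CLASS_NAMES[classes[lab] - 1],
                    **feats.as_dict(),
                }
            )
        pd.DataFrame(
            feat_rows,
            columns=["nucleus_id", "class", *morphometrics.FEATURE_NAMES],
        ).to_csv(out_dir / "features.csv", index=False)
        manifest["outputs"].append("features.csv")

        comp = morphometrics.composition(classes.values())
        comp_out = {
            "counts": comp.counts,
            "percentages": comp.percentages,
            "shannon_entropy": comp.shannon_entropy,
        }
        (out_dir / "composition.json").write_text(json.dumps(comp_out, indent=1))
        manifest["outputs"].append("composition.json")
    except Exception as exc:
        fail("features", exc)
    manifest["stages"]["features"] = {"rows": len(classes)}

    manifest["outputs"].append("manifest.json")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
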