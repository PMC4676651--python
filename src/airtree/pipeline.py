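"""One-call pipeline driver: crop → TDF → centerline → segmentation → metrics.

Parameters come from a named preset (a plain-text key = value file shipped
with the package) optionally overridden per call.  Every stage's
parameters and wall-clock time are recorded in a structured log, and the
segmentation is mapped back to the uncropped voxel grid before it is
returned or written.
"""

from __future__ import annotations

import configparser
import importlib.resources
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import AirtreeError, BinaryMask, ParameterError, VolumeImage
from .centerline import extract_centerline
from .grow import segment_from_centerline
from .io_formats import read_metaimage, write_centerline_polydata, write_metaimage
from .tdf import auto_crop, tube_probability
from .tree import CenterlineTree
from .tree_metrics import branches_per_generation, mask_volume, total_length


def load_preset(name: str, path: str | None = None) -> dict:
    """Load a named parameter preset from the packaged (or given) config file."""
    cfg = configparser.ConfigParser(inline_comment_prefixes=("#",))
    if path is None:
        text = importlib.resources.files("airtree").joinpath("presets.cfg").read_text()
        cfg.read_string(text)
    else:
        if not cfg.read(path):
            raise ParameterError(f"cannot read preset file {path}")
    if name not in cfg:
        raise ParameterError(f"unknown preset {name!r}; have {cfg.sections()}")
    sec = cfg[name]
    return {
        "air_threshold_hu": sec.getfloat("air_threshold_hu"),
        "scales_mm": tuple(float(s) for s in sec.get("scales_mm").split(",")),
        "contrast_hu": sec.getfloat("contrast_hu"),
        "probability_threshold": sec.getfloat("probability_threshold"),
        "prune_length_mm": sec.getfloat("prune_length_mm"),
        "dilation_radius_mm": sec.getfloat("dilation_radius_mm"),
        "hu_ceiling": sec.getfloat("hu_ceiling"),
        "gradient_factor": sec.getfloat("gradient_factor"),
        "intensity_margin_hu": sec.getfloat("intensity_margin_hu"),
        "connectivity": sec.getint("connectivity"),
        "lower_hu": sec.getfloat("lower_hu"),
        "upper_hu": sec.getfloat("upper_hu"),
    }


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    preset: str = "lung-airways"
    overrides: dict = field(default_factory=dict)
    params: dict = field(init=False)

    def __post_init__(self):
        self.params = load_preset(self.preset)
        unknown = set(self.overrides) - set(self.params)
        if unknown:
            raise ParameterError(f"unknown parameter overrides: {sorted(unknown)}")
        self.params.update(self.overrides)
        p = self.params
        if not 0 < p["probability_threshold"] < 1:
            raise ParameterError("probability_threshold must lie in (0, 1)")
        if p["dilation_radius_mm"] < 0 or p["prune_length_mm"] < 0:
            raise ParameterError("radii and prune length must be >= 0")
        if p["connectivity"] not in (6, 26):
            raise ParameterError("connectivity must be 6 or 26")


@dataclass
class PipelineResult:
    mask: BinaryMask
    tree: CenterlineTree
    report: dict


def run_pipeline(volume: VolumeImage | str,
                 config: PipelineConfig | None = None,
                 out_dir: str | None = None) -> PipelineResult:
    """Run the full airway pipeline on a volume (object or .mhd path).

    Returns the segmentation mask on the *original* grid, the centerline
    tree (world mm), and a report with per-generation branch counts, total
    centerline length, segmented volume, and a stage log of parameters and
    timings.  Raises the failing stage's error annotated with its name.
    """
    config = config or PipelineConfig()
    p = config.params
    if isinstance(volume, str):
        volume = read_metaimage(volume)
    log: list[dict] = []

    def stage(name, fn, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(**kw)
        except AirtreeError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3),
                    "params": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in kw.items()
                               if isinstance(v, (int, float, str, tuple))}})
        return result

    crop = stage("auto_crop", auto_crop, volume=volume,
                 air_threshold_hu=p["air_threshold_hu"])
    tpm = stage("tube_probability", tube_probability, volume=crop.volume,
                radii_mm=p["scales_mm"], contrast_hu=p["contrast_hu"])
    tree = stage("extract_centerline", extract_centerline, tpm=tpm,
                 volume=crop.volume,
                 probability_threshold=p["probability_threshold"],
                 min_spur_length_mm=p["prune_length_mm"])
    mask_c = stage("segment_from_centerline", segment_from_centerline,
                   volume=crop.volume, tree=tree,
                   dilation_radius_mm=p["dilation_radius_mm"],
                   hu_ceiling=p["hu_ceiling"],
                   gradient_factor=p["gradient_factor"],
                   intensity_margin_hu=p["intensity_margin_hu"],
                   connectivity=p["connectivity"])
    mask = crop.embed_mask(mask_c, volume.shape, volume.origin)

    hist = branches_per_generation(tree)
    report = {
        "preset": config.preset,
        "branches_per_generation": {str(g): c for g, c in sorted(hist.counts.items())},
        "total_branches": hist.total_branches,
        "max_generation": hist.max_generation,
        "total_length_mm": total_length(tree),
        "segmented_volume_mm3": mask_volume(mask),
        "crop_offset_voxels": list(crop.offset_voxels),
        "stages": log,
    }
    if out_dir is not None:
        import json
        import os
        os.makedirs(out_dir, exist_ok=True)
        write_metaimage(mask, os.path.join(out_dir, "segmentation.mhd"))
        write_centerline_polydata(tree, os.path.join(out_dir, "centerline.vtk"))
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return PipelineResult(mask, tree, report)
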