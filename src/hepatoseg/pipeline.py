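"""End-to-end orchestration of the four segmentation stages.

Runs liver segmentation, nodule/vessel extraction, vein identification and
Couinaud partitioning in sequence, writing each stage's masks and one
consolidated JSON report (mixture parameters, thresholds, branch heights and
labels, plane coefficients, per-segment volumes).  Any stage failure aborts
the remaining stages with a structured error naming the stage.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import couinaud as _couinaud
from . import vein_id as _vein_id
from .gauss_models import decompose_mixture, grow_thresholds
from .liver_levelset import LevelSetParams, segment_liver
from .mixture_seg import GrowConfig, segment_nodules, segment_vessels
from .phantom import histogram_of
from .volume_io import (
    Mask,
    Volume,
    read_mask,
    read_volume,
    write_labelmap,
    write_mask,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "run_pipeline_arrays"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    volume_path: str
    init_mask_path: str | None = None
    init_slice_index: int = 0
    out_dir: str = "."
    params: LevelSetParams = field(default_factory=LevelSetParams)
    grow: GrowConfig = field(default_factory=GrowConfig)
    stages: tuple[str, ...] = ("liver", "structures", "veins", "couinaud")
    liver_mask_path: str | None = None    # precomputed, when stage toggled off
    vessels_mask_path: str | None = None
    log_level: str = "INFO"


def _gauss_dict(g) -> dict:
    return {"K": g.K, "mu": g.mu, "sigma": g.sigma}


def run_pipeline_arrays(
    volume: Volume,
    init_slice_index: int | None = None,
    init_mask2d: np.ndarray | None = None,
    params: LevelSetParams | None = None,
    grow: GrowConfig | None = None,
    liver: Mask | None = None,
    stages: tuple[str, ...] = ("liver", "structures", "veins", "couinaud"),
) -> dict:
    """In-memory pipeline; returns a dict of stage outputs plus the report.

    ``liver`` may be supplied precomputed when the liver stage is toggled
    off.  Stages always execute in the fixed order liver -> structures ->
    veins -> couinaud; each stage requires its predecessor's output.
    """
    params = params or LevelSetParams()
    grow = grow or GrowConfig()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "params": asdict(params)}
    out: dict = {"report": report}

    if "liver" in stages:
        if init_mask2d is None or init_slice_index is None:
            raise PipelineError("liver", "initial mask and slice are required")
        try:
            liver = segment_liver(volume, init_slice_index, init_mask2d, params)
        except (ValueError, RuntimeError, IndexError) as exc:
            raise PipelineError("liver", str(exc)) from exc
    elif liver is None:
        raise PipelineError("liver", "no liver mask provided and stage off")
    out["liver"] = liver
    report["liver_voxels"] = int(liver.n_voxels)

    vessels = nodules = None
    mixture = None
    if "structures" in stages:
        try:
            hist = histogram_of(volume, liver)
            mixture = decompose_mixture(hist)
            vessels = segment_vessels(volume, liver, mixture, grow)
            nodules = segment_nodules(volume, liver, mixture, grow)
        except (ValueError, RuntimeError) as exc:
            raise PipelineError("structures", str(exc)) from exc
        out["vessels"], out["nodules"] = vessels, nodules
        report["mixture"] = {
            "G_l": _gauss_dict(mixture.G_l),
            "G_c": _gauss_dict(mixture.G_c),
            "G_r": _gauss_dict(mixture.G_r),
            "l_present": mixture.l_present,
            "r_present": mixture.r_present,
        }
        thr = {}
        for side, flag in (("left", mixture.l_present),
                           ("right", mixture.r_present)):
            if flag:
                t = grow_thresholds(mixture, side, grow.proportion)
                thr[side] = {"T_L": t.T_L, "T_H": t.T_H}
        report["grow_thresholds"] = thr

    branch_set = None
    if "veins" in stages:
        if vessels is None:
            raise PipelineError("veins", "no vessel mask available")
        try:
            branch_set = _vein_id.identify_veins(vessels, liver)
        except ValueError as exc:
            raise PipelineError("veins", str(exc)) from exc
        out["veins"] = branch_set
        report["branches"] = {
            name: {
                "height_mm": branch_set.heights_mm.get(name),
                "voxels": int(b.n_voxels),
            }
            for name, b in branch_set.branches.items()
        }
        report["portal_voxels"] = int(branch_set.portal.n_voxels)
        report["auxiliary_voxels"] = int(branch_set.auxiliary.n_voxels)

    if "couinaud" in stages:
        if branch_set is None:
            raise PipelineError("couinaud", "vein identification missing")
        try:
            planes = [
                _couinaud.plane_from_mask(branch_set.branches[name],
                                          "near_vertical")
                for name in ("right", "middle", "left")
                if name in branch_set.branches
            ]
            portal_plane = _couinaud.plane_from_mask(branch_set.portal,
                                                     "near_horizontal")
            cmap = _couinaud.partition_couinaud(liver, planes, portal_plane)
        except (ValueError, _couinaud.DegenerateGeometryError) as exc:
            raise PipelineError("couinaud", str(exc)) from exc
        out["couinaud"] = cmap
        report["planes"] = {
            "hepatic": [list(p.coefficients) for p in planes],
            "portal": list(portal_plane.coefficients),
        }
        report["segment_volumes_ml"] = {
            _couinaud.COUINAUD_LEGEND[k]: v for k, v in cmap.volumes_ml.items()
        }
    return out


def run_pipeline(cfg: PipelineConfig) -> int:
    """File-based pipeline entry point; returns a process exit status."""
    logging.basicConfig(level=cfg.log_level)
    try:
        volume = read_volume(cfg.volume_path)
        init2d = None
        if cfg.init_mask_path:
            init = read_mask(cfg.init_mask_path)
            init2d = (
                init.data[cfg.init_slice_index]
                if init.data.ndim == 3 and init.data.shape[0] > 1
                else init.data.reshape(init.data.shape[-2:])
            )
        liver = read_mask(cfg.liver_mask_path) if cfg.liver_mask_path else None
        out = run_pipeline_arrays(
            volume,
            init_slice_index=cfg.init_slice_index,
            init_mask2d=init2d,
            params=cfg.params,
            grow=cfg.grow,
            liver=liver,
            stages=cfg.stages,
        )
    except (PipelineError, ValueError, OSError) as exc:
        log.error("%s", exc)
        return 1

    os.makedirs(cfg.out_dir, exist_ok=True)
    if "liver" in out:
        write_mask(out["liver"], os.path.join(cfg.out_dir, "liver.mhd"))
    if "vessels" in out:
        write_mask(out["vessels"], os.path.join(cfg.out_dir, "vessels.mhd"))
        write_mask(out["nodules"], os.path.join(cfg.out_dir, "nodules.mhd"))
    if "veins" in out:
        bs = out["veins"]
        lab = np.zeros(out["liver"].shape, dtype=np.uint8)
        legend = {}
        for i, name in enumerate(("right", "middle", "left"), start=1):
            if name in bs.branches:
                lab[bs.branches[name].as_bool()] = i
                legend[i] = name
        lab[bs.portal.as_bool()] = 4
        legend[4] = "portal"
        from .volume_io import LabelMap

        write_labelmap(
            LabelMap(data=lab, spacing=out["liver"].spacing,
                     origin=out["liver"].origin, legend=legend),
            os.path.join(cfg.out_dir, "veins.mhd"),
        )
    if "couinaud" in out:
        write_labelmap(out["couinaud"].labels,
                       os.path.join(cfg.out_dir, "couinaud.mhd"))
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(out["report"], fh, indent=2)
    return 0
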