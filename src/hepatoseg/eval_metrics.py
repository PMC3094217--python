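"""Sliver07-style disparity metrics and human-error-anchored scoring.

Five metrics compare a segmentation against a reference mask:

* VOE  -- volumetric overlap error, percent: ``100 * (1 - |A&B| / |A|B|)``;
* RVD  -- relative volume difference, percent, signed:
  ``100 * (|A| - |B|) / |B|``;
* ASD  -- average symmetric surface distance, mm;
* RMSSD -- symmetric RMS surface distance, mm;
* MSD  -- maximum symmetric surface distance, mm.

Border voxels are mask voxels with at least one 6-neighbour outside the
mask; distances are Euclidean in mm between border-voxel centres, collected
symmetrically from both border sets (no sub-voxel surface model).

Each metric maps to a score in [0, 100] anchored on the mean disagreement
of human experts for that metric: a perfect segmentation scores 100, an
error equal to the human reference scores 75, and the score decreases
linearly with the error, clamped at 0.  The total score -- the mean of the
five -- is the quantity the genetic parameter search maximises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import Mask, same_geometry

__all__ = [
    "MetricReport",
    "HumanErrorRefs",
    "compute_metrics",
    "score_metric",
    "total_score",
]

_METRICS = ("voe", "rvd", "asd", "rmssd", "msd")


@dataclass
class HumanErrorRefs:
    """Per-metric mean human expert errors (strictly positive).

    These constants are study configuration, not part of the method: they
    must be supplied from the evaluation campaign in use.
    """

    e_voe: float
    e_rvd: float
    e_asd: float
    e_rmssd: float
    e_msd: float

    def __post_init__(self) -> None:
        for name in ("e_voe", "e_rvd", "e_asd", "e_rmssd", "e_msd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.e_voe, self.e_rvd, self.e_asd, self.e_rmssd, self.e_msd)


@dataclass
class MetricReport:
    voe: float
    rvd: float
    asd: float
    rmssd: float
    msd: float
    scores: dict[str, float]
    total_score: float

    def metric_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in _METRICS}


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask."""
    m = mask.astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return m & ~eroded


def compute_metrics(seg: Mask, ref: Mask) -> tuple[float, float, float, float, float]:
    """The five disparity metrics ``(voe, rvd, asd, rmssd, msd)``.

    Raises ``ValueError`` for an empty segmentation: overlap metrics are
    still defined (voe 100, rvd -100) but the surface distances are not,
    and the caller must treat the case explicitly.
    """
    if not same_geometry(seg, ref):
        raise ValueError("segmentation and reference geometries differ")
    a = seg.as_bool()
    b = ref.as_bool()
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("reference mask is empty")
    na = int(a.sum())
    if na == 0:
        raise ValueError(
            "empty segmentation: voe=100, rvd=-100, surface distances undefined"
        )
    inter = int((a & b).sum())
    union = int((a | b).sum())
    voe = 100.0 * (1.0 - inter / union)
    rvd = 100.0 * (na - nb) / nb

    spacing = np.asarray(seg.spacing, dtype=float)
    pa = np.argwhere(border_voxels(a)) * spacing
    pb = np.argwhere(border_voxels(b)) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    d = np.concatenate([d_ab, d_ba])
    asd = float(d.mean())
    rmssd = float(np.sqrt(np.mean(d**2)))
    msd = float(d.max())
    return voe, rvd, asd, rmssd, msd


def score_metric(error_value: float, human_error: float) -> float:
    """Linear human-anchored score: 100 at zero error, 75 at the human
    error, decreasing linearly and clamped at 0."""
    if human_error <= 0:
        raise ValueError("human_error must be strictly positive")
    return max(0.0, 100.0 - 25.0 * abs(error_value) / human_error)


def total_score(
    metrics: tuple[float, float, float, float, float],
    refs: HumanErrorRefs,
) -> MetricReport:
    """Score each metric and average the five scores.

    The signed RVD is scored by absolute value; the other metrics are
    non-negative by construction.
    """
    voe, rvd, asd, rmssd, msd = metrics
    scores = {
        m: score_metric(v, e)
        for m, v, e in zip(_METRICS, metrics, refs.as_tuple())
    }
    return MetricReport(
        voe=voe, rvd=rvd, asd=asd, rmssd=rmssd, msd=msd,
        scores=scores,
        total_score=float(np.mean(list(scores.values()))),
    )
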