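"""Nodule and vessel segmentation by mixture-driven region growing.

Inside the segmented liver, adipose nodules (darker than parenchyma) and
vessels (brighter) are extracted by a dual-threshold region growing: voxels
beyond the strict seed threshold belong to the class outright; the region
then aggregates any connected neighbour beyond the looser acceptance
threshold.  Both thresholds come from the fitted three-Gaussian mixture
(:func:`hepatoseg.gauss_models.grow_thresholds`): the seed threshold is the
intensity where the class holds at least 70% of the class+parenchyma
density, the acceptance threshold the intersection of the two components.

Only adipose (hypodense) nodules are segmented; hyperdense lesions are out
of scope.  Growing runs in 3D with 26-connectivity by default, because thin
oblique vessels fragment under 6-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .gauss_models import DegenerateModelError, MixtureModel, grow_thresholds
from .volume_io import Mask, Volume

__all__ = ["GrowConfig", "grow_region", "segment_nodules", "segment_vessels"]

log = logging.getLogger(__name__)

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GrowConfig:
    proportion: float = 0.70
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0.5 < self.proportion < 1.0:
            raise ValueError("proportion must lie in (0.5, 1)")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def grow_region(
    volume: Volume,
    domain: Mask,
    seed_rule: Callable[[np.ndarray], np.ndarray],
    accept_rule: Callable[[np.ndarray], np.ndarray],
    connectivity: int = 26,
) -> Mask:
    """Flood fill from seed voxels through acceptable voxels.

    Returns the set of domain voxels reachable from ``seed_rule`` voxels
    through ``accept_rule`` voxels under the chosen connectivity; computed
    as iterated dilation-and-mask to a fixed point.  The seed rule must
    select a subset of the accept rule.  No seeds yields an empty mask.
    """
    data = np.asarray(volume.data)
    dom = domain.as_bool()
    if not dom.any():
        raise ValueError("domain is empty")
    seeds = seed_rule(data) & dom
    accept = accept_rule(data) & dom
    if (seeds & ~accept).any():
        raise ValueError("seed rule must be at least as strict as accept rule")
    geom = dict(spacing=volume.spacing, origin=volume.origin)
    if not seeds.any():
        log.info("region growing: no seed voxels")
        return Mask(data=np.zeros(data.shape, np.uint8), **geom)
    # one labelled pass over the acceptable set is the flood-fill fixed point
    labels, _ = ndimage.label(accept, structure=_STRUCTS[connectivity])
    hit = np.unique(labels[seeds])
    grown = np.isin(labels, hit[hit > 0])
    return Mask(data=grown.astype(np.uint8), **geom)


def segment_nodules(
    volume: Volume,
    liver: Mask,
    m: MixtureModel,
    cfg: GrowConfig | None = None,
) -> Mask:
    """Adipose nodules: seeds ``g < T_L^lc``, acceptance ``g < T_H^lc``."""
    cfg = cfg or GrowConfig()
    geom = dict(spacing=volume.spacing, origin=volume.origin)
    if not m.l_present:
        log.info("no adipose nodule component in the mixture")
        return Mask(data=np.zeros(volume.shape, np.uint8), **geom)
    try:
        t = grow_thresholds(m, "left", cfg.proportion)
    except DegenerateModelError:
        log.info("nodule thresholds degenerate; returning empty mask")
        return Mask(data=np.zeros(volume.shape, np.uint8), **geom)
    return grow_region(
        volume,
        liver,
        seed_rule=lambda g: g < t.T_L,
        accept_rule=lambda g: g < t.T_H,
        connectivity=cfg.connectivity,
    )


def segment_vessels(
    volume: Volume,
    liver: Mask,
    m: MixtureModel,
    cfg: GrowConfig | None = None,
) -> Mask:
    """Vessels: seeds ``g > T_H^rc``, acceptance ``g > T_L^rc``."""
    cfg = cfg or GrowConfig()
    geom = dict(spacing=volume.spacing, origin=volume.origin)
    if not m.r_present:
        log.info("no vessel component in the mixture")
        return Mask(data=np.zeros(volume.shape, np.uint8), **geom)
    try:
        t = grow_thresholds(m, "right", cfg.proportion)
    except DegenerateModelError:
        log.info("vessel thresholds degenerate; returning empty mask")
        return Mask(data=np.zeros(volume.shape, np.uint8), **geom)
    return grow_region(
        volume,
        liver,
        seed_rule=lambda g: g > t.T_H,
        accept_rule=lambda g: g > t.T_L,
        connectivity=cfg.connectivity,
    )
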