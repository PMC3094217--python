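"""Identification of the hepatic main branches and the portal vein.

Three main branches are assumed to compose the hepatic veins (the dominant
anatomical variant), running predominantly vertically from the upper part of
the liver downwards.  They are tracked without considering bifurcations:

1. pick the most superior slice still containing unprocessed vessels;
2. take the biggest connected component of that slice as a candidate;
3. merge the component of the next inferior slice with the biggest footprint
   overlap into the candidate;
4. repeat until no overlap remains;
5. accept the candidate if it spans more than 15% of the liver height
   (measured in mm), otherwise discard it;
6. repeat until three branches are found or the seeds are exhausted.

Accepted branches are labelled right / middle / left by a clock rule on
their coronal projections: viewed from anterior with 12 o'clock superior,
they appear clockwise in the order right, middle, left around the central
axis of the thorax (approximated here by the liver centroid, with the
radiological convention that the patient's right lies at negative x
displacement from that centre).

The portal vein is the biggest connected component of the remaining vessels;
every other residual component is merged into a hepatic branch it touches or
kept as auxiliary, so the vessel voxels are conserved exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Mask

__all__ = [
    "BranchSet",
    "track_main_branches",
    "classify_clockwise",
    "extract_portal",
    "identify_veins",
]

log = logging.getLogger(__name__)

_S26 = ndimage.generate_binary_structure(3, 3)
_S8 = ndimage.generate_binary_structure(2, 2)

LABELS = ("right", "middle", "left")


@dataclass
class BranchSet:
    branches: dict[str, Mask] = field(default_factory=dict)
    portal: Mask | None = None
    auxiliary: Mask | None = None
    heights_mm: dict[str, float] = field(default_factory=dict)


def _slice_components(slice_mask: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(slice_mask, structure=_S8)


def _biggest_component(labels: np.ndarray, n: int) -> np.ndarray:
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(-sizes)
    best = order[0] + 1
    # tie on size: smaller centroid x wins (determinism)
    ties = [i + 1 for i in order if sizes[i] == sizes[best - 1]]
    if len(ties) > 1:
        cents = ndimage.center_of_mass(
            np.ones_like(labels), labels, ties
        )
        best = ties[int(np.argmin([c[1] for c in cents]))]
    return labels == best


def track_main_branches(
    vessels: Mask,
    liver: Mask,
    min_height_fraction: float = 0.15,
    n_branches: int = 3,
) -> list[Mask]:
    """Track up to ``n_branches`` tall vertical vessel branches.

    Candidate height is counted in slices times the z spacing and compared
    against the liver height in mm.  Processed candidates (accepted or not)
    are removed from future seed selection, which guarantees termination.
    """
    v = vessels.as_bool()
    if not v.any():
        raise ValueError("vessels mask is empty")
    lz = np.flatnonzero(liver.as_bool().any(axis=(1, 2)))
    if lz.size == 0:
        raise ValueError("liver mask is empty")
    sz = vessels.spacing[0]
    liver_height = (lz[-1] - lz[0] + 1) * sz

    remaining = v.copy()
    accepted: list[Mask] = []
    geom = dict(spacing=vessels.spacing, origin=vessels.origin)
    while len(accepted) < n_branches and remaining.any():
        # step 1: most superior slice with unprocessed vessels
        zs = np.flatnonzero(remaining.any(axis=(1, 2)))
        k = int(zs[-1])
        # step 2: biggest component of that slice
        labels, n = _slice_components(remaining[k])
        footprint = _biggest_component(labels, n)
        cand = np.zeros_like(remaining)
        cand[k] = footprint
        z_top = k
        # steps 3-4: merge the maximally overlapping component downward
        for kk in range(k - 1, -1, -1):
            labels, n = _slice_components(remaining[kk])
            if n == 0:
                break
            overlaps = ndimage.sum_labels(
                footprint.astype(float), labels, range(1, n + 1)
            )
            if overlaps.max() <= 0:
                break
            sizes = ndimage.sum_labels(
                np.ones_like(labels, float), labels, range(1, n + 1)
            )
            # biggest overlap; ties by larger component, then smaller x
            best_overlap = overlaps.max()
            ties = np.flatnonzero(overlaps == best_overlap) + 1
            if ties.size > 1:
                big = sizes[ties - 1].max()
                ties = ties[sizes[ties - 1] == big]
            if ties.size > 1:
                cents = ndimage.center_of_mass(
                    np.ones_like(labels, float), labels, list(ties)
                )
                ties = ties[[int(np.argmin([c[1] for c in cents]))]]
            chosen = int(ties[0])
            footprint = labels == chosen
            cand[kk] = footprint
        z_bottom = int(np.flatnonzero(cand.any(axis=(1, 2)))[0])
        height = (z_top - z_bottom + 1) * sz
        remaining &= ~cand
        # step 5: the 15%-of-liver-height acceptance rule
        if height > min_height_fraction * liver_height:
            accepted.append(Mask(data=cand.astype(np.uint8), **geom))
        else:
            log.debug(
                "candidate at z=%d rejected: height %.1f mm < %.1f mm",
                k, height, min_height_fraction * liver_height,
            )
    if len(accepted) < n_branches:
        log.warning(
            "only %d of %d hepatic branch candidates accepted",
            len(accepted), n_branches,
        )
    return accepted


def classify_clockwise(
    branches: list[Mask],
    body_axis_x: float | None = None,
    liver: Mask | None = None,
) -> dict[str, Mask]:
    """Label 1-3 branches right / middle / left by the coronal clock rule.

    Branch centroids are projected on the coronal plane (x horizontal, z
    vertical).  The clockwise angle about the thorax axis, viewed from
    anterior with 12 o'clock superior, orders the branches; the first is the
    right branch, then middle, then left.  With fewer than three branches,
    labels are assigned in that order and the missing ones reported.
    """
    if not 1 <= len(branches) <= 3:
        raise ValueError("expected between 1 and 3 branches")
    ref = branches[0]
    sz, _, sx = ref.spacing
    if body_axis_x is None:
        src = liver if liver is not None else None
        if src is not None:
            cz, _, cx = ndimage.center_of_mass(src.as_bool())
        else:
            all_b = np.zeros(ref.shape, bool)
            for b in branches:
                all_b |= b.as_bool()
            cz, _, cx = ndimage.center_of_mass(all_b)
        body_axis_x = cx * sx
        center_z = cz * sz
    else:
        czs = [ndimage.center_of_mass(b.as_bool())[0] for b in branches]
        center_z = (min(czs) - 1.0) * sz  # clock centre below the branches

    angles = []
    for b in branches:
        cz, _, cx = ndimage.center_of_mass(b.as_bool())
        dx = cx * sx - body_axis_x
        dz = cz * sz - center_z
        # clockwise from 12 o'clock seen from anterior: patient right
        # (negative dx) comes first
        angles.append(math.atan2(dx, dz))
    order = np.argsort(angles, kind="stable")
    if len(set(np.round(angles, 12))) < len(angles):
        raise ValueError("branch centroids coincide; clock order undefined")
    out: dict[str, Mask] = {}
    for label, idx in zip(LABELS, order):
        out[label] = branches[int(idx)]
    missing = [lab for lab in LABELS if lab not in out]
    if missing:
        log.warning("missing hepatic branches: %s", ", ".join(missing))
    return out


def extract_portal(
    vessels: Mask, branches: list[Mask]
) -> tuple[Mask, Mask, list[Mask]]:
    """Portal vein, auxiliary vessels and branch masks with residuals merged.

    The portal vein is the biggest connected component of the vessels once
    the hepatic branches are removed.  Every other residual component is
    merged into a branch it touches (26-connectivity) or kept as auxiliary.
    Branches, portal and auxiliary partition the input vessel voxels.
    """
    v = vessels.as_bool()
    geom = dict(spacing=vessels.spacing, origin=vessels.origin)
    branch_arrays = [b.as_bool().copy() for b in branches]
    residual = v.copy()
    for b in branch_arrays:
        residual &= ~b

    portal = np.zeros_like(v)
    aux = np.zeros_like(v)
    if not residual.any():
        log.warning("no vessels remain after removing hepatic branches")
    else:
        labels, n = ndimage.label(residual, structure=_S26)
        sizes = ndimage.sum_labels(np.ones_like(labels, float), labels,
                                   range(1, n + 1))
        portal_lab = int(np.argmax(sizes)) + 1
        portal = labels == portal_lab
        dilated = [
            ndimage.binary_dilation(b, structure=_S26) for b in branch_arrays
        ]
        for lab in range(1, n + 1):
            if lab == portal_lab:
                continue
            comp = labels == lab
            for i, d in enumerate(dilated):
                if (comp & d).any():
                    branch_arrays[i] |= comp
                    break
            else:
                aux |= comp

    merged = [Mask(data=b.astype(np.uint8), **geom) for b in branch_arrays]
    return (
        Mask(data=portal.astype(np.uint8), **geom),
        Mask(data=aux.astype(np.uint8), **geom),
        merged,
    )


def identify_veins(
    vessels: Mask,
    liver: Mask,
    min_height_fraction: float = 0.15,
    n_branches: int = 3,
) -> BranchSet:
    """Full identification: track, classify and extract the portal vein."""
    tracked = track_main_branches(vessels, liver, min_height_fraction,
                                  n_branches)
    if not tracked:
        raise ValueError("no hepatic branch candidates accepted")
    portal, aux, merged = extract_portal(vessels, tracked)
    labelled = classify_clockwise(merged, liver=liver)
    sz = vessels.spacing[0]
    heights = {}
    for name, b in labelled.items():
        zs = np.flatnonzero(b.as_bool().any(axis=(1, 2)))
        heights[name] = float((zs[-1] - zs[0] + 1) * sz) if zs.size else 0.0
    return BranchSet(
        branches=labelled, portal=portal, auxiliary=aux, heights_mm=heights
    )
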