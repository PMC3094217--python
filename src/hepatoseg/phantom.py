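"""Seeded synthetic CT phantom with liver-like structure and ground truth.

The phantom encodes the two anatomical working hypotheses of the pipeline:
the liver parenchyma is roughly homogeneous (near-Gaussian intensities) and
the liver veins lie mainly inside the liver.  The generated scene contains

* a smooth ellipsoid-like liver blob with near-Gaussian parenchyma
  intensities, embedded in a "body" of fine-grained two-phase soft tissue
  (interleaved darker/brighter patches at the 1-2 voxel scale) surrounded
  by air at 0 -- the heterogeneous abdominal surroundings are what makes
  the per-slice parenchyma fit collapse beyond the liver ends, which is the
  stop mechanism of the slice propagation,
* three bright, near-vertical "hepatic" tubes spanning most of the liver
  height plus a near-horizontal bright "portal" trunk entering mid-liver
  (kept strictly intraparenchymal so that hole filling can recover it),
* short bright distractor blobs (vessel fragments below the branch-height
  acceptance rule),
* dark spherical adipose nodules,
* optionally an adjacent iso-intense confounder blob outside the liver,
* optional additive Gaussian noise.

Default intensities (arbitrary CT-like units): background 0, parenchyma
100 +/- 15, vessels 160 +/- 10, nodules 40 +/- 10, confounder 95 +/- 15.
They reproduce the intensity ordering the segmentation relies on
(vessels brighter than parenchyma, adipose nodules darker) with
controllable overlap.

Stress presets reproduce the two documented failure modes of the
Gaussian-parenchyma heuristic: a "peripheral-nodule" phantom (nodule at the
liver border, not recoverable by hole filling) and a "big-nodule" phantom
(nodule volume comparable to the parenchyma, breaking the single-Gaussian
histogram assumption and opening a leak toward an adjacent dark structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .gauss_models import Histogram
from .volume_io import LabelMap, Mask, Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "histogram_of",
    "default_spec",
    "big_nodule_spec",
    "peripheral_nodule_spec",
    "PRESETS",
]

BRANCH_LEGEND = {1: "right", 2: "middle", 3: "left"}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    parenchyma_mean: float = 100.0
    parenchyma_sd: float = 15.0
    vessel_mean: float = 160.0
    vessel_sd: float = 10.0
    nodule_mean: float = 40.0
    nodule_sd: float = 10.0
    n_nodules: int = 2
    nodule_radius_mm: float = 10.0
    n_hepatic_branches: int = 3
    branch_height_fraction: float = 0.6
    n_distractors: int = 2
    confounder: bool = False
    dark_neighbor: bool = False        # adjacent dark blob touching the liver
    peripheral_nodule: bool = False    # one nodule straddling the liver border
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.shape):
            raise ValueError("each shape component must be >= 16")
        if not (self.vessel_mean > self.parenchyma_mean > self.nodule_mean):
            raise ValueError(
                "intensity ordering vessel_mean > parenchyma_mean > "
                "nodule_mean is required"
            )
        if min(self.parenchyma_sd, self.vessel_sd, self.nodule_sd,
               self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_nodules < 0:
            raise ValueError("n_nodules must be >= 0")


@dataclass
class PhantomTruth:
    volume: Volume
    liver: Mask
    vessels: Mask
    nodules: Mask
    hepatic_branches: LabelMap
    portal: Mask
    confounder: Mask | None = None
    spec: PhantomSpec = field(default_factory=PhantomSpec)


def default_spec(seed: int = 0) -> PhantomSpec:
    return PhantomSpec(rng_seed=seed)


def big_nodule_spec(seed: int = 0) -> PhantomSpec:
    """Nodule with volume comparable to the parenchyma plus an adjacent dark
    structure: the intra-liver histogram is no longer Gaussian shaped and the
    fitted thresholds widen enough to leak outside the liver."""
    return PhantomSpec(
        n_nodules=1,
        nodule_radius_mm=30.0,
        dark_neighbor=True,
        rng_seed=seed,
    )


def peripheral_nodule_spec(seed: int = 0) -> PhantomSpec:
    """One dark nodule straddling the liver border: intensities fall outside
    the parenchyma range and hole filling cannot recover it."""
    return PhantomSpec(peripheral_nodule=True, rng_seed=seed)


PRESETS = {
    "default": default_spec,
    "big-nodule": big_nodule_spec,
    "peripheral-nodule": peripheral_nodule_spec,
}


# ---------------------------------------------------------------------------
# geometry helpers (all coordinates in mm)


def _coord_grids(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    return z, y, x


def _liver_mask(spec: PhantomSpec, z, y, x) -> np.ndarray:
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    cz, cy, cx = nz * sz * 0.5, ny * sy * 0.5, nx * sx * 0.5
    az = 0.33 * nz * sz
    ay = 0.38 * ny * sy
    ax = 0.40 * nx * sx
    # mild lobulation so the blob is ellipsoid-like rather than exact
    bend = 0.06 * ax * np.sin(2.0 * np.pi * (z - cz) / (4.0 * az))
    r2 = (
        ((z - cz) / az) ** 2
        + ((y - cy) / ay) ** 2
        + ((x - cx - bend) / ax) ** 2
    )
    return r2 <= 1.0


def _tube(z, y, x, z_lo, z_hi, yc, xc_of_z, radius) -> np.ndarray:
    """Near-vertical tube: circular cross-section around (yc, xc(z))."""
    xc = xc_of_z(z)
    inside_z = (z >= z_lo) & (z <= z_hi)
    return inside_z & (((y - yc) ** 2 + (x - xc) ** 2) <= radius**2)


def _sphere(z, y, x, c, radius) -> np.ndarray:
    cz, cy, cx = c
    return ((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) <= radius**2


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the phantom volume and all ground-truth masks.

    Deterministic for a fixed ``rng_seed``.  Raises ``ValueError`` when the
    requested nodules cannot fit inside the liver.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    z, y, x = _coord_grids(spec)
    cz, cy, cx = nz * sz * 0.5, ny * sy * 0.5, nx * sx * 0.5

    liver = _liver_mask(spec, z, y, x)
    liver_z = np.flatnonzero(liver.any(axis=(1, 2)))
    z_lo_mm, z_hi_mm = liver_z[0] * sz, liver_z[-1] * sz
    liver_height = z_hi_mm - z_lo_mm

    # --- hepatic branches: near-vertical bright tubes from the upper liver
    branches = np.zeros(spec.shape, dtype=np.uint8)
    span = max(spec.branch_height_fraction, 0.2) * liver_height
    top = z_hi_mm - 0.05 * liver_height
    ax_mm = 0.40 * nx * sx
    offsets = np.linspace(-0.55, 0.55, max(spec.n_hepatic_branches, 1)) * ax_mm
    tube_r = 3.0
    for i in range(spec.n_hepatic_branches):
        xc0 = cx + offsets[i]
        tilt = (-1) ** i * 0.06  # slight, alternating tilt in x per mm of z
        bow = 2.0  # mm bow in x at mid-height keeps the plane fit well-posed

        def xc_of_z(zz, xc0=xc0, tilt=tilt, z0=top - span):
            t = np.clip((zz - z0) / max(span, 1e-9), 0.0, 1.0)
            return xc0 + tilt * (zz - z0) + bow * np.sin(np.pi * t)

        tube = _tube(z, y, x, top - span, top, cy - 6.0, xc_of_z, tube_r)
        branches[tube & liver] = i + 1

    # --- portal trunk: near-horizontal bright tube through mid-liver,
    # kept at a different y so it does not touch the hepatic tubes, and
    # strictly interior so per-slice hole filling can recover it
    portal_z = cz - 0.25 * liver_height
    portal_y = cy + 14.0
    eroded = ndimage.binary_erosion(liver, iterations=3)
    portal = (
        (np.abs(y - portal_y - 0.05 * (x - cx)) <= 3.5)
        & (np.abs(z - portal_z - 0.08 * (x - cx)) <= 3.5)
        & (np.abs(x - cx) <= 0.30 * nx * sx)
        & eroded
    )

    # --- short bright distractor fragments (below the 15% height rule)
    distract = np.zeros(spec.shape, dtype=bool)
    for i in range(spec.n_distractors):
        dz = 0.04 * liver_height
        zc = z_lo_mm + (0.25 + 0.18 * i) * liver_height
        yc = cy - 20.0 - 8.0 * i
        xc = cx + (-1) ** i * 0.30 * ax_mm
        frag = (
            (np.abs(z - zc) <= dz)
            & (((y - yc) ** 2 + (x - xc) ** 2) <= tube_r**2)
            & liver
        )
        distract |= frag

    vessels = (branches > 0) | portal | distract

    # --- adipose nodules: dark spheres inside (or straddling) the liver
    nodules = np.zeros(spec.shape, dtype=bool)
    r_mm = spec.nodule_radius_mm
    interior_limit = 0.40 * min(ny * sy, nx * sx) - r_mm
    if spec.n_nodules > 0 and interior_limit <= 0:
        raise ValueError("nodules too large for the liver volume")
    placed = 0
    attempts = 0
    while placed < spec.n_nodules:
        attempts += 1
        if attempts > 400:
            raise ValueError("cannot place all nodules inside the liver")
        c = (
            cz + rng.uniform(-0.15, 0.15) * nz * sz,
            cy + rng.uniform(-0.2, 0.2) * ny * sy,
            cx + rng.uniform(-0.2, 0.2) * nx * sx,
        )
        cand = _sphere(z, y, x, c, r_mm)
        if not cand.any():
            continue
        fits_liver = not (cand & ~liver).any()
        clear = not (cand & vessels).any() and not (cand & nodules).any()
        # a lesion too large to avoid the vein tree displaces it instead,
        # as large real nodules do
        relax = attempts > 100
        if fits_liver and (clear or relax):
            nodules |= cand
            placed += 1
    vessels &= ~nodules
    branches[nodules] = 0
    portal &= ~nodules
    if spec.peripheral_nodule:
        # one extra nodule centred on the liver border (partly outside)
        border_x = cx + 0.40 * nx * sx  # right on the ellipsoid surface
        cand = _sphere(z, y, x, (cz, cy, border_x), r_mm)
        nodules |= cand

    # --- confounders outside the liver
    confounder = np.zeros(spec.shape, dtype=bool)
    if spec.confounder:
        confounder = _sphere(
            z, y, x, (cz, cy - 0.30 * ny * sy, cx + 0.52 * nx * sx), 12.0
        ) & ~liver
    dark_blob = np.zeros(spec.shape, dtype=bool)
    if spec.dark_neighbor:
        dark_blob = _sphere(
            z, y, x, (cz, cy, cx + 0.46 * nx * sx), 16.0
        ) & ~liver

    # --- body: fine two-phase soft-tissue texture around the liver.
    # The patch scale sits below the curvature-arrest radius of the level
    # set, so a contour seeded over body tissue fragments and collapses --
    # the behaviour heterogeneous abdominal tissue produces in real exams.
    body = (
        ((z - cz) / (0.48 * nz * sz)) ** 2
        + ((y - cy) / (0.47 * ny * sy)) ** 2
        + ((x - cx) / (0.47 * nx * sx)) ** 2
    ) <= 1.0
    field3 = rng.normal(0.0, 1.0, spec.shape)
    field3 = ndimage.gaussian_filter(field3, sigma=1.2)
    phase_b = field3 > 0.0

    # --- intensities
    vol = np.zeros(spec.shape, dtype=float)
    outside = body & ~liver
    vol[outside & ~phase_b] = rng.normal(20.0, 6.0,
                                         int((outside & ~phase_b).sum()))
    vol[outside & phase_b] = rng.normal(70.0, 6.0,
                                        int((outside & phase_b).sum()))
    paren = liver & ~vessels & ~nodules
    vol[paren] = rng.normal(spec.parenchyma_mean, spec.parenchyma_sd,
                            int(paren.sum()))
    vol[vessels] = rng.normal(spec.vessel_mean, spec.vessel_sd,
                              int(vessels.sum()))
    vol[nodules] = rng.normal(spec.nodule_mean, spec.nodule_sd,
                              int(nodules.sum()))
    if spec.confounder:
        vol[confounder] = rng.normal(95.0, 15.0, int(confounder.sum()))
    if spec.dark_neighbor:
        vol[dark_blob] = rng.normal(spec.nodule_mean + 5.0, spec.nodule_sd,
                                    int(dark_blob.sum()))
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, spec.shape)
    vol = np.rint(vol).astype(np.int16)

    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    return PhantomTruth(
        volume=Volume(data=vol, **geom),
        liver=Mask(data=liver.astype(np.uint8), **geom),
        vessels=Mask(data=vessels.astype(np.uint8), **geom),
        nodules=Mask(data=nodules.astype(np.uint8), **geom),
        hepatic_branches=LabelMap(data=branches, legend=dict(BRANCH_LEGEND),
                                  **geom),
        portal=Mask(data=portal.astype(np.uint8), **geom),
        confounder=Mask(data=(confounder | dark_blob).astype(np.uint8), **geom)
        if (spec.confounder or spec.dark_neighbor) else None,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# histogram extraction


def histogram_of(volume: Volume, mask: Mask, bin_width: float = 1.0) -> Histogram:
    """Histogram of the voxels of ``volume`` under ``mask``.

    Bins are contiguous with uniform ``bin_width`` and anchored at the masked
    minimum, so shifting every intensity by a constant shifts the bin centres
    by the same constant.  Counts always sum to the mask cardinality.
    """
    sel = mask.as_bool() if isinstance(mask, Mask) else np.asarray(mask, bool)
    if not sel.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume.data)[sel].astype(float)
    lo = float(vals.min())
    idx = np.rint((vals - lo) / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    centers = lo + bin_width * np.arange(counts.size)
    return Histogram(bin_centers=centers, counts=counts.astype(float))


def scaled_spec(spec: PhantomSpec, shape: tuple[int, int, int]) -> PhantomSpec:
    """Same scene at a different grid resolution (for quick tests)."""
    return replace(spec, shape=shape)
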