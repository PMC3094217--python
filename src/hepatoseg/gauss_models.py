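"""Gaussian and three-component mixture estimation on intensity histograms.

The liver parenchyma is modelled as a single Gaussian in intensity; the
voxels inside a segmented liver are modelled as a mixture of three Gaussians

    H_i = G_l + G_c + G_r

where ``G_c`` (centre) is the dominant parenchyma class, ``G_l`` (left) the
darker adipose-nodule class and ``G_r`` (right) the brighter vessel class.
The decomposition exploits the dominance of ``G_c``: the centre component is
isolated by symmetrising the histogram about its mode, the side components
are then fitted to the mirrored residuals, and a final joint non-linear
refinement adjusts all nine parameters together.

Thresholds are derived in two ways:

* parenchyma segmentation thresholds ``(T_L, T_H)`` are the abscissae where
  the unit-amplitude parenchyma Gaussian equals two tunable fractions
  ``(G_L, G_H)``;
* region-growing thresholds for nodules/vessels come from the ratio between
  a side component and the side+centre mixture (seed threshold, default
  proportion 0.70) and from the intersection abscissa of the two components
  (acceptance threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "Histogram",
    "GaussianModel",
    "MixtureModel",
    "ThresholdPair",
    "DegenerateModelError",
    "fit_gaussian",
    "thresholds_from_gaussian",
    "decompose_mixture",
    "grow_thresholds",
]

# Fraction of the dominant amplitude below which a side component is treated
# as absent (no voxels of that class in the liver).
ABSENCE_FLOOR = 0.01
# Minimum number of residual bins that must support a side component.
MIN_SUPPORT_BINS = 3
# Sigma floor for degenerate (near single-bin) histograms: one bin width,
# the narrowest width the binning can resolve.  An intensity-dependent floor
# would break shift equivariance.
SIGMA_FLOOR_BINS = 1.0


class DegenerateModelError(ValueError):
    """Raised when a threshold construction has no solution (degenerate fit)."""


@dataclass
class Histogram:
    """Counts over contiguous, uniformly spaced intensity bins."""

    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.shape != self.counts.shape:
            raise ValueError("bin_centers and counts must have equal length")
        if self.bin_centers.size >= 2:
            d = np.diff(self.bin_centers)
            if np.any(d <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError("bins must have uniform width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        if self.bin_centers.size < 2:
            return 1.0
        return float(self.bin_centers[1] - self.bin_centers[0])

    def shifted(self, c: float) -> "Histogram":
        return Histogram(self.bin_centers + c, self.counts.copy())


@dataclass
class GaussianModel:
    """``K * exp(-(x - mu)^2 / (2 sigma^2))`` with ``K >= 0``, ``sigma > 0``."""

    K: float
    mu: float
    sigma: float
    degenerate: bool = False  # sigma floor was applied during the fit

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.K * np.exp(-((x - self.mu) ** 2) / (2.0 * self.sigma**2))


@dataclass
class MixtureModel:
    """Three-component mixture ordered ``mu_l < mu_c < mu_r``.

    ``l_present`` / ``r_present`` flag whether the corresponding side class
    has real support in the histogram; an absent component is returned with
    its amplitude at the absence floor and must not drive any threshold.
    """

    G_l: GaussianModel
    G_c: GaussianModel
    G_r: GaussianModel
    l_present: bool = True
    r_present: bool = True

    def __call__(self, x) -> np.ndarray:
        return self.G_l(x) + self.G_c(x) + self.G_r(x)


@dataclass
class ThresholdPair:
    T_L: float
    T_H: float

    def __post_init__(self) -> None:
        if not self.T_L < self.T_H:
            raise ValueError(f"T_L={self.T_L} must be < T_H={self.T_H}")


# ---------------------------------------------------------------------------
# Single-Gaussian fit


def _gauss(x, K, mu, sigma):
    return K * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _initial_guess(x: np.ndarray, y: np.ndarray, bin_width: float):
    """Amplitude/mode/FWHM-based starting point for the non-linear fit."""
    i = int(np.argmax(y))
    K0 = float(y[i])
    mu0 = float(x[i])
    half = K0 / 2.0
    above = y >= half
    if above.sum() >= 2:
        idx = np.flatnonzero(above)
        lo, hi = x[idx[0]], x[idx[-1]]
        fwhm = max(hi - lo, bin_width)
    else:
        fwhm = bin_width
    return K0, mu0, fwhm / 2.3548


def fit_gaussian(h: Histogram) -> GaussianModel:
    """Least-squares Gaussian fit to a histogram (Levenberg-Marquardt).

    Requires at least 3 nonzero bins for a proper fit; a degenerate
    histogram (support narrower than the fit can resolve) yields a model
    with a floored sigma and ``degenerate=True``.

    The fit runs in mode-anchored abscissae (``x - x_mode``), which makes it
    exactly equivariant under a constant intensity shift: shifted input
    yields the identical model with only ``mu`` translated.
    """
    x, y = h.bin_centers, h.counts
    nz = np.flatnonzero(y)
    if nz.size == 0:
        raise ValueError("histogram has no counts")
    floor = SIGMA_FLOOR_BINS * h.bin_width
    anchor = float(x[int(np.argmax(y))])
    xa = x - anchor
    K0, mu0, s0 = _initial_guess(xa, y, h.bin_width)
    if nz.size < MIN_SUPPORT_BINS:
        # all mass in 1-2 bins: the width is unresolvable at this binning
        return GaussianModel(K=K0, mu=mu0 + anchor, sigma=floor,
                             degenerate=True)
    s0 = max(s0, 0.5 * h.bin_width)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        try:
            popt, _ = curve_fit(
                _gauss, xa, y, p0=(K0, mu0, s0), maxfev=10000, method="lm"
            )
            K, mu, sigma = popt
            sigma = abs(float(sigma))
            K = abs(float(K))
        except RuntimeError:
            K, mu, sigma = K0, mu0, s0
    degenerate = False
    if sigma < floor:
        sigma = floor
        degenerate = True
    # never return a worse fit than the initialization
    fitted = GaussianModel(K=K, mu=float(mu), sigma=sigma, degenerate=degenerate)
    init = GaussianModel(K=K0, mu=mu0, sigma=max(s0, floor))
    if np.sum((fitted(xa) - y) ** 2) > np.sum((init(xa) - y) ** 2):
        fitted = GaussianModel(K=K0, mu=mu0, sigma=max(s0, floor),
                               degenerate=degenerate)
    fitted.mu += anchor
    return fitted


# ---------------------------------------------------------------------------
# Parenchyma thresholds


def thresholds_from_gaussian(
    g: GaussianModel, G_L: float, G_H: float
) -> ThresholdPair:
    """Invert the unit-amplitude Gaussian at fractions ``G_L`` (left) and
    ``G_H`` (right):  ``T_L = mu - sigma*sqrt(-2 ln G_L)`` and
    ``T_H = mu + sigma*sqrt(-2 ln G_H)``.
    """
    for name, val in (("G_L", G_L), ("G_H", G_H)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{name}={val} must lie in (0, 1)")
    t_l = g.mu - g.sigma * math.sqrt(-2.0 * math.log(G_L))
    t_h = g.mu + g.sigma * math.sqrt(-2.0 * math.log(G_H))
    return ThresholdPair(T_L=t_l, T_H=t_h)


# ---------------------------------------------------------------------------
# Three-component mixture decomposition


def _mirror_min(y: np.ndarray, i_max: int) -> np.ndarray:
    """min[y(x), y(2 x_max - x)] on the bin grid (out-of-range -> 0)."""
    n = y.size
    out = np.zeros(n)
    for j in range(n):
        k = 2 * i_max - j
        mirrored = y[k] if 0 <= k < n else 0.0
        out[j] = min(y[j], mirrored)
    return out


def _mirror_max(y: np.ndarray, i_max: int) -> np.ndarray:
    """max[y(x), y(2 x_max - x)] on the bin grid (out-of-range -> 0)."""
    n = y.size
    out = np.zeros(n)
    for j in range(n):
        k = 2 * i_max - j
        mirrored = y[k] if 0 <= k < n else 0.0
        out[j] = max(y[j], mirrored)
    return out


def _fit_side(residual: np.ndarray, x: np.ndarray, bin_width: float,
              K_c: float, fallback_mu: float) -> tuple[GaussianModel, bool, np.ndarray]:
    """Fit one side component to its mirrored residual; detect absence.

    Returns the model, a presence flag, and the symmetrised residual
    histogram the model was fitted to.  An absent component is placed at
    ``fallback_mu`` (beyond the centre on its own side) so the component
    ordering stays meaningful.
    """
    support = np.flatnonzero(residual > 0)
    if support.size < MIN_SUPPORT_BINS:
        mu = float(x[support[0]]) if support.size else float(fallback_mu)
        return (
            GaussianModel(K=ABSENCE_FLOOR * K_c, mu=mu,
                          sigma=max(bin_width, 1e-6), degenerate=True),
            False,
            np.zeros_like(residual),
        )
    i_max = int(support[np.argmax(residual[support])])
    sym = _mirror_max(residual, i_max)
    g = fit_gaussian(Histogram(x, sym))
    if g.K < ABSENCE_FLOOR * K_c:
        return g, False, sym
    return g, True, sym


def decompose_mixture(h_i: Histogram) -> MixtureModel:
    """Estimate the three-Gaussian mixture from an intra-liver histogram.

    Four sequential steps, assuming the centre (parenchyma) component
    dominates the mixture:

    1. centre: symmetrise ``H_i`` about its mode with a pointwise minimum
       (``H_c(x) = min[H_i(x), H_i(2 x_max - x)]``) and fit ``G_c``;
    2. left (nodules): subtract ``H_c``, keep the residual below the mode,
       mirror it about its own maximum with a pointwise maximum and fit
       ``G_l``;
    3. right (vessels): same construction on the residual above the mode
       after removing ``H_c`` and ``H_l``;
    4. joint Levenberg-Marquardt refinement of all nine parameters,
       initialised at the output of steps 1-3.

    A side component without real support is returned at the absence floor
    with its ``*_present`` flag cleared.
    """
    x, y = h_i.bin_centers, h_i.counts.astype(float)
    w = h_i.bin_width
    i_mode = int(np.argmax(y))

    # step 1: dominant centre component from the min-symmetrised histogram
    h_c = _mirror_min(y, i_mode)
    g_c = fit_gaussian(Histogram(x, h_c))

    # Excluding the centre class from the histogram is done with the fitted
    # G_c rather than the symmetrised H_c: the pointwise minimum absorbs any
    # side bump whose mirror image about the mode also carries counts, which
    # would cancel both side classes from the residual.  Residual counts
    # inside the centre's 3-sigma core are fit-mismatch and sampling noise
    # (the model assumes side classes separated from the parenchyma by at
    # least three sigma) and are muted before locating the side components.
    core = np.abs(x - g_c.mu) < 3.0 * g_c.sigma

    # step 2: left (darker) component from the residual below the mode
    resid = np.clip(y - g_c(x), 0.0, None)
    resid_l = resid.copy()
    resid_l[(x >= x[i_mode]) | core] = 0.0
    g_l, l_present, h_l = _fit_side(resid_l, x, w, g_c.K,
                                    g_c.mu - 4.0 * g_c.sigma)

    # step 3: right (brighter) component from what remains above the mode
    resid_r = np.clip(y - g_c(x) - h_l, 0.0, None)
    resid_r[(x <= x[i_mode]) | core] = 0.0
    g_r, r_present, _ = _fit_side(resid_r, x, w, g_c.K,
                                  g_c.mu + 4.0 * g_c.sigma)

    # step 4: joint refinement of the present components' parameters
    g_l, g_c, g_r = _joint_refit(x, y, g_l, g_c, g_r, l_present, r_present)

    # return components ordered by mean; presence flags travel with them
    comps = sorted(
        [(g_l, l_present), (g_c, True), (g_r, r_present)],
        key=lambda t: t[0].mu,
    )
    return MixtureModel(
        G_l=comps[0][0],
        G_c=comps[1][0],
        G_r=comps[2][0],
        l_present=comps[0][1],
        r_present=comps[2][1],
    )


def _joint_refit(x, y, g_l, g_c, g_r, l_present, r_present):
    """Simultaneous least-squares refinement of the present components.

    Absent side components stay at their floored placeholders: refitting
    them would only model noise.  A refit whose parameters run away (means
    outside the histogram span, widths wider than the span, amplitudes far
    above the counts) is rejected and the stepwise estimate kept.
    """
    comps = [(g_l, l_present), (g_c, True), (g_r, r_present)]
    free = [i for i, (_, p) in enumerate(comps) if p]
    # mode-anchored abscissae keep the refit exactly shift-equivariant
    anchor = float(x[int(np.argmax(y))])
    xa = x - anchor
    p0 = []
    for i in free:
        g = comps[i][0]
        p0.extend((g.K, g.mu - anchor, g.sigma))

    def model(xx, *params):
        out = np.zeros_like(xx, dtype=float)
        for j in range(len(free)):
            K, mu, s = params[3 * j: 3 * j + 3]
            out += _gauss(xx, K, mu, s)
        for i, (g, p) in enumerate(comps):
            if not p:
                out += _gauss(xx, g.K, g.mu - anchor, g.sigma)
        return out

    # Levenberg-Marquardt can stall in a poor basin from some stepwise
    # starts; a bounded trust-region solve of the same least-squares
    # objective provides a second candidate and the better fit wins.
    n_free = len(free)
    lo_b, hi_b = [], []
    span = float(x[-1] - x[0])
    for _ in range(n_free):
        lo_b += [0.0, float(xa[0]) - span, 0.25]
        hi_b += [5.0 * float(y.max()), float(xa[-1]) + span, span]
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        for kwargs in (
            dict(method="lm", maxfev=20000),
            dict(method="trf", bounds=(lo_b, hi_b), maxfev=20000),
        ):
            try:
                cand, _ = curve_fit(
                    model, xa, y,
                    p0=np.clip(p0, lo_b, hi_b) if "bounds" in kwargs else p0,
                    **kwargs,
                )
            except RuntimeError:
                continue
            candidates.append(cand)
    if not candidates:
        return g_l, g_c, g_r
    popt = min(candidates, key=lambda c: np.sum((model(xa, *c) - y) ** 2))
    if np.sum((model(xa, *popt) - y) ** 2) > np.sum((model(xa, *p0) - y) ** 2):
        return g_l, g_c, g_r
    span = float(x[-1] - x[0])
    ymax = float(y.max())
    w = float(x[1] - x[0]) if x.size > 1 else 1.0
    fitted = dict()
    for j, i in enumerate(free):
        K, mu, s = popt[3 * j: 3 * j + 3]
        K, s = abs(float(K)), abs(float(s))
        mu = float(mu) + anchor
        step = comps[i][0]
        # step 4 is a refinement: a component whose parameters run away or
        # whose mean wanders off its stepwise estimate is no longer
        # refining that class but modelling a different part of the
        # histogram; keep the stepwise estimate in that case
        if (
            not (x[0] - span <= mu <= x[-1] + span)
            or s > span
            or K > 5 * ymax
            or abs(mu - step.mu) > max(3.0 * step.sigma, 3.0 * w)
        ):
            return g_l, g_c, g_r
        fitted[i] = GaussianModel(K=K, mu=mu, sigma=max(s, 1e-6))
    out = [fitted.get(i, comps[i][0]) for i in range(3)]
    return tuple(out)


# ---------------------------------------------------------------------------
# Region-growing thresholds


def _intersection(a: GaussianModel, b: GaussianModel) -> float:
    """Abscissa strictly between the means where the two Gaussians are equal.

    Solved as the root of the log-equality quadratic; falls back to a grid
    scan of ``|a - b|`` when the quadratic is degenerate.
    """
    lo, hi = sorted((a.mu, b.mu))
    if hi - lo < 1e-12:
        raise DegenerateModelError("components share the same mean")
    # log a(x) = log b(x)  ->  quadratic in x
    A = 1.0 / (2 * b.sigma**2) - 1.0 / (2 * a.sigma**2)
    B = a.mu / a.sigma**2 - b.mu / b.sigma**2
    C = (
        b.mu**2 / (2 * b.sigma**2)
        - a.mu**2 / (2 * a.sigma**2)
        + math.log(a.K / b.K)
    )
    roots: list[float] = []
    if abs(A) < 1e-14:
        if abs(B) > 1e-14:
            roots = [-C / B]
    else:
        disc = B * B - 4 * A * C
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    between = [r for r in roots if lo < r < hi]
    if between:
        return float(between[0] if len(between) == 1 else min(between))
    # degenerate quadratic: scan the span between the means
    grid = np.linspace(lo, hi, 10001)[1:-1]
    d = np.abs(a(grid) - b(grid))
    i = int(np.argmin(d))
    if not np.isfinite(d[i]):
        raise DegenerateModelError("no intersection between component means")
    return float(grid[i])


def _ratio_threshold(
    side: GaussianModel,
    centre: GaussianModel,
    proportion: float,
    direction: str,
    span: tuple[float, float],
) -> float:
    """Extreme abscissa where side/(side+centre) still reaches ``proportion``.

    ``direction='left'`` returns the largest such x (scanning upward from the
    dark side); ``'right'`` returns the smallest such x.  The search runs on
    a fine grid over ``span`` and is refined by bisection to 1e-3 of a unit.
    """

    def ratio(x: float) -> float:
        s = side(np.array([x]))[0]
        c = centre(np.array([x]))[0]
        tot = s + c
        return s / tot if tot > 0 else 0.0

    lo, hi = span
    grid = np.linspace(lo, hi, 4096)
    ok = np.array([ratio(g) >= proportion for g in grid])
    if not ok.any():
        raise DegenerateModelError("proportion never reached on the scan span")
    if direction == "left":
        i = int(np.flatnonzero(ok)[-1])
        a, b = grid[i], grid[min(i + 1, grid.size - 1)]
    else:
        i = int(np.flatnonzero(ok)[0])
        a, b = grid[max(i - 1, 0)], grid[i]
    # bisect between the last satisfying point and its neighbour
    for _ in range(60):
        if b - a < 1e-3:
            break
        m = 0.5 * (a + b)
        hit = ratio(m) >= proportion
        if direction == "left":
            if hit:
                a = m
            else:
                b = m
        else:
            if hit:
                b = m
            else:
                a = m
    return float(a if direction == "left" else b)


def grow_thresholds(
    m: MixtureModel, side: str, proportion: float = 0.70
) -> ThresholdPair:
    """Seed/acceptance thresholds for region growing on one mixture side.

    ``side='left'`` (nodules): the seed threshold ``T_L`` is the largest
    intensity where the nodule class still holds at least ``proportion`` of
    the nodule+parenchyma density; the acceptance threshold ``T_H`` is the
    intersection of the two components between their means.  ``side='right'``
    (vessels) is the mirror image: ``T_L`` is the intersection and ``T_H``
    the smallest intensity where the vessel class reaches ``proportion``.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side == "left":
        if not m.l_present:
            raise DegenerateModelError("left component absent")
        g_s, g_c = m.G_l, m.G_c
        inter = _intersection(g_s, g_c)
        span = (g_s.mu - 6 * g_s.sigma, inter)
        t_l = _ratio_threshold(g_s, g_c, proportion, "left", span)
        return ThresholdPair(T_L=t_l, T_H=inter)
    if not m.r_present:
        raise DegenerateModelError("right component absent")
    g_s, g_c = m.G_r, m.G_c
    inter = _intersection(g_s, g_c)
    span = (inter, g_s.mu + 6 * g_s.sigma)
    t_h = _ratio_threshold(g_s, g_c, proportion, "right", span)
    return ThresholdPair(T_L=inter, T_H=t_h)
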