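import math

import numpy as np
import pytest

from hepatoseg.gauss_models import (
    DegenerateModelError,
    GaussianModel,
    Histogram,
    MixtureModel,
    ThresholdPair,
    decompose_mixture,
    fit_gaussian,
    grow_thresholds,
    thresholds_from_gaussian,
)


def gauss(x, K, mu, s):
    return K * np.exp(-((x - mu) ** 2) / (2 * s**2))


# ---------------------------------------------------------------------------
# single-Gaussian fit


def test_fit_recovers_exact_gaussian():
    x = np.arange(50.0, 151.0)
    y = gauss(x, 50.0, 100.0, 10.0)
    g = fit_gaussian(Histogram(x, y))
    assert abs(g.K - 50) / 50 < 1e-3
    assert abs(g.mu - 100) / 100 < 1e-3
    assert abs(g.sigma - 10) / 10 < 1e-3


def test_fit_symmetric_histogram_centered():
    x = np.arange(0.0, 21.0)
    y = np.exp(-((x - 10) ** 2) / 8.0) * 30
    g = fit_gaussian(Histogram(x, y))
    assert abs(g.mu - 10.0) < 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_fit_robust_to_uniform_noise(seed):
    """mu recovered within half a bin under 5% uniform contamination."""
    rng = np.random.default_rng(seed)
    x = np.arange(50.0, 151.0)
    y = gauss(x, 50.0, 100.0, 10.0)
    y = y + rng.uniform(0, 0.05 * 50, size=y.size)
    g = fit_gaussian(Histogram(x, y))
    assert abs(g.mu - 100.0) <= 0.5


def test_fit_degenerate_single_bin_flagged():
    x = np.arange(0.0, 11.0)
    y = np.zeros(11)
    y[4] = 120.0
    g = fit_gaussian(Histogram(x, y))
    assert g.degenerate
    assert g.sigma >= 1.0  # floored at one bin width
    assert g.mu == 4.0


# ---------------------------------------------------------------------------
# parenchyma thresholds


def test_thresholds_closed_form_and_forward_check():
    g = GaussianModel(K=1.0, mu=100.0, sigma=10.0)
    t = thresholds_from_gaussian(g, 0.5, 0.5)
    assert t.T_L == pytest.approx(88.226, abs=1e-3)
    assert t.T_H == pytest.approx(111.774, abs=1e-3)
    # forward evaluation of the unit-amplitude Gaussian reproduces G_L/G_H
    for tt, gg in ((t.T_L, 0.5), (t.T_H, 0.5)):
        val = math.exp(-((tt - g.mu) ** 2) / (2 * g.sigma**2))
        assert val == pytest.approx(gg, abs=1e-9)


def test_thresholds_tuned_fractions_standard_normal():
    g = GaussianModel(K=1.0, mu=0.0, sigma=1.0)
    t = thresholds_from_gaussian(g, 0.3859, 0.2809)
    assert t.T_L == pytest.approx(-math.sqrt(-2 * math.log(0.3859)), abs=1e-12)
    assert t.T_H == pytest.approx(math.sqrt(-2 * math.log(0.2809)), abs=1e-12)


def test_thresholds_collapse_to_mu_in_limit():
    g = GaussianModel(K=1.0, mu=50.0, sigma=5.0)
    t = thresholds_from_gaussian(g, 0.999999, 0.999999)
    assert t.T_L == pytest.approx(50.0, abs=0.01)
    assert t.T_H == pytest.approx(50.0, abs=0.01)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
def test_thresholds_fraction_out_of_range(bad):
    g = GaussianModel(K=1.0, mu=0.0, sigma=1.0)
    with pytest.raises(ValueError):
        thresholds_from_gaussian(g, bad, 0.5)


def test_threshold_pair_ordering_enforced():
    with pytest.raises(ValueError):
        ThresholdPair(T_L=5.0, T_H=5.0)


# ---------------------------------------------------------------------------
# mixture decomposition

MIX = ((2000.0, 100.0, 12.0), (150.0, 40.0, 8.0), (300.0, 160.0, 9.0))


def _mix_hist(x):
    c, l, r = MIX
    return gauss(x, *c) + gauss(x, *l) + gauss(x, *r)


def test_pure_gaussian_sides_absent():
    x = np.arange(0.0, 201.0)
    m = decompose_mixture(Histogram(x, gauss(x, 2000, 100, 12)))
    assert not m.l_present and not m.r_present
    assert abs(m.G_c.mu - 100) < 1.0


def test_noiseless_mixture_means_within_one_bin():
    x = np.arange(0.0, 221.0)
    m = decompose_mixture(Histogram(x, _mix_hist(x)))
    assert m.l_present and m.r_present
    assert abs(m.G_l.mu - 40.0) <= 1.0
    assert abs(m.G_c.mu - 100.0) <= 1.0
    assert abs(m.G_r.mu - 160.0) <= 1.0


@pytest.mark.parametrize("seed", range(10))
def test_multinomial_sampling_recovery(seed):
    """n = 200000 multinomial draws: centre within 1 bin, sides within 3."""
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, 221.0)
    p = _mix_hist(x)
    counts = rng.multinomial(200_000, p / p.sum()).astype(float)
    m = decompose_mixture(Histogram(x, counts))
    assert abs(m.G_c.mu - 100.0) <= 1.0
    assert abs(m.G_l.mu - 40.0) <= 3.0
    assert abs(m.G_r.mu - 160.0) <= 3.0


def test_shift_equivariance_of_decomposition():
    x = np.arange(0.0, 221.0)
    y = _mix_hist(x)
    m0 = decompose_mixture(Histogram(x, y))
    m1 = decompose_mixture(Histogram(x + 37.0, y))
    for a, b in ((m0.G_l, m1.G_l), (m0.G_c, m1.G_c), (m0.G_r, m1.G_r)):
        assert b.mu - a.mu == pytest.approx(37.0, abs=1e-6)
        assert b.sigma == pytest.approx(a.sigma, abs=1e-6)


# ---------------------------------------------------------------------------
# region-growing thresholds


def test_intersection_midpoint_for_equal_components():
    m = MixtureModel(
        G_l=GaussianModel(K=0.01, mu=0.0, sigma=1.0),
        G_c=GaussianModel(K=500.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=500.0, mu=160.0, sigma=10.0),
        l_present=False,
    )
    t = grow_thresholds(m, "right")
    assert t.T_L == pytest.approx(130.0, abs=1e-3)


def test_left_thresholds_match_grid_scan_oracle():
    g_c = GaussianModel(K=2000.0, mu=100.0, sigma=12.0)
    g_l = GaussianModel(K=150.0, mu=40.0, sigma=8.0)
    m = MixtureModel(G_l=g_l, G_c=g_c,
                     G_r=GaussianModel(K=0.01, mu=200.0, sigma=1.0),
                     r_present=False)
    t = grow_thresholds(m, "left", 0.70)
    # brute-force 0.01-step scan
    grid = np.arange(0.0, 100.0, 0.01)
    dl, dc = g_l(grid), g_c(grid)
    ratio = dl / (dl + dc)
    t_l_oracle = grid[np.flatnonzero(ratio >= 0.70)[-1]]
    between = (grid > 40.0) & (grid < 100.0)
    t_h_oracle = grid[between][np.argmin(np.abs(dl - dc)[between])]
    assert t.T_L == pytest.approx(t_l_oracle, abs=0.02)
    assert t.T_H == pytest.approx(t_h_oracle, abs=0.02)


def test_right_seed_threshold_collapses_toward_intersection():
    """As the proportion approaches 1/2 the seed threshold approaches the
    intersection abscissa (equal amplitudes and sigmas)."""
    m = MixtureModel(
        G_l=GaussianModel(K=0.01, mu=0.0, sigma=1.0),
        G_c=GaussianModel(K=500.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=500.0, mu=160.0, sigma=10.0),
        l_present=False,
    )
    gap_wide = grow_thresholds(m, "right", 0.70)
    gap_slim = grow_thresholds(m, "right", 0.501)
    assert gap_slim.T_H - gap_slim.T_L < gap_wide.T_H - gap_wide.T_L
    assert gap_slim.T_H == pytest.approx(130.0, abs=0.5)


def test_absent_side_raises():
    m = MixtureModel(
        G_l=GaussianModel(K=0.01, mu=0.0, sigma=1.0),
        G_c=GaussianModel(K=500.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=400.0, mu=160.0, sigma=9.0),
        l_present=False,
    )
    with pytest.raises(DegenerateModelError):
        grow_thresholds(m, "left")


def test_identical_means_degenerate():
    m = MixtureModel(
        G_l=GaussianModel(K=100.0, mu=100.0, sigma=5.0),
        G_c=GaussianModel(K=500.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=400.0, mu=160.0, sigma=9.0),
    )
    with pytest.raises(DegenerateModelError):
        grow_thresholds(m, "left")
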