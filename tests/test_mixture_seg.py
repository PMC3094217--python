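import numpy as np
import pytest
from scipy import ndimage

from hepatoseg.gauss_models import GaussianModel, MixtureModel, decompose_mixture
from hepatoseg.mixture_seg import (
    GrowConfig,
    grow_region,
    segment_nodules,
    segment_vessels,
)
from hepatoseg.phantom import histogram_of
from hepatoseg.volume_io import Mask, Volume


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(data=np.asarray(data), spacing=spacing)


def _full_mask(shape):
    return Mask(data=np.ones(shape, np.uint8))


def _default_mixture(truth):
    return decompose_mixture(histogram_of(truth.volume, truth.liver))


# ---------------------------------------------------------------------------
# grow_region


def test_corridor_flood_fill():
    """Hand flood-fill oracle: seeds <40, acceptance <50 in a 1D corridor
    [30, 45, 60, 100] reaches the first two voxels only."""
    data = np.zeros((1, 1, 4))
    data[0, 0] = [30, 45, 60, 100]
    out = grow_region(
        _vol(data), _full_mask((1, 1, 4)),
        seed_rule=lambda g: g < 40, accept_rule=lambda g: g < 50,
    )
    assert out.data[0, 0].tolist() == [1, 1, 0, 0]


def test_no_seeds_empty_output():
    data = np.full((3, 3, 3), 100.0)
    out = grow_region(
        _vol(data), _full_mask((3, 3, 3)),
        seed_rule=lambda g: g < 0, accept_rule=lambda g: g < 200,
    )
    assert out.n_voxels == 0


def test_accept_all_yields_connected_component():
    data = np.zeros((1, 5, 5))
    domain = np.zeros((1, 5, 5), np.uint8)
    domain[0, :2, :2] = 1   # component A (contains the seed)
    domain[0, 4:, 4:] = 1   # component B, disconnected
    data[0, 0, 0] = -50
    out = grow_region(
        _vol(data), Mask(data=domain),
        seed_rule=lambda g: g < -10, accept_rule=lambda g: g < np.inf,
        connectivity=26,
    )
    assert np.array_equal(out.data[0, :2, :2], np.ones((2, 2)))
    assert not out.data[0, 4:, 4:].any()


def test_monotone_in_acceptance_threshold(default_truth):
    m = _default_mixture(default_truth)
    vol, liver = default_truth.volume, default_truth.liver
    tight = grow_region(vol, liver, lambda g: g > 150, lambda g: g > 148)
    loose = grow_region(vol, liver, lambda g: g > 150, lambda g: g > 140)
    assert (tight.as_bool() & ~loose.as_bool()).sum() == 0


def test_seed_stricter_than_accept_enforced(default_truth):
    with pytest.raises(ValueError):
        grow_region(default_truth.volume, default_truth.liver,
                    seed_rule=lambda g: g > 100, accept_rule=lambda g: g > 150)


@pytest.mark.parametrize("trial", range(20))
def test_grow_matches_bfs_oracle(trial):
    """Label-based growing equals a breadth-first flood fill on random
    16-cubed masks."""
    rng = np.random.default_rng(trial)
    data = rng.integers(0, 100, size=(16, 16, 16)).astype(float)
    domain = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2) > 0
    if not domain.any():
        return
    seeds = (data < 15) & domain
    accept = (data < 55) & domain
    out = grow_region(
        _vol(data), Mask(data=domain.astype(np.uint8)),
        seed_rule=lambda g: g < 15, accept_rule=lambda g: g < 55,
        connectivity=26,
    )
    # BFS oracle
    visited = np.zeros_like(domain)
    stack = list(map(tuple, np.argwhere(seeds)))
    for p in stack:
        visited[p] = True
    while stack:
        z, y, x = stack.pop()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    q = (z + dz, y + dy, x + dx)
                    if (
                        0 <= q[0] < 16 and 0 <= q[1] < 16 and 0 <= q[2] < 16
                        and not visited[q] and accept[q]
                    ):
                        visited[q] = True
                        stack.append(q)
    assert np.array_equal(out.as_bool(), visited)


# ---------------------------------------------------------------------------
# nodules and vessels on the phantom


def test_nodule_dice_on_phantom(default_truth):
    m = _default_mixture(default_truth)
    nod = segment_nodules(default_truth.volume, default_truth.liver, m)
    truth = default_truth.nodules.as_bool()
    dice = 2 * (nod.as_bool() & truth).sum() / (nod.n_voxels + truth.sum())
    assert dice >= 0.85


def test_vessel_dice_on_phantom(default_truth):
    m = _default_mixture(default_truth)
    ves = segment_vessels(default_truth.volume, default_truth.liver, m)
    truth = default_truth.vessels.as_bool()
    dice = 2 * (ves.as_bool() & truth).sum() / (ves.n_voxels + truth.sum())
    assert dice >= 0.80


def test_outputs_disjoint_and_inside_liver(default_truth):
    m = _default_mixture(default_truth)
    nod = segment_nodules(default_truth.volume, default_truth.liver, m)
    ves = segment_vessels(default_truth.volume, default_truth.liver, m)
    liver = default_truth.liver.as_bool()
    assert not (nod.as_bool() & ~liver).any()
    assert not (ves.as_bool() & ~liver).any()
    assert not (nod.as_bool() & ves.as_bool()).any()


def test_absent_left_component_gives_empty_flagged():
    m = MixtureModel(
        G_l=GaussianModel(K=0.1, mu=40.0, sigma=1.0),
        G_c=GaussianModel(K=500.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=100.0, mu=160.0, sigma=9.0),
        l_present=False,
    )
    vol = _vol(np.full((8, 8, 8), 100.0))
    out = segment_nodules(vol, _full_mask((8, 8, 8)), m)
    assert out.n_voxels == 0


def test_nodules_brightened_above_threshold_vanish():
    """Raising every nodule voxel above the acceptance threshold leaves the
    nodule stage empty (controlled scene: no parenchyma tail below the
    threshold to act as stray seeds)."""
    from hepatoseg.gauss_models import grow_thresholds

    m = MixtureModel(
        G_l=GaussianModel(K=100.0, mu=40.0, sigma=8.0),
        G_c=GaussianModel(K=2000.0, mu=100.0, sigma=10.0),
        G_r=GaussianModel(K=0.1, mu=160.0, sigma=1.0),
        r_present=False,
    )
    t = grow_thresholds(m, "left")
    rng = np.random.default_rng(0)
    data = np.clip(rng.normal(100, 10, (16, 16, 16)), t.T_H + 1, None)
    data[4:8, 4:8, 4:8] = 40.0
    dark = segment_nodules(_vol(data), _full_mask(data.shape), m)
    assert dark.n_voxels == 4**3
    data[4:8, 4:8, 4:8] = 100.0  # brighten the nodule above T_H
    out = segment_nodules(_vol(data), _full_mask(data.shape), m)
    assert out.n_voxels == 0


def test_grow_config_validation():
    with pytest.raises(ValueError):
        GrowConfig(proportion=0.4)
    with pytest.raises(ValueError):
        GrowConfig(connectivity=18)
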