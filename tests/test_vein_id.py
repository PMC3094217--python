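import numpy as np
import pytest

from hepatoseg.vein_id import (
    classify_clockwise,
    extract_portal,
    identify_veins,
    track_main_branches,
)
from hepatoseg.volume_io import Mask


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return Mask(data=np.asarray(data, np.uint8), spacing=spacing)


def _tube(shape, z_lo, z_hi, y, x, r=1):
    out = np.zeros(shape, bool)
    out[z_lo: z_hi + 1, y - r: y + r + 1, x - r: x + r + 1] = True
    return out


def _solid_liver(shape):
    return _mask(np.ones(shape, np.uint8))


# ---------------------------------------------------------------------------
# tracking


def test_three_tall_tubes_two_short_blobs():
    shape = (40, 32, 32)
    v = np.zeros(shape, bool)
    for x in (6, 16, 26):
        v |= _tube(shape, 5, 35, 16, x)       # tall: 31/40 slices
    v |= _tube(shape, 10, 11, 5, 10)          # short blobs: 2 slices = 5%
    v |= _tube(shape, 20, 21, 5, 22)
    branches = track_main_branches(_mask(v), _solid_liver(shape))
    assert len(branches) == 3
    total = sum(b.n_voxels for b in branches)
    union = np.zeros(shape, bool)
    for b in branches:
        assert not (b.as_bool() & union).any()  # pairwise disjoint
        union |= b.as_bool()
    # the short blobs are excluded from every branch
    assert not union[10:12, 5, 10].any() and not union[20:22, 5, 22].any()


def test_single_short_tube_rejected():
    shape = (40, 16, 16)
    v = _tube(shape, 30, 33, 8, 8)  # 4/40 slices = 10% of liver height
    branches = track_main_branches(_mask(v), _solid_liver(shape))
    assert branches == []


def test_y_shaped_merge_returns_one_branch():
    """A Y-shaped vessel (two short arms joining a long trunk) yields one
    accepted branch: the first arm merges into the trunk through
    maximal-overlap tracking, the second arm alone is below the height rule."""
    shape = (40, 24, 24)
    arm1 = _tube(shape, 32, 35, 12, 8)
    arm2 = _tube(shape, 32, 35, 12, 14)
    trunk = _tube(shape, 5, 31, 12, 11, r=4)  # overlaps both arms' footprints
    v = arm1 | arm2 | trunk
    branches = track_main_branches(_mask(v), _solid_liver(shape),
                                   n_branches=3)
    assert len(branches) == 1
    got = branches[0].as_bool()
    assert (got & trunk).sum() == trunk.sum()        # trunk absorbed
    assert got.sum() >= trunk.sum() + arm1.sum()     # plus one arm


def test_height_measured_in_mm():
    """A 6-slice tube passes the 15% rule only when the z spacing makes it
    tall enough relative to the liver."""
    shape = (40, 16, 16)
    v = _tube(shape, 30, 35, 8, 8)
    liver = _solid_liver(shape)
    assert track_main_branches(_mask(v), liver) == []  # 6/40 = 15%, not >
    # halve the liver height by restricting it to 20 slices
    short_liver = np.zeros(shape, np.uint8)
    short_liver[16:36] = 1
    got = track_main_branches(_mask(v), _mask(short_liver))
    assert len(got) == 1  # 6/20 = 30% of liver height


# ---------------------------------------------------------------------------
# clock classification


def _blob_at(shape, z, x):
    out = np.zeros(shape, bool)
    out[z - 1: z + 2, 14:18, x - 1: x + 2] = True
    return out


def test_clock_order_right_middle_left():
    shape = (32, 32, 64)
    masks = [Mask(data=_blob_at(shape, 20, 32 + dx).astype(np.uint8))
             for dx in (-30, 0, 30)]
    labels = classify_clockwise(masks, body_axis_x=32.0)
    assert labels["right"] is masks[0]   # patient right = negative x
    assert labels["middle"] is masks[1]
    assert labels["left"] is masks[2]


def test_clock_permutation_equivariance():
    shape = (32, 32, 64)
    masks = [Mask(data=_blob_at(shape, 20, 32 + dx).astype(np.uint8))
             for dx in (-30, 0, 30)]
    swapped = [masks[2], masks[0], masks[1]]
    labels = classify_clockwise(swapped, body_axis_x=32.0)
    assert labels["right"] is masks[0]
    assert labels["left"] is masks[2]


def test_single_branch_labelled_right():
    shape = (32, 32, 64)
    m = Mask(data=_blob_at(shape, 20, 2).astype(np.uint8))
    labels = classify_clockwise([m], body_axis_x=32.0)
    assert labels == {"right": m}


def test_identical_centroids_rejected():
    shape = (16, 16, 16)
    m = Mask(data=_blob_at(shape, 8, 8).astype(np.uint8))
    with pytest.raises(ValueError):
        classify_clockwise([m, m], body_axis_x=8.0)


# ---------------------------------------------------------------------------
# portal extraction


def test_portal_is_largest_residual_and_conservation():
    shape = (32, 32, 32)
    branch = _tube(shape, 5, 28, 10, 10)
    trunk = np.zeros(shape, bool)
    trunk[15:18, 20:23, 4:28]= True          # large horizontal component
    frag = np.zeros(shape, bool)
    frag[6:8, 10:12, 12:14] = True           # touches the branch (26-conn)
    aux_frag = np.zeros(shape, bool)
    aux_frag[2:4, 28:30, 28:30] = True       # isolated
    vessels = _mask(branch | trunk | frag | aux_frag)
    portal, aux, merged = extract_portal(vessels, [_mask(branch)])
    assert np.array_equal(portal.as_bool(), trunk)
    assert np.array_equal(aux.as_bool(), aux_frag)
    assert np.array_equal(merged[0].as_bool(), branch | frag)
    # conservation: branches + portal + auxiliary == input vessels
    union = portal.as_bool() | aux.as_bool() | merged[0].as_bool()
    assert np.array_equal(union, vessels.as_bool())


def test_no_residuals_empty_auxiliary():
    shape = (16, 16, 16)
    branch = _tube(shape, 2, 14, 8, 8)
    portal, aux, merged = extract_portal(_mask(branch), [_mask(branch)])
    assert portal.n_voxels == 0 and aux.n_voxels == 0


# ---------------------------------------------------------------------------
# phantom end-to-end


def test_phantom_branch_labels_match_truth(default_truth):
    bs = identify_veins(default_truth.vessels, default_truth.liver)
    assert set(bs.branches) == {"right", "middle", "left"}
    for name, lab in (("right", 1), ("middle", 2), ("left", 3)):
        tb = default_truth.hepatic_branches.data == lab
        b = bs.branches[name].as_bool()
        assert (b & tb).sum() / tb.sum() >= 0.8
    # portal identified as the horizontal trunk
    tp = default_truth.portal.as_bool()
    assert (bs.portal.as_bool() & tp).sum() / tp.sum() >= 0.8
    # conservation over the whole identification
    union = bs.portal.as_bool() | bs.auxiliary.as_bool()
    for b in bs.branches.values():
        union |= b.as_bool()
    assert np.array_equal(union, default_truth.vessels.as_bool())


@pytest.mark.parametrize("seed", range(10))
def test_branch_labels_across_seeds(seed):
    """Branch labelling matches the generator truth for every seed."""
    from hepatoseg.phantom import default_spec, make_phantom, scaled_spec

    truth = make_phantom(scaled_spec(default_spec(seed), (64, 96, 96)))
    bs = identify_veins(truth.vessels, truth.liver)
    for name, lab in (("right", 1), ("middle", 2), ("left", 3)):
        tb = truth.hepatic_branches.data == lab
        assert (bs.branches[name].as_bool() & tb).sum() / tb.sum() >= 0.5
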