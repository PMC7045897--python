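"""Post-processing: thresholding, 3D components vs flood fill, slice rule."""

import numpy as np
import pytest

from deuseg import (
    binarize,
    connected_components_3d,
    postprocess_probability,
    remove_single_slice_components,
)

# ---------------------------------------------------------------------------
# independent flood-fill oracle

_OFFSETS = {
    6: [(dz, dy, dx) for dz, dy, dx in
        [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]],
    26: [(dz, dy, dx)
         for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first labeling, independent of scipy."""
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        queue = [start]
        labels[start] = next_label
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in _OFFSETS[connectivity]:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not labels[n]:
                    labels[n] = next_label
                    queue.append(n)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Equal partitions up to label permutation."""
    pairs = set(zip(a.ravel().tolist(), b.ravel().tolist()))
    return len({p[0] for p in pairs}) == len(pairs) == len({p[1] for p in pairs})


# ---------------------------------------------------------------------------


def test_binarize_examples_and_tie_rule():
    vol = np.full((2, 3, 3), 0.4)
    assert binarize(vol, 0.5).sum() == 0
    vol[0, 0, 0] = 0.5
    assert binarize(vol, 0.5)[0, 0, 0] == 1  # tie maps to foreground


def test_binarize_matches_elementwise_oracle():
    rng = np.random.default_rng(3)
    vol = rng.random((5, 6, 6))
    out = binarize(vol, 0.3)
    for idx in np.ndindex(vol.shape):
        assert out[idx] == (1 if vol[idx] >= 0.3 else 0)


def test_binarize_threshold_validation():
    with pytest.raises(ValueError):
        binarize(np.zeros((2, 2, 2)), 0.0)


def test_empty_mask_has_zero_components():
    lc = connected_components_3d(np.zeros((4, 4, 4), dtype=np.uint8))
    assert lc.component_count == 0


def test_corner_touching_voxels_depend_on_connectivity():
    mask = np.zeros((3, 3, 3), dtype=np.uint8)
    mask[0, 0, 0] = 1
    mask[1, 1, 1] = 1
    assert connected_components_3d(mask, connectivity=26).component_count == 1
    assert connected_components_3d(mask, connectivity=6).component_count == 2


@pytest.mark.parametrize("connectivity", [6, 26])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_components_match_flood_fill_oracle(connectivity, seed):
    rng = np.random.default_rng(seed)
    mask = (rng.random((8, 8, 8)) < 0.35).astype(np.uint8)
    lc = connected_components_3d(mask, connectivity)
    oracle = flood_fill_labels(mask, connectivity)
    assert lc.component_count == oracle.max()
    assert same_partition(lc.labels, oracle)


def test_non_binary_input_rejected():
    with pytest.raises(ValueError):
        connected_components_3d(np.full((2, 2, 2), 2))


def test_single_slice_component_removed():
    mask = np.zeros((10, 6, 6), dtype=np.uint8)
    mask[7, 2:4, 2:4] = 1
    out = remove_single_slice_components(connected_components_3d(mask))
    assert out.sum() == 0


def test_two_slice_component_retained_verbatim():
    mask = np.zeros((10, 6, 6), dtype=np.uint8)
    mask[7:9, 2:4, 2:4] = 1
    out = remove_single_slice_components(connected_components_3d(mask))
    assert np.array_equal(out, mask)


def test_mixture_keeps_exactly_multi_slice_components():
    mask = np.zeros((12, 10, 10), dtype=np.uint8)
    multi = np.zeros_like(mask)
    # three single-slice blobs
    mask[1, 1:3, 1:3] = 1
    mask[4, 6:8, 6:8] = 1
    mask[9, 1:3, 6:8] = 1
    # two multi-slice blobs
    multi[2:5, 1:3, 4:6] = 1
    multi[7:9, 6:9, 1:4] = 1
    mask |= multi
    out = remove_single_slice_components(connected_components_3d(mask))
    assert np.array_equal(out, multi)


def test_postprocess_never_adds_voxels_and_is_idempotent():
    rng = np.random.default_rng(5)
    prob = rng.random((6, 8, 8))
    once = postprocess_probability(prob)
    again = postprocess_probability(once.astype(float))
    assert np.all(once <= binarize(prob, 0.5))
    assert np.array_equal(once, again)
    # every surviving voxel belongs to a component spanning >= 2 slices
    lc = connected_components_3d(once)
    assert all(ext >= 2 for ext in lc.slice_extents)
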