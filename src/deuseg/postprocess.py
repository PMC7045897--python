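"""Per-patient 3D post-processing of predicted probability maps.

The per-slice network output is stacked into a probability volume,
thresholded, labeled into 3D connected components, and components confined
to a single axial slice are removed as isolated false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LabeledComponents",
    "binarize",
    "connected_components_3d",
    "remove_single_slice_components",
    "postprocess_probability",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class LabeledComponents:
    """3D component labeling: 0 = background, k = component k (1..count)."""

    labels: np.ndarray
    component_count: int
    slice_extents: list[int]

    def __post_init__(self) -> None:
        if len(self.slice_extents) != self.component_count:
            raise ValueError("one slice extent required per component")


def binarize(prob_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities; ties (p == threshold) map to foreground."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(prob_volume) >= threshold).astype(np.uint8)


def connected_components_3d(mask: np.ndarray, connectivity: int = 26) -> LabeledComponents:
    """Label 3D connected components under 6/18/26-adjacency."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, count = ndimage.label(mask, structure=structure)
    extents = []
    for k in range(1, count + 1):
        zs = np.nonzero((labels == k).any(axis=(1, 2)))[0]
        extents.append(int(zs[-1] - zs[0] + 1))
    return LabeledComponents(labels=labels, component_count=count, slice_extents=extents)


def remove_single_slice_components(labeled: LabeledComponents) -> np.ndarray:
    """Drop components confined to one axial slice; keep the rest verbatim."""
    keep = np.zeros(labeled.component_count + 1, dtype=bool)
    for k, ext in enumerate(labeled.slice_extents, start=1):
        keep[k] = ext >= 2
    return keep[labeled.labels].astype(np.uint8)


def postprocess_probability(prob_volume: np.ndarray, threshold: float = 0.5,
                            connectivity: int = 26) -> np.ndarray:
    """Full post-processing chain: binarize → 3D components → drop
    single-slice components.  Never adds voxels and is idempotent."""
    mask = binarize(prob_volume, threshold)
    labeled = connected_components_3d(mask, connectivity)
    return remove_single_slice_components(labeled)
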