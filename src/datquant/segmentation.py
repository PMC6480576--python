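"""Region-of-interest extraction: whole-brain thresholding and 3D seed
region growing of the striatal activity region.

Two ROI procedures are provided.  The *single threshold* method keeps
every voxel whose count strictly exceeds a fixed threshold (default 15,
the background level at the periphery of the head) and yields the
whole-brain sample used for histogram-shape features.  The *seed region
growing* method starts from the hottest voxel — the striatum carries the
highest dopamine-transporter uptake — and floods outward through
connected voxels whose counts stay above a fraction of the seed count
(default 50%, the standard nuclear-medicine isocontour for volumetrics).

Masks are plain boolean arrays congruent with their Volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Volume

__all__ = ["GrowConfig", "threshold_mask", "find_seed", "region_grow", "mask_volume"]

DEFAULT_THRESHOLD = 15.0


@dataclass(frozen=True)
class GrowConfig:
    """Inclusion rule for seed region growing.

    A voxel joins the region when its count >= ``include_fraction`` x seed
    count (and >= ``absolute_floor`` when set) and it is connected to the
    seed under the chosen neighbourhood (6 = faces, 26 = full 3D).
    """

    connectivity: int = 26
    include_fraction: float = 0.5
    absolute_floor: float | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        if not (0.0 < self.include_fraction <= 1.0):
            raise ValueError(f"include_fraction must be in (0, 1], got {self.include_fraction}")


def threshold_mask(volume: Volume, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Voxels with count strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return volume.counts > threshold


def find_seed(volume: Volume, within: np.ndarray | None = None) -> tuple[int, int, int]:
    """Index of the maximum-count voxel, optionally restricted to a mask.

    Ties are broken by lexicographic (C-order) index, which is what
    ``argmax`` returns for the first occurrence.
    """
    counts = volume.counts
    if counts.size == 0:
        raise ValueError("empty volume")
    if within is not None:
        if within.shape != counts.shape:
            raise ValueError("mask shape does not match volume")
        if not within.any():
            raise ValueError("empty search region")
        counts = np.where(within, counts, -np.inf)
    return tuple(int(i) for i in np.unravel_index(np.argmax(counts), counts.shape))


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def region_grow(
    volume: Volume, seed: tuple[int, int, int], cfg: GrowConfig | None = None
) -> np.ndarray:
    """Connected component of the seed under the relative inclusion rule.

    Implemented as connected-component labelling of the super-threshold
    set, which is traversal-order independent by construction.
    """
    cfg = cfg or GrowConfig()
    counts = volume.counts
    seed = tuple(int(i) for i in seed)
    if len(seed) != 3 or any(not (0 <= i < n) for i, n in zip(seed, counts.shape)):
        raise ValueError(f"seed {seed} outside grid {counts.shape}")
    seed_count = counts[seed]
    if seed_count <= 0:
        raise ValueError("seed count must be > 0 (relative inclusion rule undefined)")
    cut = cfg.include_fraction * seed_count
    if cfg.absolute_floor is not None:
        cut = max(cut, cfg.absolute_floor)
    admissible = counts >= cut
    labels, _ = ndimage.label(admissible, structure=_structure(cfg.connectivity))
    return labels == labels[seed]


def mask_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> Volume:
    """Wrap a boolean mask as a 0/1 Volume for NIfTI export / visual QC."""
    return Volume(counts=mask.astype(np.float64), spacing=spacing)
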