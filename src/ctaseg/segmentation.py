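"""Region growing, majority-rule cavity filling, and the full pipeline.

Region growing takes the connected component of the thresholded
vesselness map that contains the seed.  Enhancement responds weakly
inside thick vessels (the interior of the ascending aorta is locally
flat at coronary scales), which leaves dark cavities in the grown mask;
the 2D cavity fill repairs them slice by slice: any background pixel
with at least 4 foreground pixels among its 8 neighbours becomes
foreground, synchronously, iterated to a fixed point.  Filling only ever
adds voxels, so it is monotone and idempotent at convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .seeding import SeedingConfig, SeedingError, SeedPoint, find_aorta_seed
from .vesselness import VesselnessMap, VesselnessParams, multiscale_vesselness
from .volume_io import BinaryMask, Volume

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

# 8-neighbourhood of a pixel within its axial slice (3x3 minus centre)
_FILL_KERNEL = np.array([[[1, 1, 1],
                          [1, 0, 1],
                          [1, 1, 1]]], dtype=np.uint8)


class GrowthOverflowError(RuntimeError):
    """Region growing exceeded its voxel cap — the threshold is likely too low."""


@dataclass
class GrowConfig:
    """Region-growing parameters.

    threshold : vesselness inclusion threshold in [0, 1]
    connectivity : 6 (faces), 18 (+edges) or 26 (+corners); 26 default
        because thin oblique vessels touch diagonally
    max_voxels : growth cap; ``None`` means 10% of the volume (leak guard)
    force_seed : include a sub-threshold seed voxel with a warning
        instead of raising
    """

    threshold: float = 0.05
    connectivity: int = 26
    max_voxels: int | None = None
    force_seed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")


@dataclass
class PipelineResult:
    """Everything the full pipeline produced, for inspection/persistence."""

    mask: BinaryMask
    prefill_mask: BinaryMask
    vesselness: VesselnessMap
    seed: SeedPoint


def region_grow(vesselness: VesselnessMap | np.ndarray, seed: SeedPoint | tuple,
                config: GrowConfig | None = None) -> BinaryMask:
    """Connected component of ``{v >= threshold}`` containing the seed.

    ``vesselness`` may be a :class:`VesselnessMap` or a bare array (a
    binary array works: threshold 0.5 selects the ones).  Raises
    :class:`~ctaseg.seeding.SeedingError` if the seed falls below the
    threshold and ``force_seed`` is off, and :class:`GrowthOverflowError`
    when the region exceeds ``max_voxels``.
    """
    config = config or GrowConfig()
    if isinstance(vesselness, VesselnessMap):
        data = vesselness.data
        spacing, origin = vesselness.spacing, vesselness.origin
    else:
        data = np.asarray(vesselness)
        spacing, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    voxel = tuple(int(c) for c in (seed.voxel if isinstance(seed, SeedPoint) else seed))
    if any(c < 0 or c >= n for c, n in zip(voxel, data.shape)):
        raise ValueError(f"seed {voxel} outside volume of shape {data.shape}")
    above = data >= config.threshold
    if not above[voxel]:
        if not config.force_seed:
            raise SeedingError(
                f"seed {voxel} has vesselness {data[voxel]:.4g} below the "
                f"growing threshold {config.threshold}")
        logger.warning("seed %s below threshold (%.4g < %s); forcing it into the region",
                       voxel, float(data[voxel]), config.threshold)
        above = above.copy()
        above[voxel] = True
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[config.connectivity])
    labels, _ = ndimage.label(above, structure=structure)
    region = labels == labels[voxel]
    cap = config.max_voxels if config.max_voxels is not None else int(0.10 * data.size)
    grown = int(region.sum())
    if grown > cap:
        raise GrowthOverflowError(
            f"region growing reached {grown} voxels (cap {cap}); "
            "the vesselness threshold is likely too low for this volume")
    return BinaryMask(data=region.astype(np.uint8), spacing=spacing, origin=origin)


def _fill_pass(slices: np.ndarray) -> np.ndarray:
    """One synchronous majority pass over every axial slice at once."""
    counts = ndimage.convolve(slices, _FILL_KERNEL, mode="constant", cval=0)
    return (slices | ((slices == 0) & (counts >= 4))).astype(np.uint8)


def fill_cavities_2d(mask: BinaryMask, max_iterations: int = 10_000) -> BinaryMask:
    """Iterated 2D majority fill: >= 4 of 8 in-slice neighbours turns a
    background pixel into foreground.

    Updates within a pass are synchronous (all decisions read the
    previous state), so the result is independent of pixel visiting
    order; passes repeat until nothing changes.  Foreground is never
    removed.  Pixels outside the slice count as background.
    """
    current = np.ascontiguousarray(mask.data, dtype=np.uint8)
    for _ in range(max_iterations):
        nxt = _fill_pass(current)
        if np.array_equal(nxt, current):
            break
        current = nxt
    return BinaryMask(data=current, spacing=mask.spacing, origin=mask.origin)


def segment_pipeline(volume: Volume,
                     params: VesselnessParams | None = None,
                     grow: GrowConfig | None = None,
                     seed: SeedPoint | tuple | None = None,
                     seeding: SeedingConfig | None = None) -> PipelineResult:
    """Full segmentation: enhance -> seed -> grow -> fill.

    ``seed`` overrides automatic aorta detection.  With the default
    seeding config the Hough transform runs on the enhanced volume;
    set ``seeding.source = 'intensity'`` to use raw intensities.
    Stage failures propagate as their own exception types
    (:class:`SeedingError`, :class:`GrowthOverflowError`).
    """
    params = params or VesselnessParams()
    grow = grow or GrowConfig()
    seeding = seeding or SeedingConfig()
    vmap = multiscale_vesselness(volume, params)
    if seed is None:
        source = vmap if seeding.source == "enhanced" else volume
        seed = find_aorta_seed(source, seeding)
        logger.info("automatic %s seed at voxel %s", seed.label, seed.voxel)
    elif not isinstance(seed, SeedPoint):
        seed = SeedPoint(voxel=tuple(int(c) for c in seed), label="aorta")
    prefill = region_grow(vmap, seed, grow)
    filled = fill_cavities_2d(prefill)
    logger.info("pipeline: %d voxels grown, %d after cavity fill",
                prefill.count(), filled.count())
    return PipelineResult(mask=filled, prefill_mask=prefill, vesselness=vmap, seed=seed)
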