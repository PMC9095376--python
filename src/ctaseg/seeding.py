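"""Circle-Hough seed detection on axial slices.

The ascending aorta is the one structure a circle Hough transform finds
reliably in an (enhanced) CTA stack: a large, nearly circular, bright
cross-section that persists across many consecutive axial slices.  The
seed for region growing is taken at the centre of the most consistent
chain of per-slice circle detections; smaller persistent circles are
labelled as coronary candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import feature, transform

logger = logging.getLogger(__name__)


class SeedingError(RuntimeError):
    """No usable seed could be found automatically."""


@dataclass
class CircleDetection:
    """One circle found in one axial slice."""

    slice_index: int
    center: tuple[int, int]        # (y, x) voxel coordinates
    radius: float                  # mm
    accumulator_score: float


@dataclass
class SeedPoint:
    """A labelled starting voxel for region growing."""

    voxel: tuple[int, int, int]    # (z, y, x)
    label: str = "aorta"           # aorta | left_coronary | right_coronary | coronary


@dataclass
class SeedingConfig:
    """Knobs for aorta-seed detection.

    radius_range : circle radii searched, mm (ascending aorta ~ 10-20)
    radius_step : accumulator radius discretisation, mm
    drift_tolerance : max centre movement between consecutive slices, mm
    min_chain : minimum consecutive slices a circle must persist
    max_circles_per_slice : detections kept per slice
    coronary_radius : radius (mm) below which a persistent circle is
        labelled coronary rather than aorta
    source : 'enhanced' runs Hough on the vesselness map, 'intensity'
        on the raw volume
    support_fraction : binarise each slice at this fraction of the
        volume-wide maximum before edge detection, so the circle is fit
        to the structure's support boundary — the enhanced response of a
        large vessel fades gradually and its raw gradient ring sits well
        inside the anatomical radius the search range encodes.  ``None``
        runs the edge detector on raw values.
    """

    radius_range: tuple[float, float] = (10.0, 20.0)
    radius_step: float = 0.5
    drift_tolerance: float = 5.0
    min_chain: int = 3
    max_circles_per_slice: int = 3
    coronary_radius: float = 5.0
    source: str = "enhanced"
    support_fraction: float | None = 0.1


def hough_circles(slice_2d: np.ndarray, radius_range: tuple[float, float],
                  spacing_yx: tuple[float, float] = (1.0, 1.0),
                  radius_step: float = 0.5,
                  max_circles: int = 3,
                  edge_sigma: float = 2.0,
                  min_score: float = 0.25,
                  binarize_level: float | None = None) -> list[CircleDetection]:
    """Detect circles in one axial slice via the circle Hough transform.

    Edges come from a Canny detector on the normalised slice (or on its
    binarised support when ``binarize_level`` is given); the Hough
    accumulator is swept over radii spaced ``radius_step`` mm apart.
    Detections are returned sorted by accumulator score (the fraction of
    the circle's circumference that voted, so 1.0 is a complete circle)
    descending; scores below ``min_score`` are dropped.  A blank slice
    yields [].
    """
    lo, hi = radius_range
    if lo <= 0 or hi <= lo:
        raise ValueError(f"radius_range must be positive and increasing, got {radius_range}")
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    if binarize_level is not None:
        field = (slice_2d >= binarize_level).astype(np.float64)
    else:
        ptp = slice_2d.max() - slice_2d.min()
        if ptp == 0:
            return []
        field = (slice_2d - slice_2d.min()) / ptp
    if not field.any():
        return []
    edges = feature.canny(field, sigma=edge_sigma)
    if not edges.any():
        return []
    # Radii are physical; convert to pixels with the mean in-plane spacing
    # (axial CT voxels are square to good approximation).
    px = float(np.mean(spacing_yx))
    radii_mm = np.arange(lo, hi + radius_step / 2, radius_step)
    radii_px = np.maximum(radii_mm / px, 1.0)
    # hough_circle normalises the accumulator by circle perimeter, so
    # peak values are comparable across radii
    accum = transform.hough_circle(edges, radii_px)
    # peak suppression in hough_circle_peaks is per radius layer, so the
    # same circle surfaces at neighbouring radii; overfetch and dedupe by
    # centre distance, keeping the best-scoring radius
    _, cx, cy, r_peaks = transform.hough_circle_peaks(
        accum, radii_px, total_num_peaks=4 * max_circles, normalize=False)
    candidates = []
    for x, y, r in zip(cx, cy, r_peaks):
        k = min(int(np.searchsorted(radii_px, r)), len(radii_mm) - 1)
        score = float(accum[k, int(y), int(x)])
        if score >= min_score:
            candidates.append(CircleDetection(
                slice_index=-1, center=(int(y), int(x)),
                radius=float(radii_mm[k]), accumulator_score=score))
    candidates.sort(key=lambda d: d.accumulator_score, reverse=True)
    detections: list[CircleDetection] = []
    for cand in candidates:
        dup = any(
            np.hypot(cand.center[0] - kept.center[0], cand.center[1] - kept.center[1])
            <= 0.5 * (cand.radius + kept.radius) / px
            for kept in detections)
        if not dup:
            detections.append(cand)
        if len(detections) == max_circles:
            break
    return detections


def _detect_all_slices(data: np.ndarray, spacing, config: SeedingConfig,
                       radius_range: tuple[float, float]) -> list[list[CircleDetection]]:
    spacing_yx = (spacing[1], spacing[2])
    level = None
    if config.support_fraction is not None and data.max() > 0:
        level = config.support_fraction * float(data.max())
    per_slice: list[list[CircleDetection]] = []
    for z in range(data.shape[0]):
        dets = hough_circles(data[z], radius_range, spacing_yx,
                             radius_step=config.radius_step,
                             max_circles=config.max_circles_per_slice,
                             binarize_level=level)
        for d in dets:
            d.slice_index = z
        per_slice.append(dets)
    return per_slice


def _best_chain(per_slice: list[list[CircleDetection]], spacing,
                config: SeedingConfig) -> list[CircleDetection] | None:
    """Greedy chains of slice-consecutive detections with bounded centre drift."""
    n = len(per_slice)
    tol = config.drift_tolerance
    sy, sx = spacing[1], spacing[2]
    best: list[CircleDetection] | None = None
    best_score = -np.inf
    for z0 in range(n):
        for start in per_slice[z0]:
            chain = [start]
            prev = start
            for z in range(z0 + 1, n):
                candidates = [
                    d for d in per_slice[z]
                    if np.hypot((d.center[0] - prev.center[0]) * sy,
                                (d.center[1] - prev.center[1]) * sx) <= tol
                ]
                if not candidates:
                    break
                nxt = max(candidates, key=lambda d: d.accumulator_score)
                chain.append(nxt)
                prev = nxt
            if len(chain) >= config.min_chain:
                score = sum(d.accumulator_score for d in chain)
                if score > best_score:
                    best, best_score = chain, score
    return best


def find_aorta_seed(volume_or_map, config: SeedingConfig | None = None) -> SeedPoint:
    """Locate the ascending-aorta seed voxel.

    Runs the circle Hough transform on every axial slice in the aorta
    radius range, links detections into chains whose centres stay within
    the drift tolerance across consecutive slices, keeps the chain of
    length >= ``min_chain`` with the highest summed accumulator score,
    and returns the centre voxel of that chain's middle slice.

    Accepts a :class:`~ctaseg.volume_io.Volume` or a
    :class:`~ctaseg.vesselness.VesselnessMap` (anything with ``data``
    and ``spacing``).  Raises :class:`SeedingError` when no persistent
    circular structure exists — pass a manual seed in that case
    (``ctaseg run --seed z,y,x``).
    """
    config = config or SeedingConfig()
    data = np.asarray(volume_or_map.data, dtype=np.float64)
    spacing = volume_or_map.spacing
    if data.shape[0] < 3:
        raise SeedingError("need at least 3 axial slices to confirm an aorta chain")
    per_slice = _detect_all_slices(data, spacing, config, config.radius_range)
    chain = _best_chain(per_slice, spacing, config)
    if chain is None:
        raise SeedingError(
            "no circular structure persisted across "
            f">= {config.min_chain} consecutive slices in the "
            f"{config.radius_range} mm radius range; supply a manual seed "
            "(CLI: --seed z,y,x)")
    mid = chain[len(chain) // 2]
    return SeedPoint(voxel=(mid.slice_index, mid.center[0], mid.center[1]), label="aorta")


def detect_slices(volume_or_map, config: SeedingConfig | None = None) -> list[list[CircleDetection]]:
    """Per-slice circle detections over a whole volume (for export/inspection)."""
    config = config or SeedingConfig()
    data = np.asarray(volume_or_map.data, dtype=np.float64)
    return _detect_all_slices(data, volume_or_map.spacing, config, config.radius_range)


def detections_to_rows(detections: list[list[CircleDetection]] | list[CircleDetection]) -> list[dict]:
    """Flatten detections to CSV-ready rows
    (slice_index, center_y, center_x, radius_mm, score)."""
    flat: list[CircleDetection] = []
    for item in detections:
        flat.extend(item if isinstance(item, list) else [item])
    return [
        {"slice_index": d.slice_index, "center_y": d.center[0], "center_x": d.center[1],
         "radius_mm": d.radius, "score": d.accumulator_score}
        for d in flat
    ]


def superimpose_layers(detections: list[list[CircleDetection]],
                       config: SeedingConfig | None = None,
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> list[SeedPoint]:
    """Aggregate per-slice circle detections into 3D seed candidates.

    Detections from consecutive slices whose centres stay within the
    drift tolerance are clustered; clusters persisting for fewer than
    ``min_chain`` slices are dropped as spurious.  Each surviving
    cluster yields one seed at its middle detection, labelled ``aorta``
    or ``coronary`` by its median radius against ``coronary_radius``.
    """
    config = config or SeedingConfig()
    sy, sx = spacing[1], spacing[2]
    tol = config.drift_tolerance
    clusters: list[list[CircleDetection]] = []
    open_clusters: list[list[CircleDetection]] = []
    for dets in detections:
        still_open: list[list[CircleDetection]] = []
        used = [False] * len(dets)
        for cluster in open_clusters:
            prev = cluster[-1]
            match = None
            for i, d in enumerate(dets):
                if used[i]:
                    continue
                dist = np.hypot((d.center[0] - prev.center[0]) * sy,
                                (d.center[1] - prev.center[1]) * sx)
                if dist <= tol:
                    match = i
                    break
            if match is not None:
                used[match] = True
                cluster.append(dets[match])
                still_open.append(cluster)
            else:
                clusters.append(cluster)
        for i, d in enumerate(dets):
            if not used[i]:
                still_open.append([d])
        open_clusters = still_open
    clusters.extend(open_clusters)
    seeds = []
    for cluster in clusters:
        if len(cluster) < config.min_chain:
            continue
        mid = cluster[len(cluster) // 2]
        median_radius = float(np.median([d.radius for d in cluster]))
        label = "aorta" if median_radius >= config.coronary_radius else "coronary"
        seeds.append(SeedPoint(voxel=(mid.slice_index, mid.center[0], mid.center[1]),
                               label=label))
    # With one aorta reference, tell the two coronary ostia apart by which
    # side of the aorta they sit on (x axis of the axial plane).
    aortas = [s for s in seeds if s.label == "aorta"]
    if len(aortas) == 1:
        ax = aortas[0].voxel[2]
        for s in seeds:
            if s.label == "coronary":
                s.label = "left_coronary" if s.voxel[2] >= ax else "right_coronary"
    return seeds
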