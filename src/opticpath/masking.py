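"""Streamline density maps and the thresholded, continuity-checked tract mask.

The pipeline here is: project streamlines into voxel space as a visitation
density map, keep only voxels reaching 40% of their coronal slice's maximum
count, remove voxels dominated by the background compartment, and iterate
the background cutoff until one connected component joins the seed (LGN) and
waypoint (postorbital) regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .compartments import CompartmentFractions
from .grid import VoxelGrid

__all__ = [
    "StreamlineSet",
    "DensityMap",
    "Landmarks",
    "TractMask",
    "TractNotContinuousError",
    "density_map",
    "slicewise_threshold",
    "exclusion_mask",
    "continuity_check",
    "refine_until_continuous",
    "piecewise_union",
]

logger = logging.getLogger(__name__)

#: 3x3x3 structuring element giving 26-connectivity.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class StreamlineSet:
    """Polylines in world mm with per-streamline side and crossing labels.

    ``side[i]`` is "left" or "right" (the eye/orbit a streamline terminates
    at); ``kind[i]`` is "crossing" or "noncrossing".
    """

    streamlines: list  # of (n_i, 3) float arrays
    side: np.ndarray
    kind: np.ndarray

    def __post_init__(self) -> None:
        sls = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in sls:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (n >= 2, 3) array")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")
        side = np.asarray(self.side, dtype=object)
        kind = np.asarray(self.kind, dtype=object)
        if not (len(sls) == side.size == kind.size):
            raise ValueError("side/kind labels must match streamline count")
        object.__setattr__(self, "streamlines", sls)
        object.__setattr__(self, "side", side)
        object.__setattr__(self, "kind", kind)

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, side: str | None = None, kind: str | None = None) -> "StreamlineSet":
        keep = np.ones(len(self), dtype=bool)
        if side is not None:
            keep &= self.side == side
        if kind is not None:
            keep &= self.kind == kind
        idx = np.flatnonzero(keep)
        return StreamlineSet([self.streamlines[i] for i in idx], self.side[idx], self.kind[idx])


@dataclass(frozen=True)
class DensityMap:
    """Per-voxel streamline visitation counts on a grid."""

    counts: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != self.grid.shape:
            raise ValueError(f"counts shape {c.shape} does not match grid {self.grid.shape}")
        if np.any(c < 0):
            raise ValueError("density counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def support(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class Landmarks:
    """Seed (LGN) and waypoint (postorbital) ROIs plus the chiasm slice."""

    seed: np.ndarray  # boolean volume
    waypoint: np.ndarray  # boolean volume
    chiasm_slice: int
    grid: VoxelGrid

    def __post_init__(self) -> None:
        seed = np.asarray(self.seed, dtype=bool)
        waypoint = np.asarray(self.waypoint, dtype=bool)
        if seed.shape != self.grid.shape or waypoint.shape != self.grid.shape:
            raise ValueError("ROI volumes must match the grid shape")
        if np.any(seed & waypoint):
            raise ValueError("seed and waypoint ROIs must be disjoint")
        ap = self.grid.ap_axis
        seed_slices = np.unique(np.nonzero(seed)[ap])
        way_slices = np.unique(np.nonzero(waypoint)[ap])
        if seed_slices.size and way_slices.size:
            lo, hi = sorted((float(np.median(seed_slices)), float(np.median(way_slices))))
            if not (lo < self.chiasm_slice < hi):
                raise ValueError("chiasm slice must lie strictly between seed and waypoint")
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "waypoint", waypoint)

    @property
    def seed_voxel_count(self) -> int:
        return int(self.seed.sum())


@dataclass(frozen=True)
class TractMask:
    """Boolean tract membership with its landmarks and final nBG threshold."""

    mask: np.ndarray
    grid: VoxelGrid
    landmarks: Landmarks | None = None
    exclusion_threshold: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != self.grid.shape:
            raise ValueError(f"mask shape {m.shape} does not match grid {self.grid.shape}")
        object.__setattr__(self, "mask", m)


class TractNotContinuousError(RuntimeError):
    """No background threshold yields a continuous seed-to-waypoint tract."""


def density_map(streamlines: StreamlineSet, grid: VoxelGrid) -> DensityMap:
    """Project streamlines to a voxel visitation-count map.

    Each streamline increments a voxel at most once regardless of how often
    it re-enters. Polylines are resampled at half-voxel arclength steps so no
    traversed voxel is skipped. Points outside the grid are clipped away with
    a logged warning.
    """
    counts = np.zeros(grid.shape, dtype=np.int64)
    step = grid.voxel_size / 2.0
    n_clipped = 0
    for poly in streamlines.streamlines:
        pts = _resample(poly, step)
        idx = grid.world_to_voxel(pts)
        inside = grid.contains(idx)
        if not inside.all():
            n_clipped += 1
        idx = idx[inside]
        if idx.size == 0:
            continue
        visited = np.unique(idx, axis=0)
        counts[visited[:, 0], visited[:, 1], visited[:, 2]] += 1
    if n_clipped:
        logger.warning("%d streamline(s) extended outside the grid and were clipped", n_clipped)
    return DensityMap(counts, grid)


def _resample(poly: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at arclength spacing <= step, keeping vertices.

    Every segment is subdivided with the count required by the longest one;
    shorter segments are merely oversampled, which is harmless because voxel
    visitation is deduplicated downstream.
    """
    a, b = poly[:-1], poly[1:]
    longest = float(np.linalg.norm(b - a, axis=1).max())
    n = max(1, int(np.ceil(longest / step)))
    t = (np.arange(1, n + 1) / n)[None, :, None]
    pts = a[:, None, :] + t * (b - a)[:, None, :]
    return np.vstack([poly[:1], pts.reshape(-1, 3)])


def slicewise_threshold(density: DensityMap, fraction: float = 0.4) -> TractMask:
    """Keep voxels reaching ``fraction`` of their AP slice's maximum count.

    Per slice with any fibre, voxels with counts strictly below
    ``fraction * slice_max`` are excluded — exact ties at the cutoff are
    kept. Empty slices contribute nothing.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ap = density.grid.ap_axis
    counts = np.moveaxis(density.counts, ap, 0)
    slice_max = counts.reshape(counts.shape[0], -1).max(axis=1)
    cutoff = fraction * slice_max
    keep = counts >= cutoff[:, None, None]
    keep &= counts > 0
    return TractMask(np.moveaxis(keep, 0, ap), density.grid)


def exclusion_mask(fractions: CompartmentFractions, threshold: float) -> np.ndarray:
    """True (excluded) where the normalized background fraction >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return np.asarray(fractions.nbg) >= threshold


def continuity_check(mask: TractMask, landmarks: Landmarks) -> bool:
    """True iff one 26-connected component touches both seed and waypoint."""
    labels, n = ndimage.label(mask.mask, structure=CONNECTIVITY_26)
    if n == 0:
        return False
    seed_labels = np.unique(labels[landmarks.seed & mask.mask])
    way_labels = np.unique(labels[landmarks.waypoint & mask.mask])
    shared = np.intersect1d(seed_labels, way_labels)
    return bool(np.any(shared > 0))


def refine_until_continuous(
    density: DensityMap,
    fractions: CompartmentFractions,
    landmarks: Landmarks,
    t0: float = 0.15,
    step: float = 0.01,
    fraction: float = 0.4,
    direction: str = "decreasing",
    label: str = "",
) -> TractMask:
    """Iterate the background cutoff until the tract is continuous.

    Starting at ``t0``, the slicewise-thresholded mask minus the exclusion
    mask at threshold ``t`` is tested for seed-to-waypoint continuity; ``t``
    moves by ``step`` per iteration in ``direction`` (default decreasing)
    while it stays in (0, 1]. If that sweep fails, the opposite direction is
    tried once from ``t0`` before raising ``TractNotContinuousError``.
    """
    if not 0 < t0 <= 1:
        raise ValueError(f"t0 must be in (0, 1], got {t0}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if direction not in ("decreasing", "increasing"):
        raise ValueError(f"direction must be 'decreasing' or 'increasing', got {direction!r}")

    base = slicewise_threshold(density, fraction=fraction)
    signs = (-1.0, 1.0) if direction == "decreasing" else (1.0, -1.0)
    for sign in signs:
        i = 0
        while True:
            t = round(t0 + sign * i * step, 12)  # exact decimal ladder
            if not 0 < t <= 1:
                break
            mask = TractMask(
                base.mask & ~exclusion_mask(fractions, t),
                density.grid,
                landmarks=landmarks,
                exclusion_threshold=t,
            )
            if continuity_check(mask, landmarks):
                return mask
            i += 1
    where = f" for {label}" if label else ""
    raise TractNotContinuousError(
        f"tract not continuous{where}: no background threshold in (0, 1] "
        f"(start {t0}, step {step}) links the seed to the waypoint"
    )


def piecewise_union(pre_mask: TractMask, post_mask: TractMask) -> TractMask:
    """Voxelwise OR of pre- and postchiasmatic masks.

    Landmark metadata is merged: the seed comes from the postchiasmatic
    piece, the waypoint from the prechiasmatic one.
    """
    if pre_mask.grid != post_mask.grid:
        raise ValueError("pre and post masks must share one grid")
    merged_landmarks = None
    if pre_mask.landmarks is not None and post_mask.landmarks is not None:
        merged_landmarks = Landmarks(
            seed=post_mask.landmarks.seed,
            waypoint=pre_mask.landmarks.waypoint,
            chiasm_slice=post_mask.landmarks.chiasm_slice,
            grid=pre_mask.grid,
        )
    thresholds = [
        t for t in (pre_mask.exclusion_threshold, post_mask.exclusion_threshold) if t is not None
    ]
    return TractMask(
        pre_mask.mask | post_mask.mask,
        pre_mask.grid,
        landmarks=merged_landmarks,
        exclusion_threshold=max(thresholds) if thresholds else None,
    )
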