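"""Tract-level geometry: anatomy-scaled segment binning, ROI partition,
decussation fraction, Dice overlap and the tractography success verdict.

Segment numbering runs posterior to anterior: segment 1 is adjacent to the
LGN, segment 10 is the postchiasmatic segment adjacent to the chiasm,
segment 11 the prechiasmatic one, and segment 17 is adjacent to the orbit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masking import DensityMap, Landmarks, TractMask, continuity_check

__all__ = [
    "SegmentAssignment",
    "RoiPartition",
    "SuccessReport",
    "bin_segments",
    "partition_rois",
    "decussation_fraction",
    "dice",
    "success_report",
]

N_POST_DEFAULT = 10  # LGN -> chiasm
N_PRE_DEFAULT = 7  # chiasm -> orbit


@dataclass(frozen=True)
class SegmentAssignment:
    """Mapping of AP slices to anatomy-scaled segments.

    ``segment_of_slice`` maps AP slice index -> segment id (1..n_post+n_pre);
    slices outside [orbit, LGN] are absent. ``boundaries_mm`` holds the
    n_post+n_pre+1 segment edges from the LGN end to the orbit end.
    """

    segment_of_slice: dict[int, int]
    boundaries_mm: np.ndarray
    lgn_mm: float
    chiasm_mm: float
    orbit_mm: float
    n_post: int = N_POST_DEFAULT
    n_pre: int = N_PRE_DEFAULT

    @property
    def n_segments(self) -> int:
        return self.n_post + self.n_pre

    @property
    def mean_segment_length_mm(self) -> float:
        return (self.lgn_mm - self.orbit_mm) / self.n_segments

    def to_frame(self, grid) -> pd.DataFrame:
        """Tidy table with one row per assigned AP slice."""
        rows = sorted(self.segment_of_slice.items())
        part = partition_rois(self)
        return pd.DataFrame(
            {
                "slice_index": [s for s, _ in rows],
                "ap_mm": [grid.slice_center_mm(s) for s, _ in rows],
                "segment_id": [g for _, g in rows],
                "roi_label": [part.roi_of_segment[g] for _, g in rows],
            }
        )


@dataclass(frozen=True)
class RoiPartition:
    """Macroscopic ROI label for every segment id.

    Labels are "optic_tract" (segments 1..n_post-1), "chiasm" (the two
    juxtachiasmatic segments, pooled bilaterally downstream) and
    "optic_nerve" (segments n_post+2..end).
    """

    roi_of_segment: dict[int, str]

    def segments_of(self, roi: str) -> list[int]:
        return [s for s, r in self.roi_of_segment.items() if r == roi]


@dataclass(frozen=True)
class SuccessReport:
    success: bool
    reasons: list[str] = field(default_factory=list)


def bin_segments(
    mask: TractMask,
    landmarks: Landmarks | None = None,
    n_post: int = N_POST_DEFAULT,
    n_pre: int = N_PRE_DEFAULT,
    lgn_mm: float | None = None,
    chiasm_mm: float | None = None,
    orbit_mm: float | None = None,
) -> SegmentAssignment:
    """Divide the tract's AP extent into n_post + n_pre equal-length segments.

    The interval [chiasm, LGN] is split into ``n_post`` equal mm intervals
    and [orbit, chiasm] into ``n_pre``; per-subject interval lengths scale
    with the landmark positions. Each AP slice is assigned by its centre
    coordinate. Landmark AP positions default to the ROI centroids of
    ``landmarks`` (seed -> LGN, waypoint -> orbit) but can be given directly.
    """
    grid = mask.grid
    landmarks = landmarks if landmarks is not None else mask.landmarks
    ap = grid.ap_axis
    if lgn_mm is None or orbit_mm is None or chiasm_mm is None:
        if landmarks is None:
            raise ValueError("either landmarks or explicit landmark positions are required")
        lgn_mm = lgn_mm if lgn_mm is not None else float(
            grid.slice_center_mm(np.nonzero(landmarks.seed)[ap]).mean()
        )
        orbit_mm = orbit_mm if orbit_mm is not None else float(
            grid.slice_center_mm(np.nonzero(landmarks.waypoint)[ap]).mean()
        )
        chiasm_mm = chiasm_mm if chiasm_mm is not None else float(
            grid.slice_center_mm(landmarks.chiasm_slice)
        )
    if not lgn_mm > chiasm_mm > orbit_mm:
        raise ValueError(
            f"landmarks must be ordered LGN > chiasm > orbit on the AP axis, got "
            f"{lgn_mm} / {chiasm_mm} / {orbit_mm}"
        )

    post_edges = np.linspace(lgn_mm, chiasm_mm, n_post + 1)
    pre_edges = np.linspace(chiasm_mm, orbit_mm, n_pre + 1)
    boundaries = np.concatenate([post_edges, pre_edges[1:]])  # LGN .. orbit, decreasing

    segment_of_slice: dict[int, int] = {}
    for s in range(grid.dims[ap]):
        c = float(grid.slice_center_mm(s))
        if not orbit_mm <= c <= lgn_mm:
            continue
        # boundaries decrease; segment g spans [boundaries[g], boundaries[g-1])
        # with the shared boundary slice going to the posterior segment
        g = int(np.searchsorted(-boundaries, -c, side="right"))
        g = min(max(g, 1), n_post + n_pre)
        segment_of_slice[s] = g

    n_total = n_post + n_pre
    counts = np.bincount(list(segment_of_slice.values()), minlength=n_total + 1)[1:]
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0) + 1
        portions = sorted(
            {"postchiasmatic (LGN-chiasm)" if g <= n_post else "prechiasmatic (chiasm-orbit)"
             for g in missing}
        )
        raise ValueError(
            f"fewer slices than segments: segment(s) {missing.tolist()} in the "
            f"{' and '.join(portions)} portion(s) contain no slice"
        )
    return SegmentAssignment(
        segment_of_slice=segment_of_slice,
        boundaries_mm=boundaries,
        lgn_mm=float(lgn_mm),
        chiasm_mm=float(chiasm_mm),
        orbit_mm=float(orbit_mm),
        n_post=n_post,
        n_pre=n_pre,
    )


def partition_rois(segments: SegmentAssignment) -> RoiPartition:
    """Assign each segment to exactly one macroscopic ROI.

    The two segments flanking the chiasm (n_post and n_post+1) form the
    chiasm ROI; segments 1..n_post-1 the optic tract; the rest the optic
    nerve.
    """
    n_post, n_total = segments.n_post, segments.n_segments
    roi_of_segment = {}
    for g in range(1, n_total + 1):
        if g <= n_post - 1:
            roi_of_segment[g] = "optic_tract"
        elif g <= n_post + 1:
            roi_of_segment[g] = "chiasm"
        else:
            roi_of_segment[g] = "optic_nerve"
    return RoiPartition(roi_of_segment)


def decussation_fraction(cross_density: DensityMap, noncross_density: DensityMap) -> float:
    """Noncrossing fraction by weighted fibre volume for one LGN side.

    Weighted fibre volume is the voxelwise sum of streamline visitation
    counts; the fraction is noncrossing volume over total volume.
    """
    if cross_density.grid != noncross_density.grid:
        raise ValueError("density maps must share one grid")
    cross = float(cross_density.counts.sum())
    noncross = float(noncross_density.counts.sum())
    total = cross + noncross
    if total == 0:
        raise ValueError("both density maps are empty; fraction undefined")
    return noncross / total


def dice(mask_a: TractMask, mask_b: TractMask) -> float:
    """Dice overlap ``2 |A ^ B| / (|A| + |B|)`` of two tract masks."""
    if mask_a.grid != mask_b.grid:
        raise ValueError("masks must share one grid")
    a, b = mask_a.mask, mask_b.mask
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty; Dice undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def success_report(
    masks: dict[str, TractMask],
    noncrossing_fractions: dict[str, float],
    dice_by_side: dict[str, float] | None = None,
    dice_min: float = 0.5,
    fraction_delta: float = 0.15,
) -> SuccessReport:
    """Verdict on the three tractography success criteria.

    (i) every requested tract mask is continuous between its landmarks,
    (ii) the crossing/noncrossing Dice overlap reaches ``dice_min``, and
    (iii) each side's noncrossing fraction lies within
    ``0.5 +/- fraction_delta``.
    ``masks`` maps a tract name (e.g. "left/crossing") to its mask; Dice
    values per side are either supplied or computed from masks named
    "<side>/crossing" and "<side>/noncrossing".
    """
    reasons: list[str] = []
    for name, mask in masks.items():
        if mask.landmarks is None:
            reasons.append(f"tract {name}: no landmarks attached, continuity unverifiable")
        elif not continuity_check(mask, mask.landmarks):
            reasons.append(f"tract {name}: not continuous between seed and waypoint")

    if dice_by_side is None:
        dice_by_side = {}
        for side in ("left", "right"):
            a, b = masks.get(f"{side}/crossing"), masks.get(f"{side}/noncrossing")
            if a is not None and b is not None:
                dice_by_side[side] = dice(a, b)
    for side, d in dice_by_side.items():
        if d < dice_min:
            reasons.append(
                f"side {side}: crossing/noncrossing Dice {d:.3f} below minimum {dice_min}"
            )

    lo, hi = 0.5 - fraction_delta, 0.5 + fraction_delta
    for side, f in noncrossing_fractions.items():
        if not lo <= f <= hi:
            reasons.append(
                f"side {side}: noncrossing fraction {f:.3f} outside [{lo:.2f}, {hi:.2f}]"
            )
    return SuccessReport(success=not reasons, reasons=reasons)
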