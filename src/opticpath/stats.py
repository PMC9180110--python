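"""Along-tract statistics: per-slice means with validity filtering, weighted
segment/ROI summaries, Welch group comparison under Hochberg step-up FWE
control, and eye-mapped Pearson correlations with clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compartments import CompartmentFractions
from .geometry import RoiPartition, SegmentAssignment
from .masking import DensityMap, Landmarks, TractMask
from .tensor import ScalarMaps

__all__ = [
    "VARIABLES",
    "WelchResult",
    "slice_profile",
    "segment_means",
    "subject_stats",
    "welch_from_summary",
    "hochberg",
    "group_compare",
    "clinical_correlate",
]

#: The five along-tract variables, in reporting order.
VARIABLES = ("fa", "md", "ncsf", "ngm", "nwm")


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# per-slice and per-segment summaries
# ---------------------------------------------------------------------------

def slice_profile(
    scalars: ScalarMaps,
    fractions: CompartmentFractions,
    density: DensityMap,
    mask: TractMask,
    landmarks: Landmarks | None = None,
) -> pd.DataFrame:
    """Mean tract values per AP slice.

    FA/MD means exclude voxels failing the validity mask; compartment
    fractions are averaged over all in-mask voxels. Slices with no in-mask
    voxel get NaN rows (missing, not zero). Also reports the in-mask voxel
    count, the count of voxels containing at least one fibre, and the slice's
    maximum fibre count normalized by the number of seed voxels.
    """
    landmarks = landmarks if landmarks is not None else mask.landmarks
    m = mask.mask
    if not m.any():
        raise ValueError("tract mask is empty")
    grid = mask.grid
    ap = grid.ap_axis
    n_slices = grid.dims[ap]
    seed_count = landmarks.seed_voxel_count if landmarks is not None else None

    def per_slice(vol: np.ndarray, s: int) -> np.ndarray:
        return np.take(vol, s, axis=ap)

    rows = []
    for s in range(n_slices):
        sm = per_slice(m, s)
        nvox = int(sm.sum())
        row = {
            "slice_index": s,
            "ap_mm": float(grid.slice_center_mm(s)),
            "n_voxels": nvox,
        }
        if nvox == 0:
            row.update({v: np.nan for v in VARIABLES})
            row["n_fibre_voxels"] = 0
            row["max_fibre_norm"] = np.nan
            rows.append(row)
            continue
        valid = per_slice(scalars.valid, s) & sm
        for name, vol in (("fa", scalars.fa), ("md", scalars.md)):
            vals = per_slice(vol, s)[valid]
            row[name] = float(vals.mean()) if vals.size else np.nan
        for name, vol in (("ncsf", fractions.ncsf), ("ngm", fractions.ngm), ("nwm", fractions.nwm)):
            row[name] = float(per_slice(vol, s)[sm].mean())
        counts = per_slice(density.counts, s)
        row["n_fibre_voxels"] = int(((counts > 0) & sm).sum())
        max_count = int(counts[sm].max())
        row["max_fibre_norm"] = max_count / seed_count if seed_count else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    ok = np.isfinite(values) & (weights > 0)
    if not ok.any():
        return float("nan")
    return float(np.average(values[ok], weights=weights[ok]))


def segment_means(
    profile: pd.DataFrame,
    segments: SegmentAssignment,
    rois: RoiPartition | None = None,
) -> pd.DataFrame:
    """Bin slice means into segments and macroscopic ROIs.

    Segment (and ROI) values are means of slice means weighted by the slice
    in-mask voxel count; slices with missing values drop out per variable.
    Returns one row per segment plus one per ROI, with ``level`` in
    {"segment", "roi"} and ``item`` the segment id or ROI label.
    """
    from .geometry import partition_rois

    rois = rois if rois is not None else partition_rois(segments)
    prof = profile.set_index("slice_index")
    rows = []

    def summarize(slice_ids: list[int], level: str, item) -> dict:
        sub = prof.loc[[s for s in slice_ids if s in prof.index]]
        w = sub["n_voxels"].to_numpy(dtype=float) if len(sub) else np.array([])
        out = {"level": level, "item": item, "n_voxels": int(w.sum()) if w.size else 0}
        for v in VARIABLES:
            vals = sub[v].to_numpy(dtype=float) if len(sub) else np.array([])
            out[v] = _weighted_mean(vals, w) if vals.size else float("nan")
        return out

    by_segment: dict[int, list[int]] = {}
    for s, g in segments.segment_of_slice.items():
        by_segment.setdefault(g, []).append(s)
    for g in range(1, segments.n_segments + 1):
        rows.append(summarize(by_segment.get(g, []), "segment", g))
    for roi in ("optic_tract", "chiasm", "optic_nerve"):
        slice_ids = [s for g in rois.segments_of(roi) for s in by_segment.get(g, [])]
        rows.append(summarize(slice_ids, "roi", roi))
    return pd.DataFrame(rows)


def subject_stats(
    subject: str,
    group: str,
    tracts: dict[str, dict],
) -> pd.DataFrame:
    """Long-format per-subject table over both tracts.

    ``tracts`` maps a tract id ("LR": left LGN to right orbit, "RL": the
    mirror) to ``{"summary": segment_means output, "lgn_side": str,
    "eye_side": str}``. Optic-tract ROI rows are labelled by LGN side and
    optic-nerve rows by eye side; the chiasm ROI pools both tracts into a
    single bilateral row (tract id "both").
    """
    records = []
    chiasm_parts = []
    for tract_id, info in tracts.items():
        summary = info["summary"]
        for _, r in summary.iterrows():
            if r["level"] == "segment":
                item = f"{tract_id}/seg{int(r['item']):02d}"
            elif r["item"] == "optic_tract":
                item = f"optic_tract/{info['lgn_side'][0].upper()}"
            elif r["item"] == "optic_nerve":
                item = f"optic_nerve/{info['eye_side'][0].upper()}"
            else:
                chiasm_parts.append(r)
                continue
            for v in VARIABLES:
                records.append(
                    {
                        "subject": subject,
                        "group": group,
                        "tract": tract_id if r["level"] == "segment" else "roi",
                        "item": item,
                        "variable": v,
                        "value": r[v],
                        "n_voxels": r["n_voxels"],
                    }
                )
    if chiasm_parts:
        w = np.array([p["n_voxels"] for p in chiasm_parts], dtype=float)
        for v in VARIABLES:
            vals = np.array([p[v] for p in chiasm_parts], dtype=float)
            records.append(
                {
                    "subject": subject,
                    "group": group,
                    "tract": "both",
                    "item": "chiasm",
                    "variable": v,
                    "value": _weighted_mean(vals, w),
                    "n_voxels": int(w.sum()),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def welch_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's unequal-variance t-test from group summary statistics.

    ``t = (m1 - m2) / sqrt(sd1^2/n1 + sd2^2/n2)`` with Welch-Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need n >= 2, got n1={n1}, n2={n2}")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("both group variances are zero; t undefined")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def hochberg(pvalues: Iterable[float], alpha: float = 0.05) -> np.ndarray:
    """Hochberg step-up familywise rejection flags at level ``alpha``.

    With p-values sorted ascending as p(1) <= ... <= p(m), find the largest
    k with p(k) <= alpha / (m - k + 1) and reject the hypotheses carrying the
    k smallest p-values. Ties are broken by stable original order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_idx = np.arange(1, m + 1)
    ok = sorted_p <= alpha / (m - k_idx + 1)
    reject = np.zeros(m, dtype=bool)
    if ok.any():
        k = int(np.max(np.flatnonzero(ok))) + 1  # largest k (1-based)
        reject[order[:k]] = True
    return reject


def group_compare(
    stats_long: pd.DataFrame,
    group1: str,
    group2: str,
    family: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One Welch test per (variable, item) with Hochberg correction.

    ``stats_long`` is long format with columns subject, group, item,
    variable, value. ``family`` restricts and orders the corrected test
    family (defaults to every (variable, item) pair present). Subjects with
    missing values are dropped pairwise per test; per-test group sizes are
    reported. Raises if any test has fewer than two subjects in a group.
    """
    df = stats_long
    if family is None:
        family = sorted(
            {(v, i) for v, i in zip(df["variable"], df["item"])},
            key=lambda x: (VARIABLES.index(x[0]) if x[0] in VARIABLES else 99, x[1]),
        )
    rows = []
    for variable, item in family:
        sub = df[(df["variable"] == variable) & (df["item"] == item)]
        x1 = sub.loc[sub["group"] == group1, "value"].dropna().to_numpy(dtype=float)
        x2 = sub.loc[sub["group"] == group2, "value"].dropna().to_numpy(dtype=float)
        if x1.size < 2 or x2.size < 2:
            raise ValueError(
                f"test ({variable}, {item}) needs >= 2 subjects per group, "
                f"got {x1.size} vs {x2.size}"
            )
        res = welch_from_summary(
            x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
        )
        rows.append(
            {
                "variable": variable,
                "item": item,
                "m_g1": x1.mean(),
                "sd_g1": x1.std(ddof=1),
                "n_g1": x1.size,
                "m_g2": x2.mean(),
                "sd_g2": x2.std(ddof=1),
                "n_g2": x2.size,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    table["fwe_reject"] = hochberg(table["p"].to_numpy(), alpha=alpha)
    table["family_size"] = len(table)
    return table


# ---------------------------------------------------------------------------
# clinical correlation
# ---------------------------------------------------------------------------

#: ROI -> eye-mapping rule. Prechiasmatic (nerve) ROIs pair with the
#: ipsilateral eye; chiasmatic/postchiasmatic ROIs pair with eyes grouped by
#: affected order. NOTE: the convention of pairing the postchiasmatic optic
#: tract with the "ipsilateral" eye is ambiguous anatomically; here only the
#: prechiasmatic nerve uses the ipsilateral rule.
_IPSILATERAL_ROIS = {"optic_nerve/L": "left", "optic_nerve/R": "right"}
_AFFECTED_ORDER_ROIS = ("optic_tract/L", "optic_tract/R", "chiasm")

_COVARIATES = ("va_logmar", "rnfl_um", "duration_days")


def _quadrant_rnfl(clinical: pd.DataFrame, roi_side: str) -> pd.Series:
    """Mean RNFL of the two lateral quadrants feeding one postchiasmatic side.

    The right side receives the right temporal and left nasal quadrants; the
    left side mirrors this.
    """
    wide = clinical.pivot(index="subject", columns="eye")
    if roi_side == "right":
        return (wide[("rnfl_temporal_um", "right")] + wide[("rnfl_nasal_um", "left")]) / 2.0
    return (wide[("rnfl_temporal_um", "left")] + wide[("rnfl_nasal_um", "right")]) / 2.0


def clinical_correlate(
    stats_long: pd.DataFrame,
    clinical: pd.DataFrame,
    variables: tuple[str, ...] = ("nwm", "ngm"),
    min_pairs: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between ROI diffusion values and eye covariates.

    ``clinical`` is long format with one row per subject x eye (columns:
    subject, eye, va_logmar, rnfl_um, rnfl_temporal_um, rnfl_nasal_um,
    duration_days, affected_order). p-values are reported uncorrected and
    flagged exploratory at the pragmatic ``alpha`` threshold; correlations
    with fewer than ``min_pairs`` complete pairs yield a missing row with a
    reason.
    """
    rows = []
    roi_stats = stats_long[stats_long["item"].isin(
        list(_IPSILATERAL_ROIS) + list(_AFFECTED_ORDER_ROIS)
    )]

    def correlate(x: pd.Series, y: pd.Series, item, variable, covariate, mapping):
        joined = pd.concat([x, y], axis=1, join="inner").dropna()
        row = {
            "item": item,
            "variable": variable,
            "covariate": covariate,
            "eye_mapping": mapping,
            "n": len(joined),
        }
        if len(joined) < min_pairs:
            row.update(r=np.nan, p=np.nan, flag=False,
                       reason=f"only {len(joined)} complete pairs (< {min_pairs})")
        else:
            r, p = sps.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
            row.update(r=float(r), p=float(p), flag=bool(p < alpha), reason="")
        rows.append(row)

    for variable in variables:
        var_stats = roi_stats[roi_stats["variable"] == variable]
        for item in var_stats["item"].unique():
            vals = var_stats[var_stats["item"] == item].set_index("subject")["value"]
            if item in _IPSILATERAL_ROIS:
                eye = _IPSILATERAL_ROIS[item]
                eye_rows = clinical[clinical["eye"] == eye].set_index("subject")
                for cov in _COVARIATES:
                    correlate(vals, eye_rows[cov], item, variable, cov, f"ipsilateral/{eye}")
            else:
                for order in ("first", "second"):
                    eye_rows = clinical[clinical["affected_order"] == order].set_index("subject")
                    for cov in _COVARIATES:
                        if cov == "rnfl_um" and item != "chiasm":
                            continue  # postchiasmatic RNFL uses quadrant means below
                        correlate(vals, eye_rows[cov], item, variable, cov, f"affected/{order}")
                if item.startswith("optic_tract/"):
                    side = "left" if item.endswith("L") else "right"
                    correlate(
                        vals, _quadrant_rnfl(clinical, side), item, variable,
                        "rnfl_quadrant_um", f"quadrants/{side}",
                    )
    return pd.DataFrame(rows)
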