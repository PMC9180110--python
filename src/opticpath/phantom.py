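"""Synthetic anterior-optic-pathway phantom.

Generates geometry (four centerlines: left/right eye x crossing/noncrossing),
streamline sets, compartment/tensor/DWI volumes and clinical covariate
tables with the statistical structure the downstream analysis expects, so
every pipeline stage can be exercised without acquired data.

Conventions: the AP axis is grid axis 1 by default and AP coordinates
increase towards the LGN (LGN > chiasm > orbit). A streamline's ``side``
labels the eye/orbit it terminates at; crossing and noncrossing centerlines
of one side share the prechiasmatic (nerve) course exactly and diverge
posterior to the chiasm towards opposite LGNs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .compartments import DEFAULT_BACKGROUND_THRESHOLD
from .grid import VoxelGrid
from .masking import Landmarks, StreamlineSet
from .tensor import DWIScheme, TensorField, forward_signal

__all__ = [
    "DEFAULT_DECUSSATION_FRACTION",
    "REFERENCE_PROFILES",
    "PhantomTruth",
    "ClinicalRecord",
    "PhantomVolumes",
    "default_grid",
    "make_geometry",
    "simulate_streamlines",
    "simulate_volumes",
    "simulate_clinical",
    "simulate_cohort",
    "default_scheme",
    "make_landmarks",
    "clinical_to_frame",
]

#: Slightly asymmetric default so recovery tests can tell it from 0.5.
DEFAULT_DECUSSATION_FRACTION = 0.53

#: Reference per-ROI (mean, sd) targets for the two simulated groups.
#: MD in mm^2/s; fractions and FA unitless. Keyed [variable][roi][group].
REFERENCE_PROFILES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "fa": {
        "optic_tract/L": {"patient": (0.291, 0.019), "control": (0.392, 0.043)},
        "optic_tract/R": {"patient": (0.288, 0.038), "control": (0.376, 0.037)},
        "chiasm": {"patient": (0.166, 0.047), "control": (0.280, 0.064)},
        "optic_nerve/L": {"patient": (0.266, 0.044), "control": (0.338, 0.047)},
        "optic_nerve/R": {"patient": (0.233, 0.051), "control": (0.362, 0.057)},
    },
    "md": {
        "optic_tract/L": {"patient": (1.61e-3, 0.09e-3), "control": (1.55e-3, 0.10e-3)},
        "optic_tract/R": {"patient": (1.64e-3, 0.21e-3), "control": (1.57e-3, 0.13e-3)},
        "chiasm": {"patient": (1.77e-3, 0.37e-3), "control": (1.76e-3, 0.24e-3)},
        "optic_nerve/L": {"patient": (1.47e-3, 0.18e-3), "control": (1.50e-3, 0.29e-3)},
        "optic_nerve/R": {"patient": (1.64e-3, 0.28e-3), "control": (1.43e-3, 0.23e-3)},
    },
    "ncsf": {
        "optic_tract/L": {"patient": (0.249, 0.027), "control": (0.231, 0.039)},
        "optic_tract/R": {"patient": (0.244, 0.060), "control": (0.238, 0.054)},
        "chiasm": {"patient": (0.338, 0.138), "control": (0.357, 0.071)},
        "optic_nerve/L": {"patient": (0.177, 0.040), "control": (0.202, 0.074)},
        "optic_nerve/R": {"patient": (0.222, 0.070), "control": (0.184, 0.067)},
    },
    "ngm": {
        "optic_tract/L": {"patient": (0.338, 0.074), "control": (0.529, 0.076)},
        "optic_tract/R": {"patient": (0.324, 0.108), "control": (0.514, 0.076)},
        "chiasm": {"patient": (0.182, 0.090), "control": (0.381, 0.122)},
        "optic_nerve/L": {"patient": (0.272, 0.092), "control": (0.372, 0.060)},
        "optic_nerve/R": {"patient": (0.256, 0.096), "control": (0.357, 0.061)},
    },
    "nwm": {
        "optic_tract/L": {"patient": (0.407, 0.066), "control": (0.233, 0.075)},
        "optic_tract/R": {"patient": (0.424, 0.126), "control": (0.241, 0.063)},
        "chiasm": {"patient": (0.473, 0.117), "control": (0.225, 0.131)},
        "optic_nerve/L": {"patient": (0.228, 0.042), "control": (0.127, 0.052)},
        "optic_nerve/R": {"patient": (0.268, 0.068), "control": (0.121, 0.046)},
    },
}

N_POST, N_PRE = 10, 7  # segments LGN->chiasm, chiasm->orbit
_TUBE_RADIUS_MM = 3.2
_LGN_OFFSET_MM = 15.0
_ORBIT_OFFSET_MM = 8.0
_CHIASM_OFFSET_MM = 0.5
_FULL_SPAN_MM = 68.0  # LGN->orbit at full size; 40 posterior + 28 anterior


class _Landmark(NamedTuple):
    lgn_mm: float
    chiasm_mm: float
    orbit_mm: float


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one generated phantom."""

    grid: VoxelGrid
    centerlines: dict  # (eye_side, kind) -> (n, 3) mm polyline, LGN -> orbit
    decussation_fraction: float
    lgn_mm: float
    chiasm_mm: float
    orbit_mm: float
    group_profiles: dict = field(default_factory=lambda: REFERENCE_PROFILES)
    seed: int = 0

    @property
    def landmarks_mm(self) -> _Landmark:
        return _Landmark(self.lgn_mm, self.chiasm_mm, self.orbit_mm)

    def segment_edges_mm(self) -> np.ndarray:
        """18 segment boundaries from the LGN end to the orbit end."""
        post = np.linspace(self.lgn_mm, self.chiasm_mm, N_POST + 1)
        pre = np.linspace(self.chiasm_mm, self.orbit_mm, N_PRE + 1)
        return np.concatenate([post, pre[1:]])

    def segment_of_ap(self, ap_mm: np.ndarray) -> np.ndarray:
        """Segment id (1..17) per AP coordinate; 0 outside [orbit, LGN]."""
        edges = self.segment_edges_mm()
        ap = np.asarray(ap_mm, dtype=float)
        g = np.searchsorted(-edges, -ap, side="right")
        g = np.clip(g, 1, N_POST + N_PRE)
        g[(ap > self.lgn_mm) | (ap < self.orbit_mm)] = 0
        return g

    def roi_of_segment(self, segment: int, lgn_side: str, eye_side: str) -> str:
        if segment <= N_POST - 1:
            return f"optic_tract/{lgn_side[0].upper()}"
        if segment <= N_POST + 1:
            return "chiasm"
        return f"optic_nerve/{eye_side[0].upper()}"

    def to_json(self) -> str:
        payload = {
            "decussation_fraction": self.decussation_fraction,
            "lgn_mm": self.lgn_mm,
            "chiasm_mm": self.chiasm_mm,
            "orbit_mm": self.orbit_mm,
            "seed": self.seed,
            "grid": {
                "dims": list(self.grid.dims),
                "voxel_size": self.grid.voxel_size,
                "origin": list(self.grid.origin),
                "ap_axis": self.grid.ap_axis,
            },
            "centerlines": {
                f"{side}/{kind}": line.tolist() for (side, kind), line in self.centerlines.items()
            },
        }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject ophthalmological covariates (per-eye dicts keyed left/right)."""

    subject: str
    va_logmar: dict
    rnfl_um: dict
    rnfl_temporal_um: dict
    rnfl_nasal_um: dict
    duration_days: dict
    affected_order: str  # which eye was affected first: "left" or "right"
    nwm_nerve: dict = field(default_factory=dict)  # generator truth per eye

    def __post_init__(self) -> None:
        for eye in ("left", "right"):
            if self.rnfl_um.get(eye, 1.0) <= 0:
                raise ValueError("RNFL thickness must be positive")
            if not np.isfinite(self.va_logmar.get(eye, 0.0)):
                raise ValueError("logMAR visual acuity must be finite")


@dataclass(frozen=True)
class PhantomVolumes:
    """Simulated volumes plus voxelwise ground-truth annotations."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    tensors: TensorField
    dwi: np.ndarray
    scheme: DWIScheme
    tube: np.ndarray  # bool, inside any bundle
    segment_id: np.ndarray  # 0 outside


def default_grid() -> VoxelGrid:
    return VoxelGrid(dims=(96, 96, 60), voxel_size=2.0, ap_axis=1)


def _axes(grid: VoxelGrid) -> tuple[int, int, int]:
    """(lateral, ap, through-plane) axis indices."""
    ap = grid.ap_axis
    others = [a for a in range(3) if a != ap]
    return others[0], ap, others[1]


def _cosine_blend(y: np.ndarray, y0: float, y1: float, x0: float, x1: float) -> np.ndarray:
    """C1 interpolation with zero slope at both control points."""
    t = np.clip((y - y0) / (y1 - y0), 0.0, 1.0)
    return x0 + (x1 - x0) * (1 - np.cos(np.pi * t)) / 2


def make_geometry(
    grid: VoxelGrid | None = None,
    decussation_fraction: float = DEFAULT_DECUSSATION_FRACTION,
    seed: int = 0,
) -> PhantomTruth:
    """Lay out the four smooth centerlines and the landmark planes.

    The tract span scales with the grid's AP extent up to a full size of
    68 mm (40 mm LGN->chiasm + 28 mm chiasm->orbit), keeping the 10 + 7
    segments near 4 mm each.
    """
    grid = grid if grid is not None else default_grid()
    if not 0 <= decussation_fraction <= 1:
        raise ValueError(f"decussation_fraction must be in [0, 1], got {decussation_fraction}")
    extent = grid.ap_extent_mm()
    margin = 2 * grid.voxel_size
    if extent < 60.0:
        raise ValueError(
            f"grid AP extent {extent:.1f} mm is too small: at least 60 mm is needed "
            f"for {N_POST + N_PRE} segments of ~4 mm"
        )
    span = min(_FULL_SPAN_MM, extent - 2 * margin)
    lat_ax, ap_ax, thru_ax = _axes(grid)
    ap0 = grid.origin[ap_ax]
    orbit_mm = ap0 + margin
    lgn_mm = orbit_mm + span
    chiasm_mm = orbit_mm + span * (28.0 / 68.0)
    # snap the chiasm to a slice centre so the plane is well defined
    chiasm_mm = float(grid.slice_center_mm(grid.ap_to_slice(chiasm_mm)))

    mid_lat = grid.origin[lat_ax] + (grid.dims[lat_ax] - 1) * grid.voxel_size / 2
    mid_thru = grid.origin[thru_ax] + (grid.dims[thru_ax] - 1) * grid.voxel_size / 2
    sign = {"left": -1.0, "right": 1.0}

    centerlines: dict[tuple[str, str], np.ndarray] = {}
    ap_samples = np.linspace(lgn_mm, orbit_mm, max(int(round(span)) + 1, 32))
    for eye in ("left", "right"):
        for kind in ("noncrossing", "crossing"):
            lgn_side = eye if kind == "noncrossing" else ("left" if eye == "right" else "right")
            x_lgn = mid_lat + sign[lgn_side] * _LGN_OFFSET_MM
            x_chiasm = mid_lat + sign[eye] * _CHIASM_OFFSET_MM
            x_orbit = mid_lat + sign[eye] * _ORBIT_OFFSET_MM
            lat = np.where(
                ap_samples >= chiasm_mm,
                _cosine_blend(ap_samples, lgn_mm, chiasm_mm, x_lgn, x_chiasm),
                _cosine_blend(ap_samples, chiasm_mm, orbit_mm, x_chiasm, x_orbit),
            )
            pts = np.zeros((ap_samples.size, 3))
            pts[:, lat_ax] = lat
            pts[:, ap_ax] = ap_samples
            pts[:, thru_ax] = mid_thru
            centerlines[(eye, kind)] = pts
    return PhantomTruth(
        grid=grid,
        centerlines=centerlines,
        decussation_fraction=float(decussation_fraction),
        lgn_mm=float(lgn_mm),
        chiasm_mm=float(chiasm_mm),
        orbit_mm=float(orbit_mm),
        seed=int(seed),
    )


def _perp_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit fields perpendicular to the (normalized) tangents."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.zeros_like(t)
    ref[:, np.argmin(np.abs(t).mean(axis=0))] = 1.0
    u = np.cross(t, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)
    return u, v


def simulate_streamlines(
    truth: PhantomTruth,
    n_per_side: int,
    jitter_sd: float = 1.0,
    seed: int = 0,
) -> StreamlineSet:
    """Streamlines as centerlines plus smooth lateral Gaussian jitter.

    Per eye side, the number of crossing streamlines is a binomial draw with
    probability ``truth.decussation_fraction``. Jitter is applied in the
    plane perpendicular to the local tangent (a constant random offset plus
    one low-frequency mode per perpendicular direction), keeping arclength
    parametrization stable. Streamlines run LGN -> orbit.
    """
    if n_per_side < 1:
        raise ValueError(f"n_per_side must be >= 1, got {n_per_side}")
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be >= 0, got {jitter_sd}")
    rng = np.random.default_rng(seed)
    streamlines, sides, kinds = [], [], []
    for eye in ("left", "right"):
        n_cross = int(rng.binomial(n_per_side, truth.decussation_fraction))
        for kind, n in (("crossing", n_cross), ("noncrossing", n_per_side - n_cross)):
            if n == 0:
                continue
            center = truth.centerlines[(eye, kind)]
            tangents = np.gradient(center, axis=0)
            u, v = _perp_frame(tangents)
            t = np.linspace(0.0, 1.0, center.shape[0])
            for _ in range(n):
                coeffs = rng.normal(0.0, jitter_sd, size=4)
                phase = rng.uniform(0, 2 * np.pi, size=2)
                off_u = coeffs[0] + coeffs[1] * np.sin(np.pi * t + phase[0])
                off_v = coeffs[2] + coeffs[3] * np.sin(np.pi * t + phase[1])
                streamlines.append(center + off_u[:, None] * u + off_v[:, None] * v)
                sides.append(eye)
                kinds.append(kind)
    return StreamlineSet(streamlines, np.array(sides, dtype=object), np.array(kinds, dtype=object))


def default_scheme(seed: int = 7) -> DWIScheme:
    """Compact two-shell scheme: 2 x b=0, 15 x b=1000, 15 x b=2000."""
    rng = np.random.default_rng(seed)

    def sphere_points(n: int) -> np.ndarray:
        # Fibonacci sphere with a deterministic random rotation
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        pts = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        return pts @ q

    bvals = np.concatenate([np.zeros(2), np.full(15, 1000.0), np.full(15, 2000.0)])
    bvecs = np.vstack([np.zeros((2, 3)), sphere_points(15), sphere_points(15)])
    return DWIScheme(bvals, bvecs)


def _eigs_from_fa_md(fa: np.ndarray, md: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axially symmetric eigenvalues (lam1, lam23) matching given FA and MD."""
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1 + 2 * a), md * (1 - a)


def simulate_volumes(
    truth: PhantomTruth,
    grid: VoxelGrid | None = None,
    group: str = "control",
    noise_sd: float = 0.0,
    seed: int = 0,
    scheme: DWIScheme | None = None,
    between_subject_sd_scale: float = 0.0,
) -> PhantomVolumes:
    """Paint compartment intensities, tensors and DWI into the grid.

    Voxels within the bundle tubes receive, per segment, the group profile's
    target values (optionally shifted by a per-subject draw of
    ``between_subject_sd_scale`` times the profile sd; segments are treated
    as independent). At ``noise_sd=0`` the derived segment means equal the
    targets. Outside-tube voxels get a total tissue intensity below the
    background threshold. DWI follows ``S = S0 exp(-b g^T D g)`` with Rician
    noise of standard deviation ``noise_sd``.

    Raw tissue intensities are painted on the background-threshold scale
    (``raw = threshold * target``), so after four-compartment normalization
    the fractions reproduce the targets exactly, with the balance
    ``1 - (nWM + nGM + nCSF)`` appearing as normalized background. In the
    nerve portion that balance is sizeable, so the background exclusion and
    its iterative threshold adjustment are genuinely exercised. ``noise_sd``
    is expressed in S0 signal units; tissue-intensity jitter is scaled by
    the threshold to stay on the deconvolution amplitude scale.
    """
    grid = grid if grid is not None else truth.grid
    profiles = truth.group_profiles
    if group not in next(iter(next(iter(profiles.values())).values())):
        raise ValueError(f"unknown group {group!r}; profiles define "
                         f"{sorted(next(iter(next(iter(profiles.values())).values())))}")
    rng = np.random.default_rng(seed)
    scheme = scheme if scheme is not None else default_scheme()
    lat_ax, ap_ax, thru_ax = _axes(grid)

    # nearest centerline sample per voxel (within tube radius)
    samples, tangents, labels = [], [], []
    for (eye, kind), line in truth.centerlines.items():
        samples.append(line)
        tg = np.gradient(line, axis=0)
        tangents.append(tg / np.linalg.norm(tg, axis=1, keepdims=True))
        lgn_side = eye if kind == "noncrossing" else ("left" if eye == "right" else "right")
        labels.extend([(eye, lgn_side)] * line.shape[0])
    samples = np.vstack(samples)
    tangents = np.vstack(tangents)
    tree = cKDTree(samples)

    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)
    dist, nearest = tree.query(centers, workers=1)
    tube_flat = dist <= _TUBE_RADIUS_MM
    seg_flat = np.zeros(centers.shape[0], dtype=np.int64)
    seg_flat[tube_flat] = truth.segment_of_ap(centers[tube_flat, ap_ax])
    tube_flat &= seg_flat > 0

    # per-subject segment-level shifts (independent across segments)
    shift: dict[tuple[str, str, int], float] = {}
    n_seg = N_POST + N_PRE
    for var in ("fa", "md", "ncsf", "ngm", "nwm"):
        for side in ("L", "R"):
            for g in range(1, n_seg + 1):
                key = (var, side, g)
                shift[key] = float(rng.normal(0.0, 1.0)) * between_subject_sd_scale

    shape = grid.shape
    wm = np.zeros(shape)
    gm = np.zeros(shape)
    csf = np.zeros(shape)
    fa_vol = np.zeros(shape)
    md_vol = np.full(shape, 0.8e-3)
    tube = tube_flat.reshape(shape)
    seg_vol = seg_flat.reshape(shape)

    flat_values = {v: np.zeros(centers.shape[0]) for v in ("fa", "md", "ncsf", "ngm", "nwm")}
    in_idx = np.flatnonzero(tube_flat)
    for i in in_idx:
        eye, lgn_side = labels[nearest[i]]
        g = int(seg_flat[i])
        roi = truth.roi_of_segment(g, lgn_side, eye)
        side = lgn_side[0].upper() if g <= N_POST - 1 else eye[0].upper()
        for var in ("fa", "md", "ncsf", "ngm", "nwm"):
            m, sd = profiles[var][roi][group]
            flat_values[var][i] = m + shift[(var, side, g)] * sd

    thr = DEFAULT_BACKGROUND_THRESHOLD
    for name, vol, scale in (
        ("fa", fa_vol, 1.0),
        ("md", md_vol, 1.0),
        ("ncsf", csf, thr),
        ("ngm", gm, thr),
        ("nwm", wm, thr),
    ):
        np.put(vol.reshape(-1), in_idx, np.maximum(0.0, scale * flat_values[name][in_idx]))

    # outside-tube tissue totals stay below the background threshold
    outside = ~tube
    n_out = int(outside.sum())
    for vol in (wm, gm, csf):
        vol[outside] = rng.uniform(0.0, 0.25 * thr, size=n_out)

    if noise_sd > 0:
        for vol in (wm, gm, csf):
            vol[tube] = np.maximum(
                0.0, vol[tube] + rng.normal(0.0, noise_sd * thr, size=in_idx.size)
            )

    fa_clipped = np.clip(fa_vol, 0.0, 0.99)
    md_clipped = np.maximum(md_vol, 1e-6)
    lam1, lam23 = _eigs_from_fa_md(fa_clipped, md_clipped)
    e1 = np.zeros(shape + (3,))
    e1.reshape(-1, 3)[in_idx] = tangents[nearest[in_idx]]
    e1[..., ap_ax] = np.where(np.linalg.norm(e1, axis=-1) == 0, 1.0, e1[..., ap_ax])
    e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
    eye3 = np.eye(3)
    outer = e1[..., :, None] * e1[..., None, :]
    tensors = lam23[..., None, None] * eye3 + (lam1 - lam23)[..., None, None] * outer
    tfield = TensorField(tensors)

    s0 = np.where(tube, 1.0, 0.05)
    dwi = forward_signal(tensors, scheme, s0=s0)
    if noise_sd > 0:
        n1 = rng.normal(0.0, noise_sd, size=dwi.shape)
        n2 = rng.normal(0.0, noise_sd, size=dwi.shape)
        dwi = np.sqrt((dwi + n1) ** 2 + n2**2)

    return PhantomVolumes(
        wm=wm, gm=gm, csf=csf, tensors=tfield, dwi=dwi, scheme=scheme,
        tube=tube, segment_id=seg_vol,
    )


def make_landmarks(truth: PhantomTruth, grid: VoxelGrid | None = None) -> Landmarks:
    """Seed (LGN plane) and waypoint (orbital plane) ROIs around the tubes."""
    grid = grid if grid is not None else truth.grid
    ap_ax = grid.ap_axis
    lgn_slice = grid.ap_to_slice(truth.lgn_mm)
    orbit_slice = grid.ap_to_slice(truth.orbit_mm)
    chiasm_slice = grid.ap_to_slice(truth.chiasm_mm)

    pts = np.vstack(list(truth.centerlines.values()))
    tree = cKDTree(pts)
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)
    near = (tree.query(centers, workers=1)[0] <= _TUBE_RADIUS_MM).reshape(grid.shape)

    seed = np.zeros(grid.shape, dtype=bool)
    waypoint = np.zeros(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[ap_ax] = lgn_slice
    seed[tuple(sl)] = np.take(near, lgn_slice, axis=ap_ax)
    sl[ap_ax] = orbit_slice
    waypoint[tuple(sl)] = np.take(near, orbit_slice, axis=ap_ax)
    return Landmarks(seed=seed, waypoint=waypoint, chiasm_slice=int(chiasm_slice), grid=grid)


def simulate_clinical(
    truth: PhantomTruth,
    n_subjects: int,
    r_target: float = 0.57,
    seed: int = 0,
) -> list[ClinicalRecord]:
    """Clinical covariates with a planted nWM correlation.

    Per eye, visual acuity (logMAR) has population correlation ``r_target``
    with the subject's optic-nerve nWM and average RNFL has correlation
    ``-r_target``. Records carry the latent nWM values in ``nwm_nerve`` so
    recovery tests can pair them without running the imaging pipeline.
    """
    if abs(r_target) > 1:
        raise ValueError(f"|r_target| must be <= 1, got {r_target}")
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    rng = np.random.default_rng(seed)
    comp = np.sqrt(1.0 - r_target**2)
    nwm_m, nwm_sd = truth.group_profiles["nwm"]["optic_nerve/L"]["patient"]
    records: list[ClinicalRecord] = []
    for i in range(n_subjects):
        va, rnfl, rnfl_t, rnfl_n, dur, nwm = {}, {}, {}, {}, {}, {}
        for eye in ("left", "right"):
            z = rng.normal()
            va_z = r_target * z + comp * rng.normal()
            rnfl_z = -r_target * z + comp * rng.normal()
            nwm[eye] = nwm_m + nwm_sd * z
            va[eye] = 1.69 + 0.35 * va_z
            rnfl[eye] = max(0.5, 75.0 + 22.0 * rnfl_z)
            rnfl_t[eye] = max(0.5, rnfl[eye] * 0.9 + rng.normal(0.0, 4.0))
            rnfl_n[eye] = max(0.5, rnfl[eye] * 1.1 + rng.normal(0.0, 4.0))
            dur[eye] = float(np.round(rng.lognormal(np.log(300.0), 0.5)))
        records.append(
            ClinicalRecord(
                subject=f"P{i + 1:03d}",
                va_logmar=va,
                rnfl_um=rnfl,
                rnfl_temporal_um=rnfl_t,
                rnfl_nasal_um=rnfl_n,
                duration_days=dur,
                affected_order=("left", "right")[int(rng.integers(2))],
                nwm_nerve=nwm,
            )
        )
    return records


def clinical_to_frame(records: list[ClinicalRecord]):
    """Long-format table, one row per subject x eye (TSV-ready)."""
    import pandas as pd

    rows = []
    for r in records:
        for eye in ("left", "right"):
            rows.append(
                {
                    "subject": r.subject,
                    "eye": eye,
                    "va_logmar": r.va_logmar[eye],
                    "rnfl_um": r.rnfl_um[eye],
                    "rnfl_temporal_um": r.rnfl_temporal_um[eye],
                    "rnfl_nasal_um": r.rnfl_nasal_um[eye],
                    "duration_days": r.duration_days[eye],
                    "affected_order": "first" if eye == r.affected_order else "second",
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_patients: int,
    n_controls: int,
    seed: int = 0,
    profiles: dict | None = None,
    variables: tuple[str, ...] = ("fa", "md", "ncsf", "ngm", "nwm"),
    items: tuple[str, ...] | None = None,
):
    """Draw subject-level ROI values straight from the group profiles.

    Returns a long-format table (subject, group, item, variable, value)
    compatible with :func:`opticpath.stats.group_compare`; each subject's
    ROI value is an independent normal draw from the profile (mean, sd).
    """
    import pandas as pd

    profiles = profiles if profiles is not None else REFERENCE_PROFILES
    if items is None:
        items = tuple(next(iter(profiles.values())).keys())
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("patient", n_patients), ("control", n_controls)):
        for i in range(n):
            subject = f"{group[0].upper()}{i + 1:03d}"
            for var in variables:
                for item in items:
                    m, sd = profiles[var][item][group]
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "item": item,
                            "variable": var,
                            "value": rng.normal(m, sd),
                        }
                    )
    return pd.DataFrame(rows)
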