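"""Diffusion tensor fitting and scalar maps (FA, MD) with validity bounds.

The fit is ordinary (unweighted) log-linear least squares per voxel:
``log(S / S0) = -b * g^T D g`` is linear in the six unique tensor elements.
Multiple b=0 volumes are averaged into S0 before the fit. Non-positive
signals are clamped to a small epsilon ahead of the logarithm; negative
eigenvalues arising from noisy fits are kept and handled downstream by the
validity mask, which mirrors the exclusion-based treatment of implausible
voxel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MD_UPPER_BOUND",
    "DWIScheme",
    "TensorField",
    "ScalarMaps",
    "fit_tensor",
    "fa_md",
    "validity_mask",
    "design_matrix",
    "forward_signal",
]

#: Upper bound on plausible mean diffusivity, mm^2/s (free water is ~3e-3).
MD_UPPER_BOUND = 0.005

_LOG_EPS = 1e-10


@dataclass(frozen=True)
class DWIScheme:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), unit vectors for b > 0

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values")
        if not np.any(bvals == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("b>0 gradient directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @classmethod
    def from_fsl(cls, bval_path: str, bvec_path: str) -> "DWIScheme":
        """Read FSL-dialect text files (one whitespace-delimited row per quantity)."""
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals, bvecs)


@dataclass(frozen=True)
class TensorField:
    """Per-voxel symmetric diffusion tensors, shape ``(..., 3, 3)``, mm^2/s."""

    tensors: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensors, dtype=float)
        if t.shape[-2:] != (3, 3):
            raise ValueError(f"tensor array must end in (3, 3), got {t.shape}")
        object.__setattr__(self, "tensors", t)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tensors.shape[:-2]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel in non-increasing order, shape ``(..., 3)``."""
        return np.linalg.eigvalsh(self.tensors)[..., ::-1]


@dataclass(frozen=True)
class ScalarMaps:
    """FA (unitless) and MD (mm^2/s) maps plus the validity mask."""

    fa: np.ndarray
    md: np.ndarray
    valid: np.ndarray


def design_matrix(scheme: DWIScheme) -> np.ndarray:
    """Rows of ``b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]``."""
    g = scheme.bvecs
    b = scheme.bvals[:, None]
    return b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _coeffs_to_tensors(coeffs: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(coeffs, -1, 0)
    row0 = np.stack([dxx, dxy, dxz], axis=-1)
    row1 = np.stack([dxy, dyy, dyz], axis=-1)
    row2 = np.stack([dxz, dyz, dzz], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def forward_signal(tensors: np.ndarray, scheme: DWIScheme, s0: np.ndarray | float = 1.0) -> np.ndarray:
    """Monoexponential DWI signal ``S = S0 * exp(-b g^T D g)``.

    ``tensors`` has shape ``(..., 3, 3)``; the result has shape
    ``(..., n_volumes)``.
    """
    X = design_matrix(scheme)  # (n, 6)
    t = np.asarray(tensors, dtype=float)
    coeffs = np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
        axis=-1,
    )
    sig = np.exp(-coeffs @ X.T)
    s0 = np.asarray(s0, dtype=float)
    return s0[..., None] * sig if s0.ndim else s0 * sig


def fit_tensor(dwi: np.ndarray, scheme: DWIScheme, max_bval: float | None = None) -> TensorField:
    """Ordinary log-linear least-squares tensor fit per voxel.

    Parameters
    ----------
    dwi
        Signal array of shape ``(..., n_volumes)``.
    scheme
        Matching acquisition scheme.
    max_bval
        If given, restrict the fit to shells with ``b <= max_bval`` (b=0
        volumes always included).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI volume count {dwi.shape[-1]} does not match scheme {scheme.n_volumes}"
        )
    keep = np.ones(scheme.n_volumes, dtype=bool)
    if max_bval is not None:
        keep = scheme.bvals <= max_bval
    b0 = scheme.b0_mask
    s0 = dwi[..., b0].mean(axis=-1)

    sel = keep & ~b0
    X = design_matrix(scheme)[sel]  # (m, 6)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("gradient scheme is rank-deficient (collinear directions)")
    s = np.maximum(dwi[..., sel], _LOG_EPS)
    s0c = np.maximum(s0, _LOG_EPS)
    y = -(np.log(s) - np.log(s0c)[..., None])  # (..., m)
    # OLS via pseudoinverse; one shared design for every voxel.
    coeffs = y @ np.linalg.pinv(X).T
    return TensorField(_coeffs_to_tensors(coeffs))


def fa_md(tensor: TensorField) -> ScalarMaps:
    """FA and MD from tensor eigenvalues.

    ``MD = trace(D) / 3``; ``FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||``.
    FA of the zero tensor is undefined and mapped to 0 with the voxel marked
    invalid via the validity mask (MD = 0 falls outside the open interval).
    """
    if not np.all(np.isfinite(tensor.tensors)):
        raise ValueError("tensor field contains non-finite values")
    lam = tensor.eigenvalues()
    md = lam.mean(axis=-1)
    dev = lam - md[..., None]
    norm = np.linalg.norm(lam, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.where(norm == 0, 0.0, fa)
    maps = ScalarMaps(fa=fa, md=md, valid=np.zeros(fa.shape, dtype=bool))
    return ScalarMaps(fa=fa, md=md, valid=validity_mask(maps))


def validity_mask(scalars: ScalarMaps, md_upper: float = MD_UPPER_BOUND) -> np.ndarray:
    """True where ``0 < FA < 1`` and ``0 < MD < md_upper`` (open intervals)."""
    fa, md = scalars.fa, scalars.md
    return (fa > 0) & (fa < 1) & (md > 0) & (md < md_upper) & np.isfinite(fa) & np.isfinite(md)
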