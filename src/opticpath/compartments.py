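"""Normalization of three-tissue compartment intensities to unit-sum fractions.

Spherical deconvolution yields per-voxel WM-like, GM-like and CSF-like signal
intensities. Voxels whose total intensity falls below a small threshold are
dominated by background (bone, air, noise); a fourth "background" component
fills the deficit so that the four normalized fractions sum to unity at every
voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_BACKGROUND_THRESHOLD",
    "CompartmentFractions",
    "add_background",
    "normalize",
    "compute_fractions",
]

#: Total-intensity level below which the background component is introduced.
#: Interpreted on the scale of the deconvolution output amplitudes.
DEFAULT_BACKGROUND_THRESHOLD = 0.075


@dataclass(frozen=True)
class CompartmentFractions:
    """Per-voxel normalized compartment fractions.

    Each array has the same (volume) shape; at every voxel the four fractions
    are in [0, 1] and sum to 1.
    """

    nwm: np.ndarray
    ngm: np.ndarray
    ncsf: np.ndarray
    nbg: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.nwm, self.ngm, self.ncsf, self.nbg)}
        if len(shapes) != 1:
            raise ValueError(f"fraction volumes must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.nwm.shape

    def stacked(self) -> np.ndarray:
        """4-D array with a trailing component axis (nWM, nGM, nCSF, nBG)."""
        return np.stack([self.nwm, self.ngm, self.ncsf, self.nbg], axis=-1)


def _validate_intensities(wm: np.ndarray, gm: np.ndarray, csf: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = tuple(np.asarray(a, dtype=float) for a in (wm, gm, csf))
    for name, a in zip(("WM", "GM", "CSF"), arrs):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name} intensities contain non-finite values")
        if np.any(a < 0):
            raise ValueError(f"{name} intensities contain negative values")
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("WM/GM/CSF volumes must share one shape")
    return arrs


def add_background(
    wm: np.ndarray,
    gm: np.ndarray,
    csf: np.ndarray,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Append the raw background component.

    ``background = max(0, threshold - (WM + GM + CSF))`` per voxel; the tissue
    components pass through unchanged. Total absolute intensity is the sum of
    the (non-negative) tissue intensities; absolute values are taken
    defensively upstream by input validation.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    wm, gm, csf = _validate_intensities(wm, gm, csf)
    total = wm + gm + csf
    bg = np.maximum(0.0, threshold - total)
    return wm, gm, csf, bg


def normalize(
    wm: np.ndarray,
    gm: np.ndarray,
    csf: np.ndarray,
    bg: np.ndarray,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> CompartmentFractions:
    """Normalize four raw components so they sum to unity per voxel.

    The normalizer is ``max(WM + GM + CSF, threshold)``: for voxels at or
    above the threshold this is plain division by the tissue total (and the
    background component is zero there); below it, background fills the voxel
    to exactly the threshold, making fractions continuous in the input.
    """
    wm, gm, csf = (np.asarray(a, dtype=float) for a in (wm, gm, csf))
    bg = np.asarray(bg, dtype=float)
    denom = np.maximum(wm + gm + csf, threshold)
    fractions = CompartmentFractions(wm / denom, gm / denom, csf / denom, bg / denom)
    return fractions


def compute_fractions(
    wm: np.ndarray,
    gm: np.ndarray,
    csf: np.ndarray,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> CompartmentFractions:
    """Raw three-tissue intensities to unit-sum four-compartment fractions."""
    return normalize(*add_background(wm, gm, csf, threshold), threshold=threshold)
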