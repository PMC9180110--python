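"""File interchange: NIfTI volumes, TCK streamlines, TSV tables.

Volumes are written as NIfTI-1 with the grid's scaled-identity affine;
streamline files use the TCK format in world (RAS mm) coordinates.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .compartments import CompartmentFractions
from .grid import VoxelGrid
from .masking import StreamlineSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_fractions",
    "load_fractions",
    "save_streamlines",
    "load_streamlines",
]


def save_volume(data: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    aff = img.affine
    voxel_size = float(aff[0, 0])
    grid = VoxelGrid(
        dims=tuple(img.shape[:3]),
        voxel_size=voxel_size,
        origin=tuple(aff[:3, 3]),
    )
    return np.asanyarray(img.dataobj), grid


def save_fractions(fractions: CompartmentFractions, grid: VoxelGrid, path: str | Path) -> None:
    """4-D NIfTI with component order nWM, nGM, nCSF, nBG."""
    save_volume(fractions.stacked(), grid, path)


def load_fractions(path: str | Path) -> tuple[CompartmentFractions, VoxelGrid]:
    data, grid = load_volume(path)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError(f"expected a 4-D volume with 4 components, got shape {data.shape}")
    return CompartmentFractions(data[..., 0], data[..., 1], data[..., 2], data[..., 3]), grid


def save_streamlines(streamlines: StreamlineSet, path: str | Path) -> None:
    """Write polylines as TCK (labels go to a sidecar TSV next to the file)."""
    tractogram = nib.streamlines.Tractogram(
        streamlines.streamlines, affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.TckFile(tractogram).save(str(path))
    sidecar = Path(path).with_suffix(".labels.tsv")
    pd.DataFrame({"side": streamlines.side, "kind": streamlines.kind}).to_csv(
        sidecar, sep="\t", index=False
    )


def load_streamlines(path: str | Path) -> StreamlineSet:
    tck = nib.streamlines.load(str(path))
    polylines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    sidecar = Path(path).with_suffix(".labels.tsv")
    if sidecar.exists():
        labels = pd.read_csv(sidecar, sep="\t")
        side = labels["side"].to_numpy(dtype=object)
        kind = labels["kind"].to_numpy(dtype=object)
    else:
        side = np.array(["unknown"] * len(polylines), dtype=object)
        kind = np.array(["unknown"] * len(polylines), dtype=object)
    return StreamlineSet(polylines, side, kind)
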