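"""4-D diffusion-weighted volumes: NIfTI I/O, normalization, block tiling.

The in-memory container is :class:`DwiVolume` — the 4-D signal array
with its gradient table, voxel size and the two analysis masks (whole
brain, and brain tissue excluding CSF).  Intensity normalization and the
minimal-overlap block tiling used to feed volumes through the network in
fixed-size chunks live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientTable, read_gradient_table

__all__ = [
    "DwiVolume",
    "BlockSet",
    "load_dwi",
    "save_nifti",
    "normalize_intensities",
    "denormalize_intensities",
    "extract_blocks",
]


@dataclass
class DwiVolume:
    """A 4-D diffusion signal array plus acquisition/masking metadata.

    ``signal`` is X×Y×Z×n (scanner units, non-negative); the fourth axis
    matches ``gradients.n``.  ``tissue_mask`` (brain tissue excluding
    CSF) must be contained in ``brain_mask``.
    """

    signal: np.ndarray
    gradients: GradientTable
    voxel_size: np.ndarray | tuple = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None
    tissue_mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != self.gradients.n:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but gradient "
                f"table has {self.gradients.n}"
            )
        if np.any(self.signal < 0):
            raise ValueError("negative signal intensities")
        spatial = self.signal.shape[:3]
        if self.brain_mask is None:
            self.brain_mask = np.ones(spatial, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.tissue_mask is None:
            self.tissue_mask = self.brain_mask.copy()
        else:
            self.tissue_mask = np.asarray(self.tissue_mask).astype(bool)
        for name, m in (("brain_mask", self.brain_mask), ("tissue_mask", self.tissue_mask)):
            if m.shape != spatial:
                raise ValueError(f"{name} shape {m.shape} != spatial grid {spatial}")
        if np.any(self.tissue_mask & ~self.brain_mask):
            raise ValueError("tissue_mask contains voxels outside brain_mask")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.affine is None:
            self.affine = np.diag(np.append(self.voxel_size, 1.0))

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def mean_b0(self) -> np.ndarray:
        """Mean of the non-diffusion-weighted volumes (3-D map)."""
        b0 = self.gradients.b0_mask
        if not b0.any():
            raise ValueError("no b0 volume in the acquisition")
        return self.signal[..., b0].mean(axis=3)


@dataclass(frozen=True)
class BlockSet:
    """Fixed-size 4-D sub-arrays covering the mask bounding box."""

    blocks: list
    origins: list
    block_size: int


def _read_mask(path, spatial) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != spatial:
        raise ValueError(f"mask {path} shape {data.shape} != DWI grid {spatial}")
    return data != 0


def load_dwi(
    nifti_path,
    bval_path,
    bvec_path,
    brain_mask_path=None,
    tissue_mask_path=None,
) -> DwiVolume:
    """Load a 4-D NIfTI plus FSL bval/bvec (and optional mask NIfTIs)."""
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.dataobj, dtype=float)
    if signal.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4-D NIfTI, got {signal.ndim}-D")
    table = read_gradient_table(bval_path, bvec_path)
    spatial = signal.shape[:3]
    brain = _read_mask(brain_mask_path, spatial) if brain_mask_path else None
    tissue = _read_mask(tissue_mask_path, spatial) if tissue_mask_path else None
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DwiVolume(
        signal, table, voxel_size, brain, tissue, affine=np.asarray(img.affine)
    )


def save_nifti(data: np.ndarray, path, affine=None, voxel_size=(1, 1, 1)) -> None:
    """Write an array as NIfTI; boolean masks are stored as uint8."""
    if affine is None:
        affine = np.diag(np.append(np.asarray(voxel_size, float), 1.0))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def normalize_intensities(dwi: DwiVolume) -> tuple[DwiVolume, float]:
    """Divide all signals by the tissue median of the mean-b0 image.

    Returns the normalized volume and the scale, so S0 estimates can be
    mapped back to scanner units.
    """
    if not dwi.tissue_mask.any():
        raise ValueError("empty tissue mask")
    scale = float(np.median(dwi.mean_b0()[dwi.tissue_mask]))
    if scale <= 0:
        raise ValueError(f"degenerate normalization scale {scale}")
    out = replace(dwi, signal=dwi.signal / scale)
    return out, scale


def denormalize_intensities(dwi: DwiVolume, scale: float) -> DwiVolume:
    return replace(dwi, signal=dwi.signal * scale)


def _axis_origins(extent: int, block_size: int) -> np.ndarray:
    """Evenly spaced block origins with the last flush to the boundary."""
    if extent <= block_size:
        return np.array([0])
    count = int(np.ceil(extent / block_size))
    return np.round(np.linspace(0, extent - block_size, count)).astype(int)


def extract_blocks(dwi: DwiVolume, block_size: int) -> BlockSet:
    """Tile the brain-mask bounding box into minimal-overlap blocks.

    Per axis there are ceil(extent/block_size) origins, evenly spaced
    with the last block flush to the box boundary.  Boxes smaller than
    ``block_size`` are zero-padded (the pad is outside every mask, so it
    never enters a loss).
    """
    if not dwi.brain_mask.any():
        raise ValueError("empty brain mask")
    idx = np.argwhere(dwi.brain_mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    blocks, origins = [], []
    axis_origins = [
        _axis_origins(int(hi[a] - lo[a]), block_size) + lo[a] for a in range(3)
    ]
    for ox in axis_origins[0]:
        for oy in axis_origins[1]:
            for oz in axis_origins[2]:
                blk = np.zeros(
                    (block_size, block_size, block_size, dwi.signal.shape[3])
                )
                sx = min(block_size, dwi.signal.shape[0] - ox)
                sy = min(block_size, dwi.signal.shape[1] - oy)
                sz = min(block_size, dwi.signal.shape[2] - oz)
                blk[:sx, :sy, :sz] = dwi.signal[
                    ox : ox + sx, oy : oy + sy, oz : oz + sz
                ]
                blocks.append(blk)
                origins.append((int(ox), int(oy), int(oz)))
    return BlockSet(blocks=blocks, origins=origins, block_size=block_size)
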