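"""FSL-style gradient tables (bval/bvec text files).

A diffusion acquisition is described per volume by a b-value b_i (s/mm²)
and a unit encoding direction v_i.  The on-disk dialect is the FSL one:
whitespace-separated text, b-vectors as three rows (or three columns —
both orientations are accepted and auto-detected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientTable", "read_gradient_table", "write_gradient_table",
           "B0_THRESHOLD"]

#: b-values at or below this (s/mm²) are treated as non-diffusion-weighted.
B0_THRESHOLD = 50.0


class GradientFormatError(ValueError):
    """Malformed or inconsistent bval/bvec content."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values and unit diffusion-encoding directions.

    Parameters
    ----------
    bvals : (n,) array, s/mm², non-negative.
    bvecs : (n, 3) array; unit norm wherever ``bvals > b0_threshold``,
        may be zero for b0 volumes.
    b0_threshold : scalar, s/mm².
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise GradientFormatError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise GradientFormatError("negative b-values")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > self.b0_threshold
        if np.any(np.abs(norms[dw] - 1.0) > 1e-4):
            raise GradientFormatError("non-unit b-vector at b > b0_threshold")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def shells(self) -> np.ndarray:
        """Distinct non-zero b-values, rounded to the nearest 10 s/mm²."""
        return np.unique(np.round(self.bvals[self.dwi_mask], -1))

    def subset(self, index) -> "GradientTable":
        return GradientTable(self.bvals[index], self.bvecs[index], self.b0_threshold)


def _parse_matrix(path: Path) -> np.ndarray:
    rows = []
    for line in path.read_text().splitlines():
        toks = line.split()
        if not toks:
            continue
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise GradientFormatError(f"non-numeric token in {path}: {exc}") from exc
    if not rows:
        raise GradientFormatError(f"empty gradient file {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise GradientFormatError(f"ragged rows in {path}")
    return np.asarray(rows, dtype=float)


def read_gradient_table(
    bval_path, bvec_path, b0_threshold: float = B0_THRESHOLD
) -> GradientTable:
    """Read FSL bval/bvec files into a :class:`GradientTable`.

    The bvec file may be 3×n or n×3; orientation is auto-detected.
    Vectors at b-values above the threshold are re-normalized to unit
    length; zero vectors are allowed (and kept) at b0 volumes.
    """
    bvals = _parse_matrix(Path(bval_path)).ravel()
    mat = _parse_matrix(Path(bvec_path))
    if mat.shape[0] == 3 and (mat.shape[1] != 3 or bvals.size != 3):
        bvecs = mat.T
    elif mat.shape[1] == 3:
        bvecs = mat
    else:
        raise GradientFormatError(
            f"bvec file must be 3×n or n×3, got {mat.shape}"
        )
    if bvecs.shape[0] != bvals.size:
        raise GradientFormatError(
            f"{bvals.size} b-values but {bvecs.shape[0]} b-vectors"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dw = (bvals > b0_threshold) & (norms > 0)
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw, None]
    return GradientTable(bvals, bvecs, b0_threshold)


def write_gradient_table(table: GradientTable, bval_path, bvec_path) -> None:
    """Write FSL-style bval (one row) and bvec (three rows) text files."""
    Path(bval_path).write_text(
        " ".join(f"{b:.6g}" for b in table.bvals) + "\n"
    )
    lines = [
        " ".join(f"{v:.6g}" for v in table.bvecs[:, axis]) for axis in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")
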