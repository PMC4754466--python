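"""Diffusion tensor volumes: FA/MD maps and world-coordinate interpolation.

A diffusion tensor volume is a 3D grid of symmetric 3x3 tensors (units
mm²/s) with a voxel-to-world affine.  On disk, tensors live in a 6-volume
NIfTI whose component order is lower-triangular (Dxx, Dxy, Dyy, Dxz, Dyz,
Dzz) by default; the upper-triangular dialect (Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz) is accepted behind an explicit flag — the two are never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DiffusionTensorVolume",
    "compute_fa",
    "compute_md",
    "tensor_from_fa_md",
    "load_tensor_volume",
    "save_tensor_volume",
]

# (i, j) index pairs of the 6 unique components per dialect
_LOWER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]
_UPPER = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

_SYM_TOL = 1e-6


def _check_symmetric(tensor: np.ndarray) -> np.ndarray:
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-2:] != (3, 3):
        raise ValueError("tensor must be 3x3")
    scale = np.max(np.abs(tensor), axis=(-2, -1), keepdims=True)
    asym = np.abs(tensor - np.swapaxes(tensor, -1, -2))
    if np.any(asym > _SYM_TOL * np.maximum(scale, 1e-30)):
        raise ValueError("tensor is not symmetric within tolerance")
    return tensor


def compute_fa(tensor: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of symmetric tensor(s), in [0, 1].

    ``FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||`` over the eigenvalues.
    Negative eigenvalues (possible for noisy tensors) are clipped to zero
    first so FA stays within [0, 1]; an all-zero tensor has FA 0 by
    convention.  Accepts a single 3x3 array or any (..., 3, 3) stack.
    """
    tensor = _check_symmetric(tensor)
    lam = np.clip(np.linalg.eigvalsh(tensor), 0.0, None)
    norm = np.linalg.norm(lam, axis=-1)
    dev = lam - lam.mean(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.where(norm > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0) if fa.ndim else float(np.clip(fa, 0.0, 1.0))


def compute_md(tensor: np.ndarray) -> np.ndarray:
    """Mean diffusivity: trace/3, in mm²/s."""
    tensor = _check_symmetric(tensor)
    md = np.trace(tensor, axis1=-2, axis2=-1) / 3.0
    return md if np.ndim(md) else float(md)


def tensor_from_fa_md(fa: float, md: float, axis: np.ndarray) -> np.ndarray:
    """Prolate (cylindrically symmetric) tensor with given FA, MD and axis.

    With eigenvalues ``lam1 = MD (1 + 2 d)``, ``lam2 = lam3 = MD (1 - d)``,
    the anisotropy is ``FA = 3 d / sqrt(3 + 6 d²)``; inverting gives
    ``d = FA / sqrt(3 - 2 FA²)``, which is unique for FA in [0, 1].
    """
    if not 0 <= fa <= 1:
        raise ValueError("fa must be in [0, 1]")
    if md < 0:
        raise ValueError("md must be non-negative")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam1 = md * (1.0 + 2.0 * d)
    lam23 = md * (1.0 - d)
    return lam23 * np.eye(3) + (lam1 - lam23) * np.outer(axis, axis)


@dataclass
class DiffusionTensorVolume:
    """3D grid of symmetric diffusion tensors with a voxel-to-world affine.

    ``tensors`` has shape ``(nx, ny, nz, 3, 3)``; ``affine`` maps voxel
    indices to world mm.
    """

    tensors: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        _check_symmetric(self.tensors)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def interpolate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear component-wise tensor interpolation at world points.

        Returns ``(tensors, inside)``: an (n, 3, 3) array and a boolean mask;
        out-of-bounds points carry a zero tensor and ``inside=False`` so the
        caller can treat them as missing samples.
        """
        vox = self.world_to_voxel(points)
        shape = np.array(self.grid_shape)
        inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
        v = np.clip(vox, 0, shape - 1)
        i0 = np.minimum(v.astype(int), shape - 2)
        i0 = np.maximum(i0, 0)
        f = v - i0
        out = np.zeros((len(vox), 3, 3))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    out += w[:, None, None] * self.tensors[
                        i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                    ]
        out[~inside] = 0.0
        return out, inside

    def fa_map(self) -> np.ndarray:
        return compute_fa(self.tensors)

    def md_map(self) -> np.ndarray:
        return compute_md(self.tensors)


def _component_pairs(order: str) -> list[tuple[int, int]]:
    if order == "lower":
        return _LOWER
    if order == "upper":
        return _UPPER
    raise ValueError("component order must be 'lower' or 'upper'")


def load_tensor_volume(path: str | Path, order: str = "lower") -> DiffusionTensorVolume:
    """Read a 6-component symmetric-tensor NIfTI.

    ``order`` selects the on-disk component dialect and is never inferred.
    The affine is the sform when valid, otherwise the qform (nibabel's
    ``get_best_affine`` priority).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:  # FSL-style (x,y,z,1,6)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"{path}: expected a 6-component tensor volume")
    tensors = np.zeros(data.shape[:3] + (3, 3))
    for k, (i, j) in enumerate(_component_pairs(order)):
        tensors[..., i, j] = data[..., k]
        tensors[..., j, i] = data[..., k]
    return DiffusionTensorVolume(tensors, img.affine)


def save_tensor_volume(
    path: str | Path, volume: DiffusionTensorVolume, order: str = "lower"
) -> None:
    """Write a tensor volume as a 6-component NIfTI in the given dialect."""
    pairs = _component_pairs(order)
    data = np.stack([volume.tensors[..., i, j] for i, j in pairs], axis=-1)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))
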