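"""CT-based lung gas volumetry.

Quantitative CT expresses each voxel's attenuation in Hounsfield units
(HU): air is -1000 HU, water 0 HU.  Assuming a lung voxel is a mixture of
gas and tissue/water, its gas fraction is the linear map ``-HU / 1000`` on
[-1000, 0], clamped to 0 above 0 HU and to 1 below -1000 HU.  End-expiratory
lung volume by CT (EELV_CT) is the sum of gas fraction x voxel volume over
a lung segmentation mask, reported in mL.

Arrays are indexed (z, y, x); masks are voxel-aligned binary arrays of the
same shape (no partial-volume weighting).  Segmentation itself is out of
scope — the mask is an input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from eelvkit.errors import DomainError


@dataclass(frozen=True)
class CtVolume:
    """A 3-D CT image: Hounsfield numbers plus voxel dimensions in mm."""

    ct_numbers: np.ndarray          # HU, shape (z, y, x)
    voxel_dims: tuple[float, float, float]  # mm

    def __post_init__(self):
        arr = np.asarray(self.ct_numbers, dtype=float)
        if arr.ndim != 3:
            raise DomainError(f"ct_numbers must be 3-D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise DomainError("ct_numbers contains non-finite values")
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise DomainError(f"voxel_dims must be 3 positive mm values, got {self.voxel_dims}")
        object.__setattr__(self, "ct_numbers", arr)

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_dims
        return dz * dy * dx


@dataclass(frozen=True)
class LungMask:
    """Binary lung segmentation, same shape as its :class:`CtVolume`."""

    mask: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("mask values must be 0 or 1")
        object.__setattr__(self, "mask", arr.astype(bool))


def voxel_gas_fraction(hu):
    """Gas fraction of a voxel from its CT number.

    0 for HU > 0 (no gas), 1 for HU <= -1000 (pure gas), linear
    ``-HU/1000`` in between.  Accepts scalars or arrays.
    """
    arr = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("CT numbers must be finite")
    frac = np.clip(-arr / 1000.0, 0.0, 1.0)
    return float(frac) if np.isscalar(hu) else frac


def eelv_from_ct(volume: CtVolume, mask: LungMask) -> float:
    """EELV_CT in mL: gas fraction x voxel volume summed over the mask."""
    if volume.ct_numbers.shape != mask.mask.shape:
        raise DomainError(
            f"shape mismatch: CT {volume.ct_numbers.shape} vs mask {mask.mask.shape}"
        )
    frac = voxel_gas_fraction(volume.ct_numbers[mask.mask])
    gas_mm3 = float(np.sum(frac)) * volume.voxel_volume_mm3
    return gas_mm3 / 1000.0  # mm^3 -> mL


def load_nifti(image_path, mask_path) -> tuple[CtVolume, LungMask]:
    """Load a CT volume and mask from NIfTI files (requires nibabel)."""
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return (
        CtVolume(np.asarray(img.dataobj, dtype=float), dims),
        LungMask((np.asarray(msk.dataobj) > 0).astype(int)),
    )


# ---------------------------------------------------------------------------
# synthetic phantom


@dataclass(frozen=True)
class PhantomBlock:
    """An axis-aligned block of uniform attenuation inside a phantom."""

    start: tuple[int, int, int]  # (z, y, x) voxel corner
    shape: tuple[int, int, int]
    hu: float

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, s + n) for s, n in zip(self.start, self.shape))


def make_phantom(
    blocks: Sequence[PhantomBlock],
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
    background_hu: float = 100.0,
) -> tuple[CtVolume, LungMask, float]:
    """Deterministic block phantom with a known analytic gas volume.

    Background voxels (outside every block) take ``background_hu`` and are
    excluded from the mask.  Returns ``(volume, mask, analytic_gas_mL)``.
    Overlapping blocks are rejected: the analytic volume would be ambiguous.
    """
    arr = np.full(grid_shape, background_hu, dtype=float)
    mask = np.zeros(grid_shape, dtype=int)
    analytic_ml = 0.0
    vox_ml = (voxel_dims[0] * voxel_dims[1] * voxel_dims[2]) / 1000.0
    for block in blocks:
        sl = block.slices()
        if any(
            s.stop > dim for s, dim in zip(sl, grid_shape)
        ) or any(s.start < 0 for s in sl):
            raise DomainError(f"block {block} exceeds grid {grid_shape}")
        if mask[sl].any():
            raise DomainError(f"block {block} overlaps a previous block")
        arr[sl] = block.hu
        mask[sl] = 1
        n_vox = int(np.prod(block.shape))
        analytic_ml += n_vox * vox_ml * float(np.clip(-block.hu / 1000.0, 0, 1))
    return CtVolume(arr, voxel_dims), LungMask(mask), analytic_ml
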