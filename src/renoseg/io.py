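"""Readers and writers for the standard medical-image formats.

DICOM single/multi-frame (pydicom), NIfTI (nibabel) and grayscale
PNG/TIFF (imageio) are mapped onto :class:`IntensityImage` / :class:`Volume`;
binary masks are written back as 0/255 PNG or 0/1 NIfTI.  No registration
or patient-coordinate reorientation is performed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .image_model import IntensityImage, Volume

__all__ = [
    "read_image",
    "read_volume",
    "write_mask_png",
    "write_mask_nifti",
    "write_image_png",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _dicom_pixels(path: Path) -> tuple[np.ndarray, float]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    spacing = 1.0
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return arr, spacing


def read_image(path) -> IntensityImage:
    """Load a 2-D count image (first frame of a multi-frame input)."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        arr, spacing = _dicom_pixels(path)
        if arr.ndim == 3:
            arr = arr[0]
        return IntensityImage(values=np.maximum(arr, 0), pixel_spacing=spacing)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).astype(float)
        if arr.ndim == 3:
            arr = arr[..., 0]
        spacing = float(img.header.get_zooms()[0])
        return IntensityImage(values=np.maximum(arr.T, 0), pixel_spacing=spacing)
    import imageio.v3 as iio

    arr = iio.imread(str(path)).astype(float)
    if arr.ndim == 3:  # RGB(A) → luminance
        arr = arr[..., :3].mean(axis=-1)
    return IntensityImage(values=np.maximum(arr, 0))


def read_volume(path) -> Volume:
    """Load a slice stack from NIfTI or multi-frame DICOM."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).astype(float)
        if arr.ndim == 2:
            arr = arr[..., None]
        zooms = img.header.get_zooms()
        spacing = float(zooms[2]) if len(zooms) >= 3 else 1.0
        slices = [
            IntensityImage(values=np.maximum(arr[..., k].T, 0))
            for k in range(arr.shape[-1])
        ]
        return Volume(slices=slices, slice_spacing=spacing)
    if path.suffix.lower() == ".dcm":
        arr, _ = _dicom_pixels(path)
        if arr.ndim == 2:
            arr = arr[None]
        return Volume(
            slices=[IntensityImage(values=np.maximum(a, 0)) for a in arr],
            slice_spacing=1.0,
        )
    raise ValueError(f"unsupported volume format: {path.name}")


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    import imageio.v3 as iio

    m = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    iio.imwrite(str(path), m)


def write_mask_nifti(mask: np.ndarray, path, spacing: float = 1.0) -> None:
    """Write a 2-D or 3-D binary mask as 0/1 NIfTI."""
    import nibabel as nib

    m = np.asarray(mask, dtype=bool).astype(np.uint8)
    if m.ndim == 2:
        m = m.T
    elif m.ndim == 3:
        m = np.transpose(m, (2, 1, 0))
    img = nib.Nifti1Image(m, affine=np.diag([spacing, spacing, spacing, 1.0]))
    nib.save(img, str(path))


def write_volume_nifti(volume: Volume, path) -> None:
    """Write a count volume (stack axis last, NIfTI convention)."""
    import nibabel as nib

    arr = np.transpose(volume.as_array(), (2, 1, 0))
    s = volume.slice_spacing
    img = nib.Nifti1Image(arr.astype(np.float32), affine=np.diag([1.0, 1.0, s, 1.0]))
    nib.save(img, str(path))


def write_image_png(image: IntensityImage, path) -> None:
    """Write a count image as 16-bit PNG (values clipped to uint16)."""
    import imageio.v3 as iio

    v = np.clip(np.rint(image.values), 0, 65535).astype(np.uint16)
    iio.imwrite(str(path), v)
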