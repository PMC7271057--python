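"""Core raster types and the user-choice-driven domain partition.

A scintigraphy scan is a grid of photon counts.  Segmentation never sees the
whole grid at once: the user picks "left kidney", "right kidney" or
"two kidneys", and the image domain M is split into the part to segment
(``phi_s``, containing the kidney(s)) and its complement (``phi_s_bar``),
which supplies the background intensity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IntensityImage",
    "Volume",
    "DomainPartition",
    "split_domain",
    "InvalidPartitionError",
    "PATIENT_LEFT_ON_VIEWER_RIGHT",
]

#: Display convention.  Images are row-major, origin top-left.  With the
#: standard posterior-view rendering used here, the patient's LEFT kidney
#: appears on the VIEWER'S RIGHT (higher column indices).  Flip this single
#: constant to change the convention package-wide.
PATIENT_LEFT_ON_VIEWER_RIGHT = True

SIDE_CHOICES = ("left_kidney", "right_kidney", "two_kidneys")


class InvalidPartitionError(ValueError):
    """Raised when a domain split would produce an empty part."""


@dataclass(frozen=True)
class IntensityImage:
    """A 2-D grid of non-negative emission counts.

    Parameters
    ----------
    values
        2-D float array of per-pixel counts; must be finite and >= 0.
    pixel_spacing
        Physical pixel size in mm (isotropic), default 1.0.
    """

    values: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"image must be 2-D, got ndim={v.ndim}")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("image contains non-finite values")
        if v.min() < 0:
            raise ValueError("image contains negative counts")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Volume:
    """An ordered stack of equally shaped slices.

    The stack axis is anteroposterior: slice 0 is the most posterior.
    ``slice_spacing`` is in mm.
    """

    slices: Sequence[IntensityImage]
    slice_spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("volume needs at least one slice")
        shape = self.slices[0].shape
        for s in self.slices:
            if s.shape != shape:
                raise ValueError("all slices must share width/height")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        object.__setattr__(self, "slices", tuple(self.slices))

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices),) + self.slices[0].shape

    def as_array(self) -> np.ndarray:
        """Stack the slices into a (n_slices, H, W) array."""
        return np.stack([s.values for s in self.slices])


@dataclass(frozen=True)
class DomainPartition:
    """The Φs / Φs̄ split of the image domain.

    ``phi_s`` is the region to segment (contains the kidney side chosen by
    the user); ``phi_s_bar`` is its complement, from which the background
    intensity model is estimated.
    """

    phi_s: np.ndarray
    phi_s_bar: np.ndarray
    split_kind: str
    split_index: int
    side_choice: str

    def __post_init__(self) -> None:
        a = np.asarray(self.phi_s, dtype=bool)
        b = np.asarray(self.phi_s_bar, dtype=bool)
        if a.shape != b.shape:
            raise InvalidPartitionError("masks must share shape")
        if np.any(a & b):
            raise InvalidPartitionError("phi_s and phi_s_bar overlap")
        if not np.all(a | b):
            raise InvalidPartitionError("phi_s and phi_s_bar must cover M")
        if not a.any() or not b.any():
            raise InvalidPartitionError("both partition parts must be non-empty")
        object.__setattr__(self, "phi_s", a)
        object.__setattr__(self, "phi_s_bar", b)

    @property
    def area_phi_s(self) -> int:
        return int(self.phi_s.sum())

    @property
    def area_phi_s_bar(self) -> int:
        return int(self.phi_s_bar.sum())


def split_domain(
    image: IntensityImage,
    side_choice: str,
    split_index: Optional[int] = None,
    kidneys_half: str = "lower",
) -> DomainPartition:
    """Split the image domain into Φs and Φs̄ from the user's side choice.

    Single-kidney modes use a vertical dividing line (Φs is the image half
    on the chosen kidney's display side); ``two_kidneys`` uses a horizontal
    line (Φs is the band holding both kidneys, by default the lower half).
    When ``split_index`` is omitted the line sits at the image midline.

    Raises
    ------
    InvalidPartitionError
        If the requested line would leave either part empty.
    """
    if side_choice not in SIDE_CHOICES:
        raise ValueError(f"side_choice must be one of {SIDE_CHOICES}")
    h, w = image.shape
    if side_choice == "two_kidneys":
        kind, extent = "horizontal", h
    else:
        kind, extent = "vertical", w
    s = extent // 2 if split_index is None else int(split_index)
    if not (1 <= s <= extent - 1):
        raise InvalidPartitionError(
            f"split_index {s} leaves an empty part (valid: 1..{extent - 1})"
        )

    phi_s = np.zeros((h, w), dtype=bool)
    if kind == "horizontal":
        if kidneys_half == "lower":
            phi_s[s:, :] = True
        elif kidneys_half == "upper":
            phi_s[:s, :] = True
        else:
            raise ValueError("kidneys_half must be 'lower' or 'upper'")
    else:
        # map anatomical side to viewer side via the display convention
        viewer_right = (side_choice == "left_kidney") == PATIENT_LEFT_ON_VIEWER_RIGHT
        if viewer_right:
            phi_s[:, s:] = True
        else:
            phi_s[:, :s] = True

    return DomainPartition(
        phi_s=phi_s,
        phi_s_bar=~phi_s,
        split_kind=kind,
        split_index=s,
        side_choice=side_choice,
    )
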