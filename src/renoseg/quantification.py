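"""Relative renal function estimators.

Two routes are provided:

* the clinical-routine **planar** method: anterior/posterior count images,
  manual kidney + background ROIs, background noise subtraction, and
  geometric-mean attenuation correction;
* the **tomographic** method: raw voxel counts inside segmented kidney
  masks of a reconstructed slice stack, with no further correction (the
  segmentation already excludes background and the reconstruction is
  assumed attenuation-compensated).

Relative function (RF) is each side's percentage of the summed corrected
counts; the two sides always total 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import exp, sqrt
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_model import IntensityImage, Volume

__all__ = [
    "PlanarStudy",
    "QuantReport",
    "background_correct",
    "attenuation_correct",
    "relative_function",
    "planar_rf",
    "tomographic_rf",
    "estimate_depth",
    "DEFAULT_MU",
    "UndefinedFunctionError",
]

#: Soft-tissue linear attenuation coefficient default, cm^-1 (configurable).
DEFAULT_MU = 1.43

SIDES = ("right", "left")


class UndefinedFunctionError(ValueError):
    """Raised when both corrected counts are zero (RF undefined)."""


@dataclass(frozen=True)
class PlanarStudy:
    """Paired anterior/posterior planar views with ROIs and geometry.

    ``kidney_roi`` and ``background_roi`` map view name ("anterior",
    "posterior") then side ("right", "left") to boolean masks; kidney and
    background ROIs must be disjoint within each view/side.  ``depth_d``
    (cm, per side) is the kidney depth from the posterior surface,
    ``body_thickness_T`` the anteroposterior thickness (cm), ``mu`` the
    soft-tissue linear attenuation coefficient (cm^-1).
    """

    anterior: IntensityImage
    posterior: IntensityImage
    kidney_roi: dict
    background_roi: dict
    depth_d: dict
    body_thickness_T: float
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.body_thickness_T <= 0:
            raise ValueError("body thickness must be > 0")
        for side in SIDES:
            d = self.depth_d[side]
            if not (0 < d <= self.body_thickness_T):
                raise ValueError(f"{side} depth must be in (0, T]")
        for view in ("anterior", "posterior"):
            for side in SIDES:
                k = np.asarray(self.kidney_roi[view][side], dtype=bool)
                b = np.asarray(self.background_roi[view][side], dtype=bool)
                if (k & b).any():
                    raise ValueError(
                        f"kidney and background ROIs overlap ({view}/{side})"
                    )


@dataclass
class QuantReport:
    """Corrected counts and relative function percentages per side."""

    q_bc: dict
    q_ac: dict
    rf_right: float
    rf_left: float
    method: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.rf_right + self.rf_left - 100.0) > 1e-9:
            raise ValueError("RF percentages must sum to 100")
        for v in (self.rf_right, self.rf_left):
            if not (0.0 <= v <= 100.0):
                raise ValueError("RF percentages must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "q_bc": self.q_bc,
            "q_ac": self.q_ac,
            "rf_right": self.rf_right,
            "rf_left": self.rf_left,
            "warnings": list(self.warnings),
        }


def background_correct(
    q_b: float, n_qb: int, q_f: float, n_qf: int
) -> float:
    """Background-subtracted renal count: Q_b − N_Qb · (Q_F / N_QF).

    The per-pixel background rate estimated on the background ROI is
    scaled to the kidney ROI area and subtracted.  The raw value may be
    negative on noisy inputs; report-level callers clamp it to 0 with a
    warning.
    """
    if n_qb < 1 or n_qf < 1:
        raise ValueError("ROI pixel counts must be >= 1")
    if q_b < 0 or q_f < 0:
        raise ValueError("counts must be non-negative")
    return q_b - n_qb * (q_f / n_qf)


def attenuation_correct(
    c_ant: float,
    c_post: float,
    mu: float,
    depth_d: float,
    body_thickness_T: float,
    mode: str = "geometric_mean",
) -> float:
    """Depth-corrected renal count from paired anterior/posterior counts.

    ``geometric_mean`` (default): √(C_ant·C_post)·e^{μT/2}, which exactly
    recovers the emission count under the symmetric exponential model
    C_post = C₀e^{−μd}, C_ant = C₀e^{−μ(T−d)} — the depth d cancels.
    ``literal``: C_ant·C_post·e^{μd}, retained only for reproducing the
    routine formula as printed (dimensionally it is counts squared).
    """
    if c_ant < 0 or c_post < 0:
        raise ValueError("counts must be non-negative")
    if mu < 0 or depth_d < 0 or body_thickness_T <= 0:
        raise ValueError("invalid attenuation geometry")
    if mode == "geometric_mean":
        return sqrt(c_ant * c_post) * exp(mu * body_thickness_T / 2.0)
    if mode == "literal":
        return c_ant * c_post * exp(mu * depth_d)
    raise ValueError("mode must be 'geometric_mean' or 'literal'")


def relative_function(q_right: float, q_left: float) -> tuple[float, float]:
    """Percent split of corrected counts; (rf_right, rf_left) sums to 100."""
    if q_right < 0 or q_left < 0:
        raise ValueError("corrected counts must be non-negative")
    total = q_right + q_left
    if total <= 0:
        raise UndefinedFunctionError("both corrected counts are zero")
    rf_r = 100.0 * q_right / total
    return rf_r, 100.0 - rf_r


def _roi_stats(image: IntensityImage, mask: np.ndarray) -> tuple[float, int]:
    mask = np.asarray(mask, dtype=bool)
    return float(image.values[mask].sum()), int(mask.sum())


def planar_rf(study: PlanarStudy, mode: str = "geometric_mean") -> QuantReport:
    """Full clinical-routine planar pipeline.

    Per side and view: sum counts in the kidney ROI, subtract the
    area-scaled background ROI rate, then combine the two views with the
    attenuation correction; finally convert to percentages.
    """
    warn: list[str] = []
    q_bc: dict = {}
    q_ac: dict = {}
    views = {"anterior": study.anterior, "posterior": study.posterior}
    for side in SIDES:
        corrected = {}
        for view, img in views.items():
            qb, nqb = _roi_stats(img, study.kidney_roi[view][side])
            qf, nqf = _roi_stats(img, study.background_roi[view][side])
            c = background_correct(qb, nqb, qf, nqf)
            if c < 0:
                warn.append(
                    f"negative background-corrected count ({view}/{side}); clamped to 0"
                )
                c = 0.0
            corrected[view] = c
        q_bc[side] = corrected
        q_ac[side] = attenuation_correct(
            corrected["anterior"],
            corrected["posterior"],
            study.mu,
            study.depth_d[side],
            study.body_thickness_T,
            mode=mode,
        )
    rf_r, rf_l = relative_function(q_ac["right"], q_ac["left"])
    return QuantReport(
        q_bc=q_bc, q_ac=q_ac, rf_right=rf_r, rf_left=rf_l,
        method="planar", warnings=warn,
    )


def tomographic_rf(volume: Volume, kidney_masks: dict) -> QuantReport:
    """Relative function from raw in-mask voxel counts of a slice stack.

    ``kidney_masks`` maps side to a (n_slices, H, W) boolean stack (or a
    2-D mask applied to every slice).  No background or attenuation
    correction is applied.
    """
    arr = volume.as_array()
    counts = {}
    for side in SIDES:
        mask = np.asarray(kidney_masks[side], dtype=bool)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask, arr.shape)
        if mask.shape != arr.shape:
            raise ValueError(f"{side} mask shape {mask.shape} != volume {arr.shape}")
        counts[side] = float(arr[mask].sum())
    if counts["right"] == 0 and counts["left"] == 0:
        raise UndefinedFunctionError("both kidney masks have zero counts")
    rf_r, rf_l = relative_function(counts["right"], counts["left"])
    return QuantReport(
        q_bc={s: counts[s] for s in SIDES},
        q_ac={s: counts[s] for s in SIDES},
        rf_right=rf_r,
        rf_left=rf_l,
        method="tomographic",
    )


def estimate_depth(volume: Volume, kidney_mask: np.ndarray) -> float:
    """Kidney depth (cm) from the posterior surface along the stack axis.

    Best-effort reading of the gravity-center depth estimate: the distance
    from the mask's center of mass to slice 0 (most posterior), i.e.
    com-slice-index × slice spacing, converted from mm to cm.
    """
    mask = np.asarray(kidney_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask must match the volume shape")
    if not mask.any():
        raise ValueError("empty kidney mask")
    com_slice = ndimage.center_of_mass(mask)[0]
    return float(com_slice * volume.slice_spacing / 10.0)
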