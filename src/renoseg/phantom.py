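"""Seeded scintigraphy phantom generator with full ground truth.

The generator emulates DMSA count images: elliptical high-uptake kidneys
over a low uniform background, Poisson counting noise, a slice stack along
the anteroposterior axis, and attenuated anterior/posterior planar
projections.  Three presets mirror the study conditions:

* ``normal``    — two kidneys in orthotopic position, symmetric geometry;
* ``ectopic``   — the right kidney displaced toward the pelvis, with a
  reduced effective body thickness and an optional bone insert that extra-
  attenuates its posterior path (iliac bone / lumbar spine);
* ``hydronephrotic`` — ectopic geometry plus a ring-shaped (cold-center)
  uptake pattern and an elevated peri-kidney background patch emulating
  radioactive urine stasis.

Every sampled value flows from a single integer seed; a ``noise=False``
mode returns expected counts for closed-form tests.  Per-side uptake rates
are scaled so the expected in-mask count split equals ``true_rf_split``
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, sqrt
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_model import IntensityImage, Volume

__all__ = [
    "KidneyGeometry",
    "BoneInsert",
    "PhantomSpec",
    "make_slice",
    "make_volume",
    "project_planar",
    "GeometryError",
]

SIDES = ("right", "left")

#: Soft-tissue linear attenuation used by default when projecting, cm^-1
#: (140 keV photons in water-equivalent tissue).
PROJECTION_MU = 0.15


class GeometryError(ValueError):
    """Raised when a kidney shape exceeds the image bounds."""


@dataclass(frozen=True)
class KidneyGeometry:
    """Elliptical kidney: center (row, col), semi-axes (rows, cols), in px.

    ``ring_inner_frac`` > 0 hollows the ellipse (hydronephrotic cold
    center): the uptake mask becomes the annulus outside that fraction of
    the semi-axes.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    ring_inner_frac: float = 0.0

    def mask(self, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
        if scale <= 0:
            return np.zeros(shape, dtype=bool)
        cr, cc = self.center
        ar, ac = self.semi_axes[0] * scale, self.semi_axes[1] * scale
        if ar < 0.5 or ac < 0.5:
            return np.zeros(shape, dtype=bool)
        if cr - ar < 0 or cr + ar > shape[0] - 1 or cc - ac < 0 or cc + ac > shape[1] - 1:
            raise GeometryError("kidney ellipse exceeds image bounds")
        rr, cc_grid = np.mgrid[0 : shape[0], 0 : shape[1]]
        d2 = ((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2
        m = d2 <= 1.0
        if self.ring_inner_frac > 0:
            m &= d2 > self.ring_inner_frac**2
        return m


@dataclass(frozen=True)
class BoneInsert:
    """Extra attenuating structure on one kidney's projection path."""

    side: str = "right"
    extra_mu: float = 0.25  # cm^-1 beyond soft tissue
    thickness_cm: float = 3.0
    view: str = "posterior"

    @property
    def factor(self) -> float:
        return exp(-self.extra_mu * self.thickness_cm)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic study, including its ground truth."""

    preset: str = "normal"
    shape: tuple[int, int] = (128, 128)
    kidneys: dict = field(
        default_factory=lambda: {
            "right": KidneyGeometry(center=(82, 40), semi_axes=(16, 10)),
            "left": KidneyGeometry(center=(82, 88), semi_axes=(16, 10)),
        }
    )
    background_rate: float = 50.0
    kidney_rate: float = 150.0
    true_rf_split: tuple[float, float] = (50.0, 50.0)  # (right, left) percent
    depth_cm: dict = field(default_factory=lambda: {"right": 7.0, "left": 5.0})
    body_thickness_cm: float = 20.0
    effective_thickness_cm: Optional[dict] = None  # per side; None = global
    bone_insert: Optional[BoneInsert] = None
    peri_background_factor: float = 1.0  # >1: elevated patch around kidneys
    slice_spacing_mm: float = 10.0
    n_slices: int = 20
    ap_half_extent_cm: float = 2.0  # kidney half-thickness along the stack
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0 or self.kidney_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.kidney_rate < self.background_rate:
            raise ValueError("kidney rate must be >= background rate")
        if abs(sum(self.true_rf_split) - 100.0) > 1e-9:
            raise ValueError("true_rf_split must sum to 100")
        for side in SIDES:
            if not (0 < self.depth_cm[side] < self.body_thickness_cm):
                raise ValueError(f"{side} depth must lie inside the body")

    @property
    def contrast_ratio(self) -> float:
        return self.kidney_rate / self.background_rate

    def thickness(self, side: str) -> float:
        if self.effective_thickness_cm is None:
            return self.body_thickness_cm
        return self.effective_thickness_cm.get(side, self.body_thickness_cm)

    def mirrored(self) -> "PhantomSpec":
        """Left-right mirror: swap sides and reflect kidney columns."""
        w = self.shape[1]

        def flip(g: KidneyGeometry) -> KidneyGeometry:
            return replace(g, center=(g.center[0], w - 1 - g.center[1]))

        return replace(
            self,
            kidneys={"right": flip(self.kidneys["left"]), "left": flip(self.kidneys["right"])},
            true_rf_split=(self.true_rf_split[1], self.true_rf_split[0]),
            depth_cm={"right": self.depth_cm["left"], "left": self.depth_cm["right"]},
            effective_thickness_cm=None
            if self.effective_thickness_cm is None
            else {
                "right": self.thickness("left"),
                "left": self.thickness("right"),
            },
        )

    @classmethod
    def make(cls, preset: str = "normal", seed: int = 0, **overrides) -> "PhantomSpec":
        """Build a preset spec; any field can be overridden by keyword."""
        base: dict = {"preset": preset, "seed": seed}
        if preset == "normal":
            pass
        elif preset == "ectopic":
            base.update(
                kidneys={
                    "right": KidneyGeometry(center=(104, 58), semi_axes=(13, 9)),
                    "left": KidneyGeometry(center=(82, 88), semi_axes=(16, 10)),
                },
                depth_cm={"right": 9.0, "left": 5.0},
                effective_thickness_cm={"right": 16.0, "left": 20.0},
                bone_insert=BoneInsert(side="right"),
                true_rf_split=(45.0, 55.0),
            )
        elif preset == "hydronephrotic":
            base.update(
                kidneys={
                    "right": KidneyGeometry(
                        center=(104, 58), semi_axes=(13, 9), ring_inner_frac=0.55
                    ),
                    "left": KidneyGeometry(center=(82, 88), semi_axes=(16, 10)),
                },
                depth_cm={"right": 9.0, "left": 5.0},
                effective_thickness_cm={"right": 16.0, "left": 20.0},
                bone_insert=BoneInsert(side="right"),
                peri_background_factor=1.6,
                true_rf_split=(40.0, 60.0),
            )
        else:
            raise ValueError(f"unknown preset {preset!r}")
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------


def _side_rates(spec: PhantomSpec, areas: dict) -> dict:
    """Per-side uptake rates realizing the requested expected-count split."""
    p = {"right": spec.true_rf_split[0], "left": spec.true_rf_split[1]}
    mean_area = 0.5 * (areas["right"] + areas["left"])
    rates = {}
    for side in SIDES:
        if areas[side] == 0:
            raise GeometryError(f"{side} kidney has zero area")
        rates[side] = spec.kidney_rate * (p[side] / 50.0) * (mean_area / areas[side])
    return rates


def _peri_patch(spec: PhantomSpec, masks: dict) -> np.ndarray:
    if spec.peri_background_factor <= 1.0:
        return np.zeros(spec.shape, dtype=bool)
    union = masks["right"] | masks["left"]
    ring = ndimage.binary_dilation(union, iterations=4) & ~union
    return ring


def _rate_map(spec: PhantomSpec, masks: dict, rates: dict) -> np.ndarray:
    rate = np.full(spec.shape, spec.background_rate, dtype=float)
    peri = _peri_patch(spec, masks)
    rate[peri] = spec.background_rate * spec.peri_background_factor
    for side in SIDES:
        rate[masks[side]] = rates[side]
    return rate


def make_slice(
    spec: PhantomSpec, noise: bool = True, seed: Optional[int] = None
) -> tuple[IntensityImage, dict]:
    """A single 2-D phantom slice and its per-side ground-truth masks.

    Pixel values are Poisson draws with rate = background rate everywhere
    and the side's uptake rate inside its kidney shape (annular rate for
    hollow-center kidneys).  Deterministic for a fixed seed.
    """
    masks = {s: spec.kidneys[s].mask(spec.shape) for s in SIDES}
    rates = _side_rates(spec, {s: int(masks[s].sum()) for s in SIDES})
    rate = _rate_map(spec, masks, rates)
    if noise:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        values = rng.poisson(rate).astype(float)
    else:
        values = rate
    return IntensityImage(values=values), masks


def _slice_scales(spec: PhantomSpec, side: str, n_slices: int) -> np.ndarray:
    """Elliptical axial profile of one kidney along the stack."""
    spacing_cm = spec.slice_spacing_mm / 10.0
    center = spec.depth_cm[side] / spacing_cm
    half = max(spec.ap_half_extent_cm / spacing_cm, 0.5)
    s = np.arange(n_slices)
    t = (s - center) / half
    return np.sqrt(np.maximum(1.0 - t**2, 0.0))


def make_volume(
    spec: PhantomSpec,
    n_slices: Optional[int] = None,
    noise: bool = True,
    seed: Optional[int] = None,
) -> tuple[Volume, dict, dict]:
    """A slice stack with masks and exact per-side count bookkeeping.

    Returns ``(volume, masks, info)`` where ``masks`` maps side to a
    (n_slices, H, W) boolean stack and ``info`` carries the expected and
    realized per-side in-mask totals, so the true relative-function split
    is known exactly.  Kidney cross-sections scale elliptically along the
    stack, centered at each side's depth.
    """
    n = spec.n_slices if n_slices is None else int(n_slices)
    if n < 1:
        raise ValueError("need at least one slice")
    scales = {s: _slice_scales(spec, s, n) if n > 1 else np.ones(1) for s in SIDES}
    mask_stacks = {
        s: np.stack(
            [spec.kidneys[s].mask(spec.shape, scale=scales[s][i]) for i in range(n)]
        )
        for s in SIDES
    }
    areas = {s: int(mask_stacks[s].sum()) for s in SIDES}
    rates = _side_rates(spec, areas)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    slices = []
    realized = {s: 0.0 for s in SIDES}
    for i in range(n):
        masks_i = {s: mask_stacks[s][i] for s in SIDES}
        rate = _rate_map(spec, masks_i, rates)
        values = rng.poisson(rate).astype(float) if noise else rate
        slices.append(IntensityImage(values=values))
        for s in SIDES:
            realized[s] += float(values[masks_i[s]].sum())

    expected = {s: rates[s] * areas[s] for s in SIDES}
    tot_e = expected["right"] + expected["left"]
    tot_r = realized["right"] + realized["left"]
    info = {
        "expected_counts": expected,
        "realized_counts": realized,
        "true_split": (
            100.0 * expected["right"] / tot_e,
            100.0 * expected["left"] / tot_e,
        ),
        "realized_split": (
            100.0 * realized["right"] / tot_r if tot_r else float("nan"),
            100.0 * realized["left"] / tot_r if tot_r else float("nan"),
        ),
        "rates": rates,
        "depth_cm": dict(spec.depth_cm),
    }
    vol = Volume(slices=slices, slice_spacing=spec.slice_spacing_mm)
    return vol, mask_stacks, info


def project_planar(
    spec: PhantomSpec,
    mu: float = PROJECTION_MU,
    noise: bool = True,
    seed: Optional[int] = None,
) -> tuple[IntensityImage, IntensityImage, dict]:
    """Attenuated anterior/posterior planar projections of the phantom.

    Each kidney's true emission count C (the expected in-mask volume
    total) is spread over its 2-D footprint and attenuated exponentially
    toward each detector — posterior path length d, anterior path T − d,
    with the side's effective thickness T — plus the bone-insert factor on
    the view whose path crosses it.  A uniform background (and the
    hydronephrotic peri-kidney patch, when present) is added, then Poisson
    noise unless ``noise=False``.

    ``info`` carries the true unattenuated counts, the per-view
    attenuation factors, and ready-made kidney/background ROI masks.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    n = spec.n_slices
    scales = {s: _slice_scales(spec, s, n) if n > 1 else np.ones(1) for s in SIDES}
    areas = {
        s: sum(
            int(spec.kidneys[s].mask(spec.shape, scale=scales[s][i]).sum())
            for i in range(n)
        )
        for s in SIDES
    }
    rates = _side_rates(spec, areas)
    true_counts = {s: rates[s] * areas[s] for s in SIDES}

    footprints = {s: spec.kidneys[s].mask(spec.shape) for s in SIDES}
    factors = {"anterior": {}, "posterior": {}}
    for side in SIDES:
        d = spec.depth_cm[side]
        t_eff = spec.thickness(side)
        factors["posterior"][side] = exp(-mu * d)
        factors["anterior"][side] = exp(-mu * max(t_eff - d, 0.0))
        bi = spec.bone_insert
        if bi is not None and bi.side == side:
            factors[bi.view][side] *= bi.factor

    peri = _peri_patch(spec, footprints)
    bg = np.full(spec.shape, spec.background_rate, dtype=float)
    bg[peri] = spec.background_rate * spec.peri_background_factor
    images = {}
    for view in ("anterior", "posterior"):
        expected = bg.copy()
        for side in SIDES:
            fp = footprints[side]
            area = int(fp.sum())
            expected[fp] += true_counts[side] * factors[view][side] / area
        if noise:
            rng = np.random.default_rng(
                (spec.seed if seed is None else seed) + (0 if view == "anterior" else 1)
            )
            values = rng.poisson(expected).astype(float)
        else:
            values = expected
        images[view] = IntensityImage(values=values)

    kidney_roi = {v: dict(footprints) for v in ("anterior", "posterior")}
    background_roi = {}
    other = {"right": "left", "left": "right"}
    for view in ("anterior", "posterior"):
        background_roi[view] = {}
        for side in SIDES:
            ring = ndimage.binary_dilation(footprints[side], iterations=6) & ~ndimage.binary_dilation(
                footprints[side], iterations=2
            )
            ring &= ~footprints[other[side]] & ~peri
            background_roi[view][side] = ring

    info = {
        "true_counts": true_counts,
        "true_split": tuple(spec.true_rf_split),
        "attenuation_factors": factors,
        "kidney_roi": kidney_roi,
        "background_roi": background_roi,
        "mu": mu,
    }
    return images["anterior"], images["posterior"], info
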