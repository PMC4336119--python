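"""Synthetic B-mode thyroid phantoms with ground-truth masks.

A phantom emulates the gross appearance of a transverse thyroid scan: a
mid-gray parenchyma background, a darker (hypoechoic) elliptical nodule and
a nearly anechoic tracheal region, corrupted by multiplicative speckle and
blurred by an isotropic point-spread approximation.  Speckle is modeled as
L-look fully developed speckle: per-pixel mean-1 Gamma variates of shape L
multiply the echogenicity scene, so larger L means weaker speckle
(coefficient of variation 1/sqrt(L)).  The blur is applied after the noise,
standing in for the system PSF acting on the echo field.

The resulting gray mass concentrates in a narrow band around the
parenchyma level — the low-dynamic-range histogram that motivates contrast
preprocessing before segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = ["Ellipse", "PhantomSpec", "make_phantom", "dice"]


@dataclass(frozen=True)
class Ellipse:
    """Axis specification of an elliptical region (pixels, degrees)."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a_px, b_px) along rotated row/col axes
    rotation_deg: float = 0.0

    def mask(self, size: int) -> np.ndarray:
        rr, cc = np.mgrid[0:size, 0:size]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        th = math.radians(self.rotation_deg)
        u = dr * math.cos(th) + dc * math.sin(th)
        w = -dr * math.sin(th) + dc * math.cos(th)
        a, b = self.semi_axes
        return (u / a) ** 2 + (w / b) ** 2 <= 1.0

    def bounding_radius(self) -> float:
        return max(self.semi_axes)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity levels and noise of a synthetic scan.

    ``speckle_looks`` is the number of looks L of the multiplicative Gamma
    speckle; ``math.inf`` disables the noise.  ``blur_sigma = 0`` disables
    the point-spread blur.
    """

    size: int = 128
    background_level: float = 0.7
    nodule_level: float = 0.2
    trachea_level: float = 0.05
    nodule_ellipse: Ellipse = field(
        default_factory=lambda: Ellipse((52.0, 56.0), (16.0, 20.0), 20.0)
    )
    trachea_ellipse: Ellipse = field(
        default_factory=lambda: Ellipse((94.0, 82.0), (10.0, 13.0), 0.0)
    )
    speckle_looks: float = 20.0
    blur_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("phantom size must be >= 8")
        if not (
            0.0 <= self.trachea_level < self.nodule_level < self.background_level <= 1.0
        ):
            raise ValueError(
                "levels must satisfy 0 <= trachea < nodule < background <= 1"
            )
        if not (self.speckle_looks >= 1):
            raise ValueError("speckle_looks must be >= 1 (or inf for noise off)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        for name, ell in (
            ("nodule", self.nodule_ellipse),
            ("trachea", self.trachea_ellipse),
        ):
            r = ell.bounding_radius()
            cr, cc = ell.center
            if cr - r < 0 or cc - r < 0 or cr + r > self.size - 1 or cc + r > self.size - 1:
                raise ValueError(f"{name} ellipse extends outside the frame")
        if (self.nodule_ellipse.mask(self.size) & self.trachea_ellipse.mask(self.size)).any():
            raise ValueError("nodule and trachea ellipses overlap")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("nodule_ellipse", "trachea_ellipse"):
            e = d[key]
            d[key] = {
                "center": list(e["center"]),
                "semi_axes": list(e["semi_axes"]),
                "rotation_deg": e["rotation_deg"],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("nodule_ellipse", "trachea_ellipse"):
            if key in d and isinstance(d[key], dict):
                e = d[key]
                d[key] = Ellipse(
                    tuple(e["center"]),
                    tuple(e["semi_axes"]),
                    float(e.get("rotation_deg", 0.0)),
                )
        if "speckle_looks" in d and d["speckle_looks"] in ("inf", ".inf", None):
            d["speckle_looks"] = math.inf
        return cls(**d)


def make_phantom(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom and its ground-truth label raster.

    Returns ``(image, labels)`` where labels are 0 background, 1 nodule,
    2 trachea.  The image is the piecewise-constant scene multiplied by
    L-look Gamma speckle, Gaussian-blurred and clipped to [0, 1]; the
    output is fully determined by ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    labels = np.zeros((spec.size, spec.size), dtype=np.intp)
    labels[spec.nodule_ellipse.mask(spec.size)] = 1
    labels[spec.trachea_ellipse.mask(spec.size)] = 2
    scene = np.choose(
        labels, [spec.background_level, spec.nodule_level, spec.trachea_level]
    )
    img = scene
    if math.isfinite(spec.speckle_looks):
        rng = np.random.default_rng(spec.seed)
        L = spec.speckle_looks
        speckle = rng.gamma(shape=L, scale=1.0 / L, size=img.shape)
        img = img * speckle
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="reflect")
    return np.clip(img, 0.0, 1.0), labels


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
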