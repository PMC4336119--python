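"""Fractional-differential gradient images via Grünwald-Letnikov masks.

A fractional derivative of order ``v`` in (0, 1) interpolates between the
identity (v=0) and the first difference (v=1).  Discretized on a unit grid
it becomes a convolution with the binomial-type weights

    c_0 = 1,   c_k = c_{k-1} * (k - 1 - v) / k

whose infinite sum is 0 for v > 0 but whose truncations have *nonzero*
sum — unlike an integer-order derivative mask, a fractional mask retains a
scaled copy of the local signal, which preserves low-frequency texture
while boosting high-frequency detail.

Directional masks are built by laying the weights symmetrically outward
from the center along one of four directions (x, y, and the two
diagonals); the center coefficient is shared by the two arms and therefore
doubled.  The image response is the per-pixel maximum over the four
directional convolutions (negatives clipped at 0), a rotation-tolerant
"fractional gradient" that is finally stacked onto the source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import as_gray

__all__ = [
    "gl_coefficients",
    "FractionalMaskSet",
    "build_masks",
    "fractional_response",
    "enhance_with_gradient",
]


def gl_coefficients(v: float, K: int) -> np.ndarray:
    """First ``K`` Grünwald-Letnikov weights of fractional order ``v``.

    c_0 = 1 and c_k = c_{k-1} (k - 1 - v) / k.  At v=0 this is the
    identity [1, 0, 0, ...]; at v=1 the backward difference [1, -1, 0, ...].
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0.0 <= v <= 1.0):
        raise ValueError("order v must lie in [0, 1]")
    c = np.empty(K)
    c[0] = 1.0
    for k in range(1, K):
        c[k] = c[k - 1] * (k - 1 - v) / k
    return c


@dataclass(frozen=True)
class FractionalMaskSet:
    """Order, support and the four directional convolution masks."""

    order: float
    support: int
    masks: tuple[np.ndarray, ...] = field(repr=False)

    @property
    def mask_sum(self) -> float:
        """Common coefficient sum of the masks (response to a unit patch)."""
        return float(self.masks[0].sum())


def _line_mask(coeffs: np.ndarray, support: int, direction: str) -> np.ndarray:
    """Lay GL weights along a line through the center of a support² grid.

    The two arms share the center sample, so the center weight is 2*c_0.
    """
    m = np.zeros((support, support))
    ctr = support // 2
    steps = {
        "x": (0, 1),
        "y": (1, 0),
        "diag_right": (-1, 1),  # towards upper-right
        "diag_left": (1, 1),    # towards lower-right
    }[direction]
    m[ctr, ctr] = 2.0 * coeffs[0]
    for k in range(1, len(coeffs)):
        dr, dc = steps[0] * k, steps[1] * k
        m[ctr + dr, ctr + dc] = coeffs[k]
        m[ctr - dr, ctr - dc] = coeffs[k]
    return m


def build_masks(v: float, support: int = 5, variant: str = "gl") -> FractionalMaskSet:
    """Build the four directional fractional-differential masks.

    Parameters
    ----------
    v:
        Fractional order in (0, 1).  v=1 is rejected: its truncated weights
        sum to zero, which destroys the texture-retaining property the
        nonzero mask sum provides.
    support:
        Odd mask side length (>= 3).
    variant:
        ``"gl"`` (default) places the Grünwald-Letnikov weights
        symmetrically along x, y and both diagonals.  ``"table1"`` is a
        compact 3x3 operator with center 8 and a ring of ``-v`` (sum
        ``8 - 8v``), replicated for all four directions.
    """
    if support < 3 or support % 2 == 0:
        raise ValueError("support must be odd and >= 3")
    if not (0.0 < v <= 1.0):
        raise ValueError("order v must lie in (0, 1]")
    if variant == "gl":
        coeffs = gl_coefficients(v, (support + 1) // 2)
        if abs(2.0 * coeffs.sum()) < 1e-12:
            raise ValueError(
                f"mask coefficient sum is zero at v={v}; fractional masks "
                "require a nonzero sum (0 < v < 1)"
            )
        masks = tuple(
            _line_mask(coeffs, support, d)
            for d in ("x", "y", "diag_right", "diag_left")
        )
    elif variant == "table1":
        m = np.full((3, 3), -v)
        m[1, 1] = 8.0
        masks = (m, m.T, m[::-1].T, m[::-1])
    else:
        raise ValueError(f"unknown mask variant {variant!r}")
    return FractionalMaskSet(order=v, support=masks[0].shape[0], masks=masks)


def fractional_response(img: np.ndarray, masks: FractionalMaskSet) -> np.ndarray:
    """Fractional-differential gray-value image of a gray image.

    Convolves with each directional mask (reflective boundaries), fuses by
    per-pixel maximum, and clips negative responses to 0.
    """
    img = np.asarray(img, dtype=np.float64)
    responses = [
        ndimage.correlate(img, m, mode="reflect") for m in masks.masks
    ]
    return np.clip(np.max(responses, axis=0), 0.0, None)


def enhance_with_gradient(
    img: np.ndarray, response: np.ndarray, masks: FractionalMaskSet, lam: float = 1.0
) -> np.ndarray:
    """Stack the fractional-differential response onto the source image.

    The response of any mask to a locally constant patch is
    ``mask_sum * value``; subtracting that baseline makes flat regions
    invariant, so only genuine gradient structure is added:

        out = clip(img + lam * (response - mask_sum * img), 0, 1)
    """
    img = as_gray(img)
    response = np.asarray(response, dtype=np.float64)
    if response.shape != img.shape:
        raise ValueError(
            f"response shape {response.shape} != image shape {img.shape}"
        )
    baseline = masks.mask_sum * img
    return np.clip(img + lam * (response - baseline), 0.0, 1.0)
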