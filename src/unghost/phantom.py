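"""Analytic 2-D phantoms standing in for the imaged object m(x, y).

Every model is a sum of rotated ellipses whose geometry is known in closed
form, so the exact object support is available as an oracle for the
support-constrained correction.  All models keep a background margin of at
least 10% of the grid size on every edge — a support constraint on an object
that fills the frame would be uninformative.

Geometry is specified in fractional field-of-view units (center (0, 0), edges
at +/-0.5) and rasterized onto the centered pixel grid used by the k-space
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import disk as _disk_footprint
from scipy.ndimage import binary_dilation

from .errors import ValidationError
from .kspace import Image
from .roi import ROIMask

__all__ = ["PhantomSpec", "generate_phantom", "true_support", "PHANTOM_MODELS"]

# Each ellipse: (additive value, cx, cy, semi_x, semi_y, rotation degrees),
# positions/axes as fractions of the grid size.  Composed values stay in (0, 1].
_DISK = [(1.0, 0.0, 0.0, 0.3, 0.3, 0.0)]

_ELLIPSES = [
    (0.75, -0.08, -0.04, 0.26, 0.19, 20.0),
    (0.50, 0.10, 0.08, 0.14, 0.22, -35.0),
    (0.55, -0.12, 0.14, 0.10, 0.08, 0.0),
]

# Classic head phantom proportions scaled by 0.43 so the outer skull ellipse
# (semi-axis 0.92 of the half-FOV in the usual normalization) respects the
# 10% background margin.
_SL_SCALE = 0.43
_SHEPP_LOGAN_LIKE = [
    (1.00, 0.0, 0.0, 0.69, 0.92, 0.0),
    (-0.80, 0.0, -0.0184, 0.6624, 0.874, 0.0),
    (-0.20, 0.22, 0.0, 0.11, 0.31, -18.0),
    (-0.20, -0.22, 0.0, 0.16, 0.41, 18.0),
    (0.10, 0.0, 0.35, 0.21, 0.25, 0.0),
    (0.10, 0.0, 0.10, 0.046, 0.046, 0.0),
    (0.10, 0.0, -0.10, 0.046, 0.046, 0.0),
    (0.10, -0.08, -0.605, 0.046, 0.023, 0.0),
    (0.10, 0.0, -0.605, 0.023, 0.023, 0.0),
    (0.10, 0.06, -0.605, 0.023, 0.046, 0.0),
]
_SHEPP_LOGAN_LIKE = [
    (v, _SL_SCALE * cx, _SL_SCALE * cy, _SL_SCALE * a, _SL_SCALE * b, th)
    for (v, cx, cy, a, b, th) in _SHEPP_LOGAN_LIKE
]

# Pelvis-like: broad oval cavity, two lateral organ-like ellipses, a uterus-like
# midline body and a low-intensity fluid collection ("abscess") inclusion.
_PELVIS_LIKE = [
    (0.55, 0.0, 0.0, 0.38, 0.27, 0.0),
    (0.25, -0.18, 0.02, 0.10, 0.14, 25.0),
    (0.25, 0.18, 0.02, 0.10, 0.14, -25.0),
    (0.20, 0.0, -0.06, 0.12, 0.10, 0.0),
    (-0.45, 0.06, 0.07, 0.07, 0.05, -10.0),
]

PHANTOM_MODELS = {
    "disk": _DISK,
    "ellipses": _ELLIPSES,
    "shepp_logan_like": _SHEPP_LOGAN_LIKE,
    "pelvis_like": _PELVIS_LIKE,
}

SUPPORT_MARGIN_PX = 2  # default dilation of the oracle support mask


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``intensity_range`` maps the composed shape values (in (0, 1]) linearly
    onto ``[low, high]``; the background stays exactly 0.  ``noise_sigma`` is
    the s.d. of additive image-domain Gaussian noise, applied after
    rasterization and clipped so magnitudes stay non-negative.
    """

    size: int = 256
    model: str = "disk"
    intensity_range: tuple[float, float] = (0.0, 1.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.size, (int, np.integer)) or self.size < 8:
            raise ValidationError(f"size: must be an integer >= 8, got {self.size!r}")
        if self.size % 2:
            raise ValidationError(
                f"size: must be even for an unambiguous DC index, got {self.size}"
            )
        if self.model not in PHANTOM_MODELS:
            raise ValidationError(
                f"model: unknown phantom model {self.model!r}; "
                f"choose from {sorted(PHANTOM_MODELS)}"
            )
        low, high = self.intensity_range
        if not (np.isfinite(low) and np.isfinite(high)):
            raise ValidationError("intensity_range: values must be finite")
        if not (0.0 <= low < high <= 1.0):
            raise ValidationError(
                f"intensity_range: need 0 <= low < high <= 1, got ({low}, {high})"
            )
        if not np.isfinite(self.noise_sigma) or self.noise_sigma < 0:
            raise ValidationError(
                f"noise_sigma: must be >= 0, got {self.noise_sigma!r}"
            )


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta_deg: float) -> np.ndarray:
    """Boolean raster of one rotated ellipse on the centered pixel grid."""
    coords = np.arange(size) - size // 2
    x = coords[np.newaxis, :].astype(np.float64)
    y = coords[:, np.newaxis].astype(np.float64)
    dx = x - cx * size
    dy = y - cy * size
    th = np.deg2rad(theta_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / (a * size)) ** 2 + (v / (b * size)) ** 2 <= 1.0


def _compose(spec: PhantomSpec) -> np.ndarray:
    """Noiseless additive composition of the model's ellipses, in (0, 1]."""
    shape = np.zeros((spec.size, spec.size))
    for value, cx, cy, a, b, th in PHANTOM_MODELS[spec.model]:
        shape[_ellipse_mask(spec.size, cx, cy, a, b, th)] += value
    return np.clip(shape, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec) -> Image:
    """Rasterize the phantom described by ``spec`` into a real-valued Image.

    Deterministic: equal specs (including seed) give bit-identical arrays.
    """
    shape = _compose(spec)
    low, high = spec.intensity_range
    pixels = np.where(shape > 0.0, low + (high - low) * shape, 0.0)
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, pixels.shape)
        pixels = np.clip(pixels, 0.0, None)  # magnitude images are non-negative
    return Image(pixels)


def true_support(spec: PhantomSpec, margin_px: int = SUPPORT_MARGIN_PX) -> ROIMask:
    """Oracle support mask: union of the model's ellipses, dilated by ``margin_px``.

    By construction it covers every nonzero pixel of the noiseless phantom,
    which makes it the ground-truth region R for the support constraint.
    """
    union = np.zeros((spec.size, spec.size), dtype=bool)
    for _value, cx, cy, a, b, th in PHANTOM_MODELS[spec.model]:
        union |= _ellipse_mask(spec.size, cx, cy, a, b, th)
    if margin_px > 0:
        union = binary_dilation(union, structure=_disk_footprint(margin_px))
    return ROIMask(union, method_tag="oracle")
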