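"""Discrete k-space model: centered unitary 2-D DFT and per-line translational motion.

MRI acquires raw data in the spatial-frequency domain (k-space), one
phase-encode line ``ky`` at a time.  If the object translates between line
acquisitions by ``(p(ky), q(ky))`` pixels, the shift theorem turns the
translation into a line-dependent linear phase ramp,

    S'(kx, ky) = exp(-i 2 pi (kx p(ky) + ky q(ky)) / N) * S(kx, ky),

which leaves the k-space magnitude untouched but scrambles the phase and
produces ghosting along the phase-encode direction after reconstruction.

Conventions (documented, since continuous formulas fix neither):

* arrays are square ``N x N`` with ``N`` even; rows are ``ky`` (phase encode),
  columns ``kx`` (frequency encode);
* both domains are *centered*: spatial coordinates and integer frequencies run
  over ``[-N/2, N/2)`` with DC at index ``N/2``;
* the DFT is unitary (``norm="ortho"``), so Parseval holds exactly and image
  and k-space energies are directly comparable;
* shifts are in pixel units, i.e. the phase is in cycles per field of view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ShapeMismatchError, ValidationError

__all__ = [
    "Image",
    "KSpaceData",
    "MotionTrajectory",
    "PhaseMap",
    "forward_kspace",
    "inverse_kspace",
    "make_trajectory",
    "apply_motion",
    "phase_map_from_trajectory",
]

TRAJECTORY_MODELS = ("none", "step", "sinusoid", "random_walk", "custom")


def _validate_square_even(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ShapeMismatchError(
            f"{name}: expected a square 2-D array, got shape {arr.shape}"
        )
    if arr.shape[0] % 2 != 0:
        raise ValidationError(
            f"{name}: side length must be even (got {arr.shape[0]}); an odd grid "
            "has no unambiguous DC index under the centered convention"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: contains non-finite values")


@dataclass(frozen=True)
class Image:
    """Square 2-D image-domain array, real or complex.

    Holds the imaged object m(x, y) as well as intermediate reconstructions of
    the correction loop; callers take ``magnitude`` when a display image is
    needed.
    """

    pixels: np.ndarray
    domain_tag: str = "image"

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if not np.iscomplexobj(pix):
            pix = pix.astype(np.float64, copy=True)
        else:
            pix = pix.astype(np.complex128, copy=True)
        _validate_square_even(pix, "Image.pixels")
        pix.setflags(write=False)
        object.__setattr__(self, "pixels", pix)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.pixels)


@dataclass(frozen=True)
class KSpaceData:
    """Square complex k-space array, DC at index ``size // 2`` (centered)."""

    samples: np.ndarray
    centered: bool = True
    domain_tag: str = "kspace"

    def __post_init__(self) -> None:
        if not self.centered:
            raise ValidationError(
                "KSpaceData.centered: public interfaces carry centered k-space only"
            )
        smp = np.asarray(self.samples, dtype=np.complex128).copy()
        _validate_square_even(smp, "KSpaceData.samples")
        smp.setflags(write=False)
        object.__setattr__(self, "samples", smp)

    @property
    def size(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class MotionTrajectory:
    """Per-phase-encode-line translation (p, q) in pixels.

    ``p[i]`` / ``q[i]`` are the x- and y-shifts of the object while k-space
    row ``i`` (0-based, so ``ky = i - size/2``) was acquired.  Shifts beyond a
    quarter field of view wrap around and make correction ill-posed, so they
    are rejected rather than clipped.
    """

    p: np.ndarray
    q: np.ndarray
    model: str = "custom"
    params: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64).copy()
        q = np.asarray(self.q, dtype=np.float64).copy()
        if p.ndim != 1 or q.ndim != 1 or p.shape != q.shape:
            raise ValidationError(
                f"MotionTrajectory.p/q: expected equal-length 1-D arrays, got "
                f"{p.shape} and {q.shape}"
            )
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise ValidationError("MotionTrajectory.p/q: contains non-finite shifts")
        bound = p.shape[0] / 4.0
        worst = max(np.max(np.abs(p), initial=0.0), np.max(np.abs(q), initial=0.0))
        if worst >= bound:
            raise ValidationError(
                f"MotionTrajectory.p/q: |shift| must stay below size/4 = {bound} px "
                f"(got {worst}); larger shifts alias"
            )
        if self.model not in TRAJECTORY_MODELS:
            raise ValidationError(
                f"MotionTrajectory.model: unknown model {self.model!r}"
            )
        p.setflags(write=False)
        q.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)

    @property
    def size(self) -> int:
        return self.p.shape[0]

    def __add__(self, other: "MotionTrajectory") -> "MotionTrajectory":
        if self.size != other.size:
            raise ShapeMismatchError("cannot add trajectories of different lengths")
        return MotionTrajectory(self.p + other.p, self.q + other.q, model="custom")


@dataclass(frozen=True)
class PhaseMap:
    """Real phase array (radians) on the centered k-space grid."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=np.float64).copy()
        _validate_square_even(phi, "PhaseMap.phi")
        phi.setflags(write=False)
        object.__setattr__(self, "phi", phi)

    @property
    def size(self) -> int:
        return self.phi.shape[0]


def forward_kspace(img: Image) -> KSpaceData:
    """Centered unitary 2-D DFT of an image: m(x, y) -> S(kx, ky).

    Spatial coordinates are taken as centered integers in [-N/2, N/2), so a
    unit impulse at the center pixel transforms to a flat spectrum.
    """
    arr = np.asarray(img.pixels, dtype=np.complex128)
    ks = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(arr), norm="ortho"))
    return KSpaceData(ks)


def inverse_kspace(ks: KSpaceData) -> Image:
    """Exact inverse of :func:`forward_kspace`; returns a complex-valued Image."""
    arr = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ks.samples), norm="ortho"))
    return Image(arr)


def make_trajectory(model: str, params: Mapping | None, size: int, seed: int = 0
                    ) -> MotionTrajectory:
    """Build one of the parametric per-line motion models.

    Models and their parameters:

    ``none``
        No motion; p = q = 0.
    ``step``
        A single abrupt displacement: 0 before line
        ``floor(onset_fraction * size)``, ``amplitude_px`` after.
        Params: ``amplitude_px``, ``onset_fraction`` in (0, 1), ``axis``.
    ``sinusoid``
        Periodic (respiration-like) motion
        ``amplitude_px * sin(2 pi ky / period_lines)``.
        Params: ``amplitude_px``, ``period_lines``, ``axis``.
    ``random_walk``
        Cumulative sum of seeded Gaussian increments of s.d. ``sigma_px``.
        Params: ``sigma_px``, ``axis``.

    ``axis`` is ``"x"`` (shift goes into p), ``"y"`` (into q) or ``"both"``.
    """
    params = dict(params or {})
    if size < 2 or size % 2:
        raise ValidationError(f"size: must be even and >= 2, got {size}")
    zeros = np.zeros(size)

    def _finite(name: str) -> float:
        try:
            v = float(params[name])
        except KeyError:
            raise ValidationError(f"params.{name}: required for model {model!r}")
        if not np.isfinite(v):
            raise ValidationError(f"params.{name}: must be finite, got {v}")
        return v

    def _on_axis(shift: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        axis = params.get("axis", "x")
        if axis == "x":
            return shift, zeros
        if axis == "y":
            return zeros, shift
        if axis == "both":
            return shift, shift.copy()
        raise ValidationError(f"params.axis: expected 'x', 'y' or 'both', got {axis!r}")

    if model == "none":
        p, q = zeros, zeros.copy()
    elif model == "step":
        amplitude = _finite("amplitude_px")
        onset = _finite("onset_fraction")
        if not 0.0 < onset < 1.0:
            raise ValidationError(
                f"params.onset_fraction: must lie in (0, 1), got {onset}"
            )
        shift = np.zeros(size)
        shift[int(np.floor(onset * size)):] = amplitude
        p, q = _on_axis(shift)
    elif model == "sinusoid":
        amplitude = _finite("amplitude_px")
        period = _finite("period_lines")
        if period <= 0:
            raise ValidationError(f"params.period_lines: must be > 0, got {period}")
        ky = np.arange(size, dtype=np.float64)
        p, q = _on_axis(amplitude * np.sin(2.0 * np.pi * ky / period))
    elif model == "random_walk":
        sigma = _finite("sigma_px")
        if sigma < 0:
            raise ValidationError(f"params.sigma_px: must be >= 0, got {sigma}")
        rng = np.random.default_rng(seed)
        p, q = _on_axis(np.cumsum(rng.normal(0.0, sigma, size)))
    else:
        raise ValidationError(f"model: unknown trajectory model {model!r}")

    return MotionTrajectory(p, q, model=model, params=params, seed=seed)


def phase_map_from_trajectory(traj: MotionTrajectory, size: int) -> PhaseMap:
    """Phase error phi(kx, ky) = 2 pi (kx p(ky) + ky q(ky)) / N on the centered grid."""
    if traj.size != size:
        raise ShapeMismatchError(
            f"trajectory length {traj.size} does not match size {size}"
        )
    k = np.arange(size) - size // 2  # centered integer frequencies
    kx = k[np.newaxis, :]
    ky = k[:, np.newaxis]
    phi = 2.0 * np.pi * (kx * traj.p[:, np.newaxis] + ky * traj.q[:, np.newaxis]) / size
    return PhaseMap(phi)


def apply_motion(ks: KSpaceData, traj: MotionTrajectory) -> KSpaceData:
    """Corrupt k-space with per-line translational motion.

    Pure phase modulation: ``S' = exp(-i phi) S`` with phi from
    :func:`phase_map_from_trajectory`; ``|S'| == |S|`` exactly.
    """
    if traj.size != ks.size:
        raise ShapeMismatchError(
            f"trajectory length {traj.size} does not match k-space size {ks.size}"
        )
    phi = phase_map_from_trajectory(traj, ks.size).phi
    return KSpaceData(ks.samples * np.exp(-1j * phi))
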