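"""Support-constrained iterative phase correction of motion-corrupted k-space.

Per-line translational motion corrupts only the *phase* of k-space; the
magnitude |S'| is exactly that of the motion-free data.  The corrupted
magnitude is therefore kept as a hard constraint while the phase is recovered
by alternating two projections:

1. reconstruct the image from the current k-space iterate G_j;
2. zero every pixel outside the region of interest R (support projection),
   giving g'_j, and transform back to k-space: G'_j;
3. take the phase change phi' = arg G'_j - arg G_j introduced by the
   projection;
4. build the next iterate by re-imposing the measured magnitude.

Two variants of step 4 are provided.  The default ``cumulative`` rule,
``G_{j+1} = exp(i arg G'_j) |S'|``, is the classical error-reduction
(Gerchberg-Saxton/Fienup) scheme: it keeps the support-consistent phase and
guarantees that the fraction of image energy leaking outside R never
increases.  The ``literal`` rule, ``G_{j+1} = exp(i phi') |S'|``, uses only
the per-step phase *difference*; it is retained for fidelity experiments but
does not in general converge to a support-consistent image.

The loop stops when the relative change of the support-violation energy
between successive iterations falls below ``tol``, or after ``max_iter``
iterations — the underlying fixed-point iteration has no intrinsic stopping
rule, so this is an explicit design choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ShapeMismatchError, ValidationError
from .kspace import Image, KSpaceData, PhaseMap, forward_kspace, inverse_kspace
from .roi import ROIMask, extract_roi_levelset, extract_roi_snake, extract_roi_threshold

__all__ = [
    "CorrectionConfig",
    "CorrectionResult",
    "support_violation_energy",
    "apply_support",
    "phase_update",
    "correct",
]

logger = logging.getLogger(__name__)

_EPS_MAG = 1e-12  # below this, a complex sample's phase is treated as undefined


@dataclass(frozen=True)
class CorrectionConfig:
    """Knobs of the correction loop.

    ``roi_method`` selects how the support region is obtained from the first
    reconstruction; ``oracle`` means the caller supplies it.  With
    ``refine_roi_each_iter`` the region is re-extracted from every iterate
    instead of being held fixed.
    """

    max_iter: int = 50
    tol: float = 1e-4
    roi_method: str = "levelset"
    refine_roi_each_iter: bool = False
    update_rule: str = "cumulative"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError(f"max_iter: must be >= 1, got {self.max_iter}")
        if not (np.isfinite(self.tol) and self.tol > 0):
            raise ValidationError(f"tol: must be > 0, got {self.tol}")
        if self.roi_method not in ("threshold", "snake", "levelset", "oracle"):
            raise ValidationError(f"roi_method: unknown method {self.roi_method!r}")
        if self.update_rule not in ("cumulative", "literal"):
            raise ValidationError(f"update_rule: unknown rule {self.update_rule!r}")


@dataclass(frozen=True)
class CorrectionResult:
    corrected_image: Image
    corrected_kspace: KSpaceData
    phase_correction: PhaseMap
    roi: ROIMask
    iterations_run: int
    history: tuple[float, ...]
    converged: bool


def support_violation_energy(img: Image, roi: ROIMask) -> float:
    """Fraction of image energy outside the support region, in [0, 1].

    Measures how far the current iterate is from satisfying the support
    constraint; an all-zero image trivially satisfies it (returns 0).
    """
    if img.size != roi.size:
        raise ShapeMismatchError(
            f"image size {img.size} does not match ROI size {roi.size}"
        )
    energy = np.abs(img.pixels) ** 2
    total = float(energy.sum())
    if total == 0.0:
        logger.debug("support_violation_energy: all-zero image, defined as 0")
        return 0.0
    return float(energy[~roi.mask].sum()) / total


def apply_support(img: Image, roi: ROIMask) -> Image:
    """Support projection: keep pixels inside R, set the rest to exactly 0."""
    if img.size != roi.size:
        raise ShapeMismatchError(
            f"image size {img.size} does not match ROI size {roi.size}"
        )
    return Image(np.where(roi.mask, img.pixels, 0))


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def phase_update(Gj: KSpaceData, Gj_prime: KSpaceData) -> PhaseMap:
    """Per-sample phase change phi' = arg G'_j - arg G_j, wrapped to (-pi, pi].

    Where either magnitude is below 1e-12 the phase is undefined and phi' is
    set to 0 (no correction applied to samples carrying no signal).
    """
    if Gj.size != Gj_prime.size:
        raise ShapeMismatchError(
            f"k-space sizes differ: {Gj.size} vs {Gj_prime.size}"
        )
    phi = _wrap_phase(np.angle(Gj_prime.samples) - np.angle(Gj.samples))
    undefined = (np.abs(Gj.samples) < _EPS_MAG) | (np.abs(Gj_prime.samples) < _EPS_MAG)
    phi = np.where(undefined, 0.0, phi)
    return PhaseMap(phi)


def _extract_roi(img: Image, method: str) -> ROIMask:
    mag = Image(np.abs(img.pixels))
    if method == "threshold":
        return extract_roi_threshold(mag)
    if method == "snake":
        return extract_roi_snake(mag, extract_roi_threshold(mag))
    if method == "levelset":
        return extract_roi_levelset(mag)
    raise ValidationError(f"roi_method: cannot auto-extract with {method!r}")


def correct(corrupted: KSpaceData, config: CorrectionConfig | None = None,
            roi_override: ROIMask | None = None) -> CorrectionResult:
    """Run the support-constrained phase-correction loop on corrupted k-space.

    The region of interest is extracted once from the first (corrupted)
    reconstruction — or supplied via ``roi_override`` (required when
    ``roi_method="oracle"``) — and the loop alternates support projection and
    magnitude replacement until the support-violation energy stops changing.

    The measured-magnitude constraint ``|G_j| == |S'|`` holds at every iterate
    by construction.  Deterministic: no randomness anywhere in the loop.
    """
    config = config or CorrectionConfig()
    if config.roi_method == "oracle":
        if roi_override is None:
            raise ValidationError(
                "roi_override: required when roi_method='oracle'"
            )
    if roi_override is not None and roi_override.size != corrupted.size:
        raise ShapeMismatchError(
            f"roi_override size {roi_override.size} does not match "
            f"k-space size {corrupted.size}"
        )

    measured_mag = np.abs(corrupted.samples)
    G = corrupted.samples.copy()
    g = inverse_kspace(corrupted)
    roi = roi_override if roi_override is not None else _extract_roi(
        g, config.roi_method)

    history: list[float] = []
    phi_prime = np.zeros_like(measured_mag)
    converged = False
    iterations = 0
    for j in range(config.max_iter):
        iterations = j + 1
        if config.refine_roi_each_iter and j > 0 and roi_override is None:
            roi = _extract_roi(g, config.roi_method)
        history.append(support_violation_energy(g, roi))

        g_supported = apply_support(g, roi)
        Gp = forward_kspace(g_supported)
        phi_prime = phase_update(KSpaceData(G), Gp).phi

        if config.update_rule == "cumulative":
            G = np.exp(1j * np.angle(Gp.samples)) * measured_mag
        else:  # literal
            G = np.exp(1j * phi_prime) * measured_mag
        if not np.all(np.isfinite(G)):
            raise NumericalError(f"non-finite k-space iterate at iteration {j}")
        g = inverse_kspace(KSpaceData(G))

        if j >= 1:
            # energies below 1e-15 are numerically zero; flooring the
            # denominator lets an already-satisfied constraint converge
            prev = history[j - 1]
            rel = abs(history[j] - prev) / max(prev, 1e-15)
            if rel < config.tol:
                converged = True
                break

    return CorrectionResult(
        corrected_image=g,
        corrected_kspace=KSpaceData(G),
        phase_correction=PhaseMap(phi_prime),
        roi=roi,
        iterations_run=iterations,
        history=tuple(history),
        converged=converged,
    )
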