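"""The support-constrained phase-recovery loop and its building blocks."""

import numpy as np
import pytest

from unghost import (
    CorrectionConfig,
    Image,
    KSpaceData,
    ROIMask,
    apply_support,
    correct,
    forward_kspace,
    inverse_kspace,
    nrmse,
    phase_update,
    support_violation_energy,
)
from unghost.errors import ShapeMismatchError, ValidationError


def near_full_roi(size):
    """Vacuous support: everything except one background corner pixel."""
    mask = np.ones((size, size), dtype=bool)
    mask[0, 0] = False
    return ROIMask(mask)


class TestSupportViolationEnergy:
    def test_image_inside_roi_scores_zero(self, disk_phantom, disk_support):
        assert support_violation_energy(disk_phantom, disk_support) == 0.0

    def test_image_outside_roi_scores_one(self):
        img = np.zeros((8, 8))
        img[0, 0] = 2.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        assert support_violation_energy(Image(img), ROIMask(mask)) == 1.0

    def test_half_in_half_out(self):
        img = np.zeros((8, 8))
        img[0, 0] = img[4, 4] = 1.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        assert support_violation_energy(Image(img), ROIMask(mask)) == 0.5

    def test_all_zero_image_defined_as_zero(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        assert support_violation_energy(Image(np.zeros((8, 8))), ROIMask(mask)) == 0.0


class TestApplySupport:
    def test_idempotent(self, corrupted_recon, disk_support):
        once = apply_support(corrupted_recon, disk_support)
        twice = apply_support(once, disk_support)
        assert np.array_equal(once.pixels, twice.pixels)

    def test_vacuous_support_is_identity_on_background_corner(self, disk_phantom):
        out = apply_support(disk_phantom, near_full_roi(disk_phantom.size))
        assert np.array_equal(out.pixels, disk_phantom.pixels)

    def test_energy_removed_equals_outside_energy(self, corrupted_recon,
                                                  disk_support):
        out = apply_support(corrupted_recon, disk_support)
        removed = np.sum(np.abs(corrupted_recon.pixels) ** 2) - \
            np.sum(np.abs(out.pixels) ** 2)
        outside = np.sum(np.abs(corrupted_recon.pixels[~disk_support.mask]) ** 2)
        assert removed == pytest.approx(outside, rel=1e-12)
        assert np.all(out.pixels[~disk_support.mask] == 0)

    def test_shape_mismatch_rejected(self, disk_phantom):
        with pytest.raises(ShapeMismatchError):
            apply_support(disk_phantom, near_full_roi(64))


class TestPhaseUpdate:
    def test_identical_kspace_gives_zero_phase(self, corrupted_kspace):
        phi = phase_update(corrupted_kspace, corrupted_kspace).phi
        assert np.all(phi == 0)

    def test_global_phase_factor_recovered(self, corrupted_kspace):
        rotated = KSpaceData(corrupted_kspace.samples * np.exp(1j * np.pi / 3))
        phi = phase_update(corrupted_kspace, rotated).phi
        significant = np.abs(corrupted_kspace.samples) > 1e-9
        assert np.allclose(phi[significant], np.pi / 3, atol=1e-9)

    def test_wrapping_into_half_open_interval(self):
        base = np.full((8, 8), 1.0 + 0j)
        shifted = base * np.exp(1j * 3 * np.pi / 2)
        phi = phase_update(KSpaceData(base), KSpaceData(shifted)).phi
        assert np.allclose(phi, -np.pi / 2)
        # boundary: a difference of exactly pi stays at +pi, not -pi
        opposite = phase_update(KSpaceData(base),
                                KSpaceData(base * np.exp(1j * np.pi))).phi
        assert np.allclose(opposite, np.pi)

    def test_zero_magnitude_phase_defined_as_zero(self):
        a = np.zeros((8, 8), dtype=complex)
        b = np.full((8, 8), 1j)
        assert np.all(phase_update(KSpaceData(a), KSpaceData(b)).phi == 0)


class TestCorrectLoop:
    def test_zero_motion_is_a_fixed_point(self, disk_phantom, disk_support):
        clean = forward_kspace(disk_phantom)
        result = correct(clean, CorrectionConfig(roi_method="oracle"),
                         roi_override=disk_support)
        assert result.iterations_run <= 2
        assert result.converged
        assert result.history[0] == pytest.approx(0.0, abs=1e-12)
        err = np.max(np.abs(np.abs(result.corrected_image.pixels)
                            - disk_phantom.pixels))
        assert err <= 1e-6

    @pytest.mark.parametrize("max_iter", [1, 2, 5, 20, 50])
    def test_magnitude_constraint_at_every_iterate(self, corrupted_kspace,
                                                   disk_support, max_iter):
        """|G_j| must equal |S'| after any number of iterations."""
        result = correct(corrupted_kspace,
                         CorrectionConfig(max_iter=max_iter, roi_method="oracle"),
                         roi_override=disk_support)
        dev = np.max(np.abs(np.abs(result.corrected_kspace.samples)
                            - np.abs(corrupted_kspace.samples)))
        assert dev <= 1e-10

    def test_violation_history_non_increasing(self, standard_result):
        diffs = np.diff(standard_result.history)
        assert np.all(diffs <= 1e-9)

    def test_error_reduction_on_standard_scenario(self, disk_phantom,
                                                  corrupted_recon,
                                                  standard_result):
        n_before = nrmse(corrupted_recon, disk_phantom)
        n_after = nrmse(standard_result.corrected_image, disk_phantom)
        assert n_after < n_before
        assert 1.0 - n_after / n_before >= 0.30

    def test_vacuous_roi_leaves_reconstruction_unchanged(self, corrupted_kspace):
        """With (nearly) full-frame support the constraint does nothing."""
        roi = near_full_roi(corrupted_kspace.size)
        result = correct(corrupted_kspace,
                         CorrectionConfig(max_iter=5, roi_method="oracle"),
                         roi_override=roi)
        baseline = inverse_kspace(corrupted_kspace)
        assert np.max(np.abs(result.corrected_image.pixels
                             - baseline.pixels)) <= 1e-10

    def test_deterministic(self, corrupted_kspace, disk_support):
        cfg = CorrectionConfig(roi_method="oracle")
        a = correct(corrupted_kspace, cfg, roi_override=disk_support)
        b = correct(corrupted_kspace, cfg, roi_override=disk_support)
        assert np.array_equal(a.corrected_image.pixels, b.corrected_image.pixels)
        assert a.history == b.history
        assert a.iterations_run == b.iterations_run

    def test_literal_update_rule_also_preserves_magnitude(self, corrupted_kspace,
                                                          disk_support):
        result = correct(corrupted_kspace,
                         CorrectionConfig(max_iter=10, roi_method="oracle",
                                          update_rule="literal"),
                         roi_override=disk_support)
        dev = np.max(np.abs(np.abs(result.corrected_kspace.samples)
                            - np.abs(corrupted_kspace.samples)))
        assert dev <= 1e-10

    def test_extracted_roi_methods_run_end_to_end(self, corrupted_kspace):
        for method in ("threshold", "levelset"):
            result = correct(corrupted_kspace,
                             CorrectionConfig(max_iter=5, roi_method=method))
            assert result.roi.method_tag == method
            assert len(result.history) == result.iterations_run

    def test_per_iteration_roi_refinement_runs(self, corrupted_kspace):
        result = correct(corrupted_kspace,
                         CorrectionConfig(max_iter=4, roi_method="threshold",
                                          refine_roi_each_iter=True))
        assert result.iterations_run >= 1
        assert result.roi.method_tag == "threshold"

    def test_oracle_method_requires_override(self, corrupted_kspace):
        with pytest.raises(ValidationError, match="roi_override"):
            correct(corrupted_kspace, CorrectionConfig(roi_method="oracle"))

    @pytest.mark.parametrize("kwargs", [
        dict(max_iter=0), dict(tol=0.0), dict(roi_method="manual"),
        dict(update_rule="midpoint"),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CorrectionConfig(**kwargs)
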