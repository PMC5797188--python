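import numpy as np
import pytest

from larvreg.global_registration import (
    GlobalRegistrationResult,
    compose_linear,
    flatten_linear,
    register_linear,
    register_sdt,
    run_global_pipeline,
    select_global_path,
)
from larvreg.metrics import ncc
from larvreg.preprocess import coarse_brain_mask, robust_rescale, signed_distance_transform
from larvreg.transforms import CompositeTransform, LinearTransform, resample
from larvreg.evaluation import landmark_registration_error
from larvreg.phantom import canonical_landmarks


def _rot_deg(t):
    s = np.linalg.det(t.matrix) ** (1 / 3)
    return np.rad2deg(np.arctan2(t.matrix[1, 0] / s, t.matrix[0, 0] / s))


def _scale(t):
    return np.linalg.det(t.matrix) ** (1 / 3)


def _polar_shear(matrix):
    s = np.linalg.det(matrix) ** (1 / 3)
    R = matrix / s
    return np.linalg.norm(R @ R.T - np.eye(3))


@pytest.fixture(scope="module")
def fixed_image(rigid_phantom_module):
    return robust_rescale(rigid_phantom_module.scan.np)


@pytest.fixture(scope="module")
def rigid_phantom_module():
    from larvreg.phantom import generate_phantom

    return generate_phantom(seed=42, deform_amplitude=0.0)


class TestComposeLinear:
    def test_matches_sequential_application(self, rng):
        a = LinearTransform.similarity(scale=1.3, angles=(0, 0, 0.4),
                                       translation=(1, -2, 3), center=(5, 5, 5))
        b = LinearTransform.similarity(scale=0.8, angles=(0, 0, -0.2),
                                       translation=(-1, 0, 2), center=(2, 0, 1))
        composed = compose_linear(a, b)
        pts = rng.uniform(-10, 30, size=(50, 3))
        assert np.allclose(composed.apply(pts), a.apply(b.apply(pts)))
        assert composed.kind == "similarity"

    def test_flatten_composite(self, rng):
        a = LinearTransform.from_translation((1, 2, 3))
        b = LinearTransform.similarity(scale=2.0, center=(1, 1, 1))
        comp = CompositeTransform([a, b])
        flat = flatten_linear(comp)
        pts = rng.uniform(-5, 5, size=(20, 3))
        assert np.allclose(flat.apply(pts), comp.apply(pts))


class TestRegisterLinear:
    def test_identical_images_near_identity(self, fixed_image):
        t, mv = register_linear(fixed_image, fixed_image, kind="similarity",
                                levels=3)
        assert np.linalg.norm(t.matrix - np.eye(3)) < 1e-2
        offset = t.apply(fixed_image.grid.center) - fixed_image.grid.center
        assert np.linalg.norm(offset) < 0.5
        assert mv.value > 0.99

    def test_similarity_recovery_10deg_scale(self, fixed_image, rigid_phantom_module):
        t_true = LinearTransform.similarity(
            scale=1.1, angles=(0, 0, np.deg2rad(10)), translation=(3, -2, 1),
            center=fixed_image.grid.center,
        )
        moving = resample(fixed_image, t_true.inverse(), fixed_image.grid)
        t_est, _ = register_linear(fixed_image, moving, kind="similarity", levels=4)
        assert abs(_scale(t_est) - 1.1) / 1.1 < 0.02
        assert abs(_rot_deg(t_est) - 10.0) < 1.0

    def test_similarity_never_shears(self, fixed_image):
        moving = resample(
            fixed_image,
            LinearTransform.similarity(scale=1.05, angles=(0, 0, 0.1),
                                       center=fixed_image.grid.center),
            fixed_image.grid,
        )
        t, _ = register_linear(fixed_image, moving, kind="similarity", levels=3)
        assert _polar_shear(t.matrix) < 1e-9  # polar decomposition check

    def test_final_metric_not_below_initialization(self, fixed_image):
        from larvreg.global_registration import _evaluate, _metric_fn, _sample_points

        t0 = LinearTransform.from_translation((2.0, -1.0, 0.0))
        t, mv = register_linear(fixed_image, fixed_image, kind="similarity",
                                init=t0, levels=3)
        pts, fvals = _sample_points(fixed_image, None, 8000)
        init_score = _evaluate(_metric_fn("NCC"), fvals, fixed_image, pts, t0)
        assert mv.value >= init_score - 1e-6


class TestRegisterSDT:
    @pytest.fixture(scope="class")
    def sdt_pair_60deg(self, rigid_phantom_module):
        fixed = robust_rescale(rigid_phantom_module.scan.np)
        t_true = LinearTransform.similarity(
            angles=(0, 0, np.deg2rad(60)), center=fixed.grid.center
        )
        moving = resample(fixed, t_true.inverse(), fixed.grid)
        sdt_f = signed_distance_transform(coarse_brain_mask(fixed))
        sdt_m = signed_distance_transform(coarse_brain_mask(moving))
        return fixed, moving, sdt_f, sdt_m

    def test_recovers_60deg_where_intensity_fails(self, sdt_pair_60deg):
        fixed, moving, sdt_f, sdt_m = sdt_pair_60deg
        t_sdt, _ = register_sdt(sdt_f, sdt_m)
        assert abs(_rot_deg(t_sdt) - 60.0) < 2.0
        t_int, _ = register_linear(fixed, moving, kind="similarity",
                                   metric="NCC", levels=4)
        assert abs(_rot_deg(t_int) - 60.0) > 10.0  # local optimizer stays stuck

    def test_identical_masks_near_identity(self, rigid_phantom_module):
        sdt = signed_distance_transform(coarse_brain_mask(rigid_phantom_module.scan.np))
        t, _ = register_sdt(sdt, sdt)
        assert np.linalg.norm(t.matrix - np.eye(3)) < 2e-2

    def test_invariant_to_intensity_scale(self, rigid_phantom_module):
        # SDT depends only on the mask, so a global NP intensity scale is moot
        img = rigid_phantom_module.scan.np
        bright = img.copy(data=np.clip(img.data.astype(np.float32) * 1.7, 0, 255))
        a = signed_distance_transform(coarse_brain_mask(img))
        b = signed_distance_transform(coarse_brain_mask(bright))
        assert np.mean(np.abs(a.data - b.data)) < 0.5


class TestSelectGlobalPath:
    def _t(self):
        return LinearTransform.identity()

    def test_good_sdt_skips_intensity(self):
        calls = []

        def run_intensity():
            calls.append(1)
            return self._t(), 0.9

        res = select_global_path((self._t(), 0.6), run_intensity)
        assert res.selected_path == "sdt"
        assert res.warning is None
        assert calls == []  # intensity never run

    def test_fallback_to_intensity(self):
        res = select_global_path((self._t(), 0.3), lambda: (self._t(), 0.5))
        assert res.selected_path == "intensity"
        assert res.warning is None

    def test_both_fail_picks_higher_and_warns(self):
        res = select_global_path((self._t(), 0.3), lambda: (self._t(), 0.2))
        assert res.selected_path == "sdt"
        assert res.warning is not None and "registration failure" in res.warning

    def test_both_fail_intensity_higher(self):
        res = select_global_path((self._t(), 0.1), lambda: (self._t(), 0.35))
        assert res.selected_path == "intensity"
        assert res.warning is not None

    def test_boundary_exactly_at_threshold_accepts(self):
        calls = []
        res = select_global_path((self._t(), 0.4), lambda: calls.append(1))
        assert res.selected_path == "sdt" and res.warning is None and not calls

    def test_result_invariant_warning_form(self):
        with pytest.raises(ValueError, match="registration failure"):
            GlobalRegistrationResult(
                transform=CompositeTransform([self._t()]), warning="something else"
            )


class TestGlobalPipeline:
    def test_aligned_phantom_near_identity(self, template_package, template_cohort):
        # a scan already expressed in template space: composite stays small
        scan = template_cohort[0].scan
        res = run_global_pipeline(template_package, scan, levels=3)
        center = template_package.np_template.grid.center
        probes = center + np.array(
            [[0, 0, 0], [10, 0, 0], [0, 15, 0], [0, 0, 8.0], [-8, -10, 4]]
        )
        moved = res.transform.apply(probes)
        assert np.mean(np.linalg.norm(moved - probes, axis=1)) < 6.0

    def test_both_zflip_branches_evaluated(self, template_package, template_cohort):
        res = run_global_pipeline(template_package, template_cohort[0].scan, levels=3)
        assert "zflip:unflipped" in res.stage_scores
        assert "zflip:zflipped" in res.stage_scores

    def test_zflipped_subject_selects_flip_branch(self, template_package):
        from larvreg.model import BrainScan
        from larvreg.phantom import generate_phantom

        ph = generate_phantom(seed=55, deform_amplitude=4.0)
        np_img = ph.scan.np
        flipped = BrainScan(
            "flipped", {"NP": np_img.copy(data=np_img.data[:, :, ::-1].copy())}
        )
        res = run_global_pipeline(template_package, flipped, levels=3)
        scores = res.stage_scores
        assert (
            scores["zflip:zflipped"].value > scores["zflip:unflipped"].value
        )

    def test_known_similarity_misalignment_recovered(self, template_package):
        from larvreg.model import BrainScan
        from larvreg.phantom import generate_phantom

        ph = generate_phantom(seed=66, deform_amplitude=0.0)
        img = robust_rescale(ph.scan.np)
        t_true = LinearTransform.similarity(
            scale=1.06, angles=(0, 0, np.deg2rad(8)), translation=(2.0, -3.0, 1.0),
            center=img.grid.center,
        )
        moving = resample(ph.scan.np, t_true.inverse(), img.grid)
        res = run_global_pipeline(
            template_package, BrainScan("mis", {"NP": moving}), levels=3
        )
        # composed transform must land the 30 landmarks within 4 μm of their
        # true positions: a feature at scan point p sits at t_true(p) in the
        # resampled (misaligned) image
        res_clean = run_global_pipeline(template_package, ph.scan, levels=3)
        lms = canonical_landmarks().coords
        a = res.transform.apply(lms)
        b = t_true.apply(res_clean.transform.apply(lms))
        assert np.mean(np.linalg.norm(a - b, axis=1)) < 4.0

    def test_no_neuropil_propagates(self, template_package):
        from larvreg.model import BrainScan
        from larvreg.phantom import generate_phantom
        from larvreg.preprocess import NoNeuropilSignalError

        ph = generate_phantom(seed=9, deform_amplitude=3.0, corruption="no_np")
        with pytest.raises(NoNeuropilSignalError):
            run_global_pipeline(template_package, ph.scan, levels=3)
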