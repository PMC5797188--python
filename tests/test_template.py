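import numpy as np
import pytest

from larvreg.model import BrainScan, Grid, LandmarkSet, VolumetricImage
from larvreg.phantom import (
    QA_ANCHOR_LABELS,
    canonical_anatomy,
    canonical_landmarks,
    generate_phantom,
)
from larvreg.template import (
    PairwiseRegistrationError,
    TemplatePackage,
    build_average_space,
    fuse,
    pairwise_register_all,
    propagate_channel,
    register_template_pair,
)
from larvreg.transforms import (
    CompositeTransform,
    DisplacementField,
    LinearTransform,
    to_displacement_field,
)

from conftest import fast_deformable_config

GRID = Grid((16, 12, 8), (0.5, 0.5, 2.0))


def _img(data, label="NP"):
    return VolumetricImage(np.asarray(data, dtype=np.float32), (0.5, 0.5, 2.0),
                           channel_label=label)


class TestFuse:
    def test_identical_images_fixed_point(self, rng):
        img = _img(rng.integers(0, 255, size=(8, 8, 4)))
        for method in ("mean", "median"):
            out = fuse([img, img.copy(), img.copy()], method)
            assert np.array_equal(out.data, img.data)

    def test_median_vs_mean_arithmetic(self):
        imgs = [_img(np.full((4, 4, 2), v)) for v in (10.0, 12.0, 200.0)]
        assert np.all(fuse(imgs, "median").data == 12)
        assert np.allclose(fuse(imgs, "mean").data, 74.0)

    def test_even_count_median_is_lower_middle(self):
        imgs = [_img(np.full((2, 2, 2), v)) for v in (1.0, 2.0, 3.0, 4.0)]
        assert np.all(fuse(imgs, "median").data == 2)

    def test_median_breakdown_resistance(self, rng):
        base = rng.integers(50, 60, size=(6, 6, 4)).astype(np.float32)
        imgs = [_img(base + i) for i in range(5)]
        corrupted = imgs[2].copy()
        hit = rng.uniform(size=corrupted.data.shape) < 0.3
        corrupted.data[hit] = 255.0
        out_clean = fuse(imgs, "median")
        out_dirty = fuse(imgs[:2] + [corrupted] + imgs[3:], "median")
        assert np.abs(out_clean.data - out_dirty.data).max() <= 1.0

    def test_median_background_quieter_than_mean(self, rng):
        # per-scan background streaks: median fusion suppresses them
        scans = []
        for k in range(5):
            data = rng.normal(8.0, 2.0, size=(32, 32, 8)).astype(np.float32)
            row = rng.integers(0, 30)
            data[row : row + 2, :, :] += 120.0  # one bright streak per scan
            scans.append(_img(np.clip(data, 0, 255)))
        med = fuse(scans, "median")
        mean = fuse(scans, "mean")
        assert med.data.std() < mean.data.std()

    def test_common_grid_required(self, rng):
        a = _img(rng.uniform(size=(8, 8, 4)))
        b = VolumetricImage(rng.uniform(size=(8, 8, 4)), (1.0, 0.5, 2.0))
        with pytest.raises(ValueError, match="grid"):
            fuse([a, b], "median")

    def test_unknown_method_rejected(self, rng):
        a = _img(rng.uniform(size=(4, 4, 2)))
        with pytest.raises(ValueError, match="method"):
            fuse([a], "mode")


class TestBuildAverageSpace:
    def test_identical_scans_zero_mean_fields(self):
        zero = DisplacementField.zero(GRID)
        fields = {(i, j): zero for i in range(3) for j in range(3)}
        means = build_average_space(fields)
        assert all(np.allclose(m.vectors, 0) for m in means)

    def test_two_scan_halfway_space(self, rng):
        # scans related by field F and its inverse: T_1 = F/2 on grid nodes
        v = np.zeros((*GRID.shape, 3))
        v[..., 0] = 1.5
        F = DisplacementField(v, GRID)
        fields = {
            (0, 0): DisplacementField.zero(GRID),
            (1, 1): DisplacementField.zero(GRID),
            (0, 1): F,
            (1, 0): F.invert(),
        }
        means = build_average_space(fields, include_identity=True)
        assert np.max(np.abs(means[0].vectors - v / 2)) < 0.5

    def test_mean_of_means_shrinks(self, rng):
        # averaging property on an asymmetric 3-member set
        fields = {}
        vs = []
        for i in range(3):
            fields[(i, i)] = DisplacementField.zero(GRID)
        for i in range(3):
            for j in range(3):
                if i != j:
                    v = np.full((*GRID.shape, 3), 0.0)
                    v[..., 0] = (j - i) * 2.0 + 0.3 * (i + j)
                    fields[(i, j)] = DisplacementField(v, GRID)
                    vs.append(v)
        means = build_average_space(fields, include_identity=True)
        probe = GRID.center
        mean_disp = np.mean([m.displacement(probe) for m in means], axis=0)
        singles = [np.linalg.norm(m.displacement(probe)) for m in means]
        assert np.linalg.norm(mean_disp) < min(s for s in singles if s > 0) + 1e-9


class TestPairwise:
    def test_minimum_cohort_size(self):
        scan = BrainScan("a", {"NP": _img(np.zeros((8, 8, 4)))})
        with pytest.raises(ValueError, match="at least 3"):
            pairwise_register_all([scan, scan])

    def test_identical_phantoms_near_zero_fields(self, rigid_phantom):
        scans = [
            BrainScan(f"s{i}", dict(rigid_phantom.scan.channels)) for i in range(3)
        ]
        cfg = fast_deformable_config(levels=3, iterations_per_level=40)
        fields = pairwise_register_all(scans, cfg=cfg, linear_levels=2)
        assert len(fields) == 9
        for i in range(3):
            assert np.all(fields[(i, i)].vectors == 0)  # T_ii is zero
        off = np.max(np.abs(fields[(0, 1)].vectors))
        assert off < 1.0

    def test_known_field_recovered(self):
        # phantom B = canonical warped by a known field; T_AB recovers it
        a = generate_phantom(seed=21, deform_amplitude=0.0)
        b = generate_phantom(seed=22, deform_amplitude=7.0)
        t = register_template_pair(
            a.scan, b.scan, cfg=fast_deformable_config(), linear_levels=2
        )
        mapped = t.apply(a.landmarks.coords)
        err = np.linalg.norm(mapped - b.landmarks.coords, axis=1)
        assert err.mean() < 2.0

    def test_failure_names_the_pair(self, rigid_phantom, monkeypatch):
        import larvreg.template as template_mod

        def boom(*a, **k):
            raise RuntimeError("synthetic divergence")

        monkeypatch.setattr(template_mod, "register_bspline", boom)
        scans = [
            BrainScan(f"s{i}", dict(rigid_phantom.scan.channels)) for i in range(3)
        ]
        with pytest.raises(PairwiseRegistrationError, match="'s1' -> 's0'"):
            pairwise_register_all(scans, cfg=fast_deformable_config())


class TestPropagateChannel:
    def test_identity_chain_unchanged(self, rigid_phantom):
        scan = rigid_phantom.scan
        out = propagate_channel(scan, "NT", LinearTransform.identity(), scan.grid)
        assert np.allclose(out.data, scan.channels["NT"].data, atol=1e-4)

    def test_integer_translation_preserves_histogram(self, rigid_phantom):
        scan = rigid_phantom.scan
        t = LinearTransform.from_translation((1.0, 0.0, 0.0))  # 2 voxels in x
        out = propagate_channel(scan, "GE", t, scan.grid, interp="nearest")
        h0 = np.bincount(scan.channels["GE"].data[2:, :, :].ravel(), minlength=256)
        h1 = np.bincount(out.data[:-2, :, :].ravel(), minlength=256)
        assert np.array_equal(h0, h1)

    def test_nt_tract_follows_np_field(self):
        truth = generate_phantom(seed=23, deform_amplitude=6.0)
        canon = canonical_anatomy()
        # warping the scan's NT channel with the (NP-derived) ground-truth
        # canonical→scan map reproduces the canonical tract: centerline oracle
        canon_to_scan = to_displacement_field(
            truth.applied_transform, truth.scan.grid
        ).invert(tol=0.01)
        warped = propagate_channel(truth.scan, "NT", canon_to_scan, canon.grid)
        canon_nt = canon.channels["NT"].data
        thr = np.percentile(canon_nt, 99.0)
        pts_canon = np.argwhere(canon_nt > thr)
        pts_warp = np.argwhere(warped.data > np.percentile(warped.data, 99.0))
        spacing = np.asarray(canon.grid.spacing)
        # mean nearest-neighbour distance between the two bright skeletons
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts_canon * spacing).query(pts_warp * spacing)
        assert d.mean() < 2.0

    def test_missing_channel_rejected(self, rigid_phantom):
        with pytest.raises(KeyError):
            propagate_channel(rigid_phantom.scan, "DAPI",
                              LinearTransform.identity(), rigid_phantom.scan.grid)


class TestTemplatePackage:
    def test_anchor_count_enforced(self, template_package):
        with pytest.raises(ValueError, match="8 points"):
            TemplatePackage(
                np_template=template_package.np_template,
                brain_mask=template_package.brain_mask,
                qa_anchors=template_package.qa_anchors.subset(
                    list(QA_ANCHOR_LABELS[:4])
                ),
                qa_calibration=template_package.qa_calibration,
                fusion="median",
            )

    def test_save_load_roundtrip(self, template_package, tmp_path):
        template_package.save(tmp_path / "tpl")
        back = TemplatePackage.load(tmp_path / "tpl")
        assert np.allclose(back.np_template.data, template_package.np_template.data)
        assert np.array_equal(back.brain_mask.data, template_package.brain_mask.data)
        assert back.qa_anchors.labels == template_package.qa_anchors.labels
        assert back.qa_calibration["strain_mad"] == pytest.approx(
            template_package.qa_calibration["strain_mad"]
        )
        assert back.fusion == "median"

    def test_built_package_well_formed(self, template_package, template_cohort):
        assert len(template_package.qa_anchors) == 8
        from scipy import ndimage

        labels, n = ndimage.label(template_package.brain_mask.data)
        assert n == 1  # mask connected
        # anchors land near the cohort-mean ground-truth anchor positions
        mean_truth = np.mean(
            [
                p.landmarks.subset(template_package.qa_anchors.labels).coords
                for p in template_cohort
            ],
            axis=0,
        )
        err = np.linalg.norm(template_package.qa_anchors.coords - mean_truth, axis=1)
        assert err.max() < 2.0
        calib = template_package.qa_calibration
        assert set(calib["vi_max"]) == set(QA_ANCHOR_LABELS[:2])
        assert calib["strain_mad"] > 0
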