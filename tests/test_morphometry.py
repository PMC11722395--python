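import numpy as np
import pytest

from zbmorph import morphometry, synthetic
from zbmorph.io import BrainImage, DisplacementField, LabelAtlas, ScalarMap
from zbmorph.morphometry import (
    division_intensity,
    division_volumes,
    jacobian_determinant,
    log_jacobian,
    mask_volume_pct,
    pullback_label_counts,
)


def oracle_jacobian(u, spacing):
    """Independent dense finite-difference Jacobian (explicit slicing +
    np.linalg.det), written separately from the implementation."""
    shape = u.shape[:3]
    grad = np.empty(shape + (3, 3))
    for i in range(3):
        for j in range(3):
            comp = u[..., i]
            d = np.empty(shape)
            sl = [slice(None)] * 3
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            sl[j] = slice(1, -1)
            lo[j] = slice(0, -2)
            hi[j] = slice(2, None)
            d[tuple(sl)] = (comp[tuple(hi)] - comp[tuple(lo)]) / (2 * spacing[j])
            first = [slice(None)] * 3
            second = [slice(None)] * 3
            first[j] = 0
            second[j] = 1
            d[tuple(first)] = (comp[tuple(second)] - comp[tuple(first)]) / spacing[j]
            last = [slice(None)] * 3
            nextlast = [slice(None)] * 3
            last[j] = -1
            nextlast[j] = -2
            d[tuple(last)] = (comp[tuple(last)] - comp[tuple(nextlast)]) / spacing[j]
            grad[..., i, j] = d
    return np.linalg.det(np.eye(3) + grad)


def smooth_field(shape, spacing, amplitude, sigma, seed):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    u = np.stack(
        [gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)],
        axis=-1,
    )
    u *= amplitude / u.std()
    return DisplacementField(u, spacing)


class TestJacobian:
    def test_identity_field(self):
        fld = DisplacementField(np.zeros((5, 6, 7, 3)), (1, 1, 1))
        assert np.allclose(jacobian_determinant(fld).data, 1.0)

    @pytest.mark.parametrize("a,b,c", [(0.1, -0.05, 0.2), (0.0, 0.3, -0.1)])
    def test_affine_closed_form_everywhere(self, a, b, c):
        # gradients of a linear field are exact even with one-sided
        # boundary differences, so the closed form holds on every voxel
        spacing = (2.0, 1.0, 1.5)
        idx = np.meshgrid(*[np.arange(n) * s for n, s in zip((6, 7, 8), spacing)],
                          indexing="ij")
        u = np.stack([a * idx[0], b * idx[1], c * idx[2]], axis=-1)
        J = jacobian_determinant(DisplacementField(u, spacing))
        assert np.allclose(J.data, (1 + a) * (1 + b) * (1 + c), atol=1e-12)

    def test_matches_independent_oracle_on_random_fields(self):
        spacing = (2.0, 2.0, 1.0)
        for seed in range(5):
            fld = smooth_field((12, 14, 10), spacing, 0.4, 2.0, seed)
            J = jacobian_determinant(fld).data
            Jo = oracle_jacobian(fld.data, spacing)
            interior = (slice(1, -1),) * 3
            assert np.abs(J[interior] - Jo[interior]).max() < 1e-6

    def test_nonfinite_displacement_reports_voxel(self):
        u = np.zeros((4, 4, 4, 3))
        u[1, 2, 3, 0] = np.nan
        with pytest.raises(ValueError, match=r"\(1, 2, 3\)"):
            jacobian_determinant(DisplacementField(u, (1, 1, 1)))

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            jacobian_determinant(DisplacementField(np.zeros((2, 5, 5, 3)), (1, 1, 1)))


class TestLogJacobian:
    def test_identity_gives_zero(self):
        J = ScalarMap(np.ones((4, 4, 4)), (1, 1, 1))
        assert np.all(log_jacobian(J).data == 0.0)

    def test_contraction_value_and_sign(self):
        # a region locally smaller in the subject has J < 1, so LJD < 0:
        # contraction maps to negative volume change
        data = np.ones((5, 5, 5))
        data[2, 2, 2] = 0.8
        ljd = log_jacobian(ScalarMap(data, (1, 1, 1)))
        assert ljd.data[2, 2, 2] == pytest.approx(np.log(0.8))
        assert ljd.data[2, 2, 2] == pytest.approx(-0.2231, abs=1e-4)
        assert ljd.data[2, 2, 2] < 0

    def test_folds_clamped_and_limited(self):
        data = np.ones((10, 10, 10))
        data[0, 0, 0] = 1e-9  # a single fold: 0.1% of voxels, tolerated
        ljd = log_jacobian(ScalarMap(data, (1, 1, 1)), min_jacobian=0.05)
        assert ljd.data[0, 0, 0] == pytest.approx(np.log(0.05))
        data[:3] = -1.0  # 30% folded: invalid field
        with pytest.raises(ValueError, match="%"):
            log_jacobian(ScalarMap(data, (1, 1, 1)))


class TestDivisionVolumes:
    def test_identity_volumes_equal_voxel_counts(self, atlas):
        J = ScalarMap(np.ones(atlas.shape), atlas.spacing)
        dv = division_volumes(atlas, J).set_index("division")
        for k in atlas.labels:
            name = atlas.names[int(k)]
            expect = (atlas.data == k).sum() * atlas.voxel_volume
            assert dv.loc[name, "volume_um3"] == pytest.approx(expect)

    def test_global_scale_leaves_percentages_unchanged(self, atlas):
        J1 = ScalarMap(np.ones(atlas.shape), atlas.spacing)
        Js = ScalarMap(np.full(atlas.shape, 0.7**3), atlas.spacing)
        p1 = division_volumes(atlas, J1)["percent"].to_numpy()
        ps = division_volumes(atlas, Js)["percent"].to_numpy()
        assert np.allclose(p1, ps)

    def test_percentages_sum_to_100(self, atlas, rng):
        J = ScalarMap(1.0 + 0.1 * rng.standard_normal(atlas.shape), atlas.spacing)
        assert division_volumes(atlas, J)["percent"].sum() == pytest.approx(100.0)

    def test_implanted_atrophy_reduces_only_target(self, atlas):
        spec = synthetic.CohortSpec(warp_amplitude_um=0.0, atrophy_scale=0.8)
        fld = synthetic.make_displacement(atlas, spec, 1, scale=0.8)
        J = morphometry.jacobian_determinant(fld)
        dv = division_volumes(atlas, J).set_index("division")
        dv0 = division_volumes(
            atlas, ScalarMap(np.ones(atlas.shape), atlas.spacing)
        ).set_index("division")
        rel = dv["volume_um3"] / dv0["volume_um3"]
        assert rel["LCeP_L"] < 0.85 and rel["LCeP_R"] < 0.85
        others = rel.drop(["LCeP_L", "LCeP_R"])
        assert (np.abs(others - 1.0) < 0.01).all()

    def test_grid_mismatch_rejected(self, atlas):
        with pytest.raises(ValueError, match="mismatch"):
            division_volumes(atlas, ScalarMap(np.ones((4, 4, 4)), atlas.spacing))

    def test_pullback_mode_agrees_with_jacobian_integration(self, atlas):
        # nearest-neighbour label pull-back only resolves super-voxel
        # deformations, so cross-validate the two volumetry routes on a
        # global affine contraction (several voxels of displacement)
        a = 0.85
        spacing = np.asarray(atlas.spacing)
        center = (np.array(atlas.shape) - 1) / 2 * spacing
        coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(atlas.shape, spacing)],
                             indexing="ij")
        u = np.stack([(a - 1) * (c - cc) for c, cc in zip(coords, center)], axis=-1)
        fld = DisplacementField(u, atlas.spacing)
        J = morphometry.jacobian_determinant(fld)
        ji = division_volumes(atlas, J).set_index("division")["volume_um3"]
        pb = pullback_label_counts(atlas, fld).set_index("division")["volume_um3"]
        big = [atlas.names[int(k)] for k in atlas.labels
               if (atlas.data == k).sum() > 1500]
        assert len(big) >= 4
        assert np.allclose(pb[big], ji[big], rtol=0.08)
        # and the Jacobian route matches the closed form a^3 exactly
        counts = {atlas.names[int(k)]: (atlas.data == k).sum() for k in atlas.labels}
        for name in big:
            assert ji[name] == pytest.approx(
                a**3 * counts[name] * atlas.voxel_volume, rel=0.02)


class TestMaskVolume:
    def test_whole_brain_is_100(self, atlas):
        J = ScalarMap(np.ones(atlas.shape), atlas.spacing)
        assert mask_volume_pct(atlas.brain_mask(), atlas, J) == pytest.approx(100.0)

    def test_identity_gives_count_ratio(self, atlas):
        J = ScalarMap(np.ones(atlas.shape), atlas.spacing)
        inv = {v: k for k, v in atlas.names.items()}
        mask = atlas.data == inv["LCeP_L"]
        expect = 100.0 * mask.sum() / atlas.brain_mask().sum()
        assert mask_volume_pct(mask, atlas, J) == pytest.approx(expect)

    def test_empty_mask_rejected(self, atlas):
        J = ScalarMap(np.ones(atlas.shape), atlas.spacing)
        with pytest.raises(ValueError, match="empty"):
            mask_volume_pct(np.zeros(atlas.shape, bool), atlas, J)


class TestDivisionIntensity:
    def test_constant_image(self, atlas):
        img = BrainImage(np.full(atlas.shape + (2,), 7.0), atlas.spacing)
        tab = division_intensity(atlas, img)
        assert (tab.filter(like="mean_") == 7.0).all().all()

    def test_generator_means_recovered_within_se(self, atlas, atlas_image, rng):
        noisy = BrainImage(atlas_image.data + rng.normal(0, 5, atlas_image.data.shape),
                           atlas.spacing, channel_names=atlas_image.channel_names)
        tab = division_intensity(atlas, noisy).set_index("division")
        n = tab.loc["Tel", "n_voxels"]
        se = 5 / np.sqrt(n)
        assert abs(tab.loc["Tel", "mean_pan_neuronal"] - 100.0) < 4 * se

    def test_empty_division_reported_missing(self, atlas):
        lab = LabelAtlas(np.zeros((4, 4, 4), np.int32), (1, 1, 1),
                         names={1: "ghost"})
        img = BrainImage(np.ones((4, 4, 4, 1)), (1, 1, 1))
        tab = division_intensity(lab, img)
        row = tab.set_index("division").loc["ghost"]
        assert row["n_voxels"] == 0
        assert np.isnan(row["mean_ch1"])
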