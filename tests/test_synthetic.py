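import numpy as np
import pandas as pd
import pytest

from zbmorph import morphometry, synthetic
from zbmorph.synthetic import (
    AtlasSpec,
    CohortSpec,
    DEGenSpec,
    Division,
    TraceGenSpec,
    make_atlas,
    make_cohort,
    make_de_tables,
    make_displacement,
    make_trace,
    mirror_labels,
)


class TestAtlas:
    def test_default_atlas_mirror_symmetric(self, atlas):
        assert np.array_equal(atlas.data, mirror_labels(atlas))

    def test_single_centered_sphere_equals_own_mirror(self):
        spec = AtlasSpec(shape=(21, 20, 20), spacing=(1, 1, 1),
                         divisions=(Division("Core", (10.0, 9.5, 9.5), (6, 5, 5)),))
        atlas, _ = make_atlas(spec)
        assert np.array_equal(atlas.data, np.flip(atlas.data, axis=0))

    def test_twin_divisions_have_equal_voxel_counts(self, atlas):
        inv = {v: k for k, v in atlas.names.items()}
        nl = (atlas.data == inv["LCeP_L"]).sum()
        nr = (atlas.data == inv["LCeP_R"]).sum()
        assert nl == nr > 0

    def test_total_labeled_volume_is_sum_of_division_counts(self, atlas):
        # brute-force voxel count per label
        per_label = sum(int((atlas.data == k).sum()) for k in atlas.labels)
        total = int((atlas.data > 0).sum())
        assert per_label == total
        assert total * atlas.voxel_volume == pytest.approx(total * 8.0)

    def test_overlapping_divisions_rejected(self):
        spec_kwargs = dict(shape=(20, 20, 20), spacing=(1, 1, 1))
        divs = (Division("A", (9.5, 10, 10), (5, 5, 5)),
                Division("B", (9.5, 12, 10), (5, 5, 5)))
        with pytest.raises(ValueError, match="'A' and 'B'"):
            make_atlas(AtlasSpec(divisions=divs, **spec_kwargs))

    def test_unpaired_lateral_division_rejected(self):
        with pytest.raises(ValueError, match="twin"):
            AtlasSpec(shape=(20, 20, 20),
                      divisions=(Division("X_L", (4, 10, 10), (2, 2, 2)),))

    def test_channel_means_match_spec(self, atlas, atlas_image):
        inv = {v: k for k, v in atlas.names.items()}
        sel = atlas.data == inv["Tg"]
        assert np.allclose(atlas_image.data[sel], (100.0, 40.0, 60.0))


class TestDisplacement:
    def test_zero_amplitude_scale_one_is_identity(self, atlas):
        spec = CohortSpec(warp_amplitude_um=0.0, atrophy_scale=1.0)
        fld = make_displacement(atlas, spec, 5, scale=1.0)
        assert np.all(fld.data == 0)
        J = morphometry.jacobian_determinant(fld)
        assert np.allclose(J.data, 1.0)

    def test_pure_contraction_mean_jacobian_near_scale(self, atlas):
        spec = CohortSpec(warp_amplitude_um=0.0, atrophy_scale=0.8)
        fld = make_displacement(atlas, spec, 5, scale=0.8)
        J = morphometry.jacobian_determinant(fld)
        inv = {v: k for k, v in atlas.names.items()}
        region = np.isin(atlas.data, [inv["LCeP_L"], inv["LCeP_R"]])
        assert abs(J.data[region].mean() - 0.8) < 0.05
        assert J.data.min() > 0

    def test_total_brain_volume_conserved_within_1pct(self, atlas):
        spec = CohortSpec(warp_amplitude_um=0.0, atrophy_scale=0.8)
        fld = make_displacement(atlas, spec, 5, scale=0.8)
        J = morphometry.jacobian_determinant(fld)
        brain = atlas.brain_mask()
        assert abs(J.data[brain].mean() - 1.0) < 0.01

    def test_same_seed_same_field(self, atlas):
        spec = CohortSpec(seed=0)
        a = make_displacement(atlas, spec, 99, scale=0.8)
        b = make_displacement(atlas, spec, 99, scale=0.8)
        assert np.array_equal(a.data, b.data)

    def test_unknown_region_rejected(self, atlas):
        spec = CohortSpec(atrophy_region="Nucleus")
        with pytest.raises(ValueError, match="Nucleus"):
            make_displacement(atlas, spec, 1, scale=0.8)


class TestCohort:
    def test_group_sizes_and_flags(self, small_cohort):
        spec, samples, truth = small_cohort
        assert len(samples) == 6
        assert (truth.genotype == "crispant").sum() == 3
        assert set(truth.loc[truth.genotype == "crispant", "scale"]) == {0.8}
        assert set(truth.loc[truth.genotype == "control", "scale"]) == {1.0}

    def test_no_two_fields_identical(self, small_cohort):
        _, samples, _ = small_cohort
        flats = [s.field.data.ravel() for s in samples]
        for i in range(len(flats)):
            for j in range(i + 1, len(flats)):
                assert not np.array_equal(flats[i], flats[j])

    def test_scale_one_everywhere_in_truth(self, atlas, atlas_image):
        spec = CohortSpec(group_sizes={"control": 2, "crispant": 2},
                          atrophy_scale=1.0, seed=3)
        _, truth = make_cohort(spec, atlas, atlas_image)
        assert (truth.scale == 1.0).all()

    def test_small_group_rejected(self, atlas, atlas_image):
        spec = CohortSpec(group_sizes={"control": 1, "crispant": 4})
        with pytest.raises(ValueError, match="at least 2"):
            make_cohort(spec, atlas, atlas_image)

    def test_cohort_determinism(self, atlas, atlas_image):
        spec = CohortSpec(group_sizes={"control": 2, "crispant": 2}, seed=21)
        s1, t1 = make_cohort(spec, atlas, atlas_image)
        s2, t2 = make_cohort(spec, atlas, atlas_image)
        pd.testing.assert_frame_equal(t1, t2)
        assert np.array_equal(s1[0].field.data, s2[0].field.data)
        assert np.array_equal(s1[-1].channels.data, s2[-1].channels.data)


class TestDETables:
    def test_no_shared_de_gives_empty_shared_truth(self):
        _, _, truth = make_de_tables(DEGenSpec(n_shared_de=0, n_unique_de=(5, 5),
                                               n_genes=200, seed=1))
        assert (truth.klass == "shared").sum() == 0

    def test_large_effects_concordant_signs(self):
        spec = DEGenSpec(n_genes=300, n_shared_de=20, n_unique_de=(0, 0),
                         lfc_range=(4.0, 4.0), mean_log_mu=7.0,
                         mean_log_sigma=0.2, seed=2)
        ta, tb, truth = make_de_tables(spec)
        shared = truth.loc[truth.klass == "shared", "gene"]
        a = ta.set_index("gene").loc[shared, "log2FoldChange"]
        b = tb.set_index("gene").loc[shared, "log2FoldChange"]
        assert (np.sign(a) == np.sign(b)).all()
        assert (np.sign(a).to_numpy() == truth.set_index("gene").loc[shared, "sign"].to_numpy()).all()

    def test_basemean_is_realized_count_mean(self):
        counts_ctl = np.full((3, 3), 50.0)
        counts_mut = np.full((3, 3), 50.0)
        tab = synthetic.de_table_from_counts(["a", "b", "c"], counts_ctl, counts_mut)
        assert (tab.baseMean == 50.0).all()
        assert (tab.pvalue == 1.0).all()  # zero variance in both groups

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            DEGenSpec(dispersion=0.0)

    def test_tables_deterministic(self):
        a1, b1, t1 = make_de_tables(DEGenSpec(n_genes=150, seed=5,
                                              n_shared_de=5, n_unique_de=(3, 3)))
        a2, b2, t2 = make_de_tables(DEGenSpec(n_genes=150, seed=5,
                                              n_shared_de=5, n_unique_de=(3, 3)))
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(t1, t2)


class TestTraces:
    def test_pure_wildtype_single_peak(self):
        tr = make_trace(TraceGenSpec(wt_fraction=1.0, noise_sd=0.0))
        from zbmorph.fragqc import detect_peaks

        peaks = detect_peaks(tr.size_bp, tr.signal)
        assert len(peaks) == 1
        assert peaks.size_bp.iloc[0] == pytest.approx(250.0, abs=0.3)

    def test_half_wildtype_equal_areas(self):
        tr = make_trace(TraceGenSpec(wt_fraction=0.5, indel_offsets_bp=(-10.0,),
                                     indel_rel_areas=(1.0,), noise_sd=0.0))
        from zbmorph.fragqc import detect_peaks

        peaks = detect_peaks(tr.size_bp, tr.signal)
        assert len(peaks) == 2
        a = peaks.area.to_numpy()
        assert a[0] == pytest.approx(a[1], rel=0.02)

    def test_analytic_area_matches_trapezoid(self):
        spec = TraceGenSpec(wt_fraction=0.6, noise_sd=0.0)
        tr = make_trace(spec)
        numeric = np.trapezoid(tr.signal, tr.size_bp)
        assert numeric == pytest.approx(spec.total_area, rel=0.01)

    def test_overlap_warning(self):
        tr = make_trace(TraceGenSpec(wt_fraction=0.5, indel_offsets_bp=(0.3,),
                                     indel_rel_areas=(1.0,)))
        assert tr.overlap_warning

    def test_bad_rel_areas_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TraceGenSpec(indel_rel_areas=(0.5, 0.2, 0.1))
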