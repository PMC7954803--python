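import numpy as np
import pytest

from histoconcord import (
    DeviationSpec,
    ExtentError,
    ImageGeometry,
    LesionSpec,
    PhantomSpec,
    PhantomSpecError,
    derive_imaging_gtv,
    dsc,
    generate_cohort,
    generate_patient,
    label_components,
    make_gland,
    make_lesions,
    volume_ml,
)

FINE = ImageGeometry(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0))


def _spec(gland_semis=(20.0, 15.0, 15.0), lesions=(), geometry=FINE, center=None):
    if center is None:
        center = tuple((geometry.shape[i] - 1) / 2 * geometry.spacing[i] for i in range(3))
    return PhantomSpec(
        geometry=geometry,
        gland_center_mm=center,
        gland_semiaxes_mm=gland_semis,
        lesions=tuple(lesions),
    )


class TestGland:
    def test_volume_matches_analytic_ellipsoid(self):
        spec = _spec(gland_semis=(20.0, 15.0, 15.0), geometry=ImageGeometry((96, 96, 48), (1, 1, 2)))
        gland = make_gland(spec)
        analytic = 4 / 3 * np.pi * 20 * 15 * 15 / 1000.0  # 18.85 ml
        assert volume_ml(gland) == pytest.approx(analytic, rel=0.05)

    def test_mirrored_spec_gives_mirrored_mask(self):
        geometry = ImageGeometry((40, 30, 20), (1.0, 1.0, 2.0))
        a = make_gland(_spec((12.0, 9.0, 8.0), geometry=geometry, center=(15.0, 14.0, 19.0)))
        # mirror plane: x -> (nx-1)*sx - x
        b = make_gland(_spec((12.0, 9.0, 8.0), geometry=geometry, center=(24.0, 14.0, 19.0)))
        assert np.array_equal(a.occupancy, b.occupancy[::-1, :, :])

    def test_exceeding_grid_raises(self):
        with pytest.raises(ExtentError):
            make_gland(_spec(gland_semis=(60.0, 15.0, 15.0)))

    def test_tiny_ellipsoid_keeps_center_voxel(self):
        spec = _spec(gland_semis=(0.6, 0.6, 0.6))
        assert make_gland(spec).voxel_count >= 1


class TestLesions:
    def test_spherical_lesion_truth_is_analytic(self):
        center = (31.5, 31.5, 31.5)
        spec = _spec(
            lesions=[LesionSpec(center_mm=center, semiaxes_mm=(7.0, 7.0, 7.0))],
            center=center,
        )
        ref, truths, _ = make_lesions(spec)
        t = truths[0]
        assert t.analytic_diameter_mm == 14.0 and t.is_index
        assert t.voxel_volume_ml == pytest.approx(t.analytic_volume_ml, rel=0.05)
        assert t.feret_diameter_mm <= 14.0

    def test_small_lesion_below_index_threshold(self):
        spec = _spec(lesions=[LesionSpec((31.5, 31.5, 31.5), (4.0, 4.0, 4.0))], center=(31.5, 31.5, 31.5))
        _, truths, _ = make_lesions(spec)
        assert not truths[0].is_index

    def test_two_disjoint_lesions_found_by_pipeline(self):
        c = (31.5, 31.5, 31.5)
        spec = _spec(
            gland_semis=(24.0, 18.0, 18.0),
            lesions=[
                LesionSpec((20.0, 31.5, 31.5), (5.0, 4.0, 4.0)),
                LesionSpec((44.0, 31.5, 31.5), (5.0, 4.0, 4.0)),
            ],
            center=c,
        )
        ref, truths, _ = make_lesions(spec)
        assert len(label_components(ref)) == 2
        assert all(t.merged_with == () for t in truths)

    def test_overlapping_lesions_flagged_merged(self):
        c = (31.5, 31.5, 31.5)
        spec = _spec(
            lesions=[
                LesionSpec((28.0, 31.5, 31.5), (5.0, 4.0, 4.0)),
                LesionSpec((34.0, 31.5, 31.5), (5.0, 4.0, 4.0)),
            ],
            center=c,
        )
        ref, truths, _ = make_lesions(spec)
        assert truths[0].merged_with == (2,) and truths[1].merged_with == (1,)
        assert len(label_components(ref)) == 1

    def test_center_outside_gland_rejected(self):
        spec = _spec(lesions=[LesionSpec((5.0, 5.0, 5.0), (3.0, 3.0, 3.0))])
        with pytest.raises(PhantomSpecError):
            make_lesions(spec)


class TestDeriveGtv:
    def _patient(self):
        c = (31.5, 31.5, 31.5)
        spec = _spec(
            gland_semis=(22.0, 18.0, 18.0),
            lesions=[LesionSpec(c, (7.0, 7.0, 7.0))],
            center=c,
        )
        gland = make_gland(spec)
        ref, truths, per_lesion = make_lesions(spec)
        return spec, gland, ref, per_lesion

    def test_zero_deviation_is_identity(self):
        _, gland, ref, per_lesion = self._patient()
        out = derive_imaging_gtv(ref, DeviationSpec(), gland, per_lesion)
        assert np.array_equal(out.occupancy, ref.occupancy)
        assert dsc(out, ref) == 1.0

    def test_erosion_shrinks_sphere_by_cube_law(self):
        _, gland, ref, per_lesion = self._patient()
        out = derive_imaging_gtv(
            ref, DeviationSpec(erode_mm=2.0), gland, per_lesion
        )
        ratio = volume_ml(out) / volume_ml(ref)
        assert ratio == pytest.approx((5.0 / 7.0) ** 3, rel=0.25)
        assert volume_ml(out) < volume_ml(ref)

    def test_dilation_grows_volume(self):
        _, gland, ref, per_lesion = self._patient()
        out = derive_imaging_gtv(ref, DeviationSpec(dilate_mm=2.0), gland, per_lesion)
        assert volume_ml(out) > volume_ml(ref)

    def test_missed_lesion_removed(self):
        _, gland, ref, per_lesion = self._patient()
        out = derive_imaging_gtv(
            ref, DeviationSpec(miss_lesion_ids=(1,)), gland, per_lesion
        )
        assert out.voxel_count == 0

    def test_annihilating_erosion_warns(self):
        _, gland, ref, per_lesion = self._patient()
        with pytest.warns(UserWarning, match="annihilated"):
            derive_imaging_gtv(ref, DeviationSpec(erode_mm=20.0), gland, per_lesion)

    def test_false_lesion_creates_exactly_one_false_positive(self):
        from histoconcord import analyse_lesions

        _, gland, ref, per_lesion = self._patient()
        dev = DeviationSpec(
            false_lesions=(LesionSpec((48.0, 31.5, 31.5), (3.0, 3.0, 3.0)),)
        )
        out = derive_imaging_gtv(ref, dev, gland, per_lesion)
        table = analyse_lesions(ref, out)
        assert table.n_detected == 1
        assert len(table.false_positive_lesions) == 1

    def test_translation_preserves_volume(self):
        _, gland, ref, per_lesion = self._patient()
        out = derive_imaging_gtv(
            ref, DeviationSpec(translate_mm=(3.0, -2.0, 2.0)), gland, per_lesion
        )
        # trimmed to gland afterwards, so volume can only shrink slightly
        assert 0.9 * volume_ml(ref) <= volume_ml(out) <= volume_ml(ref)


class TestCohort:
    def test_same_master_seed_is_bit_identical(self):
        a = generate_cohort(n_patients=2, master_seed=5)
        b = generate_cohort(n_patients=2, master_seed=5)
        for (sa, ta), (sb, tb) in zip(a, b):
            assert np.array_equal(sa.reference.occupancy, sb.reference.occupancy)
            for name in sa.tests:
                assert np.array_equal(sa.tests[name].occupancy, sb.tests[name].occupancy)
            assert ta.confusion == tb.confusion

    def test_cohort_structure(self, small_cohort):
        for sset, truth in small_cohort:
            assert 1 <= len(truth.lesions) <= 3
            assert any(l.is_index for l in truth.lesions)
            # reference and tests are subsets of the gland
            assert not (sset.reference.occupancy & ~sset.gland.occupancy).any()
            for mask in sset.tests.values():
                assert not (mask.occupancy & ~sset.gland.occupancy).any()

    def test_erosive_modality_strictly_smaller(self, small_cohort):
        for sset, _ in small_cohort:
            assert volume_ml(sset.tests["MRI-like"]) < volume_ml(sset.reference)

    def test_whole_gland_patient_covers_gland(self):
        cohort = generate_cohort(
            n_patients=2, master_seed=9, whole_gland_patient_index=0
        )
        sset, truth = cohort[0]
        assert np.array_equal(sset.reference.occupancy, sset.gland.occupancy)
        c = truth.confusion[("SEG6", "MRI-like")]
        assert c["tn"] + c["fp"] == 0
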