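"""Scoring-chain tests: reduction rates, aggregation conventions, patient
factor, MELIF, MELD and the grouping rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melif.errors import GeometryError, ValidationError
from melif.image import Geometry, LiverMask, RRMap, T1Map
from melif.scoring import (
    MELIF_C,
    meld,
    meld_group,
    melif,
    patient_factor,
    rr_map,
    rrt1_liver,
    score_patient,
)


def _uniform_setup(shape=(8, 8, 8), pre=1000.0, post=400.0, spacing=2.0):
    g = Geometry.isotropic(shape, spacing)
    t1_pre = T1Map(np.full(shape, pre), g)
    t1_post = T1Map(np.full(shape, post), g)
    mask = LiverMask(np.ones(shape), g)
    return t1_pre, t1_post, mask


class TestRRMap:
    def test_direct_arithmetic(self):
        t1_pre, t1_post, mask = _uniform_setup(pre=1000.0, post=400.0)
        rr = rr_map(t1_pre, t1_post, mask)
        assert np.allclose(rr.data[mask.data], 60.0)

    def test_identity_gives_zero(self):
        t1_pre, t1_post, mask = _uniform_setup(pre=900.0, post=900.0)
        rr = rr_map(t1_pre, t1_post, mask)
        assert np.allclose(rr.data[mask.data], 0.0)

    def test_phantom_uptake_recovered(self, small_truth):
        rr = rr_map(small_truth.t1_pre, small_truth.t1_post, small_truth.mask)
        m = small_truth.mask.data
        dev = np.abs(rr.data[m] - 100.0 * small_truth.uptake_field[m])
        assert dev.mean() < 1.0  # < 1 percentage point

    def test_empty_mask_rejected(self):
        t1_pre, t1_post, _ = _uniform_setup()
        empty = LiverMask(np.zeros(t1_pre.geometry.shape), t1_pre.geometry)
        with pytest.raises(ValidationError):
            rr_map(t1_pre, t1_post, empty)

    def test_geometry_mismatch_rejected(self):
        t1_pre, t1_post, mask = _uniform_setup()
        other = Geometry.isotropic(t1_pre.geometry.shape, 3.0)
        post2 = T1Map(t1_post.data, other)
        with pytest.raises(GeometryError):
            rr_map(t1_pre, post2, mask)

    def test_invalid_and_nonpositive_pre_excluded(self):
        t1_pre, t1_post, mask = _uniform_setup()
        t1_pre.data[0, 0, 0] = 0.0
        t1_pre.valid[1, 0, 0] = False
        rr = rr_map(t1_pre, t1_post, mask)
        assert not rr.valid[0, 0, 0]
        assert not rr.valid[1, 0, 0]
        assert rr.valid.sum() == mask.n_voxels - 2

    def test_negative_rr_retained_and_clipping_counted(self):
        t1_pre, t1_post, mask = _uniform_setup(pre=500.0, post=600.0)
        rr = rr_map(t1_pre, t1_post, mask)
        assert np.allclose(rr.data[mask.data], -20.0)
        t1_post2 = T1Map(np.full(t1_pre.geometry.shape, 1500.0), t1_pre.geometry)
        rr2 = rr_map(t1_pre, t1_post2, mask)  # raw rr = -200 -> clipped
        assert np.allclose(rr2.data[mask.data], -100.0)
        assert rr2.n_clipped == mask.n_voxels

    def test_oracle_equivalence_per_voxel_loop(self, small_truth):
        """Vectorized rr_map must equal an explicit loop bit-exactly."""
        rr = rr_map(small_truth.t1_pre, small_truth.t1_post, small_truth.mask)
        pre, post = small_truth.t1_pre, small_truth.t1_post
        idx = np.argwhere(small_truth.mask.data)
        for i, j, k in idx[:: max(1, len(idx) // 500)]:
            expected = (pre.data[i, j, k] - post.data[i, j, k]) / pre.data[i, j, k] * 100.0
            expected = min(max(expected, -100.0), 100.0)
            assert rr.data[i, j, k] == expected


class TestRRT1Liver:
    def test_uniform_mean_and_integrated(self):
        g = Geometry.isotropic((10, 10, 10), 3.6)
        rr = RRMap(np.full(g.shape, 50.0), g)
        mask = LiverMask(np.ones(g.shape), g)
        assert rrt1_liver(rr, mask, "mean_pct") == pytest.approx(50.0)
        # uniform 50% over N standard-grid voxels -> 0.5 N; resampling a
        # uniform field is exact up to edge partial volume
        n_equiv = rrt1_liver(rr, mask, "integrated") / 0.5
        assert n_equiv == pytest.approx(1000, rel=0.05)

    def test_additivity_vs_intensivity(self):
        g = Geometry.isotropic((24, 12, 12), 3.6)
        data = np.full(g.shape, 40.0)
        mask1 = np.zeros(g.shape, dtype=bool)
        mask1[2:10, 2:10, 2:10] = True
        mask2 = np.zeros(g.shape, dtype=bool)
        mask2[14:22, 2:10, 2:10] = True  # disjoint translated copy
        both = mask1 | mask2
        rr = RRMap(data, g)
        m1 = LiverMask(mask1, g)
        mb = LiverMask(both, g)
        assert rrt1_liver(rr, mb, "mean_pct") == pytest.approx(
            rrt1_liver(rr, m1, "mean_pct")
        )
        assert rrt1_liver(rr, mb, "integrated") == pytest.approx(
            2.0 * rrt1_liver(rr, m1, "integrated"), rel=0.02
        )

    def test_no_valid_voxels_rejected(self):
        g = Geometry.isotropic((6, 6, 6), 2.0)
        rr = RRMap(np.full(g.shape, np.nan), g)
        mask = LiverMask(np.ones(g.shape), g)
        with pytest.raises(ValidationError):
            rrt1_liver(rr, mask, "mean_pct")

    def test_resolution_invariance_of_integrated(self, mean_patient):
        """The same physical phantom acquired at 2.5 mm and 5 mm must give
        MELIF within 2% (standard-grid convention)."""
        from melif.phantom import PhantomSpec, make_ground_truth
        from melif.t1map import resample_to
        from melif.image import resample_array

        spec = PhantomSpec(
            grid_shape=(96, 96, 96), voxel_spacing_mm=(2.5, 2.5, 2.5),
            uptake_mean=0.5, seed=3,
        )
        truth = make_ground_truth(spec, mean_patient)
        fine = score_patient(truth.t1_pre, truth.t1_post, truth.mask, mean_patient)

        coarse_geom = Geometry.isotropic((48, 48, 48), 5.0)
        pre_c = resample_to(truth.t1_pre, coarse_geom)
        post_c = resample_to(truth.t1_post, coarse_geom)
        mask_c = LiverMask(
            resample_array(
                truth.mask.data.astype(float), truth.mask.geometry, coarse_geom, order=0
            ),
            coarse_geom,
        )
        coarse = score_patient(pre_c, post_c, mask_c, mean_patient)
        assert coarse.melif == pytest.approx(fine.melif, rel=0.02)


class TestPatientFactor:
    def test_table_means(self):
        # oracle: 1.7**0.6 / (83**0.3 * 1513**0.6) evaluated independently
        assert patient_factor(1.7, 83.0, 1513.0) == pytest.approx(4.515e-3, rel=1e-3)

    def test_identity(self):
        assert patient_factor(1.0, 1.0, 1.0) == 1.0

    @given(k=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_volume_homogeneity(self, k):
        base = patient_factor(1.7, 83.0, 1500.0)
        scaled = patient_factor(1.7, 83.0, 1500.0 * k)
        assert scaled == pytest.approx(base * k**-0.6, rel=1e-9)

    @pytest.mark.parametrize("h,w,v", [(0, 80, 1500), (1.7, -1, 1500), (1.7, 80, 0)])
    def test_nonpositive_rejected(self, h, w, v):
        with pytest.raises(ValidationError):
            patient_factor(h, w, v)


class TestMelif:
    def test_zero(self):
        assert melif(4.5e-3, 0.0) == 0.0

    def test_linearity_in_c(self):
        assert melif(4.5e-3, 1e4, c=2 * MELIF_C) == pytest.approx(
            2 * melif(4.5e-3, 1e4)
        )

    def test_mean_patient_uniform_50pct_is_about_51(self):
        """Standard-grid convention anchor: Table-1-mean anthropometrics and
        a uniform 50% reduction over a 1513 mL liver land near MELIF 51."""
        n_std_voxels = 1513.0 * 1000.0 / 3.6**3
        integrated = 0.5 * n_std_voxels
        f_p = patient_factor(1.7, 83.0, 1513.0)
        assert melif(f_p, integrated) == pytest.approx(51.0, rel=0.05)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            melif(math.nan, 1.0)


class TestMeld:
    @pytest.mark.parametrize(
        "bili,inr,creat,dia,expected",
        [
            (1.0, 1.0, 1.0, False, 6),    # floor
            (2.0, 1.5, 1.2, False, 15),   # hand-computed oracle
            (0.5, 0.8, 0.4, False, 6),    # sub-1.0 labs clamp to 1.0
        ],
    )
    def test_values(self, bili, inr, creat, dia, expected):
        assert meld(bili, inr, creat, dia) == expected

    def test_creatinine_cap(self):
        assert meld(1.0, 1.0, 9.0, False) == meld(1.0, 1.0, 4.0, False)

    def test_dialysis_sets_creatinine_to_cap(self):
        assert meld(2.0, 1.5, 1.0, True) == meld(2.0, 1.5, 4.0, False)

    def test_nonpositive_lab_rejected(self):
        with pytest.raises(ValidationError):
            meld(0.0, 1.0, 1.0)

    @given(
        bili=st.floats(0.3, 30.0),
        inr=st.floats(0.8, 6.0),
        creat=st.floats(0.3, 8.0),
        bump=st.floats(0.01, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_lab(self, bili, inr, creat, bump):
        base = meld(bili, inr, creat)
        assert meld(bili + bump, inr, creat) >= base
        assert meld(bili, inr + bump, creat) >= base
        assert meld(bili, inr, creat + bump) >= base


class TestMeldGroup:
    @pytest.mark.parametrize(
        "score,expected",
        [(6, "normal"), (10, "normal"), (11, "impaired"), (18, "impaired"), (19, "severe")],
    )
    def test_boundaries(self, score, expected):
        assert meld_group(score) == expected


class TestScorePatient:
    def test_exclusion_accounting(self, small_truth, mean_patient):
        pre = small_truth.t1_pre
        pre.valid[tuple(np.argwhere(small_truth.mask.data)[0])] = False
        res = score_patient(pre, small_truth.t1_post, small_truth.mask, mean_patient)
        assert res.n_voxels_used + res.n_voxels_excluded == small_truth.mask.n_voxels
        assert res.n_voxels_excluded >= 1
        assert res.melif == pytest.approx(MELIF_C * res.f_p * res.rrt1_integrated)
        assert res.meld_group == meld_group(res.meld)

    def test_uptake_monotonicity(self, mean_patient):
        from melif.phantom import PhantomSpec, make_ground_truth

        results = []
        for uptake in (0.2, 0.4, 0.6):
            spec = PhantomSpec(
                grid_shape=(40, 40, 40), voxel_spacing_mm=(5.0, 5.0, 5.0),
                uptake_mean=uptake, seed=9,
            )
            t = make_ground_truth(spec, mean_patient)
            results.append(score_patient(t.t1_pre, t.t1_post, t.mask, mean_patient))
        means = [r.rrt1_mean_pct for r in results]
        integ = [r.rrt1_integrated for r in results]
        scores = [r.melif for r in results]
        assert means == sorted(means) and integ == sorted(integ)
        assert scores == sorted(scores)
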