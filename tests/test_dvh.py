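import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvhrisk import (
    CumulativeDVH,
    DifferentialDVH,
    DoseBin,
    cumulative_to_differential,
    differential_to_cumulative,
    mean_dose,
    read_dvh_csv,
    rebin,
    scale_dose,
    vx,
    write_dvh_csv,
)
from dvhrisk.dvh import DVHFormatError, DVHValidationError, merge_dvhs

from conftest import bin_voxels


class TestDoseBin:
    def test_midpoint(self):
        assert DoseBin(0.0, 10.0, 0.5).midpoint == 5.0

    @pytest.mark.parametrize("lo,hi,fv", [(-1, 1, 0.5), (5, 5, 0.5), (5, 4, 0.5), (0, 1, 1.5), (0, 1, -0.1)])
    def test_invalid(self, lo, hi, fv):
        with pytest.raises(DVHValidationError):
            DoseBin(lo, hi, fv)


class TestDifferentialDVH:
    def test_volume_must_sum_to_one(self):
        with pytest.raises(DVHValidationError, match="sum to 1"):
            DifferentialDVH(organ="lung", lo=[0.0], hi=[1.0], frac_volume=[0.5])

    def test_bins_must_be_contiguous(self):
        with pytest.raises(DVHValidationError, match="contiguous"):
            DifferentialDVH(organ="lung", lo=[0.0, 2.0], hi=[1.0, 3.0], frac_volume=[0.5, 0.5])

    def test_n_bins_counts_subvolumes(self, random_dvh):
        d = random_dvh(np.random.default_rng(0), n_bins=37)
        assert d.n_bins == 37

    def test_uniform_has_exact_midpoint(self, uniform_dvh):
        assert uniform_dvh(70.3).midpoints[0] == pytest.approx(70.3, abs=1e-12)


class TestCumulativeDVH:
    def test_increasing_fractions_rejected(self):
        with pytest.raises(DVHValidationError, match="non-increasing"):
            CumulativeDVH(organ="lung", dose_gy=[0.0, 10.0, 20.0], frac_ge=[1.0, 0.4, 0.6])

    def test_first_point_must_be_full_volume_at_zero(self):
        with pytest.raises(DVHValidationError):
            CumulativeDVH(organ="lung", dose_gy=[0.0, 10.0], frac_ge=[0.9, 0.4])
        with pytest.raises(DVHValidationError):
            CumulativeDVH(organ="lung", dose_gy=[1.0, 10.0], frac_ge=[1.0, 0.4])


class TestCsvIO:
    def test_three_row_differential_read_back(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "patient_id,modality,organ,bin_lo_gy,bin_hi_gy,frac_volume\n"
            "P01,3DCRT,lung,0,10,0.5\nP01,3DCRT,lung,10,20,0.3\nP01,3DCRT,lung,20,30,0.2\n"
        )
        dvhs = read_dvh_csv(p, form="differential")
        assert set(dvhs) == {("P01", "3DCRT", "lung")}
        d = dvhs[("P01", "3DCRT", "lung")]
        assert d.n_bins == 3
        np.testing.assert_allclose(d.frac_volume, [0.5, 0.3, 0.2])

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("patient_id,modality,organ,bin_lo_gy,frac_volume\nP01,HT,lung,0,1\n")
        with pytest.raises(DVHFormatError, match="bin_hi_gy"):
            read_dvh_csv(p, form="differential")

    def test_increasing_cumulative_file_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,modality,organ,dose_gy,frac_volume_ge\n"
            "P01,HT,lung,0,1.0\nP01,HT,lung,5,0.2\nP01,HT,lung,10,0.8\n"
        )
        with pytest.raises(DVHValidationError, match="non-increasing"):
            read_dvh_csv(p, form="cumulative")

    def test_round_trip_bit_identical(self, tmp_path, random_dvh):
        d = random_dvh(np.random.default_rng(42), n_bins=80)
        p = tmp_path / "rt.csv"
        write_dvh_csv(p, {("P01", "HT", "lung"): d})
        back = read_dvh_csv(p, form="differential")[("P01", "HT", "lung")]
        np.testing.assert_array_equal(back.lo, d.lo)
        np.testing.assert_array_equal(back.hi, d.hi)
        np.testing.assert_array_equal(back.frac_volume, d.frac_volume)

    def test_unknown_form(self, tmp_path):
        with pytest.raises(ValueError, match="form"):
            read_dvh_csv(tmp_path / "x.csv", form="banana")


class TestConversions:
    def test_first_differences(self):
        c = CumulativeDVH(organ="lung", dose_gy=[0.0, 10.0, 20.0], frac_ge=[1.0, 0.4, 0.0])
        d = cumulative_to_differential(c)
        np.testing.assert_allclose(d.lo, [0.0, 10.0])
        np.testing.assert_allclose(d.frac_volume, [0.6, 0.4])

    def test_uniform_dose_organ(self):
        c = CumulativeDVH(organ="lung", dose_gy=[0.0, 30.0, 31.0], frac_ge=[1.0, 1.0, 0.0])
        d = cumulative_to_differential(c)
        np.testing.assert_allclose(d.frac_volume, [0.0, 1.0])
        assert d.lo[1] == 30.0 and d.hi[1] == 31.0

    def test_degenerate_input(self):
        c = CumulativeDVH(organ="lung", dose_gy=[0.0], frac_ge=[1.0])
        with pytest.raises(DVHValidationError, match="at least 2"):
            cumulative_to_differential(c)

    def test_tail_sum_examples(self):
        d = DifferentialDVH(organ="lung", lo=[0.0, 10.0], hi=[10.0, 20.0], frac_volume=[0.6, 0.4])
        c = differential_to_cumulative(d)
        assert c.frac_ge[c.dose_gy.tolist().index(10.0)] == pytest.approx(0.4)
        assert c.frac_ge[c.dose_gy.tolist().index(20.0)] == pytest.approx(0.0)
        assert c.frac_ge[0] == 1.0

    def test_single_high_bin(self):
        d = DifferentialDVH(organ="lung", lo=[21.0], hi=[21.1], frac_volume=[1.0])
        c = differential_to_cumulative(d)
        assert c.frac_ge[c.dose_gy.tolist().index(21.0)] == pytest.approx(1.0)

    def test_brute_force_tail_sum_500_bins(self, random_dvh):
        rng = np.random.default_rng(7)
        d = random_dvh(rng, n_bins=500)
        c = differential_to_cumulative(d)
        for x in rng.uniform(0, 50, size=20):
            expected = d.frac_volume[d.lo >= x].sum()  # independent tail sum
            idx = np.searchsorted(c.dose_gy, x, side="left")
            if idx < c.dose_gy.size and c.dose_gy[idx] >= x:
                got = np.interp(x, c.dose_gy, c.frac_ge)
                # compare at the grid point at/above x
                assert c.frac_ge[idx] == pytest.approx(d.frac_volume[d.lo >= c.dose_gy[idx]].sum(), abs=1e-9)
            assert 0.0 <= expected <= 1.0

    def test_round_trip_on_shared_grid(self, random_dvh):
        d = random_dvh(np.random.default_rng(3), n_bins=40)
        c = differential_to_cumulative(d)
        d2 = cumulative_to_differential(c)
        c2 = differential_to_cumulative(d2)
        np.testing.assert_allclose(c2.dose_gy, c.dose_gy)
        np.testing.assert_allclose(c2.frac_ge, c.frac_ge, atol=1e-12)


class TestRebin:
    def test_identity_on_own_grid(self, random_dvh):
        d = random_dvh(np.random.default_rng(5), n_bins=30, width=0.1)
        r = rebin(d, 0.1)
        np.testing.assert_allclose(r.frac_volume, d.frac_volume, atol=1e-12)

    def test_merge_two_bins(self):
        d = DifferentialDVH(organ="lung", lo=[0.0, 0.05], hi=[0.05, 0.1], frac_volume=[0.5, 0.5])
        r = rebin(d, 0.1)
        assert r.n_bins == 1
        assert r.frac_volume[0] == pytest.approx(1.0, abs=1e-15)

    def test_volume_conserved_exactly(self, random_dvh):
        d = random_dvh(np.random.default_rng(9), n_bins=77, width=0.13)
        for w in (0.05, 0.1, 0.7, 3.0):
            assert rebin(d, w).frac_volume.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_dose_error_bound(self, random_dvh):
        d = random_dvh(np.random.default_rng(11), n_bins=60, width=0.1)
        r = rebin(d, 0.01)
        assert abs(mean_dose(r) - mean_dose(d)) <= 0.5 * 0.01 + 1e-9

    def test_bad_width(self, random_dvh):
        d = random_dvh(np.random.default_rng(1))
        with pytest.raises(ValueError):
            rebin(d, 0.0)


class TestMetrics:
    def test_vx_uniform(self, uniform_dvh):
        d = uniform_dvh(21.0)
        assert vx(d, 20.0) == 1.0
        assert vx(d, 22.0) == 0.0

    def test_vx_at_zero_is_total_volume(self, random_dvh):
        d = random_dvh(np.random.default_rng(2))
        assert vx(d, 0.0) == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1), st.lists(st.floats(0.0, 10.0), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_vx_non_increasing(self, seed, thresholds):
        fv = np.random.default_rng(seed).dirichlet(np.ones(30))
        lo = np.arange(30) * 0.3
        d = DifferentialDVH(organ="lung", lo=lo, hi=lo + 0.3, frac_volume=fv)
        vals = [vx(d, t) for t in sorted(thresholds)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_mean_dose_uniform(self, uniform_dvh):
        assert mean_dose(uniform_dvh(21.0)) == pytest.approx(21.0, abs=1e-12)

    def test_mean_dose_two_bins(self):
        d = DifferentialDVH(organ="lung", lo=[0.0, 10.0], hi=[10.0, 20.0], frac_volume=[0.5, 0.5])
        assert mean_dose(d) == pytest.approx(10.0)

    def test_mean_dose_voxelwise_oracle(self):
        rng = np.random.default_rng(21)
        voxels = rng.uniform(0, 30, size=20000)
        d = bin_voxels(voxels, width=0.05)
        assert mean_dose(d) == pytest.approx(voxels.mean(), abs=0.05)


class TestScaleDose:
    def test_identity(self, random_dvh):
        d = random_dvh(np.random.default_rng(4))
        s = scale_dose(d, 1.0)
        np.testing.assert_array_equal(s.lo, d.lo)
        assert s.dose_kind == d.dose_kind

    def test_rbe_example(self, uniform_dvh):
        d = scale_dose(uniform_dvh(21.0), 1.1, as_rbe=True)
        assert mean_dose(d) == pytest.approx(23.1)
        assert d.dose_kind == "rbe_weighted_gy"

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_mean_dose_linearity(self, seed, factor):
        fv = np.random.default_rng(seed).dirichlet(np.ones(20))
        lo = np.arange(20) * 0.5
        d = DifferentialDVH(organ="lung", lo=lo, hi=lo + 0.5, frac_volume=fv)
        assert mean_dose(scale_dose(d, factor)) == pytest.approx(factor * mean_dose(d), rel=1e-12)

    def test_bad_factor(self, random_dvh):
        with pytest.raises(ValueError):
            scale_dose(random_dvh(np.random.default_rng(1)), -2.0)


class TestMergeDvhs:
    def test_volume_weighted_combination(self):
        left = DifferentialDVH(organ="lung", lo=[0.0], hi=[0.1], frac_volume=[1.0])
        right = DifferentialDVH(organ="lung", lo=[0.0, 0.1], hi=[0.1, 0.2], frac_volume=[0.0, 1.0])
        merged = merge_dvhs([left, right], [1.0, 1.0], organ="lung")
        np.testing.assert_allclose(merged.frac_volume[:2], [0.5, 0.5], atol=1e-12)
        assert merged.frac_volume.sum() == pytest.approx(1.0, abs=1e-12)
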