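"""Acquisition masks, training-angle interleaving and dose accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cycloct.forward_model import Geometry, Sinogram
from cycloct.sampling import (
    AcquisitionPlan, apply_pattern, build_mask, dose_fraction, extract_partial,
    select_training_angles,
)


def cyc_plan(**kw):
    kw.setdefault("mode", "cycloidal")
    kw.setdefault("period", 8)
    kw.setdefault("aperture", 1)
    kw.setdefault("shift_per_angle", 3)
    return AcquisitionPlan(**kw)


class TestBuildMask:
    def test_cycloidal_row_residues(self):
        pat = build_mask(cyc_plan(), 16, 32)
        assert np.flatnonzero(pat.mask[0]).tolist() == [0, 8, 16, 24]
        assert np.flatnonzero(pat.mask[1]).tolist() == [3, 11, 19, 27]
        assert np.flatnonzero(pat.mask[2]).tolist() == [6, 14, 22, 30]

    def test_coprime_shift_covers_all_residues(self):
        """gcd(shift, period) = 1: any `period` consecutive rows jointly hit
        every column residue exactly once."""
        assert math.gcd(3, 8) == 1
        pat = build_mask(cyc_plan(), 64, 64)
        for start in range(0, 56):
            rows = pat.mask[start:start + 8]
            residues = sorted(np.flatnonzero(rows[i])[0] % 8 - 0 for i in range(8))
            first_cols = [np.flatnonzero(rows[i])[0] % 8 for i in range(8)]
            assert sorted(first_cols) == list(range(8))

    def test_rotation_only_union_covers_one_period_fraction(self):
        plan = AcquisitionPlan(mode="rotation_only", period=8, aperture=1)
        pat = build_mask(plan, 32, 64)
        assert np.all(pat.mask == pat.mask[0][None, :])
        union = pat.mask.any(axis=0)
        assert union.sum() == 64 // 8

    def test_training_rows_fully_sampled(self):
        pat = build_mask(cyc_plan(n_train=4), 64, 64)
        assert pat.training_angles == [0, 16, 32, 48]
        assert pat.mask[pat.training_angles].all()

    def test_angular_subsampling_keeps_every_kth_row(self):
        plan = AcquisitionPlan(mode="angular_subsampled", angular_step_keep=8,
                               period=8, aperture=1)
        pat = build_mask(plan, 64, 32)
        assert pat.mask[::8].all()
        other = np.ones(64, bool)
        other[::8] = False
        assert not pat.mask[other].any()

    def test_mask_fraction_equals_aperture_over_period(self):
        for period, aperture in [(8, 1), (6, 2), (4, 1)]:
            plan = cyc_plan(period=period, aperture=aperture, shift_per_angle=1)
            pat = build_mask(plan, period * 4, period * 8)
            assert pat.mask.mean() == pytest.approx(aperture / period)

    def test_out_of_regime_ratio_warns(self):
        with pytest.warns(UserWarning, match="1:3 to 1:10"):
            AcquisitionPlan(mode="cycloidal", period=16, aperture=1,
                            shift_per_angle=3)


class TestTrainingAngles:
    def test_paper_scale_spacing(self):
        idx = select_training_angles(1024, 33)
        assert len(idx) == 33
        gaps = np.diff(idx)
        assert set(gaps.tolist()) <= {31, 32}

    def test_edge_cases(self):
        assert select_training_angles(100, 0) == []
        assert select_training_angles(16, 16) == list(range(16))

    @given(n_angles=st.integers(2, 300), frac=st.integers(0, 10))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_and_in_range(self, n_angles, frac):
        n_train = min(frac * n_angles // 10, n_angles)
        idx = select_training_angles(n_angles, n_train)
        assert len(idx) == n_train
        assert all(0 <= a < n_angles for a in idx)
        assert all(b > a for a, b in zip(idx, idx[1:]))


class TestApplyExtract:
    def geom(self, n_angles=16, n_cols=32):
        return Geometry(n_angles=n_angles, n_cols=n_cols, pixel_size=2.0 / n_cols)

    def test_all_true_mask_is_identity(self):
        sino = Sinogram(np.arange(16 * 32, dtype=float).reshape(16, 32), self.geom())
        plan = AcquisitionPlan(mode="dithered")
        out = apply_pattern(sino, build_mask(plan, 16, 32))
        assert np.array_equal(out.values, sino.values)

    def test_cycloidal_mask_counts_and_idempotence(self):
        sino = Sinogram(np.full((16, 32), 7.0), self.geom())
        pat = build_mask(cyc_plan(), 16, 32)
        out = apply_pattern(sino, pat)
        per_row = np.isfinite(out.values).sum(axis=1)
        assert np.all(per_row == int(np.ceil(32 * 1 / 8)))
        assert np.all(out.values[np.isfinite(out.values)] == 7.0)
        again = apply_pattern(out, pat)
        assert np.array_equal(np.isnan(again.values), np.isnan(out.values))

    def test_extract_partial_defined_counts(self):
        sino = Sinogram(np.random.default_rng(0).random((16, 32)), self.geom())
        empty = extract_partial(sino, [])
        assert not empty.defined.any()
        full = extract_partial(sino, list(range(16)))
        assert full.defined.all()
        assert np.array_equal(full.values, sino.values)
        some = extract_partial(sino, [0, 5, 9])
        assert some.defined.sum() == 3 * 32
        assert np.array_equal(some.values[5], sino.values[5])
        assert np.isnan(some.values[1]).all()


class TestDose:
    def test_printed_dose_values(self):
        assert dose_fraction(AcquisitionPlan(mode="dithered"), 1024) == 100.0
        assert dose_fraction(cyc_plan(), 1024) == pytest.approx(12.5)
        assert dose_fraction(cyc_plan(n_train=33), 1024) == pytest.approx(
            100.0 * (1024 + 33 * 8) / 8192)
        # training overhead alone
        overhead = (dose_fraction(cyc_plan(n_train=33), 1024)
                    - dose_fraction(cyc_plan(), 1024))
        assert overhead == pytest.approx(100.0 * 33 * 8 / 8192)

    def test_low_exposure_and_angular(self):
        low = AcquisitionPlan(mode="low_exposure", period=8, aperture=1,
                              exposure_fraction=0.125)
        assert dose_fraction(low, 1024) == pytest.approx(12.5)
        ang = AcquisitionPlan(mode="angular_subsampled", period=8, aperture=1,
                              angular_step_keep=8)
        assert dose_fraction(ang, 1024) == pytest.approx(12.5)

    @given(n_train=st.integers(0, 64), n_angles=st.sampled_from([256, 512, 1024]))
    @settings(max_examples=30, derandomize=True)
    def test_training_overhead_is_additive(self, n_train, n_angles):
        base = dose_fraction(cyc_plan(), n_angles)
        with_train = dose_fraction(cyc_plan(n_train=n_train), n_angles)
        overhead = 100.0 * n_train * 8 / (n_angles * 8)
        assert with_train == pytest.approx(base + overhead)
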