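import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kspacesplice import (
    DegenerateDataError,
    InvalidSizeError,
    KSpaceAcquisition,
    apply_gain,
    chained_gain_factor,
    default_partition,
    gain_factor,
    line_groups,
    middle_samples,
)
from kspacesplice.gain import GroupFactors, gain_factor_bruteforce, middle_slice


def _acq(data, gain_db=0.0):
    return KSpaceAcquisition(data=np.asarray(data, complex), gain_db=gain_db)


class TestLineGroups:
    def test_two_groups_with_ceil_labels(self):
        groups = line_groups(range(37, 45))
        assert groups == [(40, (37, 38, 39, 40)), (44, (41, 42, 43, 44))]

    def test_single_block(self):
        assert line_groups([1, 2, 3, 4]) == [(4, (1, 2, 3, 4))]

    def test_size_not_divisible_by_four_rejected(self):
        with pytest.raises(InvalidSizeError):
            line_groups(range(1, 7))

    def test_region_groups_are_multiples_of_four(self):
        part = default_partition(220)
        labels = [g for g, _ in line_groups(part.region3)]
        assert labels == [4 * q for q in range(19, 38)]  # 76, 80, ..., 148


class TestMiddleSamples:
    def test_reference_window_columns(self):
        # K=440, N=120 -> 1-based columns 161..280
        sl = middle_slice(440, 120)
        assert (sl.start + 1, sl.stop) == (161, 280)

    def test_full_line_window(self):
        data = np.arange(12 * 8).reshape(12, 8)
        acq = _acq(data)
        assert np.array_equal(middle_samples(acq, 3, 8), np.abs(data[2]))

    def test_constant_complex_magnitudes(self):
        acq = _acq(np.full((12, 8), 3 + 4j))
        assert np.allclose(middle_samples(acq, 1, 5), 5.0)

    def test_window_larger_than_line_rejected(self):
        acq = _acq(np.zeros((12, 8)))
        with pytest.raises(InvalidSizeError):
            middle_samples(acq, 1, 9)


class TestGainFactor:
    def test_exact_ratio_pair(self, rng):
        B = rng.standard_normal((12, 16)) + 1j * rng.standard_normal((12, 16))
        res = gain_factor(_acq(2 * B), _acq(B), range(1, 13), N=8)
        assert res.betas == pytest.approx([2.0] * 3, abs=1e-12)
        assert res.average == pytest.approx(2.0, abs=1e-12)

    def test_identity_pair(self, rng):
        B = rng.standard_normal((12, 16)) + 1j * rng.standard_normal((12, 16))
        res = gain_factor(_acq(B), _acq(B), range(1, 13), N=16)
        assert res.average == pytest.approx(1.0, abs=1e-12)

    def test_hand_written_toy_matches_bruteforce_oracle(self):
        # 8-line toy pair with integer magnitudes; oracle written independently
        A = np.zeros((12, 6), complex)
        B = np.zeros((12, 6), complex)
        A[3] = [6, 8, 10, 12, 2, 4]  # representative line of group 1 (label 4)
        B[3] = [3, 4, 5, 6, 1, 2]
        A[7] = [9, 3, 6, 3, 9, 6]  # representative of group 2 (label 8)
        B[7] = [3, 1, 2, 1, 3, 3]
        acqA, acqB = _acq(A), _acq(B)
        res = gain_factor(acqA, acqB, range(1, 9), N=6)
        oracle = gain_factor_bruteforce(acqA, acqB, range(1, 9), N=6)
        assert res.labels == oracle.labels == (4, 8)
        assert res.betas == pytest.approx(oracle.betas, abs=1e-14)
        # and by hand: group 4 ratios all 2; group 8 ratios (3,3,3,3,3,2)
        assert res.betas[0] == pytest.approx(2.0)
        assert res.betas[1] == pytest.approx((3 * 5 + 2) / 6)

    @given(seed=st.integers(0, 2**31 - 1), ratio=st.sampled_from([1.5, 2.0, 4.0, 8.0]))
    @settings(max_examples=30, deadline=None)
    def test_vectorized_equals_bruteforce_on_random_instances(self, seed, ratio):
        rng = np.random.default_rng(seed)
        B = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        A = ratio * B + 0.1 * (
            rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        )
        acqA, acqB = _acq(A), _acq(B)
        res = gain_factor(acqA, acqB, range(1, 17), N=12)
        oracle = gain_factor_bruteforce(acqA, acqB, range(1, 17), N=12)
        assert res.labels == oracle.labels
        assert res.betas == pytest.approx(oracle.betas, rel=1e-12)
        assert res.average == pytest.approx(oracle.average, rel=1e-12)

    @pytest.mark.parametrize("ratio", [1.5, 2.0, 4.0, 8.0])
    def test_estimator_consistency_on_noiseless_pairs(self, rng, ratio):
        B = rng.standard_normal((12, 32)) + 1j * rng.standard_normal((12, 32))
        res = gain_factor(_acq(ratio * B), _acq(B), range(1, 13), N=20)
        assert res.average == pytest.approx(ratio, abs=1e-12)

    def test_all_pairs_excluded_names_group(self, rng):
        B = np.zeros((12, 8), complex)
        B[:4] = 1.0  # group 4 fine, group 8 all zero... max=0 -> excluded
        A = 2 * B
        with pytest.raises(DegenerateDataError, match="group 8"):
            gain_factor(_acq(A), _acq(B), range(1, 9), N=8)

    def test_recovery_under_noise_within_five_percent(self, low_noise_study):
        hi, mid, _ = low_noise_study
        part = default_partition(hi.M)
        lines = tuple(sorted(part.region2 + part.region3))
        res = gain_factor(hi, mid, lines, N=120)
        assert res.average == pytest.approx(2.0, rel=0.05)


class TestChainedGainFactor:
    def test_constant_factors(self):
        f1 = GroupFactors(labels=(76, 80), betas=(2.0, 2.0), average=2.0, N=4)
        f2 = GroupFactors(labels=(76, 80), betas=(2.0, 2.0), average=2.0, N=4)
        assert chained_gain_factor(f1, f2) == pytest.approx(4.0)

    def test_per_group_products_averaged(self):
        f1 = GroupFactors(labels=(76, 80), betas=(2.0, 2.0), average=2.0, N=4)
        f2 = GroupFactors(labels=(76, 80), betas=(1.9, 2.1), average=2.0, N=4)
        assert chained_gain_factor(f1, f2) == pytest.approx((3.8 + 4.2) / 2)

    def test_products_use_shared_labels_only(self):
        f1 = GroupFactors(labels=(40, 76, 80), betas=(9.0, 2.0, 2.0), average=0.0, N=4)
        f2 = GroupFactors(labels=(76, 80), betas=(2.0, 2.0), average=2.0, N=4)
        assert chained_gain_factor(f1, f2) == pytest.approx(4.0)

    def test_empty_intersection_rejected(self):
        f1 = GroupFactors(labels=(40,), betas=(2.0,), average=2.0, N=4)
        f2 = GroupFactors(labels=(76,), betas=(2.0,), average=2.0, N=4)
        with pytest.raises(DegenerateDataError):
            chained_gain_factor(f1, f2)


class TestApplyGain:
    def test_identity_factor(self, rng):
        B = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        acq = _acq(B)
        out = apply_gain(acq, range(1, 13), 1.0)
        assert np.array_equal(out.data, acq.data)

    def test_doubling_preserves_phase(self, rng):
        B = rng.standard_normal((12, 8)) + 1j * rng.standard_normal((12, 8))
        acq = _acq(B)
        out = apply_gain(acq, range(5, 9), 2.0)
        sel = slice(4, 8)
        assert np.allclose(np.abs(out.data[sel]), 2 * np.abs(B[sel]))
        assert np.max(np.abs(np.angle(out.data[sel]) - np.angle(B[sel]))) < 1e-12
        # untouched lines unchanged
        assert np.array_equal(out.data[:4], B[:4])

    def test_compensation_closes_the_loop(self, rng):
        B = rng.standard_normal((12, 16)) + 1j * rng.standard_normal((12, 16))
        acqA, acqB = _acq(2 * B), _acq(B)
        factor = gain_factor(acqA, acqB, range(1, 13), N=16).average
        out = apply_gain(acqB, range(1, 13), factor)
        assert np.allclose(out.data, acqA.data, rtol=1e-12)

    def test_nonpositive_factor_rejected(self, rng):
        acq = _acq(rng.standard_normal((12, 8)) + 0j)
        with pytest.raises(ValueError):
            apply_gain(acq, [1], 0.0)
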