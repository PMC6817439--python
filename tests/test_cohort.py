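"""Ground-truth generator and acquisition simulators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperph.cohort import (
    AcquisitionParams,
    DEFAULT_GRADE_PARAMS,
    generate_cohort,
    make_voxel_table,
    simulate_csi,
    simulate_dwi,
    simulate_expression,
    simulate_grase,
)
from hyperph.stats import spearman


class TestCohortStructure:
    def test_study_sized_cohort(self, params):
        lesions = generate_cohort(5, 7, params, seed=1)
        assert len(lesions) == 12
        assert sum(l.grade_label == "low" for l in lesions) == 5
        assert sum(l.grade_label == "high" for l in lesions) == 7

    def test_empty_cohort(self, params):
        assert generate_cohort(0, 0, params, seed=1) == []

    def test_seed_determinism_is_bitwise(self, params):
        a = generate_cohort(2, 2, params, seed=7)
        b = generate_cohort(2, 2, params, seed=7)
        for la, lb in zip(a, b):
            assert np.array_equal(la.ph_field, lb.ph_field)
            assert np.array_equal(la.lacpyr_field, lb.lacpyr_field)
            assert np.array_equal(la.adc_field, lb.adc_field)
            assert la.histology_composition == lb.histology_composition

    def test_different_seeds_differ(self, params):
        a = generate_cohort(1, 0, params, seed=1)[0]
        b = generate_cohort(1, 0, params, seed=2)[0]
        assert not np.array_equal(a.ph_field, b.ph_field)

    def test_grade_contrast_in_group_means(self, params):
        lesions = generate_cohort(8, 8, params, seed=0)
        low = [l for l in lesions if l.grade_label == "low"]
        high = [l for l in lesions if l.grade_label == "high"]
        assert np.mean([l.ph_mean for l in low]) > np.mean([l.ph_mean for l in high])
        assert np.mean([l.adc_roi_mean for l in low]) > np.mean(
            [l.adc_roi_mean for l in high]
        )
        assert np.mean([l.lacpyr_roi_mean for l in low]) < np.mean(
            [l.lacpyr_roi_mean for l in high]
        )

    def test_stratified_sampling_matches_group_mean_exactly(self, params):
        lesions = generate_cohort(5, 7, params, seed=9, sampling="stratified")
        low_means = [l.ph_mean for l in lesions if l.grade_label == "low"]
        high_means = [l.ph_mean for l in lesions if l.grade_label == "high"]
        assert np.mean(low_means) == pytest.approx(
            DEFAULT_GRADE_PARAMS["low"].ph_mean, abs=1e-9
        )
        assert np.mean(high_means) == pytest.approx(
            DEFAULT_GRADE_PARAMS["high"].ph_mean, abs=1e-9
        )

    @given(seed=st.integers(0, 10_000))
    def test_histology_composition_closure(self, seed):
        lesions = generate_cohort(1, 1, seed=seed)
        for lesion in lesions:
            assert sum(lesion.histology_composition.values()) == pytest.approx(
                1.0, abs=1e-9
            )
            assert all(0 <= f <= 1 for f in lesion.histology_composition.values())

    def test_shared_mice(self, params):
        lesions = generate_cohort(5, 7, params, seed=1, shared_mice=2)
        mice = [l.mouse_id for l in lesions]
        assert len(set(mice)) == 10
        with pytest.raises(ValueError):
            generate_cohort(1, 7, params, seed=1, shared_mice=2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionParams(csi_matrix=(0, 8))
        with pytest.raises(ValueError):
            AcquisitionParams(b_values=(0.0, 200.0, 100.0))
        with pytest.raises(ValueError):
            AcquisitionParams(b_values=(100.0, 200.0, 300.0))
        with pytest.raises(ValueError):
            AcquisitionParams(tip_bic_deg=0.0)
        with pytest.raises(ValueError):
            generate_cohort(-1, 0)


class TestCsiSimulator:
    def test_pool_ratio_follows_henderson_hasselbalch(self, low_lesion, params):
        """With equal tips the peak-integral ratio is the pool ratio B/C."""
        lesion = low_lesion
        eq = AcquisitionParams(tip_co2_deg=10.0, tip_bic_deg=10.0)
        lesion_ph7 = generate_uniform_ph_lesion(lesion, 7.0)
        fid = simulate_csi(lesion_ph7, eq, seed=0, pka=6.17, noise_sigma=0.0)
        from hyperph.csi import integrate_peak, reconstruct_csi

        spec = reconstruct_csi(fid, apodization_hz=10.0)
        bic = integrate_peak(spec, eq.freq_bic_hz, 300.0, edge_baseline=True)
        co2 = integrate_peak(spec, eq.freq_co2_hz, 300.0, edge_baseline=True)
        roi = lesion.tumor_fraction >= 0.5
        ratio = bic.value[roi] / co2.value[roi]
        assert np.allclose(ratio, 10.0**0.83, rtol=0.01)  # = 6.761

    def test_equal_pools_at_pka(self, low_lesion):
        eq = AcquisitionParams(tip_co2_deg=10.0, tip_bic_deg=10.0)
        lesion = generate_uniform_ph_lesion(low_lesion, 6.17)
        fid = simulate_csi(lesion, eq, seed=0, pka=6.17, noise_sigma=0.0)
        from hyperph.csi import integrate_peak, reconstruct_csi

        spec = reconstruct_csi(fid, apodization_hz=10.0)
        bic = integrate_peak(spec, eq.freq_bic_hz, 300.0)
        co2 = integrate_peak(spec, eq.freq_co2_hz, 300.0)
        roi = lesion.tumor_fraction >= 0.5
        assert np.allclose(bic.value[roi] / co2.value[roi], 1.0, rtol=0.01)

    def test_unphysiological_ph_rejected(self, low_lesion, params):
        bad = generate_uniform_ph_lesion(low_lesion, 7.9)
        bad.ph_field = bad.ph_field + 1.5  # bypass constructor; simulator checks
        with pytest.raises(ValueError, match="unphysiological"):
            simulate_csi(bad, params, seed=0)

    def test_noise_scaling_doubles_kspace_sd(self, low_lesion, params):
        """Doubling noise_sigma doubles the empirical k-space noise sd."""
        clean = simulate_csi(low_lesion, params, seed=4, noise_sigma=0.0).data
        n1 = simulate_csi(low_lesion, params, seed=4, noise_sigma=0.01).data - clean
        n2 = simulate_csi(low_lesion, params, seed=4, noise_sigma=0.02).data - clean
        assert n1.size >= 10_000
        sd1 = np.std(np.concatenate([n1.real.ravel(), n1.imag.ravel()]))
        sd2 = np.std(np.concatenate([n2.real.ravel(), n2.imag.ravel()]))
        assert sd1 == pytest.approx(0.01, rel=0.05)
        assert sd2 / sd1 == pytest.approx(2.0, rel=0.02)

    @given(ph=st.floats(6.0, 8.0))
    def test_henderson_hasselbalch_inversion_is_exact(self, ph):
        pka = 6.17
        ratio = 10.0 ** (ph - pka)
        assert math.log10(ratio) + pka == pytest.approx(ph, abs=1e-12)


class TestGraseSimulator:
    def test_zero_ratio_field_gives_zero_lactate(self, high_lesion, params):
        lesion = high_lesion
        zero = _with_lacpyr(lesion, 0.0)
        pyr, lac = simulate_grase(zero, params, seed=0, noise_sigma=0.0)
        assert np.all(lac == 0)

    def test_constant_ratio_two_recovered_exactly(self, high_lesion, params):
        lesion = _with_lacpyr(high_lesion, 2.0)
        pyr, lac = simulate_grase(lesion, params, seed=0, noise_sigma=0.0)
        body = pyr > 0
        assert np.allclose(lac[body] / pyr[body], 2.0)

    def test_rician_magnitudes_strictly_positive(self, high_lesion, params):
        pyr, lac = simulate_grase(high_lesion, params, seed=1, noise_sigma=2.0)
        assert np.all(pyr > 0) and np.all(lac > 0)

    def test_negative_ratio_field_rejected(self, high_lesion, params):
        bad = _with_lacpyr(high_lesion, 1.0)
        bad.lacpyr_field[0, 0, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            simulate_grase(bad, params, seed=0)


class TestDwiSimulator:
    def test_noiseless_exponential_decay_value(self, high_lesion, params):
        lesion = _with_adc(high_lesion, 1.0e-3)
        stack = simulate_dwi(lesion, s0=1000.0, params=params, seed=0,
                             noise_sigma=0.0)
        b515 = stack.signal[..., -1][lesion.roi_mask_dwi]
        assert np.allclose(b515, 1000.0 * math.exp(-0.515))  # 597.6

    def test_b0_equals_s0(self, high_lesion, params):
        stack = simulate_dwi(high_lesion, s0=500.0, params=params, seed=0,
                             noise_sigma=0.0)
        assert np.allclose(stack.signal[..., 0], 500.0)

    def test_zero_adc_constant_signal(self, high_lesion, params):
        lesion = _with_adc(high_lesion, 1e-5)
        lesion.adc_field = np.full_like(lesion.adc_field, 1e-12)
        clean = 1000.0 * np.exp(-np.asarray(params.b_values) * 1e-12)
        stack = simulate_dwi(lesion, s0=1000.0, params=params, seed=0,
                             noise_sigma=0.0)
        assert np.allclose(stack.signal, clean[None, None, None, :])

    def test_invalid_inputs_rejected(self, high_lesion, params):
        with pytest.raises(ValueError):
            simulate_dwi(high_lesion, s0=-1.0, params=params, seed=0)


class TestExpression:
    def test_mct4_monotone_decreasing_in_ph(self, params):
        lesions = generate_cohort(1, 1, params, seed=2)
        hi_ph, lo_ph = sorted(lesions, key=lambda l: -l.ph_mean)
        e_hi = simulate_expression(hi_ph, seed=0, noise_sd=0.0)
        e_lo = simulate_expression(lo_ph, seed=0, noise_sd=0.0)
        assert e_lo["Mct4"] > e_hi["Mct4"]

    def test_noiseless_spearman_is_minus_one(self, params):
        lesions = generate_cohort(5, 5, params, seed=8)
        phs, mct4 = [], []
        for lesion in lesions:
            expr = simulate_expression(lesion, seed=0, noise_sd=0.0)
            phs.append(lesion.ph_mean)
            mct4.append(expr["Mct4"])
        rho, _ = spearman(phs, mct4)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_grade_elevation_and_determinism(self, params):
        low, high = generate_cohort(1, 1, params, seed=4)
        e_low = simulate_expression(low, seed=3, noise_sd=0.0)
        e_high = simulate_expression(high, seed=3, noise_sd=0.0)
        for gene in ("Ldha", "Mct1", "Hif1a"):
            assert e_high[gene] > e_low[gene]
        assert simulate_expression(high, seed=3) == simulate_expression(high, seed=3)


def test_voxel_table_structure():
    df = make_voxel_table(n_voxels=153, n_lesions=12, n_mice=10, seed=42)
    assert len(df) == 153
    assert df["lesion_id"].nunique() == 12
    assert df["mouse_id"].nunique() == 10
    assert not df[["lesion_id", "voxel_id"]].duplicated().any()


# ---------------------------------------------------------------------------
# helpers building modified copies of a fixture lesion

def generate_uniform_ph_lesion(lesion, ph):
    import copy

    new = copy.deepcopy(lesion)
    new.ph_field = np.full_like(new.ph_field, ph)
    return new


def _with_lacpyr(lesion, value):
    import copy

    new = copy.deepcopy(lesion)
    new.lacpyr_field = np.full_like(new.lacpyr_field, value)
    return new


def _with_adc(lesion, value):
    import copy

    new = copy.deepcopy(lesion)
    new.adc_field = np.full_like(new.adc_field, value)
    return new
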