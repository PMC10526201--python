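"""Radiobiology primitives: EQD conversion, EUD reduction, LKB probit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntcpkit import (
    DifferentialDVH,
    InvalidArgumentError,
    InvalidPairingError,
    UnknownModelError,
    convert_to_eqd,
    eud,
    get_model,
    lkb_ntcp,
    model_registry,
    ntcp_from_structure,
    physical_dose_for_eqd,
)
from ntcpkit.core import ISOEFFECT_25_FRACTIONS, PER_FRACTION_REF, SINGLE_FRACTION_25GY

from conftest import random_dvh

EXPECTED_PARAMS = {
    # name: (structure, td50, n, m, alpha/beta, scheme kind, ref dose/fraction)
    "dawson_rild": ("liver_minus_gtv", 43.3, 1.1, 0.18, 2.0, PER_FRACTION_REF, 1.5),
    "pursley_albi": ("liver_minus_gtv", 32.0, 2.0, 1.5, 2.5, PER_FRACTION_REF, 2.0),
    "pursley_cp": ("liver_minus_gtv", 19.0, 16.67, 0.8, 2.5, PER_FRACTION_REF, 2.0),
    "pan_gastric_bleed": ("duodenum", 180.0, 0.12, 0.49, 2.5, PER_FRACTION_REF, 2.0),
    "holyoake_g3": ("duodenum", 299.1, 0.193, 0.51, 4.0, ISOEFFECT_25_FRACTIONS, None),
    "murphy_g2_4": ("duodenum", 24.6, 0.12, 0.23, 4.0, SINGLE_FRACTION_25GY, None),
}


def uniform_dvh(dose: float, structure: str = "liver_minus_gtv",
                volume: float = 1000.0) -> DifferentialDVH:
    return DifferentialDVH(structure, np.array([dose]), np.array([volume]), volume)


class TestRegistry:
    def test_six_models_with_published_parameters(self):
        models = {m.name: m for m in model_registry()}
        assert len(models) == 6
        for name, (st_, td50, n, m, ab, kind, dref) in EXPECTED_PARAMS.items():
            mod = models[name]
            assert (mod.structure, mod.td50, mod.n, mod.m, mod.alpha_beta) == \
                (st_, td50, n, m, ab)
            assert mod.ref_scheme.kind == kind
            assert mod.ref_scheme.dose_per_fraction == dref

    def test_three_liver_three_duodenum(self):
        structures = [m.structure for m in model_registry()]
        assert structures.count("liver_minus_gtv") == 3
        assert structures.count("duodenum") == 3

    def test_unknown_name_raises(self):
        with pytest.raises(UnknownModelError):
            get_model("no_such_model")


class TestEQDConversion:
    @pytest.mark.parametrize("dose,model_name,expected", [
        (10.0, "pursley_albi", 10.0),            # 2 Gy/fx at the 2 Gy reference
        (50.0, "dawson_rild", 50.0 * 12.0 / 3.5),  # 10 Gy/fx vs 1.5 Gy ref, a/b=2
        (0.0, "pursley_albi", 0.0),
        (50.0, "murphy_g2_4", 50.0 * 14.0 / 29.0),  # single 25 Gy fraction ref
        (0.0, "holyoake_g3", 0.0),
    ])
    def test_hand_computed_bins(self, dose, model_name, expected):
        dvh = uniform_dvh(dose, get_model(model_name).structure)
        out = convert_to_eqd(dvh, 5, get_model(model_name))
        assert out.bin_dose[0] == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert np.array_equal(out.bin_volume, dvh.bin_volume)

    @pytest.mark.parametrize("model_name", ["dawson_rild", "pursley_albi",
                                            "pursley_cp", "pan_gastric_bleed"])
    @pytest.mark.parametrize("n_fractions", [1, 3, 5, 25])
    def test_identity_when_fraction_dose_equals_reference(self, model_name, n_fractions):
        model = get_model(model_name)
        dose = model.ref_scheme.dose_per_fraction * n_fractions
        out = convert_to_eqd(uniform_dvh(dose, model.structure), n_fractions, model)
        assert out.bin_dose[0] == pytest.approx(dose, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dose=st.floats(0.0, 120.0), n_fractions=st.integers(1, 30))
    def test_isoeffect_root_satisfies_lq_equation(self, dose, n_fractions):
        model = get_model("holyoake_g3")
        ab = model.alpha_beta
        out = convert_to_eqd(uniform_dvh(dose, "duodenum"), n_fractions, model)
        x = out.bin_dose[0]
        lhs = x * (x / 25.0 + ab)
        rhs = dose * (dose / n_fractions + ab)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_hand_computed_isoeffect_bin(self):
        # 50 Gy in 5 fx, a/b = 4: X solves X(X/25 + 4) = 50 * 14 = 700
        out = convert_to_eqd(uniform_dvh(50.0, "duodenum"), 5, get_model("holyoake_g3"))
        assert out.bin_dose[0] == pytest.approx(12.5 * (-4 + math.sqrt(16 + 4 * 700 / 25)),
                                                rel=1e-12)

    def test_rejects_nonpositive_fraction_count(self):
        with pytest.raises(InvalidArgumentError):
            convert_to_eqd(uniform_dvh(10.0), 0, get_model("dawson_rild"))

    @pytest.mark.parametrize("model_name", list(EXPECTED_PARAMS))
    def test_physical_dose_inversion_roundtrip(self, model_name):
        model = get_model(model_name)
        physical = physical_dose_for_eqd(model.td50, 5, model)
        out = convert_to_eqd(uniform_dvh(physical, model.structure), 5, model)
        assert out.bin_dose[0] == pytest.approx(model.td50, rel=1e-12)


class TestEUD:
    @pytest.mark.parametrize("n", [0.05, 0.12, 1.0, 2.0, 16.67])
    def test_uniform_dose_is_fixed_point(self, n):
        assert eud(uniform_dvh(30.0), n) == pytest.approx(30.0, rel=1e-9)

    def test_n_equal_one_is_mean(self):
        dvh = DifferentialDVH("x", np.array([10.0, 30.0]), np.array([50.0, 50.0]), 100.0)
        assert eud(dvh, 1.0) == pytest.approx(20.0, rel=1e-12)

    def test_small_n_approaches_near_max(self):
        dvh = DifferentialDVH("x", np.array([10.0, 30.0]), np.array([50.0, 50.0]), 100.0)
        expected = (0.5 * 10.0 ** (1 / 0.12) + 0.5 * 30.0 ** (1 / 0.12)) ** 0.12
        value = eud(dvh, 0.12)
        assert value == pytest.approx(expected, rel=1e-9)
        assert value > 27.0

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_mean_dose_oracle_at_n_one(self, seed):
        dvh = random_dvh(np.random.default_rng(seed))
        direct = float(np.sum(dvh.bin_dose * dvh.bin_volume) / dvh.total_volume)
        assert eud(dvh, 1.0) == pytest.approx(direct, rel=1e-9)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.floats(0.05, 20.0))
    def test_bounded_by_nonzero_volume_doses(self, seed, n):
        dvh = random_dvh(np.random.default_rng(seed))
        nz = dvh.bin_dose[dvh.bin_volume > 0]
        value = eud(dvh, n)
        assert nz.min() - 1e-9 <= value <= nz.max() * (1 + 1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.floats(0.05, 20.0),
           shift=st.floats(0.1, 20.0))
    def test_monotone_under_uniform_dose_shift(self, seed, n, shift):
        dvh = random_dvh(np.random.default_rng(seed))
        shifted = dvh.with_doses(dvh.bin_dose + shift)
        assert eud(shifted, n) >= eud(dvh, n) - 1e-9

    def test_no_overflow_for_extreme_volume_exponents(self):
        dvh = DifferentialDVH("x", np.array([1.0, 400.0]), np.array([99.0, 1.0]), 100.0)
        for n in (0.05, 16.67):
            value = eud(dvh, n)
            assert np.isfinite(value)

    def test_zero_volume_rejected(self):
        dvh = DifferentialDVH("x", np.array([1.0]), np.array([0.0]), 0.0)
        with pytest.raises(InvalidArgumentError):
            eud(dvh, 1.0)


def _gauss_cdf_trapezoid(t: float, lo: float = -8.0, steps: int = 400_000) -> float:
    x = np.linspace(lo, t, steps)
    pdf = np.exp(-x * x / 2.0) / math.sqrt(2.0 * math.pi)
    return float(np.trapezoid(pdf, x))


class TestLKBProbit:
    @pytest.mark.parametrize("model_name", list(EXPECTED_PARAMS))
    def test_half_probability_at_td50(self, model_name):
        model = get_model(model_name)
        assert lkb_ntcp(model.td50, model).probability == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("model_name", list(EXPECTED_PARAMS))
    def test_one_sigma_above_td50(self, model_name):
        model = get_model(model_name)
        value = lkb_ntcp(model.td50 * (1 + model.m), model).probability
        assert value == pytest.approx(0.8413447460685429, abs=1e-9)

    def test_positive_baseline_at_zero_dose(self):
        cp = get_model("pursley_cp")
        assert lkb_ntcp(0.0, cp).probability == pytest.approx(
            _gauss_cdf_trapezoid(-1.0 / cp.m), abs=1e-6)
        assert lkb_ntcp(0.0, cp).probability > 0

    @pytest.mark.parametrize("eud_frac", [0.0, 0.5, 0.9, 1.0, 1.3, 2.0])
    def test_matches_trapezoid_gaussian_oracle(self, eud_frac):
        model = get_model("pan_gastric_bleed")
        e = model.td50 * eud_frac
        t = (e - model.td50) / (model.m * model.td50)
        assert lkb_ntcp(e, model).probability == pytest.approx(
            _gauss_cdf_trapezoid(t), abs=1e-6)

    def test_strictly_increasing_in_eud(self):
        model = get_model("dawson_rild")
        probs = [lkb_ntcp(e, model).probability for e in np.linspace(0, 80, 50)]
        assert np.all(np.diff(probs) > 0)


class TestNTCPFromStructure:
    @pytest.mark.parametrize("model_name", list(EXPECTED_PARAMS))
    def test_zero_dose_gives_baseline(self, model_name):
        model = get_model(model_name)
        dvh = uniform_dvh(0.0, model.structure)
        result = ntcp_from_structure(dvh, model, 5)
        assert result.probability == pytest.approx(
            lkb_ntcp(0.0, model).probability, abs=1e-12)

    @pytest.mark.parametrize("model_name", list(EXPECTED_PARAMS))
    def test_uniform_td50_equivalent_dose_gives_half(self, model_name):
        model = get_model(model_name)
        dose = physical_dose_for_eqd(model.td50, 5, model)
        result = ntcp_from_structure(uniform_dvh(dose, model.structure), model, 5)
        assert result.probability == pytest.approx(0.5, abs=1e-9)

    def test_rbe_weighting_increases_probability(self):
        model = get_model("pan_gastric_bleed")
        dvh = uniform_dvh(30.0, "duodenum")
        p_photon = ntcp_from_structure(dvh, model, 5, rbe_factor=1.0).probability
        p_proton = ntcp_from_structure(dvh, model, 5, rbe_factor=1.1).probability
        assert p_proton > p_photon

    def test_structure_mismatch_rejected(self):
        with pytest.raises(InvalidPairingError):
            ntcp_from_structure(uniform_dvh(10.0, "duodenum"),
                                get_model("dawson_rild"), 5)


class TestDVHValidation:
    def test_volume_sum_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            DifferentialDVH("x", np.array([1.0]), np.array([2.0]), 5.0)

    def test_non_increasing_doses_rejected(self):
        with pytest.raises(InvalidArgumentError):
            DifferentialDVH("x", np.array([2.0, 1.0]), np.array([1.0, 1.0]), 2.0)

    def test_negative_values_rejected(self):
        with pytest.raises(InvalidArgumentError):
            DifferentialDVH("x", np.array([-1.0, 1.0]), np.array([1.0, 1.0]), 2.0)
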