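"""Vector-model arithmetic: worked examples and algebraic invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odormix import (
    FamilyModel,
    Odorant,
    OdorSample,
    OIRScale,
    PsychophysicalLaw,
    compute_oav,
    cos_alpha_from_measurement,
    cos_alpha_from_slope,
    mixture_oi_binary,
    mixture_oi_n,
    nearest_oirs_level,
    oi_single,
    oirs_concentration,
    predict_mixture_oi,
    slope_from_cos_alpha,
)

ALDEHYDE_LAW = PsychophysicalLaw(k=5.6, b=-5.6)
ESTER_LAW = PsychophysicalLaw(k=1.4, b=-2.7)

oi_values = st.floats(min_value=0, max_value=100, allow_nan=False)
cos_values = st.floats(min_value=-1, max_value=1, allow_nan=False)


class TestOav:
    def test_examples(self, registry):
        assert compute_oav(0.39, registry.get("A")) == pytest.approx(10.0)
        assert compute_oav(0.0, registry.get("A")) == 0.0
        assert compute_oav(0.052, registry.get("B")) == pytest.approx(1.0)

    def test_negative_concentration_rejected(self, registry):
        with pytest.raises(ValueError):
            compute_oav(-0.1, registry.get("A"))

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            Odorant(name="x", cas="0-0-0", odor_threshold=0.0)


class TestSingleIntensity:
    def test_aldehyde_example(self, registry):
        # OAV = 10 -> 5.6*ln(10) - 5.6
        assert oi_single(0.39, registry.get("A"), ALDEHYDE_LAW) == pytest.approx(
            5.6 * math.log(10) - 5.6, abs=1e-9
        )

    def test_clamped_at_threshold(self, registry):
        # OAV = 1 -> ln OAV = 0 -> OI = b < 0 -> clamp
        assert oi_single(0.052, registry.get("B"), ALDEHYDE_LAW) == 0.0

    def test_ester_law_example(self, registry):
        od = registry.get("EA")
        conc = od.odor_threshold * math.exp(2.0)
        assert oi_single(conc, od, ESTER_LAW) == pytest.approx(0.1, abs=1e-9)

    def test_zero_concentration(self, registry):
        assert oi_single(0.0, registry.get("A"), ALDEHYDE_LAW) == 0.0

    def test_law_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            PsychophysicalLaw(k=0.0, b=1.0)


class TestMixtureSummation:
    @pytest.mark.parametrize(
        "oi_a, oi_b, c, expected",
        [
            (5, 5, 1, 10.0),
            (3, 4, 0, 5.0),
            (5, 5, 2 * 0.62**2 - 1, 6.2),
        ],
    )
    def test_binary_examples(self, oi_a, oi_b, c, expected):
        assert mixture_oi_binary(oi_a, oi_b, c) == pytest.approx(expected, abs=1e-9)

    def test_ternary_examples(self):
        assert mixture_oi_n([5, 5, 5], 0) == pytest.approx(math.sqrt(75), abs=1e-4)
        c = 2 * 0.62**2 - 1
        assert mixture_oi_n([5, 5, 5], c) == pytest.approx(
            math.sqrt(25 * (3 + 6 * c)), abs=1e-9
        )

    def test_singleton_and_empty(self):
        assert mixture_oi_n([7.25], 0.3) == 7.25
        with pytest.raises(ValueError):
            mixture_oi_n([], 0.0)

    def test_cos_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_oi_binary(1, 1, 1.5)

    def test_full_counteraction_clamps_with_warning(self):
        # many components at cos_alpha = -1: radicand goes negative
        with pytest.warns(RuntimeWarning):
            assert mixture_oi_n([5, 5, 5], -1.0) == 0.0

    @given(oi_values, oi_values, cos_values)
    @settings(max_examples=200, deadline=None)
    def test_norm_bounds(self, a, b, c):
        mix = mixture_oi_binary(a, b, c)
        assert abs(a - b) - 1e-9 <= mix <= a + b + 1e-9

    @given(oi_values, oi_values)
    @settings(max_examples=50, deadline=None)
    def test_bounds_attained_at_extremes(self, a, b):
        assert mixture_oi_binary(a, b, 1.0) == pytest.approx(a + b, abs=1e-6)
        assert mixture_oi_binary(a, b, -1.0) == pytest.approx(abs(a - b), abs=1e-6)

    @given(st.lists(oi_values, min_size=1, max_size=6), cos_values, st.randoms())
    @settings(max_examples=100, deadline=None)
    def test_permutation_symmetry(self, ois, c, rnd):
        shuffled = list(ois)
        rnd.shuffle(shuffled)
        assert mixture_oi_n(ois, c) == pytest.approx(
            mixture_oi_n(shuffled, c), rel=1e-12, abs=1e-12
        )

    @given(st.lists(oi_values, min_size=1, max_size=5), cos_values)
    @settings(max_examples=100, deadline=None)
    def test_zero_component_drops_out(self, ois, c):
        assert mixture_oi_n(ois + [0.0], c) == pytest.approx(
            mixture_oi_n(ois, c), rel=1e-12, abs=1e-12
        )

    @given(oi_values, oi_values, cos_values)
    @settings(max_examples=100, deadline=None)
    def test_binary_matches_literal_quadratic_form(self, a, b, c):
        """Oracle: the binary summation is the literal two-vector norm."""
        radicand = a**2 + b**2 + 2 * c * a * b
        expected = math.sqrt(max(radicand, 0.0))
        assert mixture_oi_binary(a, b, c) == pytest.approx(expected, abs=1e-12)

    @given(oi_values, oi_values, oi_values, cos_values)
    @settings(max_examples=100, deadline=None)
    def test_ternary_matches_literal_quadratic_form(self, a, b, c, m):
        """Oracle: n=3 equals the written-out three-vector expansion with a
        shared interaction coefficient."""
        radicand = a**2 + b**2 + c**2 + 2 * m * (a * b + a * c + b * c)
        expected = math.sqrt(max(radicand, 0.0))
        assert mixture_oi_n([a, b, c], m) == pytest.approx(expected, abs=1e-9)

    @given(st.lists(oi_values, min_size=2, max_size=6), cos_values)
    @settings(max_examples=100, deadline=None)
    def test_non_negative(self, ois, c):
        assert mixture_oi_n(ois, c) >= 0


class TestInteractionCoefficient:
    @pytest.mark.parametrize(
        "oi_ab, oi_a, oi_b, expected",
        [(10, 5, 5, 1.0), (5, 3, 4, 0.0), (6.2, 5, 5, -0.2312)],
    )
    def test_from_measurement(self, oi_ab, oi_a, oi_b, expected):
        assert cos_alpha_from_measurement(oi_ab, oi_a, oi_b) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError):
            cos_alpha_from_measurement(5, 0, 5)

    @pytest.mark.parametrize(
        "s, expected",
        [
            (1.0, 1.0),
            (1 / math.sqrt(2), 0.0),
            (0.62, -0.2312),
            (0.79, 0.2482),
        ],
    )
    def test_from_slope(self, s, expected):
        assert cos_alpha_from_slope(s) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.01])
    def test_slope_domain(self, bad):
        with pytest.raises(ValueError):
            cos_alpha_from_slope(bad)

    @pytest.mark.parametrize(
        "c, expected", [(1.0, 1.0), (0.0, 1 / math.sqrt(2)), (-0.2312, 0.62)]
    )
    def test_slope_from_cos_alpha(self, c, expected):
        assert slope_from_cos_alpha(c) == pytest.approx(expected, abs=1e-9)

    def test_slope_from_cos_alpha_domain(self):
        with pytest.raises(ValueError):
            slope_from_cos_alpha(-1.0)

    @given(st.floats(min_value=1e-3, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, s):
        # cancellation in 1 + cosα caps attainable precision for small s
        assert slope_from_cos_alpha(cos_alpha_from_slope(s)) == pytest.approx(
            s, rel=1e-9
        )

    @given(
        st.floats(min_value=1e-3, max_value=50),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_slope_identity(self, o, s):
        """Equal components o mixed under cosα = 2s² − 1 give exactly 2·s·o,
        i.e. the mixture lies on the OI_mix = s·OI_sum line."""
        assert mixture_oi_binary(o, o, cos_alpha_from_slope(s)) == pytest.approx(
            2 * s * o, rel=1e-9
        )


class TestPredictMixture:
    def test_binary_from_concentrations(self, aldehyde_family):
        sample = OdorSample({"Acetaldehyde": 0.39, "Propionaldehyde": 0.41})
        expected = 2 * 0.62 * (5.6 * math.log(10) - 5.6)
        assert predict_mixture_oi(sample, aldehyde_family) == pytest.approx(
            expected, abs=1e-6
        )
        # abbreviations resolve to the same members
        assert predict_mixture_oi(
            OdorSample({"A": 0.39, "P": 0.41}), aldehyde_family
        ) == pytest.approx(expected, abs=1e-6)

    def test_single_constituent_reduces_to_law(self, aldehyde_family, registry):
        sample = OdorSample({"A": 0.39})
        assert predict_mixture_oi(sample, aldehyde_family) == pytest.approx(
            oi_single(0.39, registry.get("A"), aldehyde_family.law)
        )

    def test_all_at_threshold_gives_zero(self, aldehyde_family):
        sample = OdorSample({"A": 0.039, "P": 0.041})
        assert predict_mixture_oi(sample, aldehyde_family) == 0.0

    def test_non_member_rejected(self, aldehyde_family):
        with pytest.raises(KeyError):
            predict_mixture_oi(OdorSample({"EA": 0.5}), aldehyde_family)

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            OdorSample({})
        with pytest.raises(ValueError):
            OdorSample({"A": -1.0})


class TestOirs:
    def test_twelve_point_scale_levels(self):
        scale = OIRScale(base_concentration=10, ratio=2, n_levels=12)
        assert oirs_concentration(1, scale) == 10
        assert oirs_concentration(8, scale) == 1280
        assert oirs_concentration(12, scale) == 20480

    def test_eight_point_scale(self):
        scale = OIRScale(base_concentration=12, ratio=2, n_levels=8)
        assert oirs_concentration(3, scale) == 48

    def test_level_out_of_range(self):
        scale = OIRScale(base_concentration=10, ratio=2, n_levels=12)
        for bad in (0, 13):
            with pytest.raises(ValueError):
                oirs_concentration(bad, scale)

    @pytest.mark.parametrize("level", range(1, 12))
    def test_geometric_progression(self, level):
        scale = OIRScale(base_concentration=10, ratio=2, n_levels=12)
        assert oirs_concentration(level + 1, scale) / oirs_concentration(
            level, scale
        ) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "oi, res, expected", [(7.2945, 0.5, 7.5), (7.2945, 1.0, 7.0), (0.25, 0.5, 0.5)]
    )
    def test_quantization(self, oi, res, expected):
        assert nearest_oirs_level(oi, res) == pytest.approx(expected)
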