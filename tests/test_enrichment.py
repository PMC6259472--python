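"""Natural-abundance correction and tracer:tracee deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cklabel.compounds import REGISTRY, Form, diagnostic_transitions
from cklabel.elements import parse_formula
from cklabel.enrichment import (
    IsotopomerMeasurement,
    SaturatedLabelingError,
    TracerTraceeModel,
    correction_matrix,
    deconvolve,
    replicate_stats,
    tracer_tracee_ratio,
)
from cklabel.isotope_pattern import natural_pattern, relative_to_monoisotopic

from conftest import enumerate_pattern

IP_FRAGMENT = parse_formula("C10H14N5+")   # iPR/pro-iPR product ion
PRODUCT_IONS = [
    diagnostic_transitions(c, derivatized=d).product_formula
    for c in REGISTRY.values()
    if c.form is Form.RIBOSIDE
    for d in (False, True)
]


def measurement(areas, fragment=IP_FRAGMENT, analyte="pro-iPR", rep="r1"):
    return IsotopomerMeasurement(
        analyte=analyte, replicate=rep, areas=tuple(areas),
        product_formula=fragment,
    )


class TestCorrectionMatrix:
    def test_window_zero_is_scalar_one(self):
        np.testing.assert_allclose(correction_matrix(IP_FRAGMENT, k=0), [[1.0]])

    def test_label_only_fragment_gives_identity(self):
        # D and P have a single isotope: delta pattern, identity matrix
        np.testing.assert_allclose(
            correction_matrix(parse_formula("D6P2"), k=3), np.eye(4)
        )

    def test_first_subdiagonal_matches_enumeration(self):
        C = correction_matrix(IP_FRAGMENT, k=3)
        oracle = enumerate_pattern(IP_FRAGMENT, k=3)
        assert C[1, 0] == pytest.approx(oracle[1] / oracle[0], abs=1e-10)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, np.tril(C))

    def test_columns_are_shifted_copies(self):
        C = correction_matrix(IP_FRAGMENT, k=3)
        r = relative_to_monoisotopic(natural_pattern(IP_FRAGMENT, k=3))
        for j in range(4):
            np.testing.assert_allclose(C[j:, j], r[: 4 - j])

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            correction_matrix(IP_FRAGMENT, k=-1)


class TestDeconvolve:
    @pytest.mark.parametrize("estimator", ["nnls", "subtraction"])
    @pytest.mark.parametrize(
        "x_true", [(1, 0, 0, 0), (2, 1, 0, 0), (1.0, 0.3, 0.05, 0.01)]
    )
    def test_noiseless_round_trip(self, estimator, x_true):
        C = correction_matrix(IP_FRAGMENT, k=3)
        I = C @ np.asarray(x_true, dtype=float)
        x, residual = deconvolve(measurement(I), estimator=estimator)
        np.testing.assert_allclose(x, x_true, atol=1e-9)
        assert residual < 1e-9

    @pytest.mark.parametrize("fragment", PRODUCT_IONS, ids=str)
    def test_estimators_agree_noiseless(self, fragment):
        C = correction_matrix(fragment, k=3)
        I = C @ np.array([1.0, 0.4, 0.1, 0.02])
        x_nnls, _ = deconvolve(measurement(I, fragment), estimator="nnls")
        x_sub, _ = deconvolve(measurement(I, fragment), estimator="subtraction")
        np.testing.assert_allclose(x_nnls, x_sub, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            measurement([0, 0, 0, 0])

    def test_noisy_recovery_median_within_3pct(self):
        # CV 1% multiplicative noise; median relative error over 1000 draws
        rng = np.random.default_rng(20101215)
        C = correction_matrix(IP_FRAGMENT, k=3)
        errors = []
        for _ in range(1000):
            x_true = rng.uniform(0.05, 1.0, size=4)
            x_true[0] = 1.0
            I = C @ x_true
            I = I * (1 + 0.01 * rng.standard_normal(4))
            x, _ = deconvolve(measurement(np.clip(I, 0, None)))
            errors.append(np.median(np.abs(x - x_true) / x_true))
        assert np.median(errors) < 0.03


class TestRatioAndStats:
    @pytest.mark.parametrize(
        "x, tt", [((1, 0, 0, 0), 0.0), ((2, 1, 0, 0), 0.5), ((1, 1, 1, 1), 3.0)]
    )
    def test_ratio_arithmetic(self, x, tt):
        assert tracer_tracee_ratio(np.asarray(x, float)) == pytest.approx(tt)

    def test_saturated_labeling_flagged(self):
        with pytest.raises(SaturatedLabelingError):
            tracer_tracee_ratio(np.array([0.0, 1.0, 0.0, 0.0]))

    @pytest.mark.parametrize(
        "values, mean, sd",
        [([1, 1, 1], 1.0, 0.0), ([1.0, 2.0], 1.5, 0.7071)],
    )
    def test_replicate_closed_forms(self, values, mean, sd):
        m, s = replicate_stats(values)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sd, abs=1e-4)

    def test_single_replicate_has_no_sd(self):
        assert replicate_stats([1.3]) == (pytest.approx(1.3), None)

    def test_cv_recovered_within_chi2_factor(self):
        # 5 replicates at CV 10%: SD/mean within a factor 2 of 0.10
        rng = np.random.default_rng(42)
        ratios = 1.5 * (1 + 0.10 * rng.standard_normal(5))
        mean, sd = replicate_stats(ratios)
        assert 0.05 < sd / mean < 0.20


class TestInvariants:
    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=4, max_size=4),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, areas, scale):
        x1, _ = deconvolve(measurement(areas))
        x2, _ = deconvolve(measurement(np.asarray(areas) * scale))
        if x1[0] > 0 and x2[0] > 0:
            assert tracer_tracee_ratio(x1) == pytest.approx(
                tracer_tracee_ratio(x2), rel=1e-9, abs=1e-12
            )

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=2.0), min_size=4,
                 max_size=4),
        st.integers(min_value=1, max_value=3),
        st.floats(min_value=0.0, max_value=0.2),
        st.floats(min_value=1.0, max_value=1e6),
    )
    def test_adding_labeled_signal_never_decreases_tt(
        self, x_true, j, extra, scale
    ):
        # on measurements consistent with the mixing model the NNLS
        # solution is interior, where extra signal in a labeled channel
        # (holding I0) provably raises t/t; wildly inconsistent vectors
        # can pin classes at zero, where the ordering is only
        # solver-tolerance sharp
        C = correction_matrix(IP_FRAGMENT, k=3)
        areas = (C @ np.asarray(x_true)) * scale
        x1, _ = deconvolve(measurement(areas))
        bumped = areas.copy()
        bumped[j] += extra * scale
        x2, _ = deconvolve(measurement(bumped))
        assert tracer_tracee_ratio(x2) >= tracer_tracee_ratio(x1) - 1e-9

    def test_zero_enrichment_fixed_point(self):
        # feeding the fragment's own natural pattern returns t/t = 0
        for fragment in PRODUCT_IONS:
            r = relative_to_monoisotopic(natural_pattern(fragment, k=3))
            x, _ = deconvolve(measurement(r * 1e6, fragment))
            assert tracer_tracee_ratio(x) <= 1e-9

    def test_window_consistency(self):
        # labels confined to <= +3: widening the window leaves t/t unchanged
        x_true = np.array([1.0, 0.4, 0.1, 0.02, 0.0, 0.0])
        for k in (3, 4, 5):
            C = correction_matrix(IP_FRAGMENT, k=k)
            I = C @ x_true[: k + 1]
            x, _ = deconvolve(measurement(I), k=k)
            assert tracer_tracee_ratio(x) == pytest.approx(
                tracer_tracee_ratio(x_true), abs=1e-9
            )


class TestModelResults:
    def _measurements(self, n=3, tt=0.5):
        C = correction_matrix(IP_FRAGMENT, k=3)
        I = C @ np.array([1.0, tt, 0.0, 0.0])
        return [measurement(I * 1e5, rep=f"r{i}") for i in range(n)]

    def test_fit_and_summary(self):
        results = TracerTraceeModel(self._measurements()).fit()
        assert results.tt == pytest.approx(0.5, abs=1e-9)
        assert results.tt_sd == pytest.approx(0.0, abs=1e-12)
        assert results.n_replicates == 3
        text = results.summary()
        assert "pro-iPR" in text and "0.5000" in text and "nnls" in text

    def test_from_dataframe(self):
        import pandas as pd

        rows = [
            {"analyte": m.analyte, "replicate": m.replicate,
             **{f"I{j}": a for j, a in enumerate(m.areas)}}
            for m in self._measurements()
        ]
        model = TracerTraceeModel.from_dataframe(pd.DataFrame(rows), IP_FRAGMENT)
        assert model.fit().tt == pytest.approx(0.5, abs=1e-9)

    def test_mixed_analytes_rejected(self):
        bad = self._measurements() + [
            measurement([1e5, 1e4, 1e3, 1e2], analyte="iPR")
        ]
        with pytest.raises(ValueError, match="one analyte"):
            TracerTraceeModel(bad)

    def test_condition_number_reported(self):
        results = TracerTraceeModel(self._measurements()).fit()
        assert 1.0 <= results.condition_number < 2.0
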