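"""Scattering model evaluation, fitting and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesokit.curves import ScatteringCurve, read_curve, write_curve
from mesokit.sans import (
    BroadPeakParams,
    CorrLengthParams,
    FitConvergenceError,
    d_spacing,
    eval_broad_peak,
    eval_broad_peak_corrlen,
    eval_corrlen,
    fit_curve,
    scaling_exponent_from_m,
)


def oracle_broad_peak(p, q):
    """Independent transcription of the two-peak broad peak model."""
    return (
        p["C0"] / (1 + (p["xi0"] * abs(q - p["q0"])) ** p["m0"])
        + p["C1"] / (1 + (p["Xi1"] * abs(q - p["q1"])) ** p["m1"])
        + p["B"]
    )


def oracle_broad_peak_corrlen(p, q):
    return (
        p["C0"] / (1 + (p["xi0"] * abs(q - p["q0"])) ** p["m0"])
        + p["C1"] / (1 + (p["Xi1"] * q) ** p["m1"])
        + p["B"]
    )


def oracle_corrlen(p, q):
    return p["C0"] / (1 + (p["xi0"] * q) ** p["m0"]) + p["B"]


class TestModelEvaluation:
    def test_both_peaks_at_maximum(self):
        p = BroadPeakParams(C0=2.0, xi0=30, q0=0.05, m0=2, C1=3.0, Xi1=50, m1=2, B=0.5, q1=0.05)
        assert eval_broad_peak(p, np.array([0.05]))[0] == pytest.approx(2.0 + 3.0 + 0.5)

    def test_first_term_halved_at_reciprocal_width(self):
        # (xi0 * |q-q0|)^2 = 1 halves the first term
        p = BroadPeakParams(C0=1.0, xi0=10, q0=0.2, m0=2, C1=0.0, Xi1=50, m1=2, B=0.1, q1=0.4)
        assert eval_broad_peak(p, np.array([0.3]))[0] == pytest.approx(0.6)

    def test_corrlen_term_limits(self):
        # q -> 0: the correlation term of the mixed model tends to C1
        p = BroadPeakParams(C0=1.0, xi0=85, q0=0.035, m0=1.5, C1=1.0, Xi1=160, m1=2.9, B=0.0)
        tiny = eval_broad_peak_corrlen(p, np.array([1e-12]))[0]
        peak0 = 1.0 / (1 + (85 * abs(1e-12 - 0.035)) ** 1.5)
        assert tiny == pytest.approx(peak0 + 1.0, rel=1e-9)
        # (Xi1 q) = 1 halves the correlation term
        p2 = BroadPeakParams(C0=0.0, xi0=85, q0=0.035, m0=1.5, C1=2.0, Xi1=100, m1=2, B=0.0)
        assert eval_broad_peak_corrlen(p2, np.array([0.01]))[0] == pytest.approx(1.0)

    def test_corrlen_examples(self):
        p = CorrLengthParams(C0=1.0, xi0=60, m0=2, B=0.0)
        assert eval_corrlen(p, np.array([1 / 60]))[0] == pytest.approx(0.5)
        p2 = CorrLengthParams(C0=1.0, xi0=60, m0=2, B=0.25)
        assert eval_corrlen(p2, np.array([1e-15]))[0] == pytest.approx(1.25)

    @pytest.mark.parametrize("model", ["broadpeak", "broadpeak-cl", "corrlen"])
    def test_against_independent_transcription(self, model):
        rng = np.random.default_rng(42)
        for _ in range(10):
            q = np.sort(rng.uniform(0.004, 0.45, 50))
            pd = {
                "C0": rng.uniform(0.1, 5),
                "xi0": rng.uniform(5, 200),
                "q0": rng.uniform(0.01, 0.3),
                "m0": rng.uniform(0.5, 4),
                "C1": rng.uniform(0.1, 5),
                "Xi1": rng.uniform(5, 400),
                "m1": rng.uniform(0.5, 4),
                "B": rng.uniform(0, 0.5),
                "q1": rng.uniform(0.01, 0.3),
            }
            if model == "corrlen":
                p = CorrLengthParams(pd["C0"], pd["xi0"], pd["m0"], pd["B"])
                got = eval_corrlen(p, q)
                want = oracle_corrlen(pd, q)
            elif model == "broadpeak":
                p = BroadPeakParams(**pd)
                got = eval_broad_peak(p, q)
                want = oracle_broad_peak(pd, q)
            else:
                pd2 = {k: v for k, v in pd.items() if k != "q1"}
                p = BroadPeakParams(**pd2)
                got = eval_broad_peak_corrlen(p, q)
                want = oracle_broad_peak_corrlen(pd2 | {"q1": 0}, q)
            assert np.max(np.abs(got - want)) < 1e-12

    def test_rejects_bad_inputs(self):
        p = CorrLengthParams(1.0, 60.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            eval_corrlen(p, np.array([-0.1, 0.2]))
        with pytest.raises(ValueError):
            eval_corrlen(CorrLengthParams(1.0, np.nan, 2.0, 0.0), np.array([0.1]))
        with pytest.raises(ValueError):
            eval_corrlen(CorrLengthParams(1.0, 60.0, -1.0, 0.0), np.array([0.1]))

    def test_intensity_floor_is_background(self):
        rng = np.random.default_rng(7)
        q = np.geomspace(0.004, 0.45, 60)
        for _ in range(5):
            p = CorrLengthParams(rng.uniform(0, 3), rng.uniform(1, 100), rng.uniform(0.5, 3), 0.2)
            assert np.all(eval_corrlen(p, q) >= 0.2)


class TestDerivedQuantities:
    def test_d_spacing_examples(self):
        assert d_spacing(0.034907) == pytest.approx(180.0, abs=0.01)
        assert d_spacing(2 * np.pi) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            d_spacing(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_d_spacing_involution(self, x):
        assert d_spacing(d_spacing(x)) == pytest.approx(x, rel=1e-12)
        assert d_spacing(x) * x == pytest.approx(2 * np.pi, rel=1e-12)

    def test_scaling_exponent(self):
        assert scaling_exponent_from_m(1.515) == pytest.approx(0.660, abs=5e-4)
        assert scaling_exponent_from_m(1.0) == 1.0
        assert scaling_exponent_from_m(2.0) == 0.5
        with pytest.raises(ValueError):
            scaling_exponent_from_m(0.0)


class TestFitting:
    q = np.geomspace(0.004, 0.45, 100)

    @pytest.mark.parametrize(
        "model,params",
        [
            ("corrlen", CorrLengthParams(C0=1.0, xi0=60.0, m0=2.0, B=0.05)),
            (
                "broadpeak-cl",
                BroadPeakParams(
                    C0=1.0, xi0=85.0, q0=2 * np.pi / 180, m0=1 / 0.66,
                    C1=10.0, Xi1=160.0, m1=1 / 0.35, B=0.01,
                ),
            ),
            (
                "broadpeak",
                BroadPeakParams(
                    C0=2.0, xi0=85.0, q0=0.035, m0=1.5,
                    C1=1.0, Xi1=120.0, m1=2.0, B=0.02, q1=0.015,
                ),
            ),
        ],
    )
    def test_noiseless_recovery(self, model, params):
        """Fitting model-generated data recovers the generating parameters."""
        from mesokit.sans import _model_eval

        ideal = _model_eval(model, params, self.q)
        curve = ScatteringCurve(self.q, ideal, 0.01 * ideal)
        fit = fit_curve(curve, model, seed=0)
        for name, err in fit.uncertainties.items():
            true = getattr(params, name)
            got = getattr(fit.params, name)
            assert got == pytest.approx(true, rel=1e-6), name
            assert err >= 0

    def test_flat_curve_reduces_to_background(self):
        curve = ScatteringCurve(self.q, np.full_like(self.q, 0.7), np.full_like(self.q, 0.007))
        fit = fit_curve(curve, "corrlen", seed=0)
        assert fit.params.C0 == pytest.approx(0.0, abs=1e-6)
        assert fit.params.B == pytest.approx(0.7, abs=1e-6)

    def test_noisy_peak_position_within_reported_uncertainty(self):
        true = BroadPeakParams(
            C0=1.0, xi0=85.0, q0=2 * np.pi / 180, m0=1 / 0.66,
            C1=10.0, Xi1=160.0, m1=1 / 0.35, B=0.01,
        )
        ideal = eval_broad_peak_corrlen(true, self.q)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = ideal + rng.normal(0, 0.01 * ideal)
            fit = fit_curve(ScatteringCurve(self.q, noisy, 0.01 * ideal), "broadpeak-cl", seed=seed)
            if abs(fit.params.q0 - true.q0) <= 3 * fit.uncertainties["q0"]:
                hits += 1
        assert hits >= 4  # 3-sigma coverage with a small failure allowance

    def test_reduced_chi2_near_one_on_calibrated_noise(self):
        true = CorrLengthParams(C0=1.0, xi0=60.0, m0=2.0, B=0.05)
        ideal = eval_corrlen(true, self.q)
        rng = np.random.default_rng(5)
        noisy = ideal + rng.normal(0, 0.01 * ideal)
        fit = fit_curve(ScatteringCurve(self.q, noisy, 0.01 * ideal), "corrlen", seed=5)
        assert 0.5 <= fit.chi2_reduced <= 2.0

    def test_too_few_points_rejected(self):
        q = np.geomspace(0.01, 0.4, 8)
        curve = ScatteringCurve(q, np.ones(8), np.full(8, 0.01))
        with pytest.raises(ValueError):
            fit_curve(curve, "corrlen")

    def test_result_serializes_to_json(self, tmp_path):
        true = CorrLengthParams(C0=1.0, xi0=60.0, m0=2.0, B=0.05)
        ideal = eval_corrlen(true, self.q)
        fit = fit_curve(ScatteringCurve(self.q, ideal, 0.01 * ideal), "corrlen", seed=0)
        out = tmp_path / "fit.json"
        fit.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["model_id"] == "corrlen"
        assert payload["params"]["xi0"] == pytest.approx(60.0, rel=1e-6)


class TestCurveIO:
    def test_round_trip(self, tmp_path):
        q = np.geomspace(0.01, 0.4, 20)
        curve = ScatteringCurve(q, np.exp(-q * 10), 0.01 * np.exp(-q * 10), label="demo")
        path = tmp_path / "curve.dat"
        write_curve(path, curve)
        back = read_curve(path)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.intensity, curve.intensity)
        assert np.allclose(back.sigma, curve.sigma)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScatteringCurve(np.array([0.2, 0.1]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            ScatteringCurve(np.array([-0.1, 0.1]), np.array([1.0, 1.0]))
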