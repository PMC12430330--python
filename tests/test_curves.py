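"""Force conversion, baseline correction and adhesion extraction."""

import numpy as np
import pytest

from forcespec import (
    Calibration,
    CurveSynthesisParams,
    ForceCurve,
    FormatError,
    ParameterError,
    correct_baseline,
    extract_adhesion,
    read_curve,
    signal_to_force,
    synthesize_force_curve,
    write_curve,
)


class TestSignalToForce:
    def test_hookes_law_arithmetic(self, calibration):
        # deflection of -1.75 nm at k = 0.2 N/m -> -350 pN (attractive)
        signal = -1.75 / calibration.sensitivity
        assert signal_to_force(signal, calibration) == pytest.approx(-350.0)

    def test_zero_signal_zero_force(self, calibration):
        assert signal_to_force(0.0, calibration) == 0.0

    def test_linear_in_sensitivity_and_signal(self):
        cal1 = Calibration(sensitivity=10.0)
        cal2 = Calibration(sensitivity=20.0)
        assert signal_to_force(0.3, cal2) == pytest.approx(2 * signal_to_force(0.3, cal1))
        assert signal_to_force(0.6, cal1) == pytest.approx(2 * signal_to_force(0.3, cal1))

    def test_non_finite_signal_rejected(self, calibration):
        with pytest.raises(ParameterError):
            signal_to_force(np.nan, calibration)
        with pytest.raises(ParameterError):
            signal_to_force([0.1, np.inf], calibration)


def _flat_curve(calibration, signal_value=0.0, n=64):
    z = np.linspace(0.0, 100.0, n)
    sig = np.full(n, signal_value)
    return ForceCurve(
        z_approach=z[::-1].copy(),
        signal_approach=sig.copy(),
        z_retract=z,
        signal_retract=sig.copy(),
        calibration=calibration,
    )


class TestCorrectBaseline:
    def test_injected_drift_removed(self, rng):
        params = CurveSynthesisParams(baseline_drift_slope=0.005, noise_sd_signal=0.002)
        curve = synthesize_force_curve(300.0, params, seed=17)
        corrected = correct_baseline(curve)
        tail = corrected.signal_retract[corrected.z_retract > 70.0]
        noise_se = 0.002 / np.sqrt(tail.size)
        assert abs(tail.mean()) < 3 * noise_se
        assert corrected.baseline[0] == pytest.approx(0.005, abs=5e-4)

    def test_drift_free_curve_nearly_unchanged(self, curve_params):
        curve = synthesize_force_curve(300.0, curve_params)
        corrected = correct_baseline(curve)
        assert np.allclose(corrected.signal_retract, curve.signal_retract, atol=1e-12)

    def test_constant_retract_gives_zero_slope(self, calibration):
        curve = _flat_curve(calibration, signal_value=0.7)
        corrected = correct_baseline(curve)
        slope, intercept = corrected.baseline
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(0.7)

    def test_too_small_tail_rejected(self, calibration):
        curve = _flat_curve(calibration, n=20)
        with pytest.raises(ParameterError):
            correct_baseline(curve, tail_fraction=0.1)


class TestExtractAdhesion:
    def test_flat_retract_no_event(self, calibration):
        event = extract_adhesion(_flat_curve(calibration))
        assert not event.has_event
        assert event.adhesion_force_pn is None

    def test_event_exactly_at_threshold_detected(self, calibration):
        """The detection boundary is closed: magnitude == threshold is an event."""
        n = 100
        z = np.linspace(0.0, 100.0, n)
        # alternating +/- tail gives an exactly computable robust noise SD
        sig = 0.001 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        # mark as already corrected so the +/- tail is used for the noise SD as-is
        corrected = ForceCurve(
            z[::-1].copy(), sig.copy(), z, sig.copy(), calibration, baseline=(0.0, 0.0)
        )
        threshold = extract_adhesion(corrected).threshold_pn
        assert threshold > 0
        # search the float neighbourhood for a signal converting to exactly -threshold
        d = -threshold / (calibration.k * calibration.sensitivity * 1000)
        for _ in range(64):
            if signal_to_force(d, calibration) == -threshold:
                break
            d = np.nextafter(d, -np.inf if signal_to_force(d, calibration) > -threshold else np.inf)
        assert signal_to_force(d, calibration) == -threshold
        corrected.signal_retract[5] = d
        event = extract_adhesion(corrected)
        assert event.has_event
        assert event.adhesion_force_pn == threshold

    def test_scale_equivariance_in_spring_constant(self, curve_params):
        curve = synthesize_force_curve(350.0, curve_params)
        scaled = ForceCurve(
            curve.z_approach,
            curve.signal_approach,
            curve.z_retract,
            curve.signal_retract,
            Calibration(k=3 * curve.calibration.k, sensitivity=curve.calibration.sensitivity),
        )
        a = extract_adhesion(curve).adhesion_force_pn
        b = extract_adhesion(scaled).adhesion_force_pn
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_false_positive_rate_on_pure_noise(self):
        """No-event soundness: <= 1% false events on 1000 pure-noise curves."""
        params = CurveSynthesisParams(noise_sd_signal=0.003)
        false_positives = sum(
            extract_adhesion(synthesize_force_curve(0.0, params, seed=s)).has_event
            for s in range(1000)
        )
        assert false_positives <= 10

    def test_unordered_positions_rejected(self, calibration):
        z = np.linspace(0, 100, 64)
        z_bad = z.copy()
        z_bad[10] = z_bad[5]
        with pytest.raises(FormatError):
            ForceCurve(z[::-1].copy(), np.zeros(64), z_bad, np.zeros(64), calibration)


class TestCurveIO:
    def test_tsv_round_trip(self, tmp_path, calibration):
        curve = synthesize_force_curve(
            275.0,
            CurveSynthesisParams(noise_sd_signal=0.001),
            seed=2,
            metadata={"sample_id": "c001", "drug": "imatinib", "field_mv_mm": "20"},
        )
        path = tmp_path / "curve.tsv"
        write_curve(curve, path)
        back = read_curve(path, calibration)
        assert back.metadata["drug"] == "imatinib"
        np.testing.assert_allclose(back.z_retract, curve.z_retract, rtol=1e-5)
        np.testing.assert_allclose(back.signal_retract, curve.signal_retract, rtol=1e-6)
        a = extract_adhesion(curve).adhesion_force_pn
        b = extract_adhesion(back).adhesion_force_pn
        assert b == pytest.approx(a, rel=1e-4)

    def test_missing_segment_rejected(self, tmp_path, calibration):
        path = tmp_path / "bad.tsv"
        path.write_text("segment\tz_nm\tsignal\n" + "\n".join(
            f"approach\t{z}\t0.0" for z in range(20)
        ))
        with pytest.raises(FormatError, match="retract"):
            read_curve(path, calibration)
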