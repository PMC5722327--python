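"""Eight-parameter reduction of measured impedance."""

import numpy as np
import pytest

from oscillab import (
    MechanicalModel,
    NoiseSpec,
    estimate_exam,
    extract_all,
    extract_reactive,
    extract_resistive,
    resonance_closed_form,
    synthesize_record,
)
from oscillab.errors import InsufficientDataError
from oscillab.spectral import MeasuredImpedance, WindowSpec

EXACT = WindowSpec(taper="rectangular", detrend="none")


def _mi(freqs, rrs, xrs):
    freqs = np.asarray(freqs, dtype=float)
    z = np.asarray(rrs, dtype=float) + 1j * np.asarray(xrs, dtype=float)
    return MeasuredImpedance(freqs=freqs, Z=z, coherence=np.ones(freqs.size))


GRID_4_16 = np.arange(4.0, 17.0, 2.0)
GRID_4_32 = np.arange(4.0, 33.0, 2.0)


class TestResistive:
    def test_constant_resistance(self):
        mi = _mi(GRID_4_16, np.full(7, 3.0), np.zeros(7))
        res = extract_resistive(mi)
        assert res.r0 == pytest.approx(3.0)
        assert res.s == pytest.approx(0.0, abs=1e-12)
        assert res.rm == pytest.approx(3.0)
        assert res.r4 == pytest.approx(3.0)

    def test_exact_line_recovered(self):
        # Re Z = 5 - 0.1 f on 4..16; grid mean is 10 Hz so Rm = 4.0
        mi = _mi(GRID_4_16, 5.0 - 0.1 * GRID_4_16, np.zeros(7))
        res = extract_resistive(mi)
        assert res.r0 == pytest.approx(5.0)
        assert res.s == pytest.approx(-0.1)
        assert res.rm == pytest.approx(4.0)
        assert res.r4 == pytest.approx(4.6)

    def test_ols_identity_machine_precision(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(3, 1), rng.normal(0, 0.1)
        mi = _mi(GRID_4_16, a + b * GRID_4_16, np.zeros(7))
        res = extract_resistive(mi)
        assert res.r0 == pytest.approx(a, rel=1e-12)
        assert res.s == pytest.approx(b, rel=1e-12)

    def test_eric_slope_recovered_end_to_end(self):
        model = MechanicalModel("eric", R=3.0, I=0.01, C=0.02, slope=-0.05)
        rec = synthesize_record(model, noise=NoiseSpec.none(), seed=0)
        mi = estimate_exam(rec, EXACT)
        res = extract_resistive(mi)
        assert res.s == pytest.approx(-0.05, abs=1e-4)
        assert res.r0 == pytest.approx(3.0, abs=1e-4)

    def test_too_few_points_raises(self):
        mi = _mi([4.0], [3.0], [0.0])
        with pytest.raises(InsufficientDataError):
            extract_resistive(mi)

    def test_missing_4hz_flags_r4(self):
        f = np.arange(6.0, 17.0, 2.0)
        res = extract_resistive(_mi(f, np.full(f.size, 3.0), np.zeros(f.size)))
        assert not res.r4_available
        assert np.isnan(res.r4)


class TestReactive:
    def test_hand_values_for_reference_ric(self, ric_model):
        # X(4) = -1.7381 -> Cdyn = 1/(2 pi 4 * 1.7381) = 0.02289,
        # Z4 = sqrt(2.77^2 + 1.7381^2) = 3.270
        from oscillab import eval_impedance

        sp = eval_impedance(ric_model, GRID_4_32)
        mi = _mi(GRID_4_32, sp.resistance, sp.reactance)
        rea = extract_reactive(mi)
        assert rea.cdyn == pytest.approx(0.02289, abs=2e-5)
        assert rea.z4 == pytest.approx(3.270, abs=1e-3)
        assert rea.cdyn_defined

    def test_interpolated_fr_close_to_closed_form(self, ric_model):
        from oscillab import eval_impedance

        sp = eval_impedance(ric_model, GRID_4_32)
        mi = _mi(GRID_4_32, sp.resistance, sp.reactance)
        rea = extract_reactive(mi)
        assert rea.fr_status == "measured"
        assert rea.fr == pytest.approx(resonance_closed_form(ric_model), abs=0.1)

    def test_degenerate_zero_reactance(self):
        mi = _mi(GRID_4_32, np.full(15, 3.0), np.zeros(15))
        rea = extract_reactive(mi)
        assert rea.xm == 0.0
        assert rea.fr_status == "unavailable" and np.isnan(rea.fr)
        assert not rea.cdyn_defined
        assert rea.z4 == pytest.approx(3.0)

    def test_all_negative_reactance_extrapolates_and_flags(self):
        # stiff system: crossing beyond 32 Hz
        x = -10.0 + 0.25 * GRID_4_32  # crosses at 40 Hz
        rea = extract_reactive(_mi(GRID_4_32, np.full(15, 3.0), x))
        assert rea.fr_status == "extrapolated"
        assert rea.fr == pytest.approx(40.0)

    def test_z4_identity(self):
        mi = _mi(GRID_4_32, np.linspace(2, 3, 15), np.linspace(-2, 1, 15))
        rea = extract_reactive(mi)
        res = extract_resistive(mi)
        assert rea.z4**2 == pytest.approx(res.r4**2 + mi.Z.imag[0]**2)


class TestExtractAll:
    def test_three_identical_exams_match_single(self, ric_model):
        from oscillab import average_exams

        rec = synthesize_record(ric_model, noise=NoiseSpec.none(), seed=0)
        exam = estimate_exam(rec, EXACT)
        single = extract_all(exam)
        avg = extract_all(average_exams([exam, exam, exam]))
        for k in ("r0", "rm", "r4", "s", "xm", "fr", "cdyn", "z4"):
            assert getattr(avg, k) == pytest.approx(getattr(single, k))

    def test_disease_like_ordering(self):
        """Higher-R / lower-C subject: R0 and fr up, Cdyn down."""
        control = MechanicalModel("eric", R=2.77, I=0.01, C=0.02, slope=-0.01)
        ae = MechanicalModel("eric", R=3.91, I=0.01, C=0.011, slope=-0.06)
        out = {}
        for name, m in (("control", control), ("ae", ae)):
            rec = synthesize_record(m, noise=NoiseSpec.none(), seed=0)
            out[name] = extract_all(estimate_exam(rec, EXACT))
        assert out["ae"].r0 > out["control"].r0
        assert out["ae"].cdyn < out["control"].cdyn
        assert out["ae"].fr > out["control"].fr
        assert out["ae"].s < out["control"].s

    def test_pure_resistor_reactive_magnitudes(self):
        """End-to-end resistor: reactive quantities vanish to the numeric
        floor (flag semantics at exact zero are covered analytically)."""
        model = MechanicalModel("pure_resistor", R=3.0)
        rec = synthesize_record(model, noise=NoiseSpec.none(), seed=0)
        p = extract_all(estimate_exam(rec, EXACT))
        assert p.xm == pytest.approx(0.0, abs=1e-9)
        assert p.z4 == pytest.approx(3.0, abs=1e-6)
        # dynamic compliance is either flagged or degenerate (|X(4)| ~ 0)
        assert (not p.cdyn_defined) or p.cdyn > 1e3


class TestPipelineRecovery:
    def test_parameter_recovery_at_default_noise(self):
        """Median errors over 100 seeded subjects at the default noise.

        R0/Rm/R4/Z4 within 2% relative, Cdyn within 5%, fr within
        0.3 Hz, S and Xm within 0.05 cmH2O.s/L absolute.
        """
        from oscillab import average_exams, eval_impedance
        from oscillab.cohort import default_groups, draw_true_parameters
        from oscillab.fot_params import extract_all as ex_all

        rng = np.random.default_rng(123)
        group = default_groups()[0]
        rel = {k: [] for k in ("r0", "rm", "r4", "z4", "cdyn")}
        abs_err = {k: [] for k in ("s", "xm", "fr")}
        comps = np.arange(4.0, 33.0, 2.0)
        for i in range(100):
            params = draw_true_parameters(group, rng)
            model = MechanicalModel("eric", R=params["R"], I=params["I"],
                                    C=params["C"], slope=params["slope"])
            exams = [estimate_exam(synthesize_record(model, seed=1000 * i + k))
                     for k in range(3)]
            est = ex_all(average_exams(exams))
            sp = eval_impedance(model, comps)
            mi_true = MeasuredImpedance(freqs=comps, Z=sp.values,
                                        coherence=np.ones(comps.size))
            truth = ex_all(mi_true)
            for k in rel:
                rel[k].append(abs(getattr(est, k) - getattr(truth, k))
                              / abs(getattr(truth, k)))
            for k in abs_err:
                abs_err[k].append(abs(getattr(est, k) - getattr(truth, k)))
        for k in ("r0", "rm", "r4", "z4"):
            assert np.median(rel[k]) <= 0.02, k
        assert np.median(rel["cdyn"]) <= 0.05
        assert np.median(abs_err["fr"]) <= 0.3
        assert np.median(abs_err["s"]) <= 0.05
        assert np.median(abs_err["xm"]) <= 0.05
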