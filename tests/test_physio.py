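"""Rate-extraction arithmetic, unit chain, QC rules, and the full round trip."""

import numpy as np
import pandas as pd
import pytest

from coralscale import physio
from coralscale import synthdata as sd
from coralscale.physio import PhysioConstants


def make_trace(times, o2, **kw):
    df = pd.DataFrame({"time_h": times, "o2_mg_l": o2})
    for k, v in kw.items():
        df[k] = v
    return df


class TestTrim:
    def test_boundary_point_kept(self):
        t = np.linspace(0, 1, 61)  # every minute for an hour
        out = physio.trim_stabilization(make_trace(t, np.ones(61)), 30.0)
        assert len(out) == 31
        assert out["time_h"].min() == pytest.approx(0.5)

    def test_zero_window_is_identity(self):
        tr = make_trace([0.0, 0.5, 1.0], [7, 6, 5])
        pd.testing.assert_frame_equal(physio.trim_stabilization(tr, 0.0), tr)

    def test_too_short_trace_rejected(self):
        tr = make_trace([0.0, 0.2, 0.4, 0.6], [7, 6, 5, 4])
        with pytest.raises(ValueError, match="too short"):
            physio.trim_stabilization(tr, 30.0)


class TestSlopeFit:
    def test_exact_line(self):
        t = np.linspace(0, 2, 13)
        fit = physio.fit_o2_slope(make_trace(t, 10 - 0.9 * t))
        assert fit.slope == pytest.approx(-0.9, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_trace_flagged_undefined(self):
        fit = physio.fit_o2_slope(make_trace([0, 1, 2], [7.0, 7.0, 7.0]))
        assert fit.slope == 0.0 and np.isnan(fit.r_squared)

    def test_three_point_hand_case(self):
        # By hand: slope = -1.8/2 = -0.9; R^2 = 1 - 0.0066667/1.6266667.
        fit = physio.fit_o2_slope(make_trace([0, 1, 2], [10.0, 9.0, 8.2]))
        assert fit.slope == pytest.approx(-0.9, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.9959016, abs=1e-6)

    def test_closed_form_oracle_on_random_inputs(self, rng):
        # OLS slope/R^2 from first principles on every input.
        for _ in range(200):
            n = rng.integers(3, 30)
            t = np.sort(rng.uniform(0, 4, n))
            t += np.arange(n) * 1e-6  # ensure strictly increasing
            y = rng.normal(7, 1, n)
            if np.ptp(y) == 0:
                continue
            fit = physio.fit_o2_slope(make_trace(t, y))
            tc, yc = t - t.mean(), y - y.mean()
            slope = float(tc @ yc / (tc @ tc))
            ss_res = float(np.sum((yc - slope * tc) ** 2))
            r2 = 1.0 - ss_res / float(yc @ yc)
            assert fit.slope == pytest.approx(slope, rel=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)

    def test_zero_time_variance_rejected(self):
        with pytest.raises(ValueError, match="time-variance"):
            physio.fit_o2_slope(make_trace([1.0, 1.0, 1.0], [7, 6, 5]))


class TestFluxAndRates:
    @pytest.mark.parametrize(
        "slope, control, volume, expected",
        [(-2.0, -2.0, 1.0, 0.0), (-2.0, -0.1, 1.0, -1.9), (3.0, 0.5, 4.0, 10.0)],
    )
    def test_flux_arithmetic(self, slope, control, volume, expected):
        assert physio.o2_flux(slope, control, volume) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "light, dark, expected",
        [(5.0, -2.0, (2.0, 5.0, 7.0)), (0.0, -2.0, (2.0, 0.0, 2.0)),
         (3.4, -1.1, (1.1, 3.4, 4.5))],
    )
    def test_rate_derivation(self, light, dark, expected):
        rates = physio.derive_rates(light, dark)
        assert rates == pytest.approx(expected)
        # Identity holds exactly: gross - net - respiration = 0.
        assert rates.gross_photosynthesis - rates.net_photosynthesis - rates.respiration == 0.0

    def test_positive_dark_flux_rejected(self):
        with pytest.raises(ValueError, match="implausible"):
            physio.derive_rates(5.0, 0.3)


class TestCalcification:
    CHEM = {"at_start_umol_kg": 2300.0, "at_end_umol_kg": 2280.0,
            "delta_t_h": 3.0, "chamber_volume_l": 1.0}

    def test_zero_drop_zero_rate(self):
        chem = dict(self.CHEM, at_end_umol_kg=2300.0)
        per_area, whole = physio.calcification_rate(chem, None, 100.0)
        assert per_area == 0.0 and whole == 0.0

    def test_hand_unit_chain(self):
        # 20 umol/kg over 2*3 h * 1.025 kg/L * 1 L = 3.41667 umol/h
        # -> *1e-6*100.0869 g/mol / 100 cm^2 = 3.4197e-6 g cm^-2 h^-1.
        per_area, _ = physio.calcification_rate(self.CHEM, None, 100.0)
        assert per_area == pytest.approx(3.4197e-6, rel=1e-4)

    def test_linear_in_alkalinity_drop(self):
        double = dict(self.CHEM, at_end_umol_kg=2260.0)
        r1, _ = physio.calcification_rate(self.CHEM, None, 100.0)
        r2, _ = physio.calcification_rate(double, None, 100.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_control_correction_subtracts_blank_drop(self):
        control = {"at_start_umol_kg": 2300.0, "at_end_umol_kg": 2295.0}
        raw, _ = physio.calcification_rate(self.CHEM, None, 100.0)
        corrected, _ = physio.calcification_rate(self.CHEM, control, 100.0)
        assert corrected == pytest.approx(raw * 15.0 / 20.0, rel=1e-12)

    def test_dimensional_oracle_on_random_inputs(self, rng):
        # Independent unit-chain oracle evaluated in a different order.
        k = PhysioConstants()
        for _ in range(1000):
            start = rng.uniform(2000, 2500)
            drop = rng.uniform(-20, 60)
            dt = rng.uniform(0.5, 6.0)
            vol = rng.choice([0.5, 1.0, 4.0])
            area = rng.uniform(10, 2000)
            chem = {"at_start_umol_kg": start, "at_end_umol_kg": start - drop,
                    "delta_t_h": dt, "chamber_volume_l": vol}
            per_area, whole = physio.calcification_rate(chem, None, area, k)
            mol_caco3 = (drop * 1e-6) * k.rho_sw * vol / 2.0  # mol over the incubation
            oracle = mol_caco3 / dt * k.molar_mass_caco3
            assert whole == pytest.approx(oracle, rel=1e-10)
            assert per_area == pytest.approx(oracle / area, rel=1e-10)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            physio.calcification_rate(dict(self.CHEM, delta_t_h=0.0), None, 100.0)


class TestQC:
    BASE = {"colony_id": "c", "calcification_g_h": 0.1, "temp_ok": True,
            "min_r_squared": 0.95, "dark_flux_positive": False}

    def frame(self, **overrides):
        return pd.DataFrame([dict(self.BASE, **overrides)])

    @pytest.mark.parametrize(
        "overrides, rule",
        [(dict(calcification_g_h=-0.1), "negative_calcification"),
         (dict(temp_ok=False), "temperature_window"),
         (dict(min_r_squared=0.75), "r_squared"),
         (dict(min_r_squared=float("nan")), "r_squared"),
         (dict(dark_flux_positive=True), "positive_dark_flux")],
    )
    def test_each_rule_fires_and_logs(self, overrides, rule):
        retained, log = physio.qc_filter(self.frame(**overrides))
        assert retained.empty
        assert log["rule"].tolist() == [rule]

    def test_clean_record_retained(self):
        retained, log = physio.qc_filter(self.frame())
        assert len(retained) == 1 and log.empty

    def test_boundary_values_retained(self):
        # R^2 exactly 0.8 and temperatures at the window edges pass.
        retained, _ = physio.qc_filter(self.frame(min_r_squared=0.8))
        assert len(retained) == 1

    def test_idempotent(self):
        df = pd.concat([self.frame(), self.frame(calcification_g_h=-1.0),
                        self.frame(temp_ok=False)], ignore_index=True)
        once, _ = physio.qc_filter(df)
        twice, log2 = physio.qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty


class TestProcessStudy:
    def test_noiseless_round_trip_recovers_all_rates(self, tmp_path):
        # The central invariant: with zero trace and titration noise the
        # extracted rates equal every colony's true rates to 1e-9.
        paths = sd.write_inputs(tmp_path, n_per_species=3, seed=21,
                                trace_noise_sd=0.0, titration_noise_sd=0.0)
        meta = pd.read_csv(paths["colonies"])
        traces = pd.read_csv(paths["traces"])
        chem = pd.read_csv(paths["chemistry"])
        retained, log = physio.process_study(meta, traces, chem)
        assert log.empty
        merged = retained.merge(meta, on="colony_id")
        np.testing.assert_allclose(
            merged["calcification_g_h"], merged["true_calcification"], rtol=1e-9)
        np.testing.assert_allclose(
            merged["respiration_mg_h"], merged["true_respiration"], rtol=1e-9)
        np.testing.assert_allclose(
            merged["net_photo_mg_h"], merged["true_net_photosynthesis"], rtol=1e-9)
        np.testing.assert_allclose(
            merged["gross_photo_mg_h"],
            merged["true_net_photosynthesis"] + merged["true_respiration"], rtol=1e-9)

    def test_missing_controls_raise_unless_overridden(self, tmp_path):
        paths = sd.write_inputs(tmp_path, n_per_species=2, seed=22)
        meta = pd.read_csv(paths["colonies"])
        traces = pd.read_csv(paths["traces"])
        chem = pd.read_csv(paths["chemistry"])
        no_ctrl = traces[~traces["is_control"]]
        with pytest.raises(ValueError, match="control"):
            physio.process_study(meta, no_ctrl, chem[~chem["is_control"]])
        retained, _ = physio.process_study(
            meta, no_ctrl, chem[~chem["is_control"]], require_controls=False)
        assert len(retained) > 0
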