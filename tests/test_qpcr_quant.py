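"""Window-of-linearity fitting, Ct, calibration, expression and QC filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pundavision import qpcr_quant as q
from pundavision import synthetic_data as sd


def make_curve(f, well="w1", sample="s1", opsin="LWS"):
    return q.AmplificationCurve(well, sample, opsin, np.asarray(f, dtype=float))


class TestWindowOfLinearity:
    def test_noiseless_exponential_recovers_efficiency_and_n0(self):
        # F(c) = 1e-6 * 1.9**c with the plateau clipped at 1.0
        f = np.minimum(1e-6 * 1.9 ** np.arange(1, 41), 1.0)
        fit = q.fit_window_of_linearity(make_curve(f), baseline_cycles=0)
        assert fit.efficiency == pytest.approx(1.9, abs=1e-6)
        assert fit.n0_raw == pytest.approx(1e-6, rel=0.01)
        assert fit.window[1] - fit.window[0] + 1 >= 4
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_is_no_amplification(self):
        with pytest.raises(q.NoAmplificationError):
            q.fit_window_of_linearity(make_curve(np.full(40, 0.01)))

    def test_too_few_cycles_rejected(self):
        with pytest.raises(q.QpcrError, match="15"):
            q.fit_window_of_linearity(make_curve(np.ones(10)))

    def test_noisy_efficiency_recovery_rate(self):
        # 0.5% multiplicative noise, E = 2: estimate within [1.95, 2.05]
        # in at least 95 of 100 seeded replicates.
        hits = 0
        c = np.arange(1, 41)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = np.minimum(1e-6 * 2.0 ** c, 1.0) * np.exp(rng.normal(0, 0.005, 40))
            fit = q.fit_window_of_linearity(make_curve(f), baseline_cycles=0)
            hits += 1.95 <= fit.efficiency <= 2.05
        assert hits >= 95


class TestCt:
    def test_closed_form_doubling(self):
        f = np.minimum(2.0 ** np.arange(1, 41), 2.0 ** 20)
        fit = q.fit_window_of_linearity(make_curve(f), baseline_cycles=0)
        assert q.compute_ct(fit, 1024.0).ct == pytest.approx(10.0, abs=1e-9)

    def test_closed_form_fractional_base(self):
        f = np.minimum(1.9 ** np.arange(1, 41), 1.9 ** 20)
        fit = q.fit_window_of_linearity(make_curve(f), baseline_cycles=0)
        assert q.compute_ct(fit, 1.9 ** 7).ct == pytest.approx(7.0, abs=1e-9)

    def test_identical_curves_identical_ct(self):
        f = np.minimum(1e-6 * 2.0 ** np.arange(1, 41), 1.0)
        fits = [q.fit_window_of_linearity(make_curve(f, well=w), baseline_cycles=0)
                for w in ("a", "b")]
        thr = q.plate_common_threshold(fits)
        assert q.compute_ct(fits[0], thr).ct == q.compute_ct(fits[1], thr).ct

    def test_threshold_outside_window_flags_extrapolation(self):
        f = np.minimum(1e-6 * 2.0 ** np.arange(1, 41), 1.0)
        fit = q.fit_window_of_linearity(make_curve(f), baseline_cycles=0)
        assert q.compute_ct(fit, 1e-5).extrapolated


class TestConstructCalibration:
    points = [(x, -3.32 * x + 40.0) for x in (-1.0, -2.0, -3.0, -4.0, -5.0, -6.0)]

    def test_noiseless_points_exact(self):
        calib = q.fit_construct_calibration(self.points)
        assert calib.slope == pytest.approx(-3.32, abs=1e-12)
        assert calib.intercept == pytest.approx(40.0, abs=1e-12)
        assert calib.r2 == pytest.approx(1.0)

    def test_perturbed_point_stays_close(self):
        pts = [(x, ct + (0.1 if x == -3.0 else 0.0)) for x, ct in self.points]
        calib = q.fit_construct_calibration(pts)
        # independent oracle: numpy polyfit on the same points
        m_ref, b_ref = np.polyfit([p[0] for p in pts], [p[1] for p in pts], 1)
        assert calib.slope == pytest.approx(m_ref, abs=1e-12)
        assert calib.intercept == pytest.approx(b_ref, abs=1e-12)
        assert calib.r2 < 1.0
        assert abs(calib.slope + 3.32) < 0.05

    def test_three_points_rejected(self):
        with pytest.raises(q.CalibrationError):
            q.fit_construct_calibration(self.points[:3])

    def test_positive_slope_rejected(self):
        with pytest.raises(q.CalibrationError, match="non-amplifying"):
            q.fit_construct_calibration([(x, 3.3 * x + 40) for x in range(-6, 0)])


class TestRelativeExpression:
    calib = q.ConstructCalibration(-3.32, 40.0, 1.0, 6)

    def test_equal_cts_give_equal_quarters(self):
        cts = {o: 22.0 for o in ("SWS2b", "SWS2a", "RH2A", "LWS")}
        profile = q.relative_expression(cts, self.calib)
        for v in profile.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_decade_spaced_cts_give_decade_weights(self):
        cts = {"LWS": 20.0, "RH2A": 23.32, "SWS2a": 26.64, "SWS2b": 29.96}
        profile = q.relative_expression(cts, self.calib)
        assert profile["LWS"] == pytest.approx(1000 / 1111, abs=1e-4)
        assert profile["RH2A"] == pytest.approx(100 / 1111, abs=1e-4)
        assert profile["SWS2a"] == pytest.approx(10 / 1111, abs=1e-4)
        assert profile["SWS2b"] == pytest.approx(1 / 1111, abs=1e-4)

    @given(delta=st.floats(min_value=-8, max_value=8))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance(self, delta):
        cts = {"LWS": 20.0, "RH2A": 22.5, "SWS2a": 25.1, "SWS2b": 28.4}
        base = q.relative_expression(cts, self.calib)
        shifted = q.relative_expression(
            {k: v + delta for k, v in cts.items()}, self.calib
        )
        for opsin in cts:
            assert shifted[opsin] == pytest.approx(base[opsin], abs=1e-12)

    @given(
        cts=st.dictionaries(
            st.sampled_from(["SWS2b", "SWS2a", "RH2A", "LWS"]),
            st.floats(min_value=10, max_value=35),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_profile_always_sums_to_one(self, cts):
        profile = q.relative_expression(cts, self.calib)
        assert sum(profile.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_opsin_rejected(self):
        with pytest.raises(q.QpcrError):
            q.relative_expression({"LWS": 20.0}, self.calib)


class TestDuplicateQc:
    @staticmethod
    def _pair(cts, effs):
        out = []
        for i, (ct, eff) in enumerate(zip(cts, effs)):
            fit = q.WindowFit(f"w{i}", (10, 14), np.log10(eff), -6.0, 0.999,
                              eff, 1e-6)
            out.append((fit, q.CtValue(f"w{i}", ct, 0.01)))
        return out

    def test_tight_duplicates_pass(self):
        qc = q.apply_duplicate_qc({("s", "LWS"): self._pair([20.0, 20.4], [1.95, 2.05])})
        row = qc.iloc[0]
        assert row["passed"]
        assert row["ct_sd"] == pytest.approx(np.sqrt(0.08), abs=1e-9)  # ~0.283

    def test_wide_ct_spread_fails(self):
        qc = q.apply_duplicate_qc({("s", "LWS"): self._pair([20.0, 21.0], [2.0, 2.0])})
        row = qc.iloc[0]
        assert not row["passed"] and row["reasons"] == "ct_sd"
        assert row["ct_sd"] == pytest.approx(np.sqrt(0.5), abs=1e-9)  # ~0.707

    def test_low_efficiency_fails(self):
        qc = q.apply_duplicate_qc({("s", "LWS"): self._pair([20.0, 20.1], [1.5, 2.0])})
        assert not qc.iloc[0]["passed"]
        assert qc.iloc[0]["reasons"] == "efficiency"

    def test_singleton_auto_fails(self):
        qc = q.apply_duplicate_qc({("s", "LWS"): self._pair([20.0], [2.0])})
        assert not qc.iloc[0]["passed"]
        assert qc.iloc[0]["reasons"] == "no duplicate"

    def test_tightening_the_band_never_passes_more(self):
        truth = {"F1": {"SWS2b": 2e-9, "SWS2a": 8e-9, "RH2A": 1.4e-8, "LWS": 7.6e-8}}
        plate, _ = sd.generate_plate(
            truth, efficiency=1.85, noise_sigma=0.01, seed=11
        )
        passing = []
        for band in ((60.0, 140.0), (75.0, 125.0), (80.0, 120.0), (84.0, 116.0)):
            _, qc = q.quantify_plate(plate, efficiency_band_pct=band)
            passing.append(set(qc[qc["passed"]].apply(
                lambda r: (r["sample_id"], r["opsin"]), axis=1)))
        for wider, tighter in zip(passing, passing[1:]):
            assert tighter <= wider


class TestIqrFilter:
    def test_planted_outlier_excluded(self):
        keep = q.iqr_outlier_filter([0.10, 0.11, 0.12, 0.13, 0.90])
        assert list(keep) == [True, True, True, True, False]

    def test_constant_values_all_kept(self):
        assert q.iqr_outlier_filter([0.2] * 6).all()

    def test_small_spread_all_kept(self):
        assert q.iqr_outlier_filter([1.0, 2.0, 3.0, 4.0]).all()

    def test_fewer_than_four_values_not_filtered(self):
        assert q.iqr_outlier_filter([0.1, 9.9, 0.1]).all()

    def test_population_filter_drop_modes(self):
        import pandas as pd

        expression = pd.DataFrame({
            "fish_id": [f"f{i}" for i in range(5)],
            "SWS2b": [0.02, 0.02, 0.02, 0.02, 0.40],  # f4 is an outlier
            "SWS2a": [0.08] * 5,
            "RH2A": [0.14] * 5,
            "LWS": [0.76, 0.76, 0.76, 0.76, 0.38],
            "n_passing_opsins": 4,
        })
        metadata = pd.DataFrame({
            "fish_id": expression["fish_id"],
            "island": "Makobe", "phenotype": "blue",
        })
        per_opsin = q.filter_population_outliers(expression, metadata)
        assert np.isnan(per_opsin.loc[4, "SWS2b"])
        assert not np.isnan(per_opsin.loc[4, "SWS2a"])  # other opsins survive
        per_fish = q.filter_population_outliers(expression, metadata, drop="fish")
        assert per_fish.loc[4, ["SWS2b", "SWS2a", "RH2A", "LWS"]].isna().all()
        assert per_fish.loc[0, "SWS2b"] == pytest.approx(0.02)
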