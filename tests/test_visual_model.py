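"""Pigment templates, quantum catch and the transplant comparison."""

import numpy as np
import pandas as pd
import pytest

from pundavision import visual_model as vm
from pundavision.io_formats import OPSINS


class TestPigmentTemplate:
    @pytest.mark.parametrize("lam_max", [425.0, 455.0, 528.0, 544.0, 559.0])
    def test_peak_value_near_unity(self, lam_max):
        assert 0.99 <= vm.pigment_absorbance(lam_max, lam_max) <= 1.02

    def test_monotone_decay_on_the_long_wavelength_limb(self):
        wl = np.arange(533.0, 701.0)
        r = vm.pigment_absorbance(wl, 528.0)
        assert np.all(np.diff(r) < 0)

    def test_violet_pigment_is_blind_at_700(self):
        assert vm.pigment_absorbance(700.0, 425.0) < 0.01

    def test_finite_over_the_valid_range(self):
        wl = np.arange(300.0, 801.0)
        for lam in (425.0, 559.0):
            assert np.all(np.isfinite(vm.pigment_absorbance(wl, lam)))


class TestLwsLambdaMax:
    @pytest.mark.parametrize(
        "genotype,expected",
        [("HH", 559.0), ("PP", 544.0), ("HP", 551.5),
         ("M3M3", 544.0), ("H-M3", 551.5), ("P-M3", 544.0)],
    )
    def test_genotype_lambda_max(self, genotype, expected):
        assert vm.lws_lambda_max(genotype) == expected

    def test_heterozygote_is_the_median_of_the_alleles(self):
        reg = vm.DEFAULT_REGISTRY
        assert vm.lws_lambda_max("HP") == np.median(
            [reg.lws_alleles["H"], reg.lws_alleles["P"]]
        )

    def test_m3_override(self):
        reg = vm.PigmentRegistry(m3_lambda_max=550.0)
        assert vm.lws_lambda_max("M3M3", reg) == 550.0

    def test_non_call_rejected(self):
        with pytest.raises(vm.VisualModelError):
            vm.lws_lambda_max("inconsistent")


class TestQuantumCatch:
    wl = np.arange(400.0, 701.0)

    def _flat(self):
        return self.wl, np.ones_like(self.wl)

    def test_zero_expression_zero_catch(self):
        profile = {"LWS": 0.0, "RH2A": 1.0, "SWS2a": 0.0, "SWS2b": 0.0}
        qc = vm.quantum_catch(profile, 559.0, *self._flat())
        assert qc.per_opsin["LWS"] == 0.0

    def test_all_on_one_opsin_matches_direct_integral(self):
        profile = {"RH2A": 1.0}
        qc = vm.quantum_catch(profile, 559.0, *self._flat())
        r = vm.pigment_absorbance(self.wl, 528.0)
        expected = np.trapezoid(r / 300.0, self.wl)
        assert qc.total == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_the_profile(self, rng):
        wl, ir = self.wl, 1.0 + np.cos(self.wl / 50.0) ** 2
        p1 = dict(zip(OPSINS, (0.1, 0.2, 0.3, 0.4)))
        p2 = dict(zip(OPSINS, (0.4, 0.3, 0.2, 0.1)))
        for alpha in (0.0, 0.25, 0.7, 1.0):
            mix = {o: alpha * p1[o] + (1 - alpha) * p2[o] for o in OPSINS}
            q_mix = vm.quantum_catch(mix, 551.5, wl, ir).total
            q1 = vm.quantum_catch(p1, 551.5, wl, ir).total
            q2 = vm.quantum_catch(p2, 551.5, wl, ir).total
            assert q_mix == pytest.approx(alpha * q1 + (1 - alpha) * q2, abs=1e-12)

    def test_spectrum_scale_invariance(self):
        profile = dict(zip(OPSINS, (0.1, 0.2, 0.3, 0.4)))
        wl, ir = self.wl, 1.0 + np.sin(self.wl / 30.0) ** 2
        a = vm.quantum_catch(profile, 544.0, wl, ir).total
        b = vm.quantum_catch(profile, 544.0, wl, 1234.5 * ir).total
        assert b == pytest.approx(a, rel=1e-12)

    def test_total_is_the_sum_of_parts(self):
        profile = dict(zip(OPSINS, (0.1, 0.2, 0.3, 0.4)))
        qc = vm.quantum_catch(profile, 559.0, *self._flat())
        assert qc.total == pytest.approx(sum(qc.per_opsin.values()), abs=1e-12)

    def test_trapezoid_matches_finer_grid(self):
        # smooth synthetic spectrum: 1 nm grid vs a 10x finer evaluation
        profile = dict(zip(OPSINS, (0.05, 0.15, 0.3, 0.5)))
        ir = np.exp(-((self.wl - 560.0) / 80.0) ** 2)
        coarse = vm.quantum_catch(profile, 551.5, self.wl, ir).total
        wl_f = np.linspace(400.0, 700.0, 3001)
        ir_f = np.exp(-((wl_f - 560.0) / 80.0) ** 2)
        fine = vm.quantum_catch(profile, 551.5, wl_f, ir_f).total
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_long_shifted_light_rewards_lws_over_sws2b(self):
        ir = np.exp((self.wl - 400.0) / 60.0)  # strongly long-shifted, OR >> 3
        base = dict(zip(OPSINS, (0.3, 0.2, 0.2, 0.3)))
        shifted = dict(zip(OPSINS, (0.1, 0.2, 0.2, 0.5)))
        q_base = vm.quantum_catch(base, 559.0, self.wl, ir).total
        q_shift = vm.quantum_catch(shifted, 559.0, self.wl, ir).total
        assert q_shift > q_base

    def test_uncovered_spectrum_rejected(self):
        wl = np.arange(450.0, 701.0)
        with pytest.raises(vm.VisualModelError, match="cover"):
            vm.quantum_catch({"LWS": 1.0}, 559.0, wl, np.ones_like(wl))


class TestDepthsAndTransplant:
    def test_frequency_weighted_mean_depth(self):
        assert vm.frequency_weighted_mean_depth([1.0, 1.0, 3.0]) == pytest.approx(5 / 3)
        assert vm.frequency_weighted_mean_depth([2.5]) == 2.5
        assert vm.frequency_weighted_mean_depth([3.0, 1.0, 1.0]) == pytest.approx(5 / 3)

    def test_empty_roster_rejected(self):
        with pytest.raises(vm.VisualModelError):
            vm.frequency_weighted_mean_depth([])

    @staticmethod
    def _spectra():
        wl = np.arange(400.0, 701.0)
        frames = []
        for island, tilt in (("Makobe", 0.001), ("Python", 0.004)):
            for depth in (1.0, 2.0, 3.0):
                ir = np.exp(tilt * depth * (wl - 400.0))
                frames.append(pd.DataFrame({
                    "island": island, "depth_m": depth,
                    "wavelength_nm": wl, "irradiance": ir,
                }))
        return pd.concat(frames, ignore_index=True)

    @staticmethod
    def _fish(fish_id, island, phenotype, depth, genotype, profile):
        return {"fish_id": fish_id, "island": island, "phenotype": phenotype,
                "capture_depth_m": depth, "genotype": genotype,
                **dict(zip(OPSINS, profile))}

    def test_identical_immigrant_matches_resident_exactly(self):
        profile = (0.1, 0.1, 0.2, 0.6)
        fish = pd.DataFrame([
            self._fish("r1", "Makobe", "red", 2.0, "HH", profile),
            self._fish("i1", "Python", "red", 2.0, "HH", profile),
        ])
        per_fish, summary = vm.transplant_comparison(fish, self._spectra())
        makobe = per_fish[per_fish["resident_island"] == "Makobe"]
        assert makobe["Qc_total"].nunique() == 1

    def test_island_without_spectra_is_excluded(self):
        fish = pd.DataFrame([
            self._fish("a1", "Anchor", "red", 2.0, "HH", (0.1, 0.1, 0.2, 0.6)),
            self._fish("r1", "Makobe", "red", 2.0, "HH", (0.1, 0.1, 0.2, 0.6)),
        ])
        _, summary = vm.transplant_comparison(fish, self._spectra())
        assert "Anchor" not in set(summary["resident_island"])
        # Anchor fish still appear as immigrants at measured islands
        assert "Anchor" in set(summary["source_island"])

    def test_non_canonical_genotypes_left_out_by_default(self):
        fish = pd.DataFrame([
            self._fish("r1", "Makobe", "red", 2.0, "HH", (0.1, 0.1, 0.2, 0.6)),
            self._fish("r2", "Makobe", "red", 2.0, "HP", (0.1, 0.1, 0.2, 0.6)),
            self._fish("b1", "Makobe", "blue", 1.0, "HH", (0.1, 0.1, 0.2, 0.6)),
        ])
        per_fish, _ = vm.transplant_comparison(fish, self._spectra())
        assert set(per_fish["fish_id"]) == {"r1"}
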