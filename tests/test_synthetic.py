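"""Synthetic-data generators: model values, seeded determinism, and the
closed-form Gaussian-area oracle for simulated chromatograms."""

import math
from dataclasses import replace

import numpy as np
import pytest

from lipidphys import (
    ChromSimConfig,
    GrowthSimConfig,
    ScenarioConfig,
    generate_chromatogram,
    generate_growth_curve,
    generate_scenario,
)
from lipidphys.synthetic import DETECTOR_K, model_curve


def noiseless_chrom(**kw):
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("baseline_drift", 0.0)
    kw.setdefault("baseline_offset", 0.0)
    return ChromSimConfig(**kw)


def peak_area(chrom, rt_center, half_width=0.5):
    """Trapezoid oracle: integrate the trace around an isolated peak."""
    m = (chrom.rt > rt_center - half_width) & (chrom.rt < rt_center + half_width)
    return np.trapezoid(chrom.intensity[m], chrom.rt[m])


class TestGrowthCurve:
    def test_noiseless_curve_starts_at_od0(self):
        cfg = GrowthSimConfig(od0=0.5, lag_true=0.0, mu_true=0.2, od_max_true=10.0,
                              noise_sd=0.0)
        series = generate_growth_curve(cfg)
        assert series.od[0] == pytest.approx(0.5)
        assert series.times[0] == 0.0
        assert series.times[-1] == pytest.approx(cfg.duration)
        assert np.all(np.diff(series.times) > 0)

    def test_delayed_logistic_is_flat_during_lag(self):
        # a fast grower with a pronounced lag keeps OD exactly at od0 until
        # the lag ends, then rises
        cfg = GrowthSimConfig(od0=0.5, mu_true=0.71, lag_true=5.19,
                              od_max_true=20.86, noise_sd=0.0)
        series = generate_growth_curve(cfg)
        in_lag = series.times <= 5.19
        assert np.all(series.od[in_lag] == 0.5)
        assert series.od[~in_lag][2] > 0.5

    def test_baranyi_reduces_to_logistic_without_lag(self):
        t = np.linspace(0, 30, 61)
        base = dict(od0=0.5, mu_true=0.4, od_max_true=15.0, lag_true=0.0, noise_sd=0.0)
        dl = model_curve(t, GrowthSimConfig(model="delayed_logistic", **base))
        br = model_curve(t, GrowthSimConfig(model="baranyi", **base))
        np.testing.assert_allclose(dl, br, rtol=1e-9)

    def test_baranyi_lag_slows_early_growth(self):
        t = np.linspace(0, 30, 61)
        base = dict(od0=0.5, mu_true=0.4, od_max_true=15.0, noise_sd=0.0, model="baranyi")
        no_lag = model_curve(t, GrowthSimConfig(lag_true=0.0, **base))
        lagged = model_curve(t, GrowthSimConfig(lag_true=4.0, **base))
        assert np.all(lagged <= no_lag + 1e-12)
        assert lagged[10] < no_lag[10]

    def test_seeded_determinism(self):
        cfg = GrowthSimConfig(noise_sd=0.05, seed=42)
        a, b = generate_growth_curve(cfg), generate_growth_curve(cfg)
        np.testing.assert_array_equal(a.od, b.od)
        c = generate_growth_curve(replace(cfg, seed=43))
        assert not np.array_equal(a.od, c.od)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(model="gompertz"),
            dict(od0=25.0),  # od0 >= od_max
            dict(lag_true=-1.0),
            dict(duration=2.0, lag_true=5.0),
            dict(sampling_interval=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GrowthSimConfig(**kw)


class TestChromatogram:
    def test_equal_masses_give_equal_areas(self):
        cfg = noiseless_chrom(fa_masses_ug={"C18:1(n-9)": 75.0}, is_mass_ug=75.0)
        chrom = generate_chromatogram(cfg)
        a_fa = peak_area(chrom, cfg.rt_library["C18:1(n-9)"].rt)
        a_is = peak_area(chrom, cfg.rt_library["C17:0"].rt)
        assert a_fa == pytest.approx(a_is, rel=0.005)

    def test_empty_masses_leaves_only_internal_standard(self):
        cfg = noiseless_chrom(fa_masses_ug={})
        chrom = generate_chromatogram(cfg)
        a_is = peak_area(chrom, cfg.rt_library["C17:0"].rt)
        assert a_is == pytest.approx(DETECTOR_K * 75.0, rel=0.005)
        # everything away from the IS peak is flat baseline
        far = np.abs(chrom.rt - cfg.rt_library["C17:0"].rt) > 0.5
        assert np.all(np.abs(chrom.intensity[far]) < 1e-6)

    def test_areas_scale_with_mass_ratio(self):
        cfg = noiseless_chrom(fa_masses_ug={"C14:0": 10.0, "C16:0": 20.0})
        chrom = generate_chromatogram(cfg)
        a = peak_area(chrom, cfg.rt_library["C14:0"].rt)
        b = peak_area(chrom, cfg.rt_library["C16:0"].rt)
        assert b / a == pytest.approx(2.0, rel=0.005)

    def test_trapezoid_area_matches_k_rf_m(self):
        # closed-form Gaussian integral == k * RF * m; the sampled trace
        # must agree within 0.5%
        cfg = noiseless_chrom(fa_masses_ug={"C16:0": 33.0},
                              response_factors={"C16:0": 1.3})
        chrom = generate_chromatogram(cfg)
        a = peak_area(chrom, cfg.rt_library["C16:0"].rt)
        assert a == pytest.approx(DETECTOR_K * 1.3 * 33.0, rel=0.005)

    def test_overlapping_retention_times_noted(self, rt_library):
        cfg = noiseless_chrom(fa_masses_ug={"C16:0": 10.0}, peak_width_sd=0.8)
        chrom = generate_chromatogram(cfg)
        assert any("overlapping" in n for n in chrom.notes)

    def test_unknown_fatty_acid_rejected(self):
        with pytest.raises(ValueError, match="missing from RT library"):
            ChromSimConfig(fa_masses_ug={"C20:4": 1.0})

    def test_seeded_determinism(self):
        cfg = ChromSimConfig(fa_masses_ug={"C16:0": 50.0}, noise_sd=3.0, seed=7)
        a, b = generate_chromatogram(cfg), generate_chromatogram(cfg)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestScenario:
    def _scenario(self, pcts=(20.0, 50.0, 30.0), cdw_per_od=1.0, seed=0):
        comp = {"C18:1(n-9)": 0.8, "C16:0": 0.2}
        return ScenarioConfig(
            growth=GrowthSimConfig(noise_sd=0.0, seed=seed),
            trajectory_true=tuple((f, p, comp) for f, p in zip((0.2, 0.5, 1.0), pcts)),
            cdw_per_od=cdw_per_od,
            chrom=noiseless_chrom(),
        )

    def test_total_true_mass_arithmetic(self):
        # 50 %CDW of a 10-mg aliquot (1 mg/OD x 10 OD) is 5000 ug of FA
        cfg = self._scenario(pcts=(10.0, 50.0, 30.0), cdw_per_od=1.0)
        scen = generate_scenario(cfg)
        mid = scen.chromatograms[1]
        total = sum(
            peak_area(mid, cfg.chrom.rt_library[fa].rt)
            for fa in ("C18:1(n-9)", "C16:0")
        ) / DETECTOR_K
        assert total == pytest.approx(5000.0, rel=0.01)

    def test_declining_trajectory_gives_decreasing_masses(self):
        cfg = self._scenario(pcts=(34.4, 24.0, 15.2))
        scen = generate_scenario(cfg)
        totals = [
            sum(peak_area(c, cfg.chrom.rt_library[fa].rt)
                for fa in ("C18:1(n-9)", "C16:0"))
            for c in scen.chromatograms
        ]
        assert totals[0] > totals[1] > totals[2]

    def test_same_seed_identical_bundle(self):
        comp = {"C18:1(n-9)": 1.0}
        cfg = ScenarioConfig(
            growth=GrowthSimConfig(noise_sd=0.02, seed=11),
            trajectory_true=((0.2, 10.0, comp), (0.5, 20.0, comp), (1.0, 30.0, comp)),
        )
        a, b = generate_scenario(cfg), generate_scenario(cfg)
        np.testing.assert_array_equal(a.series.od, b.series.od)
        for ca, cb in zip(a.chromatograms, b.chromatograms):
            np.testing.assert_array_equal(ca.intensity, cb.intensity)

    def test_pct_cdw_over_100_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            self._scenario(pcts=(20.0, 120.0, 30.0))

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScenarioConfig(
                growth=GrowthSimConfig(),
                trajectory_true=tuple(
                    (f, 10.0, {"C16:0": 0.6}) for f in (0.2, 0.5, 1.0)
                ),
            )
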