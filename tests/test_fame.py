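"""Peak detection, retention-time assignment and internal-standard
quantification, checked against closed-form Gaussian areas, an exhaustive
nearest-assignment oracle and hand arithmetic."""

import math

import numpy as np
import pytest

from lipidphys import (
    Chromatogram,
    ChromSimConfig,
    LibraryEntry,
    Peak,
    PeakTable,
    RTLibrary,
    assign_peaks,
    default_rt_library,
    detect_peaks,
    generate_chromatogram,
    quantify,
)


def gaussian_trace(peaks, rt_max=10.0, rate=100.0, baseline=0.0, sigma=0.04):
    """Build a chromatogram from (center, area) pairs; closed-form areas."""
    rt = np.arange(int(rt_max * rate) + 1) / rate
    y = np.full_like(rt, baseline, dtype=float)
    for center, area in peaks:
        y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((rt - center) / sigma) ** 2
        )
    return Chromatogram(rt=rt, intensity=y, aliquot_cdw_mg=5.5)


def table(*rts):
    return PeakTable(tuple(
        Peak(rt_apex=r, area=100.0, left=r - 0.1, right=r + 0.1, height=10.0)
        for r in rts
    ))


def c17_library(rt=6.0, tol_entries=()):
    entries = [LibraryEntry("C17:0", rt, is_internal_standard=True)]
    entries += [LibraryEntry(n, r) for n, r in tol_entries]
    return RTLibrary(tuple(entries))


class TestDetectPeaks:
    def test_single_gaussian_area_within_half_percent(self):
        chrom = gaussian_trace([(5.0, 1000.0)], baseline=20.0)
        peaks = detect_peaks(chrom)
        assert len(peaks) == 1
        assert peaks.peaks[0].area == pytest.approx(1000.0, rel=0.005)
        assert peaks.peaks[0].rt_apex == pytest.approx(5.0, abs=0.01)

    def test_flat_baseline_gives_empty_table(self):
        chrom = gaussian_trace([], baseline=50.0)
        assert len(detect_peaks(chrom)) == 0

    def test_two_separated_gaussians_integrate_independently(self):
        # 5 sigma apart: each area within 1% of its configured value
        sigma = 0.04
        chrom = gaussian_trace([(5.0, 800.0), (5.0 + 5 * sigma, 400.0)], sigma=sigma)
        peaks = detect_peaks(chrom)
        assert len(peaks) == 2
        areas = sorted(p.area for p in peaks.peaks)
        assert areas[0] == pytest.approx(400.0, rel=0.01)
        assert areas[1] == pytest.approx(800.0, rel=0.01)

    def test_saturated_peak_flagged_not_dropped(self):
        chrom0 = gaussian_trace([(5.0, 1000.0)])
        clipped = np.minimum(chrom0.intensity, 0.5 * chrom0.intensity.max())
        chrom = Chromatogram(rt=chrom0.rt, intensity=clipped)
        peaks = detect_peaks(chrom)
        assert len(peaks) == 1
        assert "saturated" in peaks.peaks[0].flags

    def test_drifting_baseline_subtracted(self):
        rt = np.arange(1001) / 100.0
        drift = 10.0 + 3.0 * rt
        y = drift + 1000.0 / (0.04 * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((rt - 5.0) / 0.04) ** 2
        )
        peaks = detect_peaks(Chromatogram(rt=rt, intensity=y))
        assert len(peaks) == 1
        assert peaks.peaks[0].area == pytest.approx(1000.0, rel=0.01)


class TestAssignPeaks:
    def test_within_tolerance_assigned(self):
        out = assign_peaks(table(6.01), c17_library(6.0), rt_tolerance=0.05)
        assert out.peaks[0].assignment == "C17:0"

    def test_outside_tolerance_unassigned(self):
        out = assign_peaks(table(6.20), c17_library(6.0), rt_tolerance=0.05)
        assert out.peaks[0].assignment is None

    def test_nearest_peak_wins_the_entry(self):
        out = assign_peaks(table(5.99, 6.03), c17_library(6.0), rt_tolerance=0.05)
        assert out.peaks[0].assignment == "C17:0"
        assert out.peaks[1].assignment is None

    def test_matches_exhaustive_nearest_assignment_oracle(self, rng):
        lib = default_rt_library()
        for _ in range(25):
            n = rng.integers(1, 8)
            rts = np.sort(rng.uniform(1.5, 9.0, size=n))
            if np.any(np.diff(rts) < 1e-3):
                continue
            out = assign_peaks(table(*rts), lib, rt_tolerance=0.3)
            # oracle: greedy over all (peak, entry) pairs by distance
            pairs = sorted(
                (abs(r - e.rt), i, e.fa_name)
                for i, r in enumerate(rts)
                for e in lib.entries
                if abs(r - e.rt) <= 0.3
            )
            expected, used_p, used_e = {}, set(), set()
            for d, i, name in pairs:
                if i not in used_p and name not in used_e:
                    expected[i] = name
                    used_p.add(i)
                    used_e.add(name)
            got = {i: p.assignment for i, p in enumerate(out.peaks) if p.assignment}
            assert got == expected


class TestQuantify:
    def test_equal_area_to_internal_standard_gives_is_mass(self):
        lib = c17_library(6.0, [("C18:1(n-9)", 7.0)])
        peaks = assign_peaks(table(6.0, 7.0), lib, rt_tolerance=0.05)
        q = quantify(peaks, lib, aliquot_cdw_mg=10.0, is_mass_ug=75.0)
        assert q.masses_ug["C18:1(n-9)"] == pytest.approx(75.0)

    def test_hand_arithmetic_two_analytes(self):
        # areas A=2x, B=x, IS=x, CDW 10 mg -> masses 150 and 75 ug,
        # total lipid 225/10000 = 2.25 %CDW
        lib = c17_library(6.0, [("A", 7.0), ("B", 8.0)])
        peaks = PeakTable((
            Peak(6.0, 500.0, 5.9, 6.1, 1.0),
            Peak(7.0, 1000.0, 6.9, 7.1, 1.0),
            Peak(8.0, 500.0, 7.9, 8.1, 1.0),
        ))
        peaks = assign_peaks(peaks, lib, rt_tolerance=0.05)
        q = quantify(peaks, lib, aliquot_cdw_mg=10.0, is_mass_ug=75.0)
        assert q.masses_ug == pytest.approx({"A": 150.0, "B": 75.0})
        assert q.pct_cdw_total == pytest.approx(2.25)
        assert q.mg_per_g_cdw == pytest.approx({"A": 15.0, "B": 7.5})
        assert q.fractions["A"] == pytest.approx(2.0 / 3.0)

    def test_response_factor_divides_mass(self):
        lib = RTLibrary((
            LibraryEntry("C17:0", 6.0, is_internal_standard=True),
            LibraryEntry("A", 7.0, response_factor=2.0),
        ))
        peaks = assign_peaks(table(6.0, 7.0), lib, rt_tolerance=0.05)
        q = quantify(peaks, lib, aliquot_cdw_mg=10.0, is_mass_ug=75.0)
        assert q.masses_ug["A"] == pytest.approx(37.5)

    def test_only_internal_standard_gives_zero_total(self):
        lib = c17_library(6.0)
        peaks = assign_peaks(table(6.0), lib, rt_tolerance=0.05)
        q = quantify(peaks, lib, aliquot_cdw_mg=10.0)
        assert q.pct_cdw_total == 0.0
        assert q.fractions == {}
        assert "zero_total" in q.flags

    def test_missing_internal_standard_is_fatal(self):
        lib = c17_library(6.0, [("A", 7.0)])
        peaks = assign_peaks(table(7.0), lib, rt_tolerance=0.05)
        with pytest.raises(ValueError, match="internal standard"):
            quantify(peaks, lib, aliquot_cdw_mg=10.0)

    def test_global_intensity_rescaling_cancels(self):
        cfg = ChromSimConfig(fa_masses_ug={"C16:0": 120.0, "C18:0": 40.0},
                             noise_sd=0.0, baseline_drift=0.0, baseline_offset=0.0)
        chrom = generate_chromatogram(cfg, aliquot_cdw_mg=5.5)
        lib = default_rt_library()

        def quant(scale):
            c = Chromatogram(rt=chrom.rt, intensity=chrom.intensity * scale,
                             aliquot_cdw_mg=5.5)
            p = assign_peaks(detect_peaks(c), lib)
            return quantify(p, lib, aliquot_cdw_mg=5.5)

        q1, q3 = quant(1.0), quant(3.0)
        assert q3.masses_ug["C16:0"] == pytest.approx(q1.masses_ug["C16:0"], rel=1e-6)
        assert q3.pct_cdw_total == pytest.approx(q1.pct_cdw_total, rel=1e-6)

    def test_pct_cdw_additive_and_linear_in_mass(self):
        lib = default_rt_library()

        def pct(masses):
            cfg = ChromSimConfig(fa_masses_ug=masses, noise_sd=0.0,
                                 baseline_drift=0.0, baseline_offset=0.0)
            c = generate_chromatogram(cfg, aliquot_cdw_mg=5.5)
            p = assign_peaks(detect_peaks(c), lib)
            return quantify(p, lib, aliquot_cdw_mg=5.5).pct_cdw_total

        a = pct({"C16:0": 100.0})
        b = pct({"C18:0": 300.0})
        both = pct({"C16:0": 100.0, "C18:0": 300.0})
        double = pct({"C16:0": 200.0})
        assert both == pytest.approx(a + b, rel=0.005)
        assert double == pytest.approx(2 * a, rel=0.005)
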