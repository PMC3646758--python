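"""GC-FID fatty-acid methyl-ester (FAME) quantification.

Turns a flame-ionization-detector chromatogram plus aliquot metadata into
per-fatty-acid masses, composition and total lipid content normalised to
cell dry weight (CDW). Quantification uses the internal-standard method:
a known mass of C17:0 (75 ug by default) is spiked into each sample, and

    mass_i = (area_i / area_IS) * mass_IS / RF_i

for each identified peak, where RF_i is a per-compound response factor
(1.0 by default: FID response is close to uniform across FAMEs). Because
only area ratios enter, the detector gain cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Chromatogram",
    "RTLibrary",
    "LibraryEntry",
    "Peak",
    "PeakTable",
    "FAQuant",
    "detect_peaks",
    "assign_peaks",
    "quantify",
]

INTERNAL_STANDARD = "C17:0"
DEFAULT_IS_MASS_UG = 75.0


@dataclass(frozen=True)
class Chromatogram:
    """A GC-FID trace with aliquot metadata.

    ``rt`` is in minutes (strictly increasing, near-uniform grid),
    ``intensity`` in pA. ``aliquot_cdw_mg`` is the dry weight of the
    extracted aliquot; ``aliquot_od_units`` the OD600-units harvested
    (10 by convention); ``is_mass_ug`` the spiked internal-standard mass.
    """

    rt: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    aliquot_od_units: float = 10.0
    aliquot_cdw_mg: float | None = None
    is_mass_ug: float = DEFAULT_IS_MASS_UG
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", y)
        if rt.size < 100:
            raise ValueError("chromatogram needs at least 100 points")
        if rt.shape != y.shape:
            raise ValueError("rt and intensity must have equal length")
        d = np.diff(rt)
        if not np.all(d > 0):
            raise ValueError("retention times must be strictly increasing")
        if (d.max() - d.min()) > 0.01 * d.mean():
            raise ValueError("retention-time grid must be uniform within 1%")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class LibraryEntry:
    fa_name: str
    rt: float
    response_factor: float = 1.0
    is_internal_standard: bool = False


@dataclass(frozen=True)
class RTLibrary:
    """Retention-time library mapping FAME names to expected RTs.

    Exactly one entry must be flagged as the internal standard (C17:0 in
    this workflow); retention times must be unique.
    """

    entries: tuple[LibraryEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        rts = [e.rt for e in self.entries]
        if len(set(rts)) != len(rts):
            raise ValueError("library retention times must be unique")
        n_is = sum(e.is_internal_standard for e in self.entries)
        if n_is != 1:
            raise ValueError(f"library must have exactly one internal standard, got {n_is}")
        if any(e.response_factor <= 0 for e in self.entries):
            raise ValueError("response factors must be positive")

    @property
    def internal_standard(self) -> LibraryEntry:
        return next(e for e in self.entries if e.is_internal_standard)

    def __getitem__(self, fa_name: str) -> LibraryEntry:
        for e in self.entries:
            if e.fa_name == fa_name:
                return e
        raise KeyError(fa_name)

    def __contains__(self, fa_name: str) -> bool:
        return any(e.fa_name == fa_name for e in self.entries)

    def names(self, include_is: bool = True) -> list[str]:
        return [e.fa_name for e in self.entries if include_is or not e.is_internal_standard]


@dataclass(frozen=True)
class Peak:
    rt_apex: float
    area: float
    left: float
    right: float
    height: float
    assignment: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PeakTable:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        for p in self.peaks:
            if p.area < 0:
                raise ValueError("peak areas must be non-negative")
            if not (p.left <= p.rt_apex <= p.right):
                raise ValueError("peak bounds must bracket the apex")
        names = [p.assignment for p in self.peaks if p.assignment]
        if len(set(names)) != len(names):
            raise ValueError("assignments must be unique per compound")

    def __len__(self) -> int:
        return len(self.peaks)

    def assigned(self) -> dict[str, Peak]:
        return {p.assignment: p for p in self.peaks if p.assignment}


@dataclass(frozen=True)
class FAQuant:
    """Per-fatty-acid quantification for one aliquot.

    ``masses_ug`` excludes the internal standard. ``pct_cdw_total`` is the
    summed FA mass as a percentage of the aliquot dry weight; ``fractions``
    are mass fractions over the detected fatty acids (empty, with the
    ``zero_total`` flag, when nothing was detected).
    """

    sample_id: str
    masses_ug: dict[str, float]
    mg_per_g_cdw: dict[str, float]
    pct_cdw_total: float
    fractions: dict[str, float]
    aliquot_cdw_mg: float
    flags: tuple[str, ...] = ()


def _estimate_baseline(rt: np.ndarray, y: np.ndarray, baseline_window: float) -> np.ndarray:
    """Rolling-minimum baseline followed by a mean smoother of equal width."""
    dt = float(np.mean(np.diff(rt)))
    half = max(1, int(round(baseline_window / dt / 2)))
    n = y.size
    mins = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        mins[i] = y[lo:hi].min()
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    pad = np.pad(mins, half, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_peaks(
    chrom: Chromatogram,
    min_prominence: float = 50.0,
    baseline_window: float = 1.0,
    bound_frac: float = 1e-3,
) -> PeakTable:
    """Baseline-correct a chromatogram and integrate its peaks.

    The baseline is a rolling minimum over ``baseline_window`` minutes,
    smoothed and subtracted. Peaks are local maxima of the corrected signal
    with prominence >= ``min_prominence`` pA. Integration bounds extend from
    each apex to the nearest point where the corrected signal falls below
    ``bound_frac`` of the peak height (effectively the baseline crossing) or
    to the valley shared with an adjacent peak, whichever comes first; the
    area is the trapezoidal integral of the corrected signal between bounds.

    Flat-topped (saturated) peaks are integrated as-is but flagged.
    """
    rt, y = chrom.rt, chrom.intensity
    base = _estimate_baseline(rt, y, baseline_window)
    corrected = y - base

    idx, props = signal.find_peaks(corrected, prominence=min_prominence)
    if idx.size == 0:
        return PeakTable(())

    peaks: list[Peak] = []
    for k, apex in enumerate(idx):
        height = corrected[apex]
        floor = max(bound_frac * height, 0.0)
        # shared-valley limits with neighbouring detected peaks
        lo_limit = idx[k - 1] if k > 0 else 0
        hi_limit = idx[k + 1] if k + 1 < idx.size else corrected.size - 1
        if k > 0:
            lo_limit = lo_limit + int(np.argmin(corrected[lo_limit : apex + 1]))
        if k + 1 < idx.size:
            hi_limit = apex + int(np.argmin(corrected[apex : hi_limit + 1]))
        left = apex
        while left > lo_limit and corrected[left - 1] > floor:
            left -= 1
        right = apex
        while right < hi_limit and corrected[right + 1] > floor:
            right += 1
        area = float(np.trapezoid(corrected[left : right + 1], rt[left : right + 1]))
        flags: tuple[str, ...] = ()
        # flat-top: consecutive samples at the apex level suggest clipping
        plateau = np.sum(np.isclose(corrected[left : right + 1], height, rtol=1e-6))
        if plateau >= 3:
            flags = ("saturated",)
        peaks.append(
            Peak(
                rt_apex=float(rt[apex]),
                area=max(area, 0.0),
                left=float(rt[left]),
                right=float(rt[right]),
                height=float(height),
                flags=flags,
            )
        )
    return PeakTable(tuple(peaks))


def assign_peaks(peaks: PeakTable, lib: RTLibrary, rt_tolerance: float = 0.05) -> PeakTable:
    """Match peaks to library entries by nearest retention time.

    Greedy globally-nearest matching: candidate (peak, entry) pairs within
    ``rt_tolerance`` minutes are taken in order of increasing |delta RT|;
    each entry captures at most one peak and each peak at most one entry.
    Unmatched peaks keep ``assignment=None``.
    """
    cands = []
    for i, p in enumerate(peaks.peaks):
        for e in lib.entries:
            d = abs(p.rt_apex - e.rt)
            if d <= rt_tolerance:
                cands.append((d, i, e.fa_name))
    cands.sort()
    used_peaks: set[int] = set()
    used_entries: set[str] = set()
    assignment: dict[int, str] = {}
    for d, i, name in cands:
        if i in used_peaks or name in used_entries:
            continue
        assignment[i] = name
        used_peaks.add(i)
        used_entries.add(name)
    return PeakTable(
        tuple(
            replace(p, assignment=assignment.get(i)) for i, p in enumerate(peaks.peaks)
        )
    )


def quantify(
    peaks: PeakTable,
    lib: RTLibrary,
    aliquot_cdw_mg: float,
    is_mass_ug: float = DEFAULT_IS_MASS_UG,
    sample_id: str = "",
) -> FAQuant:
    """Internal-standard quantification of an assigned peak table.

    Requires the internal-standard peak to be assigned with positive area;
    raises ``ValueError`` otherwise (no IS, no quantification). Total lipid
    content is reported as % of aliquot CDW over the identified FAs.
    """
    if aliquot_cdw_mg is None or aliquot_cdw_mg <= 0:
        raise ValueError("aliquot_cdw_mg must be positive")
    assigned = peaks.assigned()
    is_name = lib.internal_standard.fa_name
    is_peak = assigned.get(is_name)
    if is_peak is None or is_peak.area <= 0:
        raise ValueError(
            f"internal standard {is_name} not found in chromatogram; cannot quantify"
        )

    masses: dict[str, float] = {}
    for name, peak in assigned.items():
        if name == is_name:
            continue
        rf = lib[name].response_factor
        masses[name] = (peak.area / is_peak.area) * is_mass_ug / rf

    total_ug = sum(masses.values())
    cdw_ug = aliquot_cdw_mg * 1000.0
    pct = 100.0 * total_ug / cdw_ug
    mg_per_g = {k: v / aliquot_cdw_mg for k, v in masses.items()}  # ug/mg == mg/g
    flags: tuple[str, ...] = ()
    if total_ug > 0:
        fractions = {k: v / total_ug for k, v in masses.items()}
    else:
        fractions = {}
        flags = ("zero_total",)
    return FAQuant(
        sample_id=sample_id,
        masses_ug=masses,
        mg_per_g_cdw=mg_per_g,
        pct_cdw_total=pct,
        fractions=fractions,
        aliquot_cdw_mg=float(aliquot_cdw_mg),
        flags=flags,
    )
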