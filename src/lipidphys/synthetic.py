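"""Seeded synthetic-data generators for the whole pipeline.

Every downstream stage (growth fitting, peak integration, internal-standard
quantification, trajectory classification) can be exercised offline against
known ground truth:

* growth curves — a lag + exponential + deceleration OD600 model with
  either a *delayed logistic* (flat at od0 until the lag ends, logistic
  thereafter; gives exact lag recovery) or the smooth *Baranyi* model
  (``h0 = mu * lag``);
* chromatograms — resolved Gaussian peaks whose areas are proportional to
  per-fatty-acid mass through a single detector constant k, plus a C17:0
  internal-standard peak, linear baseline drift and Gaussian noise;
* scenarios — a growth curve plus one chromatogram per physiological time
  point (1/5, 1/2 and 1 x OD max), with true per-FA masses set so that the
  configured total lipid %CDW and composition are exactly encoded.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fame import (
    DEFAULT_IS_MASS_UG,
    Chromatogram,
    LibraryEntry,
    RTLibrary,
)
from .growth import ODTimeSeries

__all__ = [
    "GrowthSimConfig",
    "ChromSimConfig",
    "ScenarioConfig",
    "Scenario",
    "DETECTOR_K",
    "default_rt_library",
    "generate_growth_curve",
    "generate_chromatogram",
    "generate_scenario",
]

#: Detector constant: peak area (pA*min) per ug of analyte. Arbitrary but
#: fixed; it cancels in the internal-standard area ratio.
DETECTOR_K = 1000.0

_GROWTH_MODELS = ("delayed_logistic", "baranyi")


def default_rt_library() -> RTLibrary:
    """FAME retention-time library at 1-minute spacings.

    Covers the C14-C18 compounds that dominate oleaginous-yeast profiles,
    with C17:0 as the internal standard (odd-chain, absent from the cells).
    """
    names = ["C14:0", "C16:0", "C16:1(n-7)", "C17:0", "C18:0", "C18:1(n-9)", "C18:2(n-6)"]
    return RTLibrary(
        tuple(
            LibraryEntry(fa_name=n, rt=2.0 + i, response_factor=1.0,
                         is_internal_standard=(n == "C17:0"))
            for i, n in enumerate(names)
        )
    )


@dataclass(frozen=True)
class GrowthSimConfig:
    """Ground-truth parameters for one simulated growth curve.

    ``lag_true = 0`` encodes "no lag phase" (the behaviour of all clade
    strains on oleic acid). ``noise_sd`` is the standard deviation of
    multiplicative log-normal OD noise (on the log scale), which keeps
    simulated OD positive.
    """

    strain_label: str = "strain"
    medium_label: str = "glucose"
    od0: float = 0.5
    od_max_true: float = 20.0
    mu_true: float = 0.5
    lag_true: float = 0.0
    model: str = "delayed_logistic"
    sampling_interval: float = 0.5
    duration: float = 30.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _GROWTH_MODELS:
            raise ValueError(
                f"unknown growth model {self.model!r}; choose from {_GROWTH_MODELS}"
            )
        if self.od0 <= 0 or self.od0 >= self.od_max_true:
            raise ValueError("need 0 < od0 < od_max_true")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.lag_true < 0:
            raise ValueError("lag_true must be >= 0")
        if self.duration < self.lag_true:
            raise ValueError("duration must cover the lag phase")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _logistic(t: np.ndarray, od0: float, mu: float, od_max: float) -> np.ndarray:
    e = np.exp(mu * t)
    return od_max * od0 * e / (od_max + od0 * (e - 1.0))


def _delayed_logistic(t: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    od = np.full_like(t, cfg.od0, dtype=float)
    after = t >= cfg.lag_true
    od[after] = _logistic(t[after] - cfg.lag_true, cfg.od0, cfg.mu_true, cfg.od_max_true)
    return od

def _baranyi(t: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    # adjustment function with h0 = mu*lag; reduces to plain logistic at lag=0
    mu, lag = cfg.mu_true, cfg.lag_true
    h0 = mu * lag
    a = t + np.log(np.exp(-mu * t) + math.exp(-h0) - np.exp(-mu * t - h0)) / mu
    y0 = math.log(cfg.od0)
    ymax = math.log(cfg.od_max_true)
    y = y0 + mu * a - np.log(1.0 + (np.exp(mu * a) - 1.0) / math.exp(ymax - y0))
    return np.exp(y)


def model_curve(t: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    """Noiseless model OD600 at arbitrary times (used by oracle tests too)."""
    t = np.asarray(t, dtype=float)
    if cfg.model == "delayed_logistic":
        return _delayed_logistic(t, cfg)
    return _baranyi(t, cfg)


def generate_growth_curve(config: GrowthSimConfig, replicate: str = "1") -> ODTimeSeries:
    """Simulate one OD600 time series on a regular grid from 0 to duration."""
    n = int(round(config.duration / config.sampling_interval)) + 1
    t = np.arange(n) * config.sampling_interval
    od = model_curve(t, config)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        od = od * np.exp(rng.normal(0.0, config.noise_sd, size=od.shape))
    od = np.maximum(od, 1e-6)
    return ODTimeSeries(
        strain_label=config.strain_label,
        medium_label=config.medium_label,
        times=t,
        od=od,
        replicate=replicate,
    )


@dataclass(frozen=True)
class ChromSimConfig:
    """Ground truth for one simulated GC-FID chromatogram.

    Each fatty acid of mass m (ug) contributes a Gaussian peak at its library
    retention time with area ``DETECTOR_K * RF * m``; the internal standard
    contributes ``DETECTOR_K * is_mass_ug``. Response factors default to 1.
    """

    fa_masses_ug: dict[str, float] = field(default_factory=dict)
    is_mass_ug: float = DEFAULT_IS_MASS_UG
    response_factors: dict[str, float] = field(default_factory=dict)
    rt_library: RTLibrary = field(default_factory=default_rt_library)
    peak_width_sd: float = 0.04
    baseline_drift: float = 1.0
    baseline_offset: float = 10.0
    noise_sd: float = 2.0
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, m in self.fa_masses_ug.items():
            if name not in self.rt_library:
                raise ValueError(f"fatty acid {name!r} missing from RT library")
            if not np.isfinite(m) or m < 0:
                raise ValueError(f"mass for {name!r} must be finite and >= 0")
        for name, rf in self.response_factors.items():
            if rf <= 0:
                raise ValueError("response factors must be positive")
        if self.peak_width_sd <= 0 or self.sampling_rate <= 0:
            raise ValueError("peak_width_sd and sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_chromatogram(
    config: ChromSimConfig,
    sample_id: str = "",
    aliquot_od_units: float = 10.0,
    aliquot_cdw_mg: float | None = None,
) -> Chromatogram:
    """Simulate a chromatogram from true per-FA masses.

    Peaks whose library retention times are closer than 3x the peak width
    to a neighbour are noted as overlapping in the chromatogram metadata
    (they are still generated).
    """
    lib = config.rt_library
    rt_max = max(e.rt for e in lib.entries) + 1.0
    n = int(round(rt_max * config.sampling_rate)) + 1
    rt = np.arange(n) / config.sampling_rate

    sigma = config.peak_width_sd
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    y = config.baseline_offset + config.baseline_drift * rt

    contributions: list[tuple[str, float]] = [
        (lib.internal_standard.fa_name, DETECTOR_K * config.is_mass_ug)
    ]
    for name, mass in config.fa_masses_ug.items():
        rf = config.response_factors.get(name, lib[name].response_factor)
        contributions.append((name, DETECTOR_K * rf * mass))

    rts_used = sorted(lib[name].rt for name, area in contributions if area > 0)
    notes: list[str] = []
    for a, b in zip(rts_used, rts_used[1:]):
        if b - a < 3.0 * sigma:
            notes.append(f"overlapping peaks at {a:.2f} and {b:.2f} min")

    for name, area in contributions:
        if area <= 0:
            continue
        mu = lib[name].rt
        y = y + area * norm * np.exp(-0.5 * ((rt - mu) / sigma) ** 2)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)

    return Chromatogram(
        rt=rt,
        intensity=y,
        sample_id=sample_id,
        aliquot_od_units=aliquot_od_units,
        aliquot_cdw_mg=aliquot_cdw_mg,
        is_mass_ug=config.is_mass_ug,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """One strain x medium scenario: a growth curve plus a 3-point lipid
    trajectory sampled at 1/5, 1/2 and 1 x OD max.

    ``trajectory_true`` lists, per time point, ``(fraction_of_odmax,
    total lipid %CDW, composition fractions summing to 1)``. The aliquot dry
    weight is ``cdw_per_od * aliquot_od_units``.
    """

    growth: GrowthSimConfig
    trajectory_true: tuple[tuple[float, float, dict[str, float]], ...]
    cdw_per_od: float = 0.55
    aliquot_od_units: float = 10.0
    chrom: ChromSimConfig = field(default_factory=ChromSimConfig)

    def __post_init__(self) -> None:
        if self.cdw_per_od <= 0:
            raise ValueError("cdw_per_od must be positive")
        if len(self.trajectory_true) != 3:
            raise ValueError("trajectory_true must have exactly 3 points")
        for frac, pct, comp in self.trajectory_true:
            if not 0.0 < frac <= 1.0:
                raise ValueError("fraction of OD max must be in (0, 1]")
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"%CDW must lie in [0, 100], got {pct}")
            s = sum(comp.values())
            if comp and abs(s - 1.0) > 1e-9:
                raise ValueError(f"composition fractions must sum to 1, got {s}")

    @property
    def aliquot_cdw_mg(self) -> float:
        return self.cdw_per_od * self.aliquot_od_units


@dataclass(frozen=True)
class Scenario:
    """Generated bundle: the OD series plus (chromatogram, CDW) per point."""

    config: ScenarioConfig
    series: ODTimeSeries
    chromatograms: tuple[Chromatogram, ...]
    timepoint_labels: tuple[str, ...] = ("fifth", "half", "max")

    @property
    def aliquot_cdw_mg(self) -> float:
        return self.config.aliquot_cdw_mg


def true_masses_for_point(
    pct_cdw: float, composition: dict[str, float], aliquot_cdw_mg: float
) -> dict[str, float]:
    """Per-FA masses (ug) encoding a %CDW and composition in one aliquot."""
    total_ug = pct_cdw / 100.0 * aliquot_cdw_mg * 1000.0
    return {name: frac * total_ug for name, frac in composition.items()}


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the growth series and the three time-point chromatograms.

    Child seeds for the chromatograms are derived deterministically from the
    growth seed, so a scenario is fully reproducible from one integer.
    """
    series = generate_growth_curve(config.growth)
    cdw = config.aliquot_cdw_mg
    ss = np.random.SeedSequence(config.growth.seed)
    child_seeds = ss.generate_state(4)[1:]  # one per time point
    chroms = []
    for k, ((frac, pct, comp), label) in enumerate(
        zip(config.trajectory_true, ("fifth", "half", "max"))
    ):
        masses = true_masses_for_point(pct, comp, cdw)
        ccfg = replace(
            config.chrom,
            fa_masses_ug=masses,
            seed=int(child_seeds[k] % (2**31)),
        )
        chroms.append(
            generate_chromatogram(
                ccfg,
                sample_id=f"{config.growth.strain_label}_{config.growth.medium_label}_{label}",
                aliquot_od_units=config.aliquot_od_units,
                aliquot_cdw_mg=cdw,
            )
        )
    return Scenario(config=config, series=series, chromatograms=tuple(chroms))
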