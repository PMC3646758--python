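"""Reference values for the nine Yarrowia-clade type strains.

Published growth parameters (maximum specific growth rate, generation time,
lag phase, maximum cell density) measured on 2% oleic acid and 2% glucose
media for Y. lipolytica W29 (YALI), Y. yakushimensis (YAYA), Y. deformans
(YADE), C. galli (YAGA), C. oslonensis (YAOS), C. hollandica (YAHO),
C. phangngensis (YAPH), C. alimentaria (YAAL) and C. hispaniensis (YAHI),
together with the reported lipid-content landmarks (%CDW) and accumulation
patterns. These drive the packaged synthetic scenarios: where a study
reports only trajectory endpoints or a maximum, the remaining points of the
synthetic trajectory are representative values chosen to respect the
reported landmarks and pattern (see docs/methods.md); such filled-in values
are synthetic, not measurements.
"""

from __future__ import annotations

import numpy as np

from .phenotype import PhenotypeMatrix, Score, SubstrateClass
from .synthetic import ChromSimConfig, GrowthSimConfig, ScenarioConfig

__all__ = [
    "STRAINS",
    "GROWTH_PARAMETERS",
    "LIPID_TRAJECTORIES",
    "COMPOSITIONS",
    "growth_sim_config",
    "scenario_config",
    "reference_scenarios",
    "nonhydrophobic_phenotype_matrix",
    "hydrophobic_phenotype_matrix",
]

STRAINS = ("YALI", "YAYA", "YADE", "YAGA", "YAOS", "YAHO", "YAPH", "YAAL", "YAHI")

#: (mu_max h^-1, generation time h, lag h or None, OD600 max) per strain and medium.
#: Lag is None on oleic acid: all strains grew without a lag phase.
GROWTH_PARAMETERS: dict[tuple[str, str], tuple[float, float, float | None, float]] = {
    ("YALI", "oleic"): (0.21, 3.27, None, 35.31),
    ("YAYA", "oleic"): (0.18, 3.73, None, 20.35),
    ("YADE", "oleic"): (0.25, 2.74, None, 17.60),
    ("YAGA", "oleic"): (0.18, 3.91, None, 23.52),
    ("YAOS", "oleic"): (0.22, 3.12, None, 19.98),
    ("YAHO", "oleic"): (0.26, 2.67, None, 33.66),
    ("YAPH", "oleic"): (0.32, 2.18, None, 46.80),
    ("YAAL", "oleic"): (0.28, 2.46, None, 28.27),
    ("YAHI", "oleic"): (0.34, 2.06, None, 53.10),
    ("YALI", "glucose"): (0.44, 1.56, 2.54, 25.00),
    ("YAYA", "glucose"): (0.71, 0.97, 5.19, 20.86),
    ("YADE", "glucose"): (0.78, 0.89, 5.61, 17.80),
    ("YAGA", "glucose"): (0.42, 1.64, 3.38, 23.71),
    ("YAOS", "glucose"): (0.63, 1.09, 5.71, 19.00),
    ("YAHO", "glucose"): (0.53, 1.32, 3.85, 27.86),
    ("YAPH", "glucose"): (0.57, 1.21, 1.26, 29.14),
    ("YAAL", "glucose"): (0.64, 1.08, 8.77, 23.20),
    ("YAHI", "glucose"): (0.53, 1.32, 7.93, 17.30),
}

#: %CDW at the three physiological time points (1/5, 1/2, 1 x OD max).
#: Reported landmarks: YAHI max 67.1, YALI max 52.2, YAOS max 29.4,
#: YADE decline 34.4 -> 15.2 on oleic acid; YAHI 5.1 -> 7.2, YAAL 4.0 -> 4.5
#: and YAYA 6 -> 4.7 on glucose. Other values are representative synthetic
#: fill-ins consistent with the reported accumulation pattern of each strain
#: (oleic acid: peak for YALI/YAGA/YAAL/YAHI, continuous increase for
#: YAOS/YAPH, decline for YADE/YAYA/YAHO).
LIPID_TRAJECTORIES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("YALI", "oleic"): (30.0, 52.2, 40.0),
    ("YAGA", "oleic"): (25.0, 38.0, 30.0),
    ("YAAL", "oleic"): (28.0, 40.0, 33.0),
    ("YAHI", "oleic"): (45.0, 67.1, 55.0),
    ("YAOS", "oleic"): (15.0, 22.0, 29.4),
    ("YAPH", "oleic"): (18.0, 27.0, 36.0),
    ("YADE", "oleic"): (34.4, 24.0, 15.2),
    ("YAYA", "oleic"): (33.0, 26.0, 20.0),
    ("YAHO", "oleic"): (35.0, 28.0, 22.0),
    ("YALI", "glucose"): (5.0, 5.2, 5.1),
    ("YAYA", "glucose"): (6.0, 5.4, 4.7),
    ("YADE", "glucose"): (3.5, 4.5, 6.0),
    ("YAGA", "glucose"): (3.0, 4.0, 6.5),
    ("YAOS", "glucose"): (3.5, 4.5, 6.2),
    ("YAHO", "glucose"): (3.8, 4.8, 6.4),
    ("YAPH", "glucose"): (3.2, 4.2, 5.8),
    ("YAAL", "glucose"): (4.0, 4.2, 4.5),
    ("YAHI", "glucose"): (5.1, 5.8, 7.2),
}

_OLEIC_COMPOSITION = {
    "C18:1(n-9)": 0.70,
    "C16:1(n-7)": 0.10,
    "C16:0": 0.08,
    "C18:0": 0.05,
    "C18:2(n-6)": 0.05,
    "C14:0": 0.02,
}
_GLUCOSE_COMPOSITION = {
    "C18:1(n-9)": 0.45,
    "C16:0": 0.25,
    "C18:2(n-6)": 0.12,
    "C16:1(n-7)": 0.08,
    "C18:0": 0.07,
    "C14:0": 0.03,
}
# C18:2(n-6) dominates on glucose in YAAL and YAYA.
_GLUCOSE_C182_MAJOR = {
    "C18:2(n-6)": 0.40,
    "C18:1(n-9)": 0.25,
    "C16:0": 0.18,
    "C16:1(n-7)": 0.07,
    "C18:0": 0.07,
    "C14:0": 0.03,
}
# YAHI on glucose accumulates C16:0 and C18:1(n-9) in near-equal amounts.
_GLUCOSE_YAHI = {
    "C16:0": 0.34,
    "C18:1(n-9)": 0.34,
    "C18:2(n-6)": 0.12,
    "C16:1(n-7)": 0.08,
    "C18:0": 0.08,
    "C14:0": 0.04,
}

#: Fatty-acid composition (mass fractions) used at all three time points.
COMPOSITIONS: dict[tuple[str, str], dict[str, float]] = {
    **{(s, "oleic"): _OLEIC_COMPOSITION for s in STRAINS},
    **{(s, "glucose"): _GLUCOSE_COMPOSITION for s in STRAINS},
    ("YAAL", "glucose"): _GLUCOSE_C182_MAJOR,
    ("YAYA", "glucose"): _GLUCOSE_C182_MAJOR,
    ("YAHI", "glucose"): _GLUCOSE_YAHI,
}


def saturation_time(mu: float, lag: float, od0: float, od_max: float,
                    coverage: float = 0.995) -> float:
    """Duration needed for the delayed-logistic curve to reach
    ``coverage`` x od_max (closed form of the logistic time course)."""
    q = coverage / (1.0 - coverage)
    t_sat = np.log(q * (od_max - od0) / od0) / mu
    return float(lag + t_sat)


def growth_sim_config(
    strain: str,
    medium: str,
    seed: int = 0,
    od0: float = 0.5,
    sampling_interval: float = 0.5,
    noise_sd: float = 0.02,
    duration: float | None = None,
    model: str = "delayed_logistic",
) -> GrowthSimConfig:
    """Simulation config reproducing one strain x medium growth record.

    The default duration runs to 99.5% of the maximum cell density plus a
    2 h margin, so the plateau is observable for slow and fast growers alike.
    """
    mu, _gt, lag, od_max = GROWTH_PARAMETERS[(strain, medium)]
    lag = lag or 0.0
    if duration is None:
        duration = saturation_time(mu, lag, od0, od_max) + 2.0
        duration = np.ceil(duration / sampling_interval) * sampling_interval
    return GrowthSimConfig(
        strain_label=strain,
        medium_label=medium,
        od0=od0,
        od_max_true=od_max,
        mu_true=mu,
        lag_true=lag,
        model=model,
        sampling_interval=sampling_interval,
        duration=float(duration),
        noise_sd=noise_sd,
        seed=seed,
    )


def scenario_config(
    strain: str,
    medium: str,
    seed: int = 0,
    noise_sd: float = 0.02,
    cdw_per_od: float = 0.55,
    chrom: ChromSimConfig | None = None,
) -> ScenarioConfig:
    """Full scenario config (growth + 3-point lipid trajectory) for one
    strain x medium combination."""
    pcts = LIPID_TRAJECTORIES[(strain, medium)]
    comp = COMPOSITIONS[(strain, medium)]
    growth = growth_sim_config(strain, medium, seed=seed, noise_sd=noise_sd)
    return ScenarioConfig(
        growth=growth,
        trajectory_true=tuple(
            (frac, pct, comp) for frac, pct in zip((0.2, 0.5, 1.0), pcts)
        ),
        cdw_per_od=cdw_per_od,
        chrom=chrom if chrom is not None else ChromSimConfig(),
    )


def reference_scenarios(seed: int = 0, media: tuple[str, ...] = ("glucose", "oleic")):
    """The packaged 9-strain x 2-media scenario grid, seeded per scenario."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(STRAINS) * len(media))
    out = []
    k = 0
    for medium in media:
        for strain in STRAINS:
            out.append(scenario_config(strain, medium, seed=int(seeds[k] % (2**31))))
            k += 1
    return out


# -- Phenotype fixtures -------------------------------------------------------

#: The three carbon sources used by every strain of the clade.
UNIVERSAL_SUBSTRATES = ("glucose", "fructose", "glycerol")

#: The seven substrates on which growth varies between strains.
VARIABLE_SUBSTRATES = (
    "trehalose",
    "lactate",
    "erythritol",
    "mannitol",
    "N-acetyl-glucosamine",
    "potassium gluconate",
    "sorbitol",
)

#: 21 assimilation-panel carbon sources used by none of the strains.
UNUSED_SUBSTRATES = (
    "galactose", "sorbose", "sucrose", "maltose", "lactose", "raffinose",
    "melibiose", "cellobiose", "melezitose", "inositol", "xylose",
    "arabinose", "ribose", "rhamnose", "glucosamine", "methyl-glucoside",
    "salicin", "xylitol", "palatinose", "glucuronate", "levulinate",
)


def nonhydrophobic_phenotype_matrix() -> PhenotypeMatrix:
    """Synthetic fixture: the 9 strains x 31 non-hydrophobic carbon sources.

    Built from the reported strain-level facts — fructose, glycerol and
    glucose support every strain; 21 compounds support none; seven vary, with
    YAHI uniquely growing on trehalose and uniquely failing on lactate and
    erythritol — with the remaining variable cells filled in synthetically.
    Its integrity check is the 3/21/7 universal/unused/variable partition.
    """
    substrates = list(UNIVERSAL_SUBSTRATES + VARIABLE_SUBSTRATES + UNUSED_SUBSTRATES)
    m = PhenotypeMatrix(
        strains=list(STRAINS),
        substrates=substrates,
        substrate_classes={s: SubstrateClass.SUGAR_OTHER for s in substrates},
    )
    for strain in STRAINS:
        for sub in UNIVERSAL_SUBSTRATES:
            m.set_score(strain, sub, "MMB", Score.GROWTH)
        for sub in UNUSED_SUBSTRATES:
            m.set_score(strain, sub, "MMB", Score.NONE)
        # variable substrates: YAHI-specific calls, synthetic fill elsewhere
        m.set_score(strain, "trehalose", "MMB",
                    Score.GROWTH if strain == "YAHI" else Score.NONE)
        m.set_score(strain, "lactate", "MMB",
                    Score.NONE if strain == "YAHI" else Score.GROWTH)
        m.set_score(strain, "erythritol", "MMB",
                    Score.NONE if strain == "YAHI" else Score.GROWTH)
    # synthetic split for the four substrates with unspecified per-strain calls
    varies = {
        "mannitol": {"YALI", "YADE", "YAOS", "YAHO", "YAHI"},
        "N-acetyl-glucosamine": {"YALI", "YADE"},
        "potassium gluconate": {"YALI", "YAPH", "YAHI", "YAGA"},
        "sorbitol": {"YADE", "YAOS", "YAAL"},
    }
    for sub, growers in varies.items():
        for strain in STRAINS:
            m.set_score(strain, sub, "MMB",
                        Score.GROWTH if strain in growers else Score.NONE)
    return m


def hydrophobic_phenotype_matrix() -> PhenotypeMatrix:
    """Synthetic fixture: drop tests on hydrophobic substrates (MMB and YP).

    Encodes the reported observations: tributyrin, methyl myristate and
    methyl palmitate support all strains on minimal medium; the two C6
    compounds (hexanoic acid, methyl hexanoate) support none and inhibit
    growth even on rich medium; tributyrin halos form around YALI, YADE,
    YAOS, YAPH and YAHO. Cells not pinned down by those observations are
    synthetic fill-ins.
    """
    substrates = [
        "tributyrin", "triolein", "methyl hexanoate", "methyl decanoate",
        "methyl myristate", "methyl palmitate", "methyl oleate",
        "hexanoic acid", "oleic acid", "erucic acid",
        "decane", "dodecane", "hexadecane",
    ]
    classes = {
        "tributyrin": SubstrateClass.TRIGLYCERIDE,
        "triolein": SubstrateClass.TRIGLYCERIDE,
        "methyl hexanoate": SubstrateClass.METHYLATE,
        "methyl decanoate": SubstrateClass.METHYLATE,
        "methyl myristate": SubstrateClass.METHYLATE,
        "methyl palmitate": SubstrateClass.METHYLATE,
        "methyl oleate": SubstrateClass.METHYLATE,
        "hexanoic acid": SubstrateClass.FREE_FATTY_ACID,
        "oleic acid": SubstrateClass.FREE_FATTY_ACID,
        "erucic acid": SubstrateClass.FREE_FATTY_ACID,
        "decane": SubstrateClass.ALKANE,
        "dodecane": SubstrateClass.ALKANE,
        "hexadecane": SubstrateClass.ALKANE,
    }
    m = PhenotypeMatrix(
        strains=list(STRAINS),
        substrates=substrates,
        substrate_classes=classes,
        yp_control={s: Score.GROWTH for s in STRAINS},
        notes=["methyl decanoate: growth inhibition on MMB at high cell density only"],
    )
    universal = {"tributyrin", "methyl myristate", "methyl palmitate"}
    toxic_c6 = {"methyl hexanoate", "hexanoic acid"}
    # YAAL cannot use C18:1 in any form, nor C22:1; YAYA cannot use C18:1 or
    # methyl decanoate and, of the alkanes, grows only on hexadecane; YALI
    # forms no colonies on alkane minimal media.
    c18_1 = {"triolein", "methyl oleate", "oleic acid"}
    alkanes = {"decane", "dodecane", "hexadecane"}
    for strain in STRAINS:
        for sub in substrates:
            if sub in toxic_c6:
                mmb, yp = Score.NONE, Score.NONE
            elif sub in universal:
                mmb, yp = Score.GROWTH, Score.GROWTH
            elif strain == "YAAL" and (sub in c18_1 or sub == "erucic acid"):
                mmb, yp = Score.NONE, Score.GROWTH
            elif strain == "YAAL":
                mmb, yp = Score.WEAK, Score.GROWTH
            elif strain == "YAYA" and (sub in c18_1 or sub == "methyl decanoate"
                                       or sub in alkanes - {"hexadecane"}):
                mmb, yp = Score.NONE, Score.GROWTH
            elif strain == "YAYA":
                mmb, yp = Score.WEAK, Score.GROWTH
            elif strain == "YALI" and sub in alkanes:
                mmb, yp = Score.NONE, Score.GROWTH
            else:
                mmb, yp = Score.GROWTH, Score.GROWTH
            m.set_score(strain, sub, "MMB", mmb)
            m.set_score(strain, sub, "YP", yp)
    halo_strains = {"YALI", "YADE", "YAOS", "YAPH", "YAHO"}
    for strain in STRAINS:
        for medium in ("MMB", "YP"):
            m.halo[(strain, "tributyrin", medium)] = strain in halo_strains
    return m
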