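"""Categorical substrate-assimilation phenotypes.

Encodes drop-test / assimilation scores for strains x substrates x media
(minimal medium base MMB and rich medium YP), together with halo flags
(clearing zones on insoluble-substrate plates, indicating secreted lipases,
esterases or surfactants), and computes the standard summaries:

* partition of the tested substrates into universal (used by every strain),
  unused (no strain grows) and variable (some strains grow);
* the set of halo-forming strains per substrate;
* toxicity vs non-metabolization calls from the MMB/YP contrast: a substrate
  that abolishes growth even on rich medium is toxic, one that merely fails
  to support growth on minimal medium is not metabolized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Score",
    "SubstrateClass",
    "PhenotypeMatrix",
    "SubstrateSummary",
    "summarize_substrates",
    "halo_table",
    "toxicity_flags",
]


class Score(str, Enum):
    GROWTH = "growth"
    WEAK = "weak"  # collapses "delayed, weak or slow" into one level
    NONE = "none"
    UNTESTED = "untested"


class SubstrateClass(str, Enum):
    SUGAR_OTHER = "sugar/other"
    TRIGLYCERIDE = "triglyceride"
    METHYLATE = "methylate"
    FREE_FATTY_ACID = "free_fatty_acid"
    ALKANE = "alkane"


MEDIA = ("MMB", "YP")


@dataclass
class PhenotypeMatrix:
    """Strains x substrates x media categorical growth scores.

    ``scores`` maps ``(strain, substrate, medium)`` to a :class:`Score`;
    ``halo`` flags halo formation for the same keys; ``yp_control`` holds
    the growth score of each strain on the YP base alone (needed for
    toxicity calls); ``notes`` is free text for observations that are
    recorded but not modelled (e.g. density-dependent inhibition).
    """

    strains: list[str]
    substrates: list[str]
    substrate_classes: dict[str, SubstrateClass] = field(default_factory=dict)
    scores: dict[tuple[str, str, str], Score] = field(default_factory=dict)
    halo: dict[tuple[str, str, str], bool] = field(default_factory=dict)
    yp_control: dict[str, Score] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def score(self, strain: str, substrate: str, medium: str) -> Score:
        return self.scores.get((strain, substrate, medium), Score.UNTESTED)

    def set_score(
        self, strain: str, substrate: str, medium: str, score: Score | str,
        halo: bool | None = None,
    ) -> None:
        self.scores[(strain, substrate, medium)] = Score(score)
        if halo is not None:
            self.halo[(strain, substrate, medium)] = halo

    def media_present(self) -> set[str]:
        return {m for (_, _, m) in self.scores}


@dataclass(frozen=True)
class SubstrateSummary:
    """Partition of the tested substrates for one medium."""

    universal: frozenset[str]
    unused: frozenset[str]
    variable: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.universal), len(self.unused), len(self.variable))


def summarize_substrates(
    matrix: PhenotypeMatrix,
    medium: str = "MMB",
    weak_counts_as_growth: bool = True,
) -> SubstrateSummary:
    """Partition substrates into universal / unused / variable for a medium.

    Universal substrates support growth of every strain (weak growth counts
    by default, matching how weak growers are tallied in assimilation
    surveys); unused substrates support none; the rest are variable.
    Untested cells are an error (every strain must be scored on every
    substrate in the chosen medium).
    """
    growing = {Score.GROWTH, Score.WEAK} if weak_counts_as_growth else {Score.GROWTH}
    missing = [
        (s, sub)
        for sub in matrix.substrates
        for s in matrix.strains
        if matrix.score(s, sub, medium) is Score.UNTESTED
    ]
    if missing:
        raise ValueError(f"untested combinations in medium {medium!r}: {missing}")

    universal, unused, variable = set(), set(), set()
    for sub in matrix.substrates:
        col = [matrix.score(s, sub, medium) for s in matrix.strains]
        if all(sc in growing for sc in col):
            universal.add(sub)
        elif all(sc is Score.NONE for sc in col):
            unused.add(sub)
        else:
            variable.add(sub)
    return SubstrateSummary(frozenset(universal), frozenset(unused), frozenset(variable))


def halo_table(matrix: PhenotypeMatrix, substrate: str, medium: str) -> frozenset[str]:
    """Strains forming a halo on the given substrate and medium.

    Returns an empty set (with a recorded note) when no halo observations
    exist for the substrate.
    """
    keys = [k for k in matrix.halo if k[1] == substrate and k[2] == medium]
    if not keys:
        matrix.notes.append(f"no halo records for {substrate} on {medium}")
        return frozenset()
    return frozenset(s for (s, _, _) in keys if matrix.halo[(s, substrate, medium)])


def toxicity_flags(
    matrix: PhenotypeMatrix, substrates: list[str] | None = None
) -> dict[str, dict[str, str]]:
    """Per-substrate, per-strain toxicity / non-metabolization calls.

    A substrate is *toxic* for a strain when the strain fails to grow on
    YP + substrate despite growing on YP alone (the substrate inhibits even
    on rich medium); it is *non-metabolized* when the strain fails on
    MMB + substrate but grows on YP + substrate (the substrate is tolerated
    but cannot serve as sole carbon source). Returns
    ``{substrate: {strain: "toxic"|"non_metabolized"|"ok"}}``.

    Requires YP-alone control scores for every strain.
    """
    if substrates is None:
        substrates = matrix.substrates
    missing = [s for s in matrix.strains if s not in matrix.yp_control]
    if missing:
        raise ValueError(f"missing YP-alone control for strains: {missing}")
    growing = {Score.GROWTH, Score.WEAK}
    out: dict[str, dict[str, str]] = {}
    for sub in substrates:
        calls: dict[str, str] = {}
        for strain in matrix.strains:
            yp = matrix.score(strain, sub, "YP")
            mmb = matrix.score(strain, sub, "MMB")
            if yp is Score.UNTESTED or mmb is Score.UNTESTED:
                raise ValueError(
                    f"substrate {sub!r} needs both MMB and YP scores for {strain!r}"
                )
            grows_on_yp_alone = matrix.yp_control[strain] in growing
            if yp is Score.NONE and grows_on_yp_alone:
                calls[strain] = "toxic"
            elif mmb is Score.NONE and yp in growing:
                calls[strain] = "non_metabolized"
            else:
                calls[strain] = "ok"
        out[sub] = calls
    return out
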