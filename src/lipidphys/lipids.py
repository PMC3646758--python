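"""Lipid-trajectory assembly and classification.

Combines per-time-point FAME quantifications into a three-point lipid
trajectory (1/5, 1/2 and 1 x OD max) and applies the classification rules
used in comparative oleaginous-yeast physiology:

* accumulation pattern — accumulate-then-mobilize (a peak followed by
  reconsumption), continuous increase, decline, or stable;
* oleaginy — maximum lipid content above a %CDW threshold (20% default,
  the conventional lower bound for calling a yeast oleaginous);
* major compound — the dominant fatty acid at the OD-max time point, with
  near-ties (within 1% relative) reported as a tie set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fame import FAQuant

__all__ = [
    "PATTERNS",
    "TIMEPOINT_LABELS",
    "TrajectoryPoint",
    "LipidTrajectory",
    "classify_pattern",
    "call_oleaginous",
    "major_compound",
    "build_trajectory",
]

PATTERNS = ("accumulate_then_mobilize", "continuous_increase", "decline", "stable")
TIMEPOINT_LABELS = ("fifth", "half", "max")


@dataclass(frozen=True)
class TrajectoryPoint:
    label: str  # "fifth" | "half" | "max"
    pct_cdw: float
    composition_mg_g: dict[str, float]


@dataclass(frozen=True)
class LipidTrajectory:
    strain_label: str
    medium_label: str
    points: tuple[TrajectoryPoint, ...]
    pattern: str | None
    max_pct_cdw: float | None
    oleaginous: bool | None
    major_compound_at_max: frozenset[str] | None
    complete: bool = True


def classify_pattern(
    contents: tuple[float, float, float] | list[float],
    epsilon: float = 0.10,
    floor: float = 1e-9,
) -> str:
    """Classify a three-point lipid-content trajectory.

    With relative steps ``d12 = (c2-c1)/max(c1, floor)`` and
    ``d23 = (c3-c2)/max(c2, floor)``:

    * ``accumulate_then_mobilize`` — a rise beyond epsilon then a fall beyond
      epsilon (accumulation during exponential growth followed by
      reconsumption in the deceleration phase);
    * ``continuous_increase`` — a sustained net rise (d12 > eps without a
      subsequent fall and a net gain over the whole course, or flat then
      rising);
    * ``decline`` — a net loss over the course without an initial rise;
    * ``stable`` — everything else.
    """
    c1, c2, c3 = (float(c) for c in contents)
    if min(c1, c2, c3) < 0:
        raise ValueError("lipid contents must be non-negative")
    eps = epsilon
    d12 = (c2 - c1) / max(c1, floor)
    d23 = (c3 - c2) / max(c2, floor)
    if d12 > eps and d23 < -eps:
        return "accumulate_then_mobilize"
    if (d12 > eps and d23 >= -eps and c3 > c1 * (1 + eps)) or (-eps <= d12 <= eps and d23 > eps):
        return "continuous_increase"
    if c3 < c1 * (1 - eps) and d12 <= eps:
        return "decline"
    return "stable"


def call_oleaginous(max_pct_cdw: float, threshold: float = 20.0) -> bool:
    """True when the maximum lipid content strictly exceeds the threshold."""
    if not 0.0 < threshold < 100.0:
        raise ValueError("oleaginy threshold must lie in (0, 100)")
    if not 0.0 <= max_pct_cdw <= 100.0:
        raise ValueError("max_pct_cdw must lie in [0, 100]")
    return max_pct_cdw > threshold


def major_compound(
    composition: dict[str, float], tie_rel: float = 0.01
) -> frozenset[str] | None:
    """Dominant fatty acid(s) of a composition.

    Returns the argmax by mass; compounds within ``tie_rel`` relative of the
    maximum are included as a tie set (a frozenset of size 1 for a clear
    winner). Returns ``None`` for an all-zero composition.
    """
    if not composition:
        raise ValueError("composition must be non-empty")
    top = max(composition.values())
    if top <= 0:
        return None
    ties = frozenset(k for k, v in composition.items() if v >= top * (1 - tie_rel))
    return ties


def build_trajectory(
    quants: list[FAQuant | None],
    strain_label: str,
    medium_label: str,
    epsilon: float = 0.10,
    oleaginy_threshold: float = 20.0,
) -> LipidTrajectory:
    """Assemble three time-point quantifications into a labelled trajectory.

    ``quants`` must be in time-point order (fifth, half, max). A missing
    quantification (``None``) yields a partial trajectory whose
    classification fields are unset and ``complete`` is False.
    """
    if len(quants) != 3:
        raise ValueError("a trajectory needs exactly three time points")
    points = tuple(
        TrajectoryPoint(label=lab, pct_cdw=q.pct_cdw_total, composition_mg_g=dict(q.mg_per_g_cdw))
        for lab, q in zip(TIMEPOINT_LABELS, quants)
        if q is not None
    )
    if len(points) < 3:
        return LipidTrajectory(
            strain_label=strain_label,
            medium_label=medium_label,
            points=points,
            pattern=None,
            max_pct_cdw=max((p.pct_cdw for p in points), default=None),
            oleaginous=None,
            major_compound_at_max=None,
            complete=False,
        )
    contents = tuple(p.pct_cdw for p in points)
    max_pct = max(contents)
    comp_at_max = points[2].composition_mg_g
    major = major_compound(comp_at_max) if comp_at_max else None
    return LipidTrajectory(
        strain_label=strain_label,
        medium_label=medium_label,
        points=points,
        pattern=classify_pattern(contents, epsilon=epsilon),
        max_pct_cdw=max_pct,
        oleaginous=call_oleaginous(min(max_pct, 100.0), threshold=oleaginy_threshold),
        major_compound_at_max=major,
        complete=True,
    )
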