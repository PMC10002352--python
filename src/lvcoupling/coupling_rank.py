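"""Force-on indices, mutualism degree, and the S-E rank classification.

The force-on index of each subsystem combines the carrying-capacity ratio
with the competition coefficient: s_on_pollution = K_I/K_H + alpha measures
the net force development exerts on pollution control, and s_on_hdi =
K_H/K_I + beta the reverse.  The mutualism degree S1 = (sp + sh) /
sqrt(sp^2 + sh^2) lies in [-sqrt(2), sqrt(2)]; it exceeds 1 exactly when
both forces are positive and falls below -1 exactly when both are negative,
so the rank table's sign rules and its S1 thresholds are equivalent.

Ranks: S (both forces positive, advanced mutualism), A/B (mixed signs, the
positive force dominating in magnitude), C/D (mixed signs, the negative
force dominating), E (both negative, mutual suppression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import DegenerateDynamicsError, DomainError, UndefinedIndexError
from .lv_model import LVFit

Rank = Literal["S", "A", "B", "C", "D", "E"]
Quadrant = Literal["both_positive", "pos_neg", "neg_pos", "both_negative"]

#: Values within this tolerance of zero are treated as non-positive.
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CouplingAssessment:
    """Rank outcome for one entity, window, and pollution type."""

    entity: str
    window: tuple[int, int]
    pollution_type: str  # "industrial" | "domestic"
    s_on_pollution: float
    s_on_hdi: float
    s1: float
    rank: Rank
    quadrant: Quadrant


def force_on_indices(fit: LVFit, use_printed_forms: bool = False
                     ) -> tuple[float, float]:
    """Directional force-on indices from a fitted LV system.

    The canonical composite definitions are K_I/K_H + alpha and K_H/K_I +
    beta.  ``use_printed_forms`` switches to an alternative pair of closed
    forms in the raw (a, b, c) coefficients, (a_I c_H - b_H a_I)/(b_I a_H)
    and (a_H b_I + a_H c_I)/(c_H a_I), kept only for comparison: the two
    parameterizations are not algebraically equal in general.
    """
    if use_printed_forms:
        den1 = fit.b_i * fit.a_h
        den2 = fit.c_h * fit.a_i
        if abs(den1) < ZERO_TOL or abs(den2) < ZERO_TOL:
            raise DegenerateDynamicsError("printed-form denominator near zero")
        sp = (fit.a_i * fit.c_h - fit.b_h * fit.a_i) / den1
        sh = (fit.a_h * fit.b_i + fit.a_h * fit.c_i) / den2
        return sp, sh
    if not (math.isfinite(fit.k_i) and math.isfinite(fit.k_h)):
        raise DegenerateDynamicsError("non-finite carrying capacities")
    if abs(fit.k_i) < ZERO_TOL or abs(fit.k_h) < ZERO_TOL:
        raise DegenerateDynamicsError("zero carrying capacity")
    sp = fit.k_i / fit.k_h + fit.alpha
    sh = fit.k_h / fit.k_i + fit.beta
    return sp, sh


def mutualism_index(sp: float, sh: float) -> float:
    """Resultant mutualism degree S1 = (sp + sh)/sqrt(sp^2 + sh^2)."""
    norm = math.hypot(sp, sh)
    if norm == 0.0:
        raise UndefinedIndexError("mutualism index undefined at (0, 0)")
    return (sp + sh) / norm


def assign_rank(sp: float, sh: float, tol: float = ZERO_TOL) -> Rank:
    """Six-level rank from the two force-on indices.

    Values within ``tol`` of zero count as non-positive, and exact magnitude
    ties between the positive and negative force resolve to the lower rank
    (C or D) — a conservative, deterministic convention.
    """
    if not (math.isfinite(sp) and math.isfinite(sh)):
        raise DomainError(f"non-finite force-on indices ({sp}, {sh})")
    sp_pos = sp > tol
    sh_pos = sh > tol
    if sp_pos and sh_pos:
        return "S"
    if not sp_pos and not sh_pos:
        return "E"
    if sp_pos:  # sh non-positive
        return "A" if abs(sh) < sp else "C"
    return "B" if abs(sp) < sh else "D"


def classify_force_quadrant(sp: float, sh: float, tol: float = ZERO_TOL) -> Quadrant:
    """Sign-pattern quadrant of the force pair (the Tables 2-3 row key)."""
    if not (math.isfinite(sp) and math.isfinite(sh)):
        raise DomainError(f"non-finite force-on indices ({sp}, {sh})")
    sp_pos = sp > tol
    sh_pos = sh > tol
    if sp_pos and sh_pos:
        return "both_positive"
    if sp_pos:
        return "pos_neg"
    if sh_pos:
        return "neg_pos"
    return "both_negative"


#: Ranks compatible with each sign quadrant (magnitudes decide within A/C, B/D).
QUADRANT_RANKS: dict[Quadrant, tuple[Rank, ...]] = {
    "both_positive": ("S",),
    "pos_neg": ("A", "C"),
    "neg_pos": ("B", "D"),
    "both_negative": ("E",),
}


def assess(entity: str, window: tuple[int, int], pollution_type: str,
           fit: LVFit, tol: float = ZERO_TOL) -> CouplingAssessment:
    """Full coupling assessment for one fitted entity-window pair."""
    sp, sh = force_on_indices(fit)
    return CouplingAssessment(
        entity=entity,
        window=window,
        pollution_type=pollution_type,
        s_on_pollution=sp,
        s_on_hdi=sh,
        s1=mutualism_index(sp, sh),
        rank=assign_rank(sp, sh, tol),
        quadrant=classify_force_quadrant(sp, sh, tol),
    )
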