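"""Intergenerational conflict over reproductive timing.

A household holds two actors of reproductive age: a *parent* (G1) and her
*adolescent* offspring (G2) who has not yet reproduced.  Each decides whether
to reproduce (R) or not (N).  Because household resources (alloparenting,
calories) are shared, an infant that shares the household with a second infant
survives at a reduced ratio ``s`` relative to being the sole infant.  Payoffs
are expected inclusive-fitness contributions: own offspring are weighted by
relatedness 0.5, a grandchild by 0.25, and the parent's new infant by the
adolescent's expected relatedness to it, ``0.25 * (1 + c)``, where ``c`` is
the probability that the parent reproduces with the same partner who produced
the adolescent (full sibling, r = 0.5) rather than a new partner (half
sibling, r = 0.25).  Reproductive senescence enters through the *youth
benefit* ``y``, the fitness of the adolescent's infant relative to the
parent's.

For part of the parameter space the actors are in a hawk-dove game: each would
rather be the one to reproduce, but neither wants two infants in the
household.  Play is sequential -- the second mover observes the first mover's
choice and best-responds -- and whoever stands to lose more from moving second
is predicted to win the contest for the first-mover position.

The module is laid out in the order the analysis runs:

1.  parameters, roles, actions, relatedness weights;
2.  the conditional payoff functions and sole-reproducer preferences;
3.  the sequential game: best responses, closed-form thresholds, first-mover
    payoffs, losses-to-second, zone classification, winner prediction, and a
    brute-force backward-induction oracle;
4.  comparative statics: parental-absence effect sizes, family-structure
    parameterisations, age-at-first-birth rank checks, and parameter sweeps;
5.  a seeded Monte Carlo household simulator that re-derives the analytic
    payoffs from realised infant survival and sibling-identity draws.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ATOL",
    "GameParams",
    "Role",
    "Action",
    "Preference",
    "RelatednessWeights",
    "relatedness_weights",
    "PayoffTable",
    "payoff",
    "payoff_table",
    "sole_reproducer_preference",
    "critical_youth_benefit",
    "ThresholdSet",
    "thresholds",
    "best_response",
    "SequentialOutcome",
    "sequential_outcome",
    "bruteforce_solve",
    "loss_to_second",
    "Winner",
    "classify_zone",
    "ConflictAnalysis",
    "predict_winner",
    "AbsenceEffect",
    "absence_effect",
    "FamilyStructure",
    "FamilyStructureProfile",
    "family_structure_params",
    "AfbRankReport",
    "afb_rank_consistency",
    "sweep",
    "SimConfig",
    "SimResult",
    "simulate",
    "convergence_report",
]

logger = logging.getLogger("kinconflict")

# Package-wide absolute tolerance for every "indifferent" / threshold-equality
# decision.  Strict inequalities are strict beyond this band.
ATOL = 1e-9


# ---------------------------------------------------------------------------
# 1. Parameters, actors, actions
# ---------------------------------------------------------------------------


class Role(str, Enum):
    """The two actors: the parent (G1) and her adolescent offspring (G2)."""

    PARENT = "parent"
    ADOLESCENT = "adolescent"

    @property
    def other(self) -> "Role":
        return Role.ADOLESCENT if self is Role.PARENT else Role.PARENT


class Action(str, Enum):
    """Reproduce or not."""

    R = "R"
    N = "N"


class Preference(str, Enum):
    SELF = "self"
    OTHER = "other"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class GameParams:
    """One instance of the game.

    Parameters
    ----------
    s : float
        Survival ratio: survivorship of an infant sharing the household with
        a second infant relative to being the sole infant.  In [0, 1]; 1
        means co-residence is costless.
    c : float
        Parental continuity: probability the parent's next infant has the
        same second parent as the adolescent (full rather than half sibling).
        In [0, 1].
    y : float
        Youth benefit: fitness of the adolescent's infant relative to the
        parent's infant.  Positive; y > 1 encodes parental reproductive
        senescence, y < 1 an advantage to the older generation.
    """

    s: float
    c: float
    y: float

    def __post_init__(self) -> None:
        for name in ("s", "c", "y"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
            object.__setattr__(self, name, float(v))
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"survival ratio s must lie in [0, 1], got {self.s}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"parental continuity c must lie in [0, 1], got {self.c}")
        if not self.y > 0.0:
            raise ValueError(f"youth benefit y must be positive, got {self.y}")


@dataclass(frozen=True)
class RelatednessWeights:
    """Relatedness coefficients weighting each infant in the payoffs.

    ``adolescent_to_sibling`` is the expectation over the sibling-identity
    draw: 0.5 with probability c (full sibling), 0.25 otherwise.
    """

    own_offspring: float = 0.5
    parent_to_grandchild: float = 0.25
    adolescent_to_sibling: float = 0.25


def relatedness_weights(c: float) -> RelatednessWeights:
    """Relatedness weights at parental continuity ``c``."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"parental continuity c must lie in [0, 1], got {c}")
    return RelatednessWeights(adolescent_to_sibling=0.25 * (1.0 + c))


# ---------------------------------------------------------------------------
# 2. Conditional inclusive-fitness payoffs
# ---------------------------------------------------------------------------


def payoff(role: Role, own: Action, other: Action, params: GameParams) -> float:
    """Expected inclusive-fitness payoff V_role(own | other).

    With both actors reproducing, each infant survives at ratio ``s``; a sole
    infant survives at the reference ratio 1.  The first term is the actor's
    own infant (r = 0.5, the adolescent's weighted by quality y), the second
    the other actor's infant (0.25*y for the parent valuing a grandchild,
    0.25*(1+c) for the adolescent valuing an expected full/half sibling).
    """
    role = Role(role)
    own = Action(own)
    other = Action(other)
    s, c, y = params.s, params.c, params.y
    if own is Action.N and other is Action.N:
        return 0.0
    if role is Role.PARENT:
        if own is Action.R and other is Action.R:
            return 0.5 * s + 0.25 * s * y
        if own is Action.R:
            return 0.5
        return 0.25 * y
    if own is Action.R and other is Action.R:
        return 0.5 * s * y + 0.25 * s * (1.0 + c)
    if own is Action.R:
        return 0.5 * y
    return 0.25 * (1.0 + c)


@dataclass(frozen=True)
class PayoffTable:
    """All eight conditional payoffs V_i(own | other) for one game instance."""

    params: GameParams
    v1_rr: float
    v1_rn: float
    v1_nr: float
    v1_nn: float
    v2_rr: float
    v2_rn: float
    v2_nr: float
    v2_nn: float

    def get(self, role: Role, own: Action, other: Action) -> float:
        key = f"v{1 if Role(role) is Role.PARENT else 2}_{Action(own).value.lower()}{Action(other).value.lower()}"
        return getattr(self, key)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("v1_rr", "v1_rn", "v1_nr", "v1_nn", "v2_rr", "v2_rn", "v2_nr", "v2_nn")
        }


def payoff_table(params: GameParams) -> PayoffTable:
    """Tabulate payoff() for every (actor, own action, other action)."""
    vals = {}
    for role, idx in ((Role.PARENT, 1), (Role.ADOLESCENT, 2)):
        for own, other in itertools.product(Action, Action):
            vals[f"v{idx}_{own.value.lower()}{other.value.lower()}"] = payoff(
                role, own, other, params
            )
    return PayoffTable(params=params, **vals)


def sole_reproducer_preference(role: Role, params: GameParams) -> Preference:
    """When only one actor is to reproduce, which one does ``role`` prefer?

    Compares V(R|N) against V(N|R).  The parent prefers herself iff
    0.5 > 0.25*y, i.e. y < 2; the adolescent prefers herself iff
    0.5*y > 0.25*(1+c) -- always strict for y >= 1 unless c = 1 and y = 1.
    """
    self_first = payoff(role, Action.R, Action.N, params)
    other_first = payoff(role, Action.N, Action.R, params)
    if abs(self_first - other_first) <= ATOL:
        return Preference.INDIFFERENT
    return Preference.SELF if self_first > other_first else Preference.OTHER


def critical_youth_benefit(
    role: Role = Role.PARENT, c: float = 0.0, bracket: tuple[float, float] = (1e-6, 100.0)
) -> float:
    """Youth benefit at which ``role`` is indifferent about who is the sole
    reproducer, found as the root of V(R|N) - V(N|R) in y.

    For the parent this is y = 2; for the adolescent y = (1 + c) / 2.
    """

    def gap(y: float) -> float:
        p = GameParams(s=0.5, c=c, y=y)  # s is irrelevant to sole-reproducer payoffs
        return payoff(role, Action.R, Action.N, p) - payoff(role, Action.N, Action.R, p)

    return float(brentq(gap, *bracket, xtol=1e-12))


# ---------------------------------------------------------------------------
# 3. The sequential game
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdSet:
    """Closed-form critical survival ratios governing second-mover behaviour.

    Attributes
    ----------
    adolescent_adds_second : float
        s above which the adolescent reproduces given the parent has,
        ``(1 + c) / (2y + 1 + c)``.
    parent_wants_adolescent_second : float
        s above which the parent *wants* the adolescent to add a second
        infant, ``2 / (y + 2)``.
    parent_adds_second : float
        s above which the parent reproduces given the adolescent has,
        ``y / (y + 2)``.
    adolescent_wants_parent_second : float
        s above which the adolescent wants the parent to add a second infant,
        ``2y / (2y + 1 + c)``.
    """

    adolescent_adds_second: float
    parent_wants_adolescent_second: float
    parent_adds_second: float
    adolescent_wants_parent_second: float


def thresholds(params: GameParams) -> ThresholdSet:
    """The four critical s values (params.s itself is ignored)."""
    c, y = params.c, params.y
    return ThresholdSet(
        adolescent_adds_second=(1.0 + c) / (2.0 * y + 1.0 + c),
        parent_wants_adolescent_second=2.0 / (y + 2.0),
        parent_adds_second=y / (y + 2.0),
        adolescent_wants_parent_second=2.0 * y / (2.0 * y + 1.0 + c),
    )


def best_response(
    role: Role, other_action: Action, params: GameParams
) -> tuple[Action, bool]:
    """The actor's best reply to ``other_action``; R only on strict gain.

    Returns ``(action, tie_flag)``.  Exact indifference (within ATOL)
    resolves to N with the tie flag set, keeping the strict-inequality
    convention of the threshold conditions testable.
    """
    v_r = payoff(role, Action.R, other_action, params)
    v_n = payoff(role, Action.N, other_action, params)
    if abs(v_r - v_n) <= ATOL:
        return Action.N, True
    return (Action.R, False) if v_r > v_n else (Action.N, False)


@dataclass(frozen=True)
class SequentialOutcome:
    """Resolution of one sequential play of the game.

    ``first_action`` is R by convention in :func:`sequential_outcome`; the
    brute-force oracle may report N when the first mover voluntarily
    abstains.  ``n_infants`` counts R actions.
    """

    first_mover: Role
    first_action: Action
    second_action: Action
    n_infants: int
    payoff_parent: float
    payoff_adolescent: float
    second_tie: bool = False
    first_tie: bool = False

    def payoff_of(self, role: Role) -> float:
        return self.payoff_parent if Role(role) is Role.PARENT else self.payoff_adolescent


def sequential_outcome(first_mover: Role, params: GameParams) -> SequentialOutcome:
    """First mover reproduces; second mover best-responds.

    The second mover's branch is chosen by the closed-form threshold on s
    (``(1+c)/(2y+1+c)`` when the parent moved first, ``y/(y+2)`` when the
    adolescent did); s exactly at the threshold resolves to N with the tie
    flag set.  Payoffs are the matching piecewise first-mover payoffs.
    """
    first_mover = Role(first_mover)
    thr = thresholds(params)
    crit = (
        thr.adolescent_adds_second
        if first_mover is Role.PARENT
        else thr.parent_adds_second
    )
    if abs(params.s - crit) <= ATOL:
        second, tie = Action.N, True
    elif params.s > crit:
        second, tie = Action.R, False
    else:
        second, tie = Action.N, False
    table = payoff_table(params)
    if first_mover is Role.PARENT:
        p1 = table.get(Role.PARENT, Action.R, second)
        p2 = table.get(Role.ADOLESCENT, second, Action.R)
    else:
        p2 = table.get(Role.ADOLESCENT, Action.R, second)
        p1 = table.get(Role.PARENT, second, Action.R)
    return SequentialOutcome(
        first_mover=first_mover,
        first_action=Action.R,
        second_action=second,
        n_infants=1 + (second is Action.R),
        payoff_parent=p1,
        payoff_adolescent=p2,
        second_tie=tie,
    )


def bruteforce_solve(
    first_mover: Role, params: GameParams, optimize_first: bool = True
) -> SequentialOutcome:
    """Backward induction on the two-stage tree using only the payoff table.

    Independent of the closed-form thresholds: for each candidate first
    action the second mover's reply is found by direct payoff comparison,
    then (when ``optimize_first``) the first mover picks the action with the
    strictly larger own payoff.  Ties at either stage resolve to N for the
    second mover and to R for the first mover, with flags.  A first mover
    who plays N reports the voluntary abstention through ``first_action``;
    with very large youth benefits (y > 2) even the parent abstains in
    favour of the adolescent reproducing alone.
    """
    first_mover = Role(first_mover)
    second_mover = first_mover.other
    table = payoff_table(params)

    def subgame(first_action: Action) -> tuple[Action, bool, float, float]:
        v_r = table.get(second_mover, Action.R, first_action)
        v_n = table.get(second_mover, Action.N, first_action)
        if abs(v_r - v_n) <= ATOL:
            reply, tie = Action.N, True
        else:
            reply, tie = (Action.R, False) if v_r > v_n else (Action.N, False)
        v_first = table.get(first_mover, first_action, reply)
        v_second = table.get(second_mover, reply, first_action)
        return reply, tie, v_first, v_second

    reply_r, tie_r, first_r, second_r = subgame(Action.R)
    if optimize_first:
        reply_n, tie_n, first_n, second_n = subgame(Action.N)
        if first_n > first_r + ATOL:
            chosen, reply, tie, v_first, v_second, first_tie = (
                Action.N, reply_n, tie_n, first_n, second_n, False,
            )
        else:
            chosen, reply, tie, v_first, v_second = (
                Action.R, reply_r, tie_r, first_r, second_r,
            )
            first_tie = abs(first_n - first_r) <= ATOL
    else:
        chosen, reply, tie, v_first, v_second, first_tie = (
            Action.R, reply_r, tie_r, first_r, second_r, False,
        )
    if first_mover is Role.PARENT:
        p1, p2 = v_first, v_second
    else:
        p1, p2 = v_second, v_first
    return SequentialOutcome(
        first_mover=first_mover,
        first_action=chosen,
        second_action=reply,
        n_infants=(chosen is Action.R) + (reply is Action.R),
        payoff_parent=p1,
        payoff_adolescent=p2,
        second_tie=tie,
        first_tie=first_tie,
    )


def loss_to_second(role: Role, params: GameParams) -> float:
    """Fitness loss to ``role`` from the other actor reproducing first.

    Payoff when this actor moves first (and reproduces, per the sequential
    convention) minus payoff when the other actor moves first.  Negative
    values are meaningful: the actor prefers the second-mover position
    (endogenous timing) and has no incentive to compete to move first.
    """
    role = Role(role)
    own_first = sequential_outcome(role, params)
    other_first = sequential_outcome(role.other, params)
    return own_first.payoff_of(role) - other_first.payoff_of(role)


class Winner(str, Enum):
    PARENT = "parent"
    ADOLESCENT = "adolescent"
    TIE = "tie"
    NO_CONFLICT = "no_conflict"


def classify_zone(params: GameParams) -> tuple[int, tuple[float, float], bool]:
    """Assign (s, c, y) to one of three qualitative zones.

    Zone 1: s below both critical values -- only one actor reproduces.
    Zone 2: s strictly between them -- the infant count depends on who moves
    first.  Zone 3: s above both -- both reproduce regardless of order.  The
    delimiting values are ``(1+c)/(2y+1+c)`` and ``y/(y+2)``; their order
    flips at y = sqrt(1+c), where zone 2 is empty.  Returns
    ``(zone, (lower, upper), on_boundary)``; an s exactly on a bound is
    assigned to the adjacent lower-numbered zone and flagged.
    """
    thr = thresholds(params)
    lo, hi = sorted((thr.adolescent_adds_second, thr.parent_adds_second))
    s = params.s
    on_boundary = abs(s - lo) <= ATOL or abs(s - hi) <= ATOL
    if abs(s - lo) <= ATOL:
        zone = 1
    elif abs(s - hi) <= ATOL:
        zone = 1 if hi - lo <= ATOL else 2
    elif s < lo:
        zone = 1
    elif s > hi:
        zone = 3
    else:
        zone = 2
    return zone, (lo, hi), on_boundary


@dataclass(frozen=True)
class ConflictAnalysis:
    """Full resolution of one game instance: losses, zone, predicted winner.

    The winner is the actor with the strictly larger loss-to-second -- the
    one willing to expend more competitive effort for the first-mover
    position.  ``endogenous_timing`` is set when some actor's loss is
    negative (both actors agree on who should move first).  The
    ``*_abstains_first`` flags come from the backward-induction oracle and
    mark a first mover who would voluntarily forgo reproducing.
    """

    params: GameParams
    loss_parent: float
    loss_adolescent: float
    zone: int
    zone_bounds: tuple[float, float]
    on_boundary: bool
    winner: Winner
    endogenous_timing: bool
    parent_abstains_first: bool
    adolescent_abstains_first: bool


def predict_winner(params: GameParams) -> ConflictAnalysis:
    """Predict who wins the contest to reproduce first.

    ``no_conflict`` when neither actor would pay anything to move first
    (both losses <= ATOL: zone 3, or an actor prefers going second and the
    other loses nothing); ``tie`` when both losses are positive and equal
    within ATOL (the symmetric game at c=0, y=1)."""
    lp = loss_to_second(Role.PARENT, params)
    la = loss_to_second(Role.ADOLESCENT, params)
    zone, bounds, on_boundary = classify_zone(params)
    if lp <= ATOL and la <= ATOL:
        winner = Winner.NO_CONFLICT
    elif abs(lp - la) <= ATOL:
        winner = Winner.TIE
    elif lp > la:
        winner = Winner.PARENT
    else:
        winner = Winner.ADOLESCENT
    if on_boundary:
        logger.warning(
            "s=%g sits on a zone boundary (bounds %.6g, %.6g); classification flagged",
            params.s, *bounds,
        )
    return ConflictAnalysis(
        params=params,
        loss_parent=lp,
        loss_adolescent=la,
        zone=zone,
        zone_bounds=bounds,
        on_boundary=on_boundary,
        winner=winner,
        endogenous_timing=lp < -ATOL or la < -ATOL,
        parent_abstains_first=bruteforce_solve(Role.PARENT, params).first_action is Action.N,
        adolescent_abstains_first=bruteforce_solve(Role.ADOLESCENT, params).first_action
        is Action.N,
    )


# ---------------------------------------------------------------------------
# 4. Comparative statics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbsenceEffect:
    """Parental-absence effect on the adolescent's willingness to reproduce.

    Thresholds are the minimum survival ratio at which the adolescent adds a
    second infant given the parent reproduced, with both genetic parents
    present (c = 1) versus one absent (c = 0).  The effect size is the
    percent difference with the c = 1 threshold as denominator.
    """

    y: float
    threshold_present: float
    threshold_absent: float
    percent_difference: float


def absence_effect(y: float) -> AbsenceEffect:
    """Effect of losing a parent on the adolescent's reproduce-threshold.

    ``threshold_present`` = 2/(2y+2) = 1/(y+1) (c=1); ``threshold_absent`` =
    1/(2y+1) (c=0).  The percent difference, 100*y/(2y+1), grows with the
    youth benefit and vanishes as y -> 0.
    """
    if not (isinstance(y, (int, float)) and math.isfinite(y) and y > 0):
        raise ValueError(f"youth benefit y must be positive and finite, got {y!r}")
    t_present = thresholds(GameParams(s=0.5, c=1.0, y=y)).adolescent_adds_second
    t_absent = thresholds(GameParams(s=0.5, c=0.0, y=y)).adolescent_adds_second
    return AbsenceEffect(
        y=float(y),
        threshold_present=t_present,
        threshold_absent=t_absent,
        percent_difference=100.0 * (t_present - t_absent) / t_present,
    )


class FamilyStructure(str, Enum):
    TWO_GENETIC_PARENTS = "two_genetic_parents"
    PARENT_AND_STEPPARENT = "parent_and_stepparent"
    WIDOWED_SINGLE_PARENT = "widowed_single_parent"
    OTHER_SINGLE_PARENT = "other_single_parent"


_AFB_ORDINAL = {"latest": 0, "intermediate": 1, "earliest": 2}

# structure -> (default c, non-kin actor present, parent mate-search cost, AFB rank)
_FAMILY_DEFAULTS: dict[FamilyStructure, tuple[float, bool, str, str]] = {
    FamilyStructure.TWO_GENETIC_PARENTS: (1.0, False, "no", "latest"),
    FamilyStructure.PARENT_AND_STEPPARENT: (0.0, True, "no", "intermediate"),
    FamilyStructure.WIDOWED_SINGLE_PARENT: (0.0, False, "yes", "earliest"),
    FamilyStructure.OTHER_SINGLE_PARENT: (0.5, False, "maybe", "intermediate"),
}


@dataclass(frozen=True)
class FamilyStructureProfile:
    """Parameterisation of a household composition.

    ``c`` is the parental-continuity value the structure implies.  The
    non-kin and mate-search flags are qualitative metadata only -- they do
    not enter the payoffs.  ``afb_rank`` is the predicted ordering of the
    adolescent's age at first birth across structures.
    """

    structure: FamilyStructure
    c: float
    nonkin_present: bool
    mate_search_cost_parent: str
    afb_rank: str

    @property
    def afb_ordinal(self) -> int:
        return _AFB_ORDINAL[self.afb_rank]


def family_structure_params(
    structure: FamilyStructure | str, c_override: float | None = None
) -> FamilyStructureProfile:
    """Map a household composition onto a parental-continuity value.

    Two genetic parents imply near-certain continuity (default c = 1.0);
    stepparent and widowed households imply half-siblings only (c = 0);
    other single-parent households (separation, labour migration) leave some
    chance of continuity (default c = 0.5).  Defaults for the qualitative
    "~1" and "> 0" assignments are overridable via ``c_override``.
    """
    try:
        structure = FamilyStructure(structure)
    except ValueError as exc:
        known = ", ".join(m.value for m in FamilyStructure)
        raise ValueError(f"unknown family structure {structure!r}; expected one of {known}") from exc
    c_default, nonkin, search, rank = _FAMILY_DEFAULTS[structure]
    c = c_default if c_override is None else float(c_override)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"parental continuity override must lie in [0, 1], got {c}")
    return FamilyStructureProfile(
        structure=structure,
        c=c,
        nonkin_present=nonkin,
        mate_search_cost_parent=search,
        afb_rank=rank,
    )


@dataclass(frozen=True)
class AfbRankReport:
    """Computed conflict quantities per family structure plus a rank check."""

    table: pd.DataFrame
    consistent: bool


def afb_rank_consistency(
    structures: Sequence[FamilyStructureProfile] | None = None,
    s: float = 0.2,
    y: float = 1.0,
) -> AfbRankReport:
    """Check the predicted age-at-first-birth ordering against the game.

    For each structure's c, the adolescent's loss-to-second at (s, c, y)
    measures her incentive to reproduce first; the parent's winner margin
    (loss_parent - loss_adolescent) measures the pressure delaying her.  The
    ordering is consistent when the adolescent's loss is weakly larger, and
    the parent's margin weakly smaller, for structures ranked toward earlier
    first births.  Structures sharing a rank (the two intermediate
    households) are not ordered against each other.  Raises if any tested
    point falls in zone 3, where there is no conflict and the ordering is
    undefined.
    """
    if structures is None:
        structures = [family_structure_params(m) for m in FamilyStructure]
    rows = []
    for prof in structures:
        params = GameParams(s=s, c=prof.c, y=y)
        zone, _, _ = classify_zone(params)
        if zone == 3:
            raise ValueError(
                f"(s={s}, c={prof.c}, y={y}) lies in zone 3: both actors reproduce "
                "regardless of order, so the AFB ordering is undefined"
            )
        lp = loss_to_second(Role.PARENT, params)
        la = loss_to_second(Role.ADOLESCENT, params)
        rows.append(
            {
                "structure": prof.structure.value,
                "c": prof.c,
                "afb_rank": prof.afb_rank,
                "afb_ordinal": prof.afb_ordinal,
                "zone": zone,
                "loss_parent": lp,
                "loss_adolescent": la,
                "parent_margin": lp - la,
            }
        )
    table = pd.DataFrame(rows)
    consistent = True
    for i, j in itertools.combinations(range(len(table)), 2):
        a, b = table.iloc[i], table.iloc[j]
        if a["afb_ordinal"] == b["afb_ordinal"]:
            continue
        later, earlier = (a, b) if a["afb_ordinal"] < b["afb_ordinal"] else (b, a)
        if later["loss_adolescent"] > earlier["loss_adolescent"] + ATOL:
            consistent = False
        if later["parent_margin"] < earlier["parent_margin"] - ATOL:
            consistent = False
    return AfbRankReport(table=table, consistent=consistent)


_PARAM_BOUNDS = {"s": (0.0, 1.0), "c": (0.0, 1.0), "y": (np.nextafter(0.0, 1.0), np.inf)}


def _axis_values(name: str, spec) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 3:
        lo, hi, step = map(float, spec)
        values = np.arange(lo, hi + step / 2.0, step)
    else:
        values = np.asarray(list(spec), dtype=float)
    if values.size == 0:
        raise ValueError(f"axis {name!r} is empty")
    lo_b, hi_b = _PARAM_BOUNDS[name]
    if values.min() < lo_b or values.max() > hi_b:
        raise ValueError(f"axis {name!r} leaves the bounds [{lo_b}, {hi_b}]")
    return values


def sweep(
    axes: Mapping[str, Iterable[float] | tuple[float, float, float]],
    fixed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Evaluate the full analysis on a parameter grid.

    ``axes`` maps up to two of {"s", "c", "y"} to value sequences (or
    (min, max, step) tuples); ``fixed`` supplies the remaining parameters.
    Returns a tidy frame, one row per grid point, carrying the four
    thresholds, both losses, zone, zone bounds, winner, and the
    endogenous-timing flag -- the tables behind the threshold, loss, and
    absence-effect figures.  Deterministic: no randomness anywhere.
    """
    fixed = dict(fixed or {})
    unknown = (set(axes) | set(fixed)) - {"s", "c", "y"}
    if unknown:
        raise ValueError(f"unknown parameter(s) {sorted(unknown)}")
    if set(axes) & set(fixed):
        raise ValueError("a parameter cannot be both swept and fixed")
    if set(axes) | set(fixed) != {"s", "c", "y"}:
        raise ValueError("axes plus fixed values must cover exactly {s, c, y}")
    if len(axes) > 2:
        raise ValueError("at most two parameters may be swept")
    axis_names = list(axes)
    axis_values = [_axis_values(n, axes[n]) for n in axis_names]
    rows = []
    for combo in itertools.product(*axis_values):
        point = dict(fixed)
        point.update(zip(axis_names, combo))
        params = GameParams(**point)
        thr = thresholds(params)
        res = predict_winner(params)
        rows.append(
            {
                "s": params.s,
                "c": params.c,
                "y": params.y,
                "thr_adolescent_adds_second": thr.adolescent_adds_second,
                "thr_parent_wants_adolescent_second": thr.parent_wants_adolescent_second,
                "thr_parent_adds_second": thr.parent_adds_second,
                "thr_adolescent_wants_parent_second": thr.adolescent_wants_parent_second,
                "loss_parent": res.loss_parent,
                "loss_adolescent": res.loss_adolescent,
                "zone": res.zone,
                "zone_lower": res.zone_bounds[0],
                "zone_upper": res.zone_bounds[1],
                "on_boundary": res.on_boundary,
                "winner": res.winner.value,
                "endogenous_timing": res.endogenous_timing,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 5. Monte Carlo validation of the payoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """One simulation cell: a game instance, an action profile, reps, seed."""

    params: GameParams
    actions: tuple[Action, Action]  # (parent, adolescent)
    n_reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "actions", (Action(self.actions[0]), Action(self.actions[1]))
        )
        if not (isinstance(self.n_reps, int) and self.n_reps >= 1):
            raise ValueError(f"n_reps must be an integer >= 1, got {self.n_reps!r}")


@dataclass(frozen=True)
class SimResult:
    config: SimConfig
    mean_payoff_parent: float
    mean_payoff_adolescent: float
    se_parent: float
    se_adolescent: float
    analytic_parent: float
    analytic_adolescent: float
    z_parent: float
    z_adolescent: float


def _z(mean: float, analytic: float, se: float) -> float:
    if se > 0.0:
        return (mean - analytic) / se
    return 0.0 if abs(mean - analytic) <= ATOL else math.inf


def simulate(config: SimConfig) -> SimResult:
    """Household simulator re-deriving the analytic payoffs by averaging.

    Per replicate: each actor who plays R produces one infant.  A sole
    infant survives with probability 1; when two infants share the household
    each survives independently with marginal probability s.  If the parent
    reproduces, the new infant is a full sibling of the adolescent with
    probability c (relatedness 0.5) and a half sibling otherwise (0.25).
    Realised payoffs sum relatedness x quality over surviving infants
    (quality y for the adolescent's infant, 1 for the parent's; the parent
    values the grandchild at 0.25*y, her own infant at 0.5; the adolescent
    values her own at 0.5*y).  Means over replicates estimate the analytic
    conditional payoffs; z-scores standardise the discrepancy.
    """
    rng = np.random.default_rng(config.seed)
    s, c, y = config.params.s, config.params.c, config.params.y
    a_parent, a_adol = config.actions
    n = config.n_reps
    parent_r = a_parent is Action.R
    adol_r = a_adol is Action.R
    p_survive = s if (parent_r and adol_r) else 1.0

    surv_parent_infant = (
        (rng.random(n) < p_survive).astype(float) if parent_r else np.zeros(n)
    )
    surv_adol_infant = (
        (rng.random(n) < p_survive).astype(float) if adol_r else np.zeros(n)
    )
    # sibling identity only matters (and is only drawn) when the parent reproduces
    if parent_r:
        r_sib = np.where(rng.random(n) < c, 0.5, 0.25)
    else:
        r_sib = np.zeros(n)

    pay_parent = 0.5 * surv_parent_infant + 0.25 * y * surv_adol_infant
    pay_adol = 0.5 * y * surv_adol_infant + r_sib * surv_parent_infant

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        m = float(x.mean())
        se = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        return m, se

    m1, se1 = mean_se(pay_parent)
    m2, se2 = mean_se(pay_adol)
    a1 = payoff(Role.PARENT, a_parent, a_adol, config.params)
    a2 = payoff(Role.ADOLESCENT, a_adol, a_parent, config.params)
    return SimResult(
        config=config,
        mean_payoff_parent=m1,
        mean_payoff_adolescent=m2,
        se_parent=se1,
        se_adolescent=se2,
        analytic_parent=a1,
        analytic_adolescent=a2,
        z_parent=_z(m1, a1, se1),
        z_adolescent=_z(m2, a2, se2),
    )


def convergence_report(
    param_grid: Sequence[GameParams],
    actions: tuple[Action, Action] = (Action.R, Action.R),
    rep_schedule: Sequence[int] = (100, 10_000, 1_000_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Absolute Monte Carlo error per grid point and replicate count.

    Each (point, n_reps) cell gets an independent child seed spawned from
    ``seed``, so errors shrink as O(1/sqrt(n_reps)) in expectation and the
    whole table is reproducible bit-for-bit from the same inputs.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(param_grid) * len(rep_schedule)))
    rows = []
    for params in param_grid:
        for n_reps in rep_schedule:
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            res = simulate(SimConfig(params=params, actions=actions, n_reps=int(n_reps), seed=child_seed))
            rows.append(
                {
                    "s": params.s,
                    "c": params.c,
                    "y": params.y,
                    "action_parent": Action(actions[0]).value,
                    "action_adolescent": Action(actions[1]).value,
                    "n_reps": int(n_reps),
                    "abs_err_parent": abs(res.mean_payoff_parent - res.analytic_parent),
                    "abs_err_adolescent": abs(
                        res.mean_payoff_adolescent - res.analytic_adolescent
                    ),
                    "se_parent": res.se_parent,
                    "se_adolescent": res.se_adolescent,
                    "z_parent": res.z_parent,
                    "z_adolescent": res.z_adolescent,
                }
            )
    return pd.DataFrame(rows)
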