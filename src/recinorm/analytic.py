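"""Closed-form CESS classification in the rare-error limit.

In the limit of vanishing error rates a self-cooperative norm drives the
population to ``h* = 1`` (up to the global G/B relabeling, which the
classifier tries in both orientations).  Self-cooperation pins down

    P(G,G) = 1,  R1(G,G,C) = 1,  R2(G,G,C) = 1,
    recovery:  R̄1(G,B) + R̄2(G,B) + R̄1(B,G) + R̄2(B,G) > 2,

and strictness forces ``P(G,B) = 0`` (cooperating with the rare bad player
would make reputations worthless).  What remains is a per-context optimality
check of the action rule against one-shot deviations, each of which turns
into a bound on ``b/c``.  The two branches ``P(B,G) = 1`` (bad donors buy
their reputation back by cooperating) and ``P(B,G) = 0`` (bad donors defect
and are forgiven) have different reputation-recovery times and therefore
different bound structures:

* branch ``P(B,G)=1``: every ratio shares the numerator
  ``N = R1(B,G,C) + R2(G,B,D)``;
* branch ``P(B,G)=0``: lower bounds take the form
  ``1 + (R1(B,G,D) + R2(G,B,D)) / denom`` — one extra round of defection is
  unavoidable before recovery.

A ratio with a non-positive denominator is an unfulfillable condition and is
treated as an infinite bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .norms import (BB, BG, C, D, GB, GG, ErrorRates, Norm,
                    generous_scoring_norm, sl2_norm, ss1_norm, swap_labels)

__all__ = [
    "AnalyticVerdict", "classify_cess", "sl2_bounds", "ss1_bounds",
    "second_order_cess", "generous_scoring", "nash_payoff_gap",
]


@dataclass(frozen=True)
class AnalyticVerdict:
    """Result of the rare-error-limit classification."""

    is_cess: bool
    branch: str | None            # "P(B,G)=1" | "P(B,G)=0" | None
    bc_lower: float
    bc_upper: float
    forced_pbb: float | None
    failed_conditions: tuple[str, ...]
    orientation: str = "as-given"  # or "swapped" when h*=1 holds after relabel

    @property
    def feasible(self) -> bool:
        return self.bc_lower < self.bc_upper


def _ratio(num: float, den: float) -> float:
    """Bound ratio; a non-positive denominator means the condition can never
    be met for finite b/c."""
    if den <= 0.0:
        return math.inf
    return num / den


def _classify_oriented(norm: Norm, *, compute_forced: bool = True
                       ) -> AnalyticVerdict:
    P, R1, R2 = norm.P, norm.R1, norm.R2
    failed: list[str] = []

    for ctx, label in ((BG, "P(B,G)"), (BB, "P(B,B)")):
        if P[ctx] not in (0.0, 1.0):
            failed.append(f"{label} in {{0,1}} (stochastic action rules are "
                          "payoff-neutral, never strict)")
    if P[GG] != 1.0:
        failed.append("P(G,G)=1")
    if P[GB] != 0.0:
        failed.append("P(G,B)=0")
    if R1[GG, C] != 1.0:
        failed.append("R1(G,G,C)=1")
    if R2[GG, C] != 1.0:
        failed.append("R2(G,G,C)=1")
    if R1[GG, D] >= 1.0:
        failed.append("R1(G,G,D)<1")
    if failed:
        return AnalyticVerdict(False, None, 1.0, math.inf, None,
                               tuple(failed))

    branch_coop = P[BG] == 1.0
    branch = "P(B,G)=1" if branch_coop else "P(B,G)=0"

    # Error-recovery inequality: a stray bad reputation must heal.
    if branch_coop:
        recovery = R1[GB, D] + R2[GB, D] + R1[BG, C] + R2[BG, C]
    else:
        recovery = R1[GB, D] + R2[GB, D] + R1[BG, D] + R2[BG, D]
    if not recovery > 2.0:
        failed.append("recovery: Rbar1(G,B)+Rbar2(G,B)+Rbar1(B,G)+Rbar2(B,G)>2")

    lower = 1.0
    upper = math.inf

    if branch_coop:
        num = R1[BG, C] + R2[GB, D]
        # (B,G): cooperation must pay off for a bad donor.
        if not R1[BG, C] > R1[BG, D]:
            failed.append("R1(B,G,C)>R1(B,G,D)")
        lower = max(lower, _ratio(num, R1[BG, C] - R1[BG, D]))
        # (G,G): cooperation must preserve the good donor's standing.
        lower = max(lower, _ratio(num, R1[GG, C] - R1[GG, D]))
        # (G,B): defection against the bad must not be tempting to drop.
        if R1[GB, C] > R1[GB, D]:
            upper = min(upper, _ratio(num, R1[GB, C] - R1[GB, D]))
        # (B,B): the norm's own P(B,B) must be the optimal action.
        if P[BB] == 1.0:
            if not R1[BB, C] > R1[BB, D]:
                failed.append("P(B,B)=1 requires R1(B,B,C)>R1(B,B,D)")
            lower = max(lower, _ratio(num, R1[BB, C] - R1[BB, D]))
        else:
            if R1[BB, C] > R1[BB, D]:
                upper = min(upper, _ratio(num, R1[BB, C] - R1[BB, D]))
    else:
        num0 = R1[BG, D] + R2[GB, D]
        den_gg = R1[GG, C] - R1[GG, D]
        lower = max(lower, 1.0 + _ratio(num0, den_gg))
        # (B,G): defection must beat buying the reputation back.
        if R1[BG, C] > R1[BG, D]:
            upper = min(upper, _ratio(R1[BG, C] + R2[GB, D],
                                      R1[BG, C] - R1[BG, D]))
        # (G,B): justified defection must beat cooperation.
        if R1[GB, C] > R1[GB, D]:
            upper = min(upper, 1.0 + _ratio(num0, R1[GB, C] - R1[GB, D]))
        # (B,B)
        if P[BB] == 1.0:
            if not R1[BB, C] > R1[BB, D]:
                failed.append("P(B,B)=1 requires R1(B,B,C)>R1(B,B,D)")
            lower = max(lower, 1.0 + _ratio(num0, R1[BB, C] - R1[BB, D]))
        else:
            if R1[BB, C] > R1[BB, D]:
                upper = min(upper, 1.0 + _ratio(num0, R1[BB, C] - R1[BB, D]))

    if math.isinf(lower):
        failed.append("finite lower b/c bound")
    if not lower < upper:
        failed.append("nonempty b/c interval (L < U)")

    is_cess = not failed
    forced = _forced_pbb(norm) if compute_forced else None
    return AnalyticVerdict(is_cess, branch, float(lower), float(upper),
                           forced, tuple(failed))


def _forced_pbb(norm: Norm) -> float | None:
    """The P(B,B) value admitting a feasible interval, if any.

    The (B,B) deviation bound depends on b/c, so in principle both actions can
    be optimal on disjoint b/c ranges; the reported value is the norm's own
    P(B,B) when it is feasible, otherwise the alternative if that would be."""
    own = float(norm.P[BB])
    candidates = (own, 1.0 - own) if own in (0.0, 1.0) else (1.0, 0.0)
    for pbb in candidates:
        p = norm.P.copy()
        p[BB] = pbb
        cand = Norm(p, norm.R1, norm.R2)
        if _classify_oriented(cand, compute_forced=False).is_cess:
            return pbb
    return None


def classify_cess(norm: Norm) -> AnalyticVerdict:
    """Exact CESS classification of a (possibly stochastic) norm.

    Both label orientations are tried — self-cooperation only requires the
    *majority* reputation to be self-sustaining, and the relabeled norm has
    the mirrored dynamics — so the verdict is invariant under
    :func:`~recinorm.norms.swap_labels`.
    """
    direct = _classify_oriented(norm)
    if direct.is_cess:
        return direct
    swapped = _classify_oriented(swap_labels(norm))
    if swapped.is_cess:
        return AnalyticVerdict(True, swapped.branch, swapped.bc_lower,
                               swapped.bc_upper, swapped.forced_pbb,
                               (), orientation="swapped")
    return direct


def sl2_bounds(p1: float, p2: float, p3: float, p4: float = 0.0
               ) -> tuple[float, bool, bool]:
    """CESS bound for the stochastic-L2 family.

    Returns ``(bc_lower, is_cess, strict_caption_inequality)`` where the last
    flag reports whether the stricter reading ``1 - p1 > p3`` additionally
    holds (for ``p3 <= 1 - p1`` the bound clamps at 1; the classifier itself
    only requires a nonempty interval).  The bound evaluates to
    ``max{(p3+p4)/(1-p1), (p3+p4)/p3, 1}`` when feasible.
    """
    for name, v in (("p1", p1), ("p2", p2), ("p3", p3), ("p4", p4)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    verdict = classify_cess(sl2_norm(p1, p2, p3, p4))
    return verdict.bc_lower, verdict.is_cess, bool(1.0 - p1 > p3)


def ss1_bounds(p1: float, p2: float, p3: float) -> tuple[float, bool]:
    """CESS bound ``1 + p3/(1-p1)`` for the stochastic-S1 family (requires
    ``p1 < 1`` and ``p2 + p3 > 1``).  Returns ``(bc_lower, is_cess)``."""
    for name, v in (("p1", p1), ("p2", p2), ("p3", p3)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    verdict = classify_cess(ss1_norm(p1, p2, p3))
    return verdict.bc_lower, verdict.is_cess


def second_order_cess(norm: Norm) -> tuple[AnalyticVerdict, bool]:
    """Classify a second-order norm and flag the unit-bound specialization.

    Second-order norms ignore the donor's own reputation, which forces the
    cooperative branch (``P(B,G) = P(G,G) = 1``).  The returned flag is True
    when the norm moreover satisfies the conditions making it a CESS for
    *every* ``b/c > 1``: ``R1(-,G,D) = 0``, ``R1(-,B,D) > 0``,
    ``R1(-,B,C) <= R1(-,B,D)``, ``R2(-,G,C) = 1`` and ``R2(-,B,D) = 0``.
    """
    if norm.order > 2:
        raise ValueError("norm is third order: entries depend on the donor's "
                         "own reputation")
    verdict = classify_cess(norm)
    R1, R2 = norm.R1, norm.R2
    # Conditions in (-, Y) form; rows GG/BG share (-, G), GB/BB share (-, B).
    unit_bound = bool(
        verdict.is_cess
        and R1[GG, D] == 0.0
        and R1[GB, D] > 0.0
        and R1[GB, C] <= R1[GB, D]
        and R2[GG, C] == 1.0
        and R2[GB, D] == 0.0
    )
    return verdict, unit_bound


def generous_scoring(b: float, c: float) -> Norm:
    """Construct first-order Generous Scoring for benefit ``b``, cost ``c``.

    The norm is self-cooperative and payoff-indifferent against every action
    rule (a non-strict Nash equilibrium): its lower and upper ``b/c`` bounds
    coincide at ``b/c`` itself, so :func:`classify_cess` reports it as not a
    strict CESS.
    """
    return generous_scoring_norm(b, c)


def nash_payoff_gap(norm: Norm, b: float, c: float,
                    mu: float = 1e-6) -> float:
    """Max payoff advantage of any deterministic action-rule mutant.

    Evaluated numerically at small error rate ``mu``; a norm is a (weak) Nash
    equilibrium in the rare-error limit when this tends to <= 0 as
    ``mu -> 0``.
    """
    from .stability import (DETERMINISTIC_ACTION_RULES, mutant_good_fraction,
                            payoffs)
    from .dynamics import stationary_state

    errors = ErrorRates.uniform(mu)
    state = stationary_state(norm, errors)
    gap = -math.inf
    for mutant_P in DETERMINISTIC_ACTION_RULES:
        out = mutant_good_fraction(norm, state, mutant_P, errors)
        pi_res, pi_mut = payoffs(b, c, state.p_res_res, out.p_mut_res,
                                 out.p_res_mut)
        gap = max(gap, pi_mut - pi_res)
    return gap
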