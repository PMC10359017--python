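"""Evolutionary stability of a resident norm against action-rule mutants.

An infinitesimal minority that deviates in its *action rule* ``P'`` (keeping
the population's assessment rules — rare mutants cannot shift how the public
assigns reputations) reaches its own stationary good fraction ``H*`` inside a
resident population at ``h*``.  Payoffs in the donation game with benefit
``b`` and cost ``c`` are

    pi_res = (b - c) p_res->res,
    pi_mut = b p_res->mut - c p_mut->res,

and strict stability against the mutant translates, branch by branch, into a
bound on ``b/c``.  Intersecting the bounds over all 15 deterministic mutant
action rules (per-context optimal deviations are deterministic) yields the
feasible ``(L, U)`` interval; a self-cooperative norm with a nonempty interval
is a cooperative evolutionarily stable strategy (CESS) at the given error
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .norms import BB, BG, C, D, GB, GG, ErrorRates, Norm
from .dynamics import StationaryState, stationary_state

__all__ = [
    "MutantOutcome", "BcInterval", "CessVerdict",
    "DETERMINISTIC_ACTION_RULES", "action_rule_bits",
    "mutant_good_fraction", "cross_cooperation", "payoffs",
    "bc_constraint", "cess_check", "trace_to_frame",
]

#: Default error rates for numerical CESS determination.
DEFAULT_ERRORS = ErrorRates(1e-3, 1e-3, 1e-3)
#: Default self-cooperation threshold.
DEFAULT_P_TH = 0.98
#: Tie tolerance splitting the stability-condition branches.
_TIE_TOL = 1e-9


def action_rule_bits(index: int) -> np.ndarray:
    """Deterministic action rule number ``index`` in ``[0, 16)``.

    Bit order matches the norm encoding: ``P(GG) P(GB) P(BG) P(BB)``, most
    significant first, so e.g. rule 0 is ALLD and rule 15 is ALLC.
    """
    if not 0 <= index < 16:
        raise ValueError(f"action rule index must be in [0, 16), got {index}")
    return np.array([(index >> 3) & 1, (index >> 2) & 1,
                     (index >> 1) & 1, index & 1], dtype=float)


DETERMINISTIC_ACTION_RULES = tuple(action_rule_bits(i) for i in range(16))


@dataclass(frozen=True)
class MutantOutcome:
    """Stationary reputation and cooperation levels of a rare mutant."""

    H_star: float
    p_mut_res: float
    p_res_mut: float
    H1: float
    H2: float
    H3: float
    H4: float


def mutant_good_fraction(resident: Norm, resident_state: StationaryState,
                         mutant_P, errors: ErrorRates) -> MutantOutcome:
    """Stationary good fraction of a mutant with action rule ``mutant_P``.

    The mutant is assessed by the resident rules: as a donor through
    ``R̄1(X, Y | P')`` (its own effective action feeding the resident ``R1``),
    as a recipient through the resident context averages ``R̄2``.  The linear
    flow for the mutant good fraction ``H(t)`` has the unique stable fixed
    point ``H* = [h* H1 + (1-h*) H2] / [2 - h* H3 - (1-h*) H4]``.
    """
    eff = resident_state.effective
    p_mut_eff = (1.0 - errors.mu_e) * np.asarray(mutant_P, dtype=float)
    rbar1_mut = p_mut_eff * eff.R1[:, C] + (1.0 - p_mut_eff) * eff.R1[:, D]
    rbar2 = resident_state.rbar2
    h = resident_state.h_star

    h1 = rbar1_mut[BG] + rbar2[GB]
    h2 = rbar1_mut[BB] + rbar2[BB]
    h3 = rbar1_mut[GG] + rbar2[GG] - h1
    h4 = rbar1_mut[GB] + rbar2[BG] - h2
    denom = 2.0 - h * h3 - (1.0 - h) * h4
    if denom <= 0.0:  # unreachable for probability-valued rules
        raise ArithmeticError("mutant reputation flow is not contracting")
    H = (h * h1 + (1.0 - h) * h2) / denom
    p_mr, p_rm = cross_cooperation(eff, p_mut_eff, h, H)
    return MutantOutcome(H_star=float(H), p_mut_res=p_mr, p_res_mut=p_rm,
                         H1=float(h1), H2=float(h2), H3=float(h3),
                         H4=float(h4))


def cross_cooperation(eff: Norm, p_mut_eff: np.ndarray, h_star: float,
                      H_star: float) -> tuple[float, float]:
    """Cooperation rates mutant->resident and resident->mutant.

    Both are bilinear in ``(H*, h*)``; note the context transposition in the
    resident->mutant direction (the mutant is then the recipient).
    """
    h, H = h_star, H_star
    pm = p_mut_eff
    p = eff.P
    p_mut_res = (H * h * pm[GG] + H * (1 - h) * pm[GB]
                 + (1 - H) * h * pm[BG] + (1 - H) * (1 - h) * pm[BB])
    p_res_mut = (H * h * p[GG] + H * (1 - h) * p[BG]
                 + (1 - H) * h * p[GB] + (1 - H) * (1 - h) * p[BB])
    return float(p_mut_res), float(p_res_mut)


def payoffs(b: float, c: float, p_res_res: float, p_mut_res: float,
            p_res_mut: float) -> tuple[float, float]:
    """Donation-game payoffs of resident and mutant."""
    if not b > c > 0:
        raise ValueError(f"require b > c > 0, got b={b}, c={c}")
    return (b - c) * p_res_res, b * p_res_mut - c * p_mut_res


@dataclass
class BcInterval:
    """Feasible benefit-to-cost interval ``L < b/c < U`` (``U`` may be inf)."""

    lower: float = 1.0
    upper: float = math.inf
    infeasible_flag: bool = False

    @property
    def feasible(self) -> bool:
        return not self.infeasible_flag and self.lower < self.upper

    def update_lower(self, ratio: float) -> None:
        self.lower = max(self.lower, ratio)

    def update_upper(self, ratio: float) -> None:
        self.upper = min(self.upper, ratio)

    def mark_infeasible(self) -> None:
        self.infeasible_flag = True


def bc_constraint(p_res_res: float, p_mut_res: float, p_res_mut: float,
                  tol: float = _TIE_TOL) -> tuple[str, float | None]:
    """Stability condition against one mutant, as an interval update.

    Strict stability ``pi_res > pi_mut`` rearranges to
    ``b (p_res->res - p_res->mut) > c (p_res->res - p_mut->res)``:

    * ``p_res->res > p_res->mut``: lower bound
      ``b/c > (p_res->res - p_mut->res) / (p_res->res - p_res->mut)``;
    * ``p_res->res < p_res->mut``: the same ratio as an upper bound;
    * tie: stable for every ``b/c`` iff ``p_res->res < p_mut->res``.

    Returns ``(branch, ratio)`` with branch one of ``"lower"``, ``"upper"``,
    ``"none"`` (tie, stable), ``"infeasible"`` (tie, unstable).
    """
    diff = p_res_res - p_res_mut
    ratio_num = p_res_res - p_mut_res
    if diff > tol:
        return "lower", ratio_num / diff
    if diff < -tol:
        return "upper", ratio_num / diff
    if p_mut_res - p_res_res > tol:
        return "none", None
    return "infeasible", None


@dataclass(frozen=True)
class CessVerdict:
    """Outcome of the numerical CESS determination."""

    norm: Norm
    errors: ErrorRates
    p_th: float
    p_res_res: float
    self_cooperative_pass: bool
    interval: BcInterval
    is_cess: bool
    edge_case: bool
    constraint_trace: list = field(default_factory=list)

    @property
    def bc_lower(self) -> float:
        return self.interval.lower

    @property
    def bc_upper(self) -> float:
        return self.interval.upper


def cess_check(norm: Norm, errors: ErrorRates = DEFAULT_ERRORS,
               p_th: float = DEFAULT_P_TH, *, gap_tol: float = 1e-3,
               max_lower: float = 10.0) -> CessVerdict:
    """Numerical CESS determination at finite error rates.

    Rejects the norm if the resident self-cooperation rate falls below
    ``p_th``; otherwise intersects the ``b/c`` constraints against the 15
    deterministic action rules differing from the resident's.  Near-degenerate
    results (interval narrower than ``gap_tol`` or a lower bound above
    ``max_lower``) are flagged as numerical edge cases and not certified.

    Residents with a stochastic action rule are rejected outright: per-context
    best responses are deterministic, so such residents are at best neutral
    against some deterministic rule and never *strictly* stable.
    """
    if not np.all((norm.P == 0.0) | (norm.P == 1.0)):
        raise ValueError(
            "cess_check requires a deterministic action rule: a stochastic "
            "P is payoff-neutral against some deterministic deviation and "
            "therefore never a strict ESS")
    state = stationary_state(norm, errors)
    p_rr = state.p_res_res
    self_pass = p_rr >= p_th
    interval = BcInterval()
    trace: list[dict] = []
    if self_pass:
        resident_bits = norm.P.astype(int)
        for idx in range(16):
            mutant_P = DETERMINISTIC_ACTION_RULES[idx]
            if np.array_equal(mutant_P.astype(int), resident_bits):
                continue
            out = mutant_good_fraction(norm, state, mutant_P, errors)
            branch, ratio = bc_constraint(p_rr, out.p_mut_res, out.p_res_mut)
            if branch == "lower":
                interval.update_lower(ratio)
            elif branch == "upper":
                interval.update_upper(ratio)
            elif branch == "infeasible":
                interval.mark_infeasible()
            trace.append({
                "mutant": idx,
                "mutant_P": "".join(str(int(v)) for v in mutant_P),
                "H_star": out.H_star,
                "p_mut_res": out.p_mut_res,
                "p_res_mut": out.p_res_mut,
                "branch": branch,
                "ratio": ratio,
                "lower": interval.lower,
                "upper": interval.upper,
            })
    edge_case = interval.feasible and (
        abs(interval.upper - interval.lower) < gap_tol
        or interval.lower > max_lower)
    is_cess = bool(self_pass and interval.feasible and not edge_case)
    return CessVerdict(norm=norm, errors=errors, p_th=p_th, p_res_res=p_rr,
                       self_cooperative_pass=bool(self_pass),
                       interval=interval, is_cess=is_cess,
                       edge_case=bool(edge_case), constraint_trace=trace)


def trace_to_frame(verdict: CessVerdict):
    """Per-mutant constraint trace as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(verdict.constraint_trace)
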