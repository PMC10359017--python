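"""Reputation dynamics in a homogeneous population.

With public assessment the whole population agrees on everyone's standing, so
the state of an infinitely large homogeneous population is the single number
``h(t)``: the fraction of players currently assessed as good.  Donor-recipient
pairs are drawn at random, the donor acts, and *both* players are re-assessed,
which gives the mean-field flow

    dh/dt = h^2 s(G,G) + h(1-h) [s(G,B) + s(B,G)] + (1-h)^2 s(B,B) - 2 h,

where ``s(X, Y) = R̄1(X, Y) + R̄2(X, Y)`` sums the expected good-assessment
probabilities of donor and recipient in a context, averaged over the donor's
(effective) action.  The right-hand side is quadratic in ``h``; with positive
assessment error rates the flow is inward at both boundaries, so the fixed
point ``h*`` is unique and stable and solves ``A h^2 + B h + C = 0``.

The stationary cooperation rate of the resident population is then the action
rule averaged over stationary reputation matchings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .norms import BB, BG, C, D, GB, GG, ErrorRates, Norm, effective_norm

__all__ = [
    "StationaryState", "expected_assessments", "hdot",
    "stationary_state", "self_cooperation_rate",
    "integrate_dynamics", "simulate_finite_population",
]

#: |A| below which the quadratic is treated as linear.
_LINEAR_THRESHOLD = 1e-9
#: Newton polish on the quadratic residual.
_NEWTON_TOL = 1e-14
_NEWTON_MAX_ITER = 50
#: Stand-in assessment error used to take the zero-error limit by continuity.
_LIMIT_MU = 1e-12


def expected_assessments(eff: Norm) -> tuple[np.ndarray, np.ndarray]:
    """Context-averaged good-assessment probabilities ``(R̄1, R̄2)``.

    ``R̄i(X, Y) = P̃(X, Y) R̃i(X, Y, C) + (1 - P̃(X, Y)) R̃i(X, Y, D)`` for an
    already error-perturbed norm ``eff``.
    """
    p = eff.P
    rbar1 = p * eff.R1[:, C] + (1.0 - p) * eff.R1[:, D]
    rbar2 = p * eff.R2[:, C] + (1.0 - p) * eff.R2[:, D]
    return rbar1, rbar2


def hdot(h: float, eff: Norm) -> float:
    """Rate of change of the good fraction at ``h`` under effective rules."""
    rbar1, rbar2 = expected_assessments(eff)
    s = rbar1 + rbar2
    return (h * h * s[GG] + h * (1.0 - h) * (s[GB] + s[BG])
            + (1.0 - h) ** 2 * s[BB] - 2.0 * h)


@dataclass(frozen=True)
class StationaryState:
    """Stationary reputation state of a homogeneous resident population."""

    rbar1: np.ndarray          # context-averaged donor assessments (4,)
    rbar2: np.ndarray          # context-averaged recipient assessments (4,)
    quad_a: float
    quad_b: float
    quad_c: float
    h_star: float              # stationary fraction of good players
    p_res_res: float           # resident self-cooperation rate
    effective: Norm            # the effective (error-perturbed) norm used

    def residual(self) -> float:
        """``|dh/dt|`` at the reported fixed point."""
        return abs(hdot(self.h_star, self.effective))


def _solve_quadratic(a: float, b: float, c: float, eff: Norm) -> float:
    if abs(a) < _LINEAR_THRESHOLD:
        if abs(b) > _LINEAR_THRESHOLD:
            h = -c / b
        else:
            # Degenerate flow; fall back to a bracketed root of hdot itself.
            h = brentq(lambda x: hdot(x, eff), 0.0, 1.0, xtol=1e-15)
    else:
        disc = b * b - 4.0 * a * c
        disc = max(disc, 0.0)
        h = (-b - np.sqrt(disc)) / (2.0 * a)
        if not -_LINEAR_THRESHOLD <= h <= 1.0 + _LINEAR_THRESHOLD:
            h = (-b + np.sqrt(disc)) / (2.0 * a)
    # Newton polish of the quadratic residual (the closed form can lose
    # precision when A is small but above the linear threshold).
    for _ in range(_NEWTON_MAX_ITER):
        f = a * h * h + b * h + c
        if abs(f) < _NEWTON_TOL:
            break
        fp = 2.0 * a * h + b
        if fp == 0.0:
            break
        h -= f / fp
    return float(min(max(h, 0.0), 1.0))


def stationary_state(norm: Norm, errors: ErrorRates | None = None,
                     *, already_effective: bool = False) -> StationaryState:
    """Solve for the stationary good fraction and self-cooperation rate.

    With ``errors`` given, the norm is first error-perturbed.  At exactly zero
    error rates the boundary points 0 and 1 can both be roots; the fixed point
    reported is the one approached in the positive-error limit, implemented by
    substituting a vanishing assessment error (1e-12) for the zero rates.
    """
    if already_effective:
        eff = norm
    else:
        errors = errors or ErrorRates()
        if errors.all_zero:
            errors = ErrorRates(0.0, _LIMIT_MU, _LIMIT_MU)
        eff = effective_norm(norm, errors)
    rbar1, rbar2 = expected_assessments(eff)
    s = rbar1 + rbar2
    a = s[GG] - s[GB] - s[BG] + s[BB]
    b = s[GB] + s[BG] - 2.0 * s[BB] - 2.0
    c = s[BB]
    h = _solve_quadratic(a, b, c, eff)
    p_rr = self_cooperation_rate(eff, h)
    return StationaryState(rbar1=rbar1, rbar2=rbar2, quad_a=float(a),
                           quad_b=float(b), quad_c=float(c), h_star=h,
                           p_res_res=p_rr, effective=eff)


def self_cooperation_rate(eff: Norm, h_star: float) -> float:
    """Resident-vs-resident cooperation probability at stationarity."""
    h = h_star
    p = eff.P
    return float(h * h * p[GG] + h * (1.0 - h) * (p[GB] + p[BG])
                 + (1.0 - h) ** 2 * p[BB])


def integrate_dynamics(eff: Norm, h0: float, horizon: float = 200.0,
                       n_points: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """Numerically integrate the mean-field flow (test oracle).

    Returns ``(t, h(t))`` on a uniform grid; the terminal value converges to
    the closed-form fixed point for any admissible start ``h0 in [0, 1]``.
    """
    if not 0.0 <= h0 <= 1.0:
        raise ValueError(f"h0 must be in [0, 1], got {h0}")
    ts = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(lambda _, y: hdot(float(y[0]), eff), (0.0, horizon), [h0],
                    t_eval=ts, rtol=1e-12, atol=1e-12, method="LSODA")
    if not sol.success:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"reputation flow integration failed: {sol.message}")
    return sol.t, sol.y[0]


def simulate_finite_population(norm: Norm, errors: ErrorRates, n_agents: int,
                               n_steps: int, seed: int,
                               burn_in: int | None = None
                               ) -> tuple[float, float]:
    """Agent-based realization of the interaction process (test oracle).

    A population of ``n_agents`` holds public binary reputations (all good
    initially).  Each step draws a donor-recipient pair, realizes the donor's
    action under the implementation error, and re-assesses both players under
    the assessment errors.  Returns the time-averaged good fraction and the
    empirical cooperation rate after ``burn_in`` steps (default: a quarter of
    ``n_steps``).
    """
    if n_agents < 2:
        raise ValueError("need at least two agents")
    rng = np.random.default_rng(seed)
    eff = effective_norm(norm, errors)
    rep = np.ones(n_agents, dtype=np.int8)  # 1 = good
    burn = n_steps // 4 if burn_in is None else burn_in

    pairs = rng.integers(0, n_agents, size=(n_steps, 2))
    # Redraw self-pairings (donor plays someone else).
    clash = pairs[:, 0] == pairs[:, 1]
    while np.any(clash):
        pairs[clash, 1] = rng.integers(0, n_agents, size=int(clash.sum()))
        clash = pairs[:, 0] == pairs[:, 1]
    u_act = rng.random(n_steps)
    u_r1 = rng.random(n_steps)
    u_r2 = rng.random(n_steps)

    p_eff = eff.P.tolist()
    r1_eff = eff.R1.tolist()
    r2_eff = eff.R2.tolist()
    rep_list = rep.tolist()
    n_good = n_agents
    good_sum = 0.0
    coop_count = 0
    n_obs = 0
    pair_list = pairs.tolist()
    for t in range(n_steps):
        donor, recip = pair_list[t]
        x, y = 1 - rep_list[donor], 1 - rep_list[recip]   # 0 = G, 1 = B
        ctx = 2 * x + y
        act = C if u_act[t] < p_eff[ctx] else D
        new_d = 1 if u_r1[t] < r1_eff[ctx][act] else 0
        new_r = 1 if u_r2[t] < r2_eff[ctx][act] else 0
        n_good += (new_d - rep_list[donor]) + (new_r - rep_list[recip])
        rep_list[donor] = new_d
        rep_list[recip] = new_r
        if t >= burn:
            good_sum += n_good
            coop_count += (act == C)
            n_obs += 1
    return good_sum / (n_obs * n_agents), coop_count / n_obs
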