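"""Error sensitivity of cooperative norms.

A single assessment slip plants one bad player in an otherwise good
population.  Until that reputation heals, the norm prescribes defections
(justified punishment, or the bad player's own defections), and each of those
interactions can in turn taint further players.  Summing the resulting
geometric cascade gives chi, the expected total number of defections caused
by one bad player; an implementation error additionally contributes its own
defection plus the ``2 - R1(G,G,D) - R2(G,G,D)`` bad reputations it creates.
To first order in the error rates,

    1 - p_res->res  ~=  (1 + [2 - R1(G,G,D) - R2(G,G,D)] chi) mu_e
                        + chi mu_a1 + chi mu_a2.

The denominator of chi equals ``-d(hdot)/dh`` at ``h = 1`` in the rare-error
limit: both measure how fast the population recovers full good standing.
Norms with small chi tolerate errors well but, because the same assessment
entries enter the evolutionary ``b/c`` bounds, they need a larger benefit of
cooperation to stay stable — the central tradeoff this module quantifies.

Throughout, the single-parameter sensitivity uses the equal-rate convention
``mu_e = mu_a1 = mu_a2 = mu`` for every norm, recipient-passive ones
included (the passive R2 table is still subject to assessment noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .norms import BB, BG, C, D, GB, GG, ErrorRates, Norm
from .dynamics import stationary_state
from .analytic import classify_cess

__all__ = [
    "SensitivityReport", "chi", "sensitivity_expansion", "sensitivity_factor",
    "numerical_sensitivity", "tradeoff_scan", "report",
]


def chi(norm: Norm) -> float:
    """Expected number of defections triggered by a single bad player.

    Branch ``P(B,G)=1``: defections happen only while the bad player is the
    recipient; branch ``P(B,G)=0``: the bad player also defects as a donor,
    doubling the count and drawing on different recovery entries.  A
    non-positive denominator means the cascade does not die out (no recovery)
    and chi is infinite.
    """
    R1, R2 = norm.R1, norm.R2
    if norm.P[BG] == 1.0:
        den = R1[GB, D] + R2[GB, D] + R1[BG, C] + R2[BG, C] - 2.0
        num = 1.0
    elif norm.P[BG] == 0.0:
        den = R1[GB, D] + R2[GB, D] + R1[BG, D] + R2[BG, D] - 2.0
        num = 2.0
    else:
        raise ValueError("chi requires a deterministic P(B,G) branch")
    if den <= 0.0:
        return math.inf
    return num / den


def sensitivity_expansion(norm: Norm, errors: ErrorRates) -> float:
    """First-order prediction of ``1 - p_res->res`` at the given rates."""
    x = chi(norm)
    coeff_e = 1.0 + (2.0 - norm.R1[GG, D] - norm.R2[GG, D]) * x
    return float(coeff_e * errors.mu_e + x * errors.mu_a1 + x * errors.mu_a2)


def sensitivity_factor(norm: Norm) -> float:
    """Equal-rate sensitivity ``(1 - p_res->res)/mu`` to first order.

    This is the expansion evaluated at ``mu_e = mu_a1 = mu_a2 = mu``, divided
    by ``mu``:  ``1 + (2 - R1(G,G,D) - R2(G,G,D)) chi + 2 chi``.
    """
    x = chi(norm)
    return float(1.0 + (2.0 - norm.R1[GG, D] - norm.R2[GG, D]) * x + 2.0 * x)


def numerical_sensitivity(norm: Norm, mu: float) -> float:
    """Exact ``(1 - p_res->res)/mu`` at equal error rates ``mu``."""
    if not mu > 0:
        raise ValueError("mu must be positive")
    state = stationary_state(norm, ErrorRates.uniform(mu))
    return (1.0 - state.p_res_res) / mu


@dataclass(frozen=True)
class SensitivityReport:
    """Error robustness summary of one norm."""

    chi: float
    expansion_factor: float       # first-order (1 - p_res->res)/mu
    numerical: float              # exact value at the probed mu
    mu: float
    bc_lower: float               # companion evolutionary bound
    is_cess: bool


def report(norm: Norm, mu: float = 1e-3) -> SensitivityReport:
    """Full sensitivity report; non-CESS norms are evaluated but flagged
    (the expansion is derived for CESS norms only)."""
    verdict = classify_cess(norm)
    return SensitivityReport(
        chi=chi(norm),
        expansion_factor=sensitivity_factor(norm),
        numerical=numerical_sensitivity(norm, mu),
        mu=mu,
        bc_lower=verdict.bc_lower,
        is_cess=verdict.is_cess,
    )


def tradeoff_scan(norms: Iterable[tuple[str, Norm]] | Iterable[Norm],
                  mu: float = 1e-3, *, skip_non_cess: bool = True,
                  aggregate: bool = True) -> pd.DataFrame:
    """Sensitivity-vs-stability table for a set of norms.

    Accepts norms or ``(label, norm)`` pairs; returns one row per norm (or per
    distinct ``(sensitivity, bc_lower, label)`` cluster when ``aggregate``)
    with columns ``label, chi, sensitivity, bc_lower, count``.  Non-CESS
    entries are skipped (with a ``skipped`` attribute on the frame) unless
    ``skip_non_cess`` is False.
    """
    rows = []
    skipped = []
    for item in norms:
        label, norm = item if isinstance(item, tuple) else (
            getattr(item, "name", None) or "norm", item)
        verdict = classify_cess(norm)
        if not verdict.is_cess and skip_non_cess:
            skipped.append((label, "; ".join(verdict.failed_conditions)
                            or "not CESS"))
            continue
        rows.append({
            "label": label,
            "chi": chi(norm),
            "sensitivity": numerical_sensitivity(norm, mu),
            "expansion": sensitivity_factor(norm),
            "bc_lower": verdict.bc_lower,
        })
    frame = pd.DataFrame(rows,
                         columns=["label", "chi", "sensitivity", "expansion",
                                  "bc_lower"])
    if aggregate and not frame.empty:
        frame = (frame
                 .groupby(["label", "chi", "expansion", "bc_lower"],
                          as_index=False)
                 .agg(sensitivity=("sensitivity", "mean"),
                      count=("sensitivity", "size")))
        frame = frame[["label", "chi", "sensitivity", "expansion",
                       "bc_lower", "count"]]
    elif not frame.empty:
        frame["count"] = 1
    frame.attrs["skipped"] = skipped
    return frame
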