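"""Exhaustive scans of the deterministic norm space.

Deterministic norms are 20-bit integers (4 action bits, 8 donor-assessment
bits, 8 recipient-assessment bits), so the full dual-update space holds
2^20 = 1,048,576 norms — 524,800 up to the global G/B relabeling.  The
recipient-passive subspace (R2 fixed to "keep the recipient's standing")
has 2^12 members.  This module scans either space with the analytic
rare-error conditions or the finite-error numerical check, both vectorized
over norm ids, and sorts the survivors into the named CESS families
(leading-eight variants, secondary-sixteen variants, and the L'/S'/S''
classes that only exist with recipient updating).

Counting convention: CESS norms are counted directly in the G-majority
orientation (the one with ``h* = 1``); the orbit tally under relabeling is
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norms import (BB, BG, C, D, GB, GG, N_DETERMINISTIC, ErrorRates, Norm,
                    catalog_lookup, decode_deterministic, encode_deterministic,
                    passive_r2)
from .stability import DEFAULT_ERRORS, DEFAULT_P_TH

__all__ = [
    "FamilyLabel", "CensusReport", "enumerate_cess", "classify_family",
    "second_order_census", "swap_ids", "canonical_ids", "PASSIVE_R2_BITS",
]

#: R2 bit pattern (GG.C .. BB.D) of the recipient-passive rule.
PASSIVE_R2_BITS = 0b11001100

# Bit positions, most significant first (see norms.encode_deterministic).
_BIT = {
    "pGG": 19, "pGB": 18, "pBG": 17, "pBB": 16,
    "r1GGC": 15, "r1GGD": 14, "r1GBC": 13, "r1GBD": 12,
    "r1BGC": 11, "r1BGD": 10, "r1BBC": 9, "r1BBD": 8,
    "r2GGC": 7, "r2GGD": 6, "r2GBC": 5, "r2GBD": 4,
    "r2BGC": 3, "r2BGD": 2, "r2BBC": 1, "r2BBD": 0,
}


def _bits(ids: np.ndarray) -> dict[str, np.ndarray]:
    return {k: ((ids >> pos) & 1).astype(np.uint8) for k, pos in _BIT.items()}


def swap_ids(ids: np.ndarray) -> np.ndarray:
    """Vectorized G/B relabeling on encoded ids."""
    b = _bits(np.asarray(ids, dtype=np.int64))
    out = np.zeros_like(np.asarray(ids, dtype=np.int64))
    # Action rule: contexts permute (GG<->BB, GB<->BG).
    pairs = {
        "pGG": b["pBB"], "pGB": b["pBG"], "pBG": b["pGB"], "pBB": b["pGG"],
    }
    # Assessments: permute contexts and complement the assigned label.
    for rule in ("r1", "r2"):
        for ctx, swapped in (("GG", "BB"), ("GB", "BG"),
                             ("BG", "GB"), ("BB", "GG")):
            for act in "CD":
                pairs[f"{rule}{ctx}{act}"] = 1 - b[f"{rule}{swapped}{act}"]
    for key, val in pairs.items():
        out |= val.astype(np.int64) << _BIT[key]
    return out


def canonical_ids(ids: np.ndarray) -> np.ndarray:
    """Orbit representative ``min(id, swapped id)`` for each id."""
    ids = np.asarray(ids, dtype=np.int64)
    return np.minimum(ids, swap_ids(ids))


def _passive_space_ids() -> np.ndarray:
    """All 2^12 ids with P and R1 free and R2 recipient-passive."""
    return (np.arange(1 << 12, dtype=np.int64) << 8) | PASSIVE_R2_BITS


# -- analytic census -----------------------------------------------------------


def _analytic_cess_mask(ids: np.ndarray) -> np.ndarray:
    """Rare-error-limit CESS test in the G-orientation, vectorized.

    Specializes the closed-form conditions to binary entries: the shared
    preconditions, the branch recovery inequality, the per-context optimality
    of the action rule (which for binary assessment differences either leaves
    the bound unchanged or collapses the interval), and the pinned P(B,B).
    """
    b = {k: v.astype(np.int64) for k, v in _bits(ids).items()}
    base = ((b["pGG"] == 1) & (b["pGB"] == 0)
            & (b["r1GGC"] == 1) & (b["r1GGD"] == 0) & (b["r2GGC"] == 1))
    pbb_ok = b["pBB"] == ((b["r1BBC"] == 1) & (b["r1BBD"] == 0))

    coop = b["pBG"] == 1
    rec1 = (b["r1GBD"] + b["r2GBD"] + b["r1BGC"] + b["r2BGC"]) >= 3
    br1 = (coop & rec1
           & (b["r1BGC"] == 1) & (b["r1BGD"] == 0)
           & (b["r1GBC"] <= b["r1GBD"]))

    rec0 = (b["r1GBD"] + b["r2GBD"] + b["r1BGD"] + b["r2BGD"]) >= 3
    br0 = (~coop & rec0
           & (b["r1BGC"] <= b["r1BGD"])
           & (b["r1GBC"] <= b["r1GBD"]))

    return base & pbb_ok & (br1 | br0)


def _analytic_bc_lower(ids: np.ndarray) -> np.ndarray:
    """Analytic lower b/c bound for G-oriented CESS ids."""
    b = {k: v.astype(np.int64) for k, v in _bits(ids).items()}
    coop = b["pBG"] == 1
    return np.where(coop,
                    1.0 + b["r2GBD"],
                    1.0 + b["r1BGD"] + b["r2GBD"]).astype(float)


# -- numerical census ----------------------------------------------------------


def _numerical_cess_mask(ids: np.ndarray, errors: ErrorRates, p_th: float,
                         gap_tol: float, max_lower: float,
                         tie_tol: float = 1e-9) -> np.ndarray:
    """Vectorized finite-error CESS check (mirrors stability.cess_check)."""
    bits = _bits(ids)
    n = len(ids)
    p = np.stack([bits["pGG"], bits["pGB"], bits["pBG"], bits["pBB"]],
                 axis=1).astype(float)
    r1 = np.stack([[bits["r1GGC"], bits["r1GGD"]],
                   [bits["r1GBC"], bits["r1GBD"]],
                   [bits["r1BGC"], bits["r1BGD"]],
                   [bits["r1BBC"], bits["r1BBD"]]], axis=0)
    r2 = np.stack([[bits["r2GGC"], bits["r2GGD"]],
                   [bits["r2GBC"], bits["r2GBD"]],
                   [bits["r2BGC"], bits["r2BGD"]],
                   [bits["r2BBC"], bits["r2BBD"]]], axis=0)
    r1 = np.moveaxis(r1, 2, 0).astype(float)   # (n, 4, 2)
    r2 = np.moveaxis(r2, 2, 0).astype(float)

    p_eff = (1.0 - errors.mu_e) * p
    r1e = (1.0 - errors.mu_a1) * r1 + errors.mu_a1 * (1.0 - r1)
    r2e = (1.0 - errors.mu_a2) * r2 + errors.mu_a2 * (1.0 - r2)
    rbar1 = p_eff * r1e[:, :, C] + (1.0 - p_eff) * r1e[:, :, D]
    rbar2 = p_eff * r2e[:, :, C] + (1.0 - p_eff) * r2e[:, :, D]
    s = rbar1 + rbar2

    a = s[:, GG] - s[:, GB] - s[:, BG] + s[:, BB]
    bq = s[:, GB] + s[:, BG] - 2.0 * s[:, BB] - 2.0
    cq = s[:, BB]
    h = np.empty(n)
    lin = np.abs(a) < 1e-9
    h[lin] = -cq[lin] / bq[lin]
    disc = np.maximum(bq * bq - 4.0 * a * cq, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        root = (-bq - np.sqrt(disc)) / (2.0 * a)
        alt = (-bq + np.sqrt(disc)) / (2.0 * a)
    root = np.where((root < -1e-9) | (root > 1.0 + 1e-9), alt, root)
    h[~lin] = root[~lin]
    for _ in range(8):  # Newton polish on the quadratic residual
        f = a * h * h + bq * h + cq
        fp = 2.0 * a * h + bq
        step = np.where(fp != 0.0, f / np.where(fp != 0.0, fp, 1.0), 0.0)
        h = h - step
    h = np.clip(h, 0.0, 1.0)

    p_rr = (h * h * p_eff[:, GG] + h * (1 - h) * (p_eff[:, GB] + p_eff[:, BG])
            + (1 - h) ** 2 * p_eff[:, BB])
    self_ok = p_rr >= p_th

    lower = np.ones(n)
    upper = np.full(n, np.inf)
    infeasible = np.zeros(n, dtype=bool)
    p_bits = p.astype(np.int64)
    resident_idx = (p_bits[:, 0] << 3 | p_bits[:, 1] << 2
                    | p_bits[:, 2] << 1 | p_bits[:, 3])
    for idx in range(16):
        same = resident_idx == idx
        m = np.array([(idx >> 3) & 1, (idx >> 2) & 1,
                      (idx >> 1) & 1, idx & 1], dtype=float)
        pm = (1.0 - errors.mu_e) * m
        rbar1m = pm * r1e[:, :, C] + (1.0 - pm) * r1e[:, :, D]
        h1 = rbar1m[:, BG] + rbar2[:, GB]
        h2 = rbar1m[:, BB] + rbar2[:, BB]
        h3 = rbar1m[:, GG] + rbar2[:, GG] - h1
        h4 = rbar1m[:, GB] + rbar2[:, BG] - h2
        H = (h * h1 + (1 - h) * h2) / (2.0 - h * h3 - (1 - h) * h4)
        p_mr = (H * h * pm[GG] + H * (1 - h) * pm[GB]
                + (1 - H) * h * pm[BG] + (1 - H) * (1 - h) * pm[BB])
        p_rm = (H * h * p_eff[:, GG] + H * (1 - h) * p_eff[:, BG]
                + (1 - H) * h * p_eff[:, GB]
                + (1 - H) * (1 - h) * p_eff[:, BB])
        diff = p_rr - p_rm
        num = p_rr - p_mr
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / diff
        lo = (diff > tie_tol) & ~same
        up = (diff < -tie_tol) & ~same
        tie_bad = (np.abs(diff) <= tie_tol) & ~(p_mr - p_rr > tie_tol) & ~same
        lower = np.where(lo, np.maximum(lower, ratio), lower)
        upper = np.where(up, np.minimum(upper, ratio), upper)
        infeasible |= tie_bad

    feasible = ~infeasible & (lower < upper)
    with np.errstate(invalid="ignore"):
        edge = feasible & ((upper - lower < gap_tol) | (lower > max_lower))
    return self_ok & feasible & ~edge, h


# -- families ------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyLabel:
    """CESS family of a deterministic dual-update norm."""

    name: str          # e.g. "L8-variant", "S16-variant", "L'", "pure-L8"
    row: str           # distinguishing R2 entries, e.g. "R2(G,B,D)=0,R2(B,G,C)=1"
    row_index: int     # family-table row number, 1..9
    bc_lower: float
    chi: float
    base: str | None   # the named donor rule (L1..L8 / S1..S16) if applicable


_L_PR1 = {name: (encode_deterministic(catalog_lookup(name)) >> 8)
          for name in [f"L{i}" for i in range(1, 9)]}
_S_PR1 = {name: (encode_deterministic(catalog_lookup(name)) >> 8)
          for name in [f"S{i}" for i in range(1, 17)]}


def _match_prime(kind: str, p: np.ndarray, r1: np.ndarray) -> bool:
    ok_pbb = p[BB] == (1.0 if (r1[BB, C] == 1.0 and r1[BB, D] == 0.0) else 0.0)
    if kind == "L'":
        return (tuple(p[:3]) == (1, 0, 1) and ok_pbb
                and tuple(r1[GG]) == (1, 0) and tuple(r1[GB]) == (0, 0)
                and tuple(r1[BG]) == (1, 0))
    if kind == "S'":
        return (tuple(p[:3]) == (1, 0, 0) and ok_pbb
                and tuple(r1[GG]) == (1, 0) and r1[GB, D] == 1
                and tuple(r1[BG]) == (0, 0))
    if kind == "S''":
        return (tuple(p[:3]) == (1, 0, 0) and ok_pbb
                and tuple(r1[GG]) == (1, 0) and tuple(r1[GB]) == (0, 0)
                and r1[BG, D] == 1)
    raise ValueError(kind)  # pragma: no cover


def classify_family(norm: Norm) -> FamilyLabel:
    """Assign a deterministic CESS norm (G-orientation) to its family row.

    Raises ``ValueError`` for a CESS norm matching no family — that would
    contradict the completeness of the family decomposition.
    """
    if not norm.is_deterministic:
        raise ValueError("family classification applies to deterministic norms")
    nid = encode_deterministic(norm)
    pr1 = nid >> 8
    r2 = norm.R2

    base = next((n for n, bits in _L_PR1.items() if bits == pr1), None)
    if base is not None and r2[GG, C] == 1.0:
        key = (r2[GB, D], r2[BG, C])
        rows = {(0.0, 1.0): ("R2(G,B,D)=0, R2(B,G,C)=1", 1, 1.0, 1.0),
                (1.0, 0.0): ("R2(G,B,D)=1, R2(B,G,C)=0", 2, 2.0, 1.0),
                (1.0, 1.0): ("R2(G,B,D)=1, R2(B,G,C)=1", 3, 2.0, 0.5)}
        if key in rows:
            row, ridx, bc, x = rows[key]
            name = ("pure-L8" if norm.is_recipient_passive else "L8-variant")
            return FamilyLabel(name, row, ridx, bc, x, base)

    base = next((n for n, bits in _S_PR1.items() if bits == pr1), None)
    if base is not None and r2[GG, C] == 1.0:
        key = (r2[GB, D], r2[BG, D])
        rows = {(0.0, 1.0): ("R2(G,B,D)=0, R2(B,G,D)=1", 4, 2.0, 2.0),
                (1.0, 0.0): ("R2(G,B,D)=1, R2(B,G,D)=0", 5, 3.0, 2.0),
                (1.0, 1.0): ("R2(G,B,D)=1, R2(B,G,D)=1", 6, 3.0, 1.0)}
        if key in rows:
            row, ridx, bc, x = rows[key]
            name = ("pure-S16" if norm.is_recipient_passive else "S16-variant")
            return FamilyLabel(name, row, ridx, bc, x, base)

    if (_match_prime("L'", norm.P, norm.R1) and r2[GG, C] == 1.0
            and r2[GB, D] == 1.0 and r2[BG, C] == 1.0):
        return FamilyLabel("L'", "R2(G,B,D)=1, R2(B,G,C)=1", 7, 2.0, 1.0, None)
    if (_match_prime("S'", norm.P, norm.R1) and r2[GG, C] == 1.0
            and r2[GB, D] == 1.0 and r2[BG, D] == 1.0):
        return FamilyLabel("S'", "R2(G,B,D)=1, R2(B,G,D)=1", 8, 2.0, 2.0, None)
    if (_match_prime("S''", norm.P, norm.R1) and r2[GG, C] == 1.0
            and r2[GB, D] == 1.0 and r2[BG, D] == 1.0):
        return FamilyLabel("S''", "R2(G,B,D)=1, R2(B,G,D)=1", 9, 3.0, 2.0, None)
    raise ValueError(
        f"CESS norm {nid} matches no family row — family table incomplete?")


# -- census --------------------------------------------------------------------


@dataclass
class CensusReport:
    """Outcome of an exhaustive CESS scan."""

    space: str                     # "passive-r2" | "dual-update"
    method: str                    # "analytic" | "numerical"
    total_scanned: int
    independent: int               # orbit count of the scanned space
    cess_count: int                # direct count, G-orientation
    cess_orbit_count: int          # distinct relabeling orbits among CESS
    ids: np.ndarray                # G-oriented CESS ids, sorted
    family_counts: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)     # family-table row -> n
    row_bounds: dict = field(default_factory=dict)     # row -> (bc_lower, chi)
    errors: ErrorRates | None = None
    p_th: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per CESS norm: canonical id, family, bounds, chi."""
        rows = []
        for nid in self.ids:
            norm = decode_deterministic(int(nid))
            fam = classify_family(norm)
            rows.append({
                "id": int(nid),
                "canonical_id": int(canonical_ids(np.array([nid]))[0]),
                "family": fam.name,
                "base": fam.base or "",
                "row": fam.row,
                "bc_lower": fam.bc_lower,
                "bc_upper": math.inf,
                "chi": fam.chi,
            })
        return pd.DataFrame(rows)


def enumerate_cess(recipient_update: bool = True, method: str = "analytic",
                   errors: ErrorRates = DEFAULT_ERRORS,
                   p_th: float = DEFAULT_P_TH, *, gap_tol: float = 1e-3,
                   max_lower: float = 10.0,
                   chunk: int = 1 << 16) -> CensusReport:
    """Scan the deterministic norm space and count the CESS norms.

    ``recipient_update=False`` restricts to the recipient-passive subspace
    (2^12 ids); ``method`` selects the analytic rare-error conditions or the
    vectorized numerical check at ``errors``/``p_th``.
    """
    if method not in ("analytic", "numerical"):
        raise ValueError(f"unknown method: {method!r}")
    ids = (np.arange(N_DETERMINISTIC, dtype=np.int64) if recipient_update
           else _passive_space_ids())
    cess_chunks = []
    for start in range(0, len(ids), chunk):
        part = ids[start:start + chunk]
        if method == "analytic":
            # Selects the G-majority (h* = 1) orientation directly.
            cess_chunks.append(part[_analytic_cess_mask(part)])
        else:
            mask, h = _numerical_cess_mask(part, errors, p_th, gap_tol,
                                           max_lower)
            # The finite-error check is orientation-blind: a B-majority
            # cooperator passes too.  Report the h* >= 1/2 representative
            # of each survivor so the count matches the G-oriented tally.
            sel = part[mask]
            cess_chunks.append(np.where(h[mask] >= 0.5, sel, swap_ids(sel)))
    cess_ids = np.unique(np.concatenate(cess_chunks))

    independent = len(np.unique(canonical_ids(ids)))
    orbit_count = len(np.unique(canonical_ids(cess_ids)))
    report = CensusReport(
        space="dual-update" if recipient_update else "passive-r2",
        method=method,
        total_scanned=len(ids),
        independent=independent,
        cess_count=len(cess_ids),
        cess_orbit_count=orbit_count,
        ids=cess_ids,
        errors=errors if method == "numerical" else None,
        p_th=p_th if method == "numerical" else None,
    )
    counts: dict[str, int] = {}
    row_counts: dict[int, int] = {}
    row_bounds: dict[int, tuple[float, float]] = {}
    for nid in report.ids:
        fam = classify_family(decode_deterministic(int(nid)))
        counts[fam.name] = counts.get(fam.name, 0) + 1
        row_counts[fam.row_index] = row_counts.get(fam.row_index, 0) + 1
        row_bounds[fam.row_index] = (fam.bc_lower, fam.chi)
    report.family_counts = counts
    report.row_counts = row_counts
    report.row_bounds = row_bounds
    return report


_SECOND_ORDER_ROWS = (
    ("L3/L6, R2(-,B,D)=0", 1.0, 1.0),
    ("L3/L6, R2(-,B,D)=1", 2.0, 0.5),
    ("L', R2(-,B,D)=1", 2.0, 1.0),
)


def second_order_census(report: CensusReport | None = None) -> CensusReport:
    """Second-order norms among the deterministic dual-update CESS.

    Second-order rules ignore the donor's own reputation; the survivors are
    variants of Simple Standing, Stern Judging, and the second-order L'.
    """
    if report is None:
        report = enumerate_cess(recipient_update=True, method="analytic")
    second = []
    for nid in report.ids:
        norm = decode_deterministic(int(nid))
        if norm.order <= 2:
            second.append(int(nid))
    ids = np.array(sorted(second), dtype=np.int64)
    counts: dict[str, int] = {}
    for nid in ids:
        norm = decode_deterministic(int(nid))
        fam = classify_family(norm)
        r2bd = norm.R2[GB, D]
        if fam.name in ("pure-L8", "L8-variant"):
            row = _SECOND_ORDER_ROWS[0] if r2bd == 0.0 else _SECOND_ORDER_ROWS[1]
        else:
            row = _SECOND_ORDER_ROWS[2]
        counts[row[0]] = counts.get(row[0], 0) + 1
    return CensusReport(
        space=report.space, method=report.method + "+second-order",
        total_scanned=report.cess_count, independent=report.independent,
        cess_count=len(ids),
        cess_orbit_count=len(np.unique(canonical_ids(ids))) if len(ids) else 0,
        ids=ids, family_counts=counts,
        errors=report.errors, p_th=report.p_th,
    )
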