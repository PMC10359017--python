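"""Social norms for indirect reciprocity with dual reputation updates.

A social norm combines an action rule ``P(X, Y)`` — the probability that a
donor with reputation ``X`` cooperates with a recipient of reputation ``Y`` —
with two assessment rules: ``R1(X, Y, A)``, the probability that the donor is
assigned a good reputation after taking action ``A``, and ``R2(X, Y, A)``, the
probability that the *recipient* is assigned a good reputation.  Reputations
are binary (good ``G`` / bad ``B``) and assessments are public: every observer
applies the same rule to the same interaction.

Entries may be any probability in ``[0, 1]``; a norm is *deterministic* when
all 20 entries are 0 or 1.  Deterministic norms are in bijection with 20-bit
integers (see :func:`encode_deterministic`), which makes the space exhaustively
enumerable.  The classical donor-only model is recovered by the
*recipient-passive* rule ``R2(X, Y, A) = 1 if Y == G else 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GG", "GB", "BG", "BB", "C", "D",
    "CONTEXTS", "ACTIONS",
    "ErrorRates", "Norm",
    "make_norm", "catalog_lookup", "catalog_names", "effective_norm",
    "encode_deterministic", "decode_deterministic", "swap_labels",
    "canonical_id", "passive_r2", "norm_from_json", "norm_to_json",
    "N_DETERMINISTIC", "N_BITS",
]

# Context order used throughout: (donor X, recipient Y).
GG, GB, BG, BB = 0, 1, 2, 3
CONTEXTS = ("GG", "GB", "BG", "BB")
# Action index within an assessment rule.
C, D = 0, 1
ACTIONS = ("C", "D")

N_BITS = 20
N_DETERMINISTIC = 1 << N_BITS  # 2^20 = 1,048,576

#: Context permutation induced by relabeling G <-> B.
_SWAP_CTX = (BB, BG, GB, GG)


def passive_r2() -> np.ndarray:
    """The recipient-passive assessment rule ``R2(X, Y, A) = δ(Y, G)``.

    The recipient keeps its current standing regardless of the interaction;
    this recovers the classical model in which only donors are (re)assessed.
    """
    return np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])


@dataclass(frozen=True)
class ErrorRates:
    """Implementation and assessment error probabilities.

    Parameters
    ----------
    mu_e:
        Implementation error: a donor intending to cooperate defects by
        mistake with this probability.  Must lie in ``[0, 1)``.
    mu_a1, mu_a2:
        Assessment errors: the reputation assigned to the donor (``mu_a1``)
        or the recipient (``mu_a2``) is flipped with this probability.
        Must lie in ``[0, 1/2)``.
    """

    mu_e: float = 0.0
    mu_a1: float = 0.0
    mu_a2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_e < 1.0:
            raise ValueError(f"mu_e must be in [0, 1), got {self.mu_e}")
        for name in ("mu_a1", "mu_a2"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 1/2), got {v}")

    @classmethod
    def uniform(cls, mu: float) -> "ErrorRates":
        """Equal rates ``mu_e = mu_a1 = mu_a2 = mu``."""
        return cls(mu, mu, mu)

    @property
    def all_zero(self) -> bool:
        return self.mu_e == 0.0 and self.mu_a1 == 0.0 and self.mu_a2 == 0.0


def _as_prob_array(values, shape, rule: str, keys: Sequence[str]) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(shape)
    flat = arr.ravel()
    for k, v in zip(keys, flat):
        if not np.isfinite(v) or v < 0.0 or v > 1.0:
            raise ValueError(f"{rule}({k}) = {v} is not a probability in [0, 1]")
    return arr


_P_KEYS = list(CONTEXTS)
_R_KEYS = [f"{ctx}.{a}" for ctx in CONTEXTS for a in ACTIONS]


@dataclass(frozen=True)
class Norm:
    """A social norm: action rule ``P`` and assessment rules ``R1``, ``R2``.

    ``P`` has shape ``(4,)`` indexed by context ``(GG, GB, BG, BB)``; ``R1``
    and ``R2`` have shape ``(4, 2)`` with the second axis indexed by the
    donor's observed action ``(C, D)``.
    """

    P: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", _as_prob_array(self.P, (4,), "P", _P_KEYS))
        object.__setattr__(self, "R1", _as_prob_array(self.R1, (4, 2), "R1", _R_KEYS))
        object.__setattr__(self, "R2", _as_prob_array(self.R2, (4, 2), "R2", _R_KEYS))
        self.P.setflags(write=False)
        self.R1.setflags(write=False)
        self.R2.setflags(write=False)

    # -- structural predicates -------------------------------------------------

    @property
    def is_deterministic(self) -> bool:
        ent = self.entries()
        return bool(np.all((ent == 0.0) | (ent == 1.0)))

    @property
    def is_recipient_passive(self) -> bool:
        """True when ``R2`` never changes the recipient's standing."""
        return bool(np.array_equal(self.R2, passive_r2()))

    @property
    def order(self) -> int:
        """Informational order of the norm (structural, exact comparison).

        3: rules depend on the donor's reputation ``X``;
        2: rules depend at most on ``(Y, A)``;
        1: assessments depend only on the action ``A`` and the recipient is
        never re-assessed (the action rule may still depend on ``Y``).
        """
        second = (
            self.P[GG] == self.P[BG]
            and self.P[GB] == self.P[BB]
            and np.array_equal(self.R1[GG], self.R1[BG])
            and np.array_equal(self.R1[GB], self.R1[BB])
            and np.array_equal(self.R2[GG], self.R2[BG])
            and np.array_equal(self.R2[GB], self.R2[BB])
        )
        if not second:
            return 3
        first = (
            np.array_equal(self.R1[GG], self.R1[GB])
            and self.is_recipient_passive
        )
        return 1 if first else 2

    def entries(self) -> np.ndarray:
        """All 20 probability entries in the documented bit order."""
        return np.concatenate([self.P, self.R1.ravel(), self.R2.ravel()])

    def with_name(self, name: str | None) -> "Norm":
        return replace(self, name=name)

    # -- conversions -----------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {}
        if self.name is not None:
            d["name"] = self.name
        d["P"] = {k: float(v) for k, v in zip(_P_KEYS, self.P)}
        d["R1"] = {k: float(v) for k, v in zip(_R_KEYS, self.R1.ravel())}
        d["R2"] = {k: float(v) for k, v in zip(_R_KEYS, self.R2.ravel())}
        return d

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = self.name or ("#%d" % encode_deterministic(self)
                              if self.is_deterministic else "stochastic")
        return f"Norm({label}, P={self.P.tolist()})"


def make_norm(P, R1, R2, name: str | None = None) -> Norm:
    """Validate and build a :class:`Norm` from 4 + 8 + 8 probabilities.

    ``P`` may be a sequence in context order or a mapping with keys
    ``GG, GB, BG, BB``; ``R1``/``R2`` a sequence of 8 in ``(context, action)``
    order or a mapping with keys like ``"GG.C"``.
    """
    def unpack(values, keys, rule):
        if isinstance(values, Mapping):
            extra = set(values) - set(keys)
            missing = set(keys) - set(values)
            if extra or missing:
                raise ValueError(
                    f"{rule} keys mismatch: missing {sorted(missing)}, "
                    f"unexpected {sorted(extra)}")
            return [values[k] for k in keys]
        return values

    return Norm(
        P=unpack(P, _P_KEYS, "P"),
        R1=unpack(R1, _R_KEYS, "R1"),
        R2=unpack(R2, _R_KEYS, "R2"),
        name=name,
    )


# -- error-perturbed effective rules ------------------------------------------


def effective_norm(norm: Norm, errors: ErrorRates) -> Norm:
    """The effective rules actually realized under errors.

    Implementation errors turn intended cooperation into defection:
    ``P~ = (1 - mu_e) P``.  Assessment errors flip assigned reputations:
    ``R~i = (1 - mu_ai) Ri + mu_ai (1 - Ri)``, so every effective assessment
    lies in ``[mu_ai, 1 - mu_ai]``.
    """
    p = (1.0 - errors.mu_e) * norm.P
    r1 = (1.0 - errors.mu_a1) * norm.R1 + errors.mu_a1 * (1.0 - norm.R1)
    r2 = (1.0 - errors.mu_a2) * norm.R2 + errors.mu_a2 * (1.0 - norm.R2)
    return Norm(p, r1, r2, name=norm.name)


# -- 20-bit integer encoding of deterministic norms ----------------------------
#
# Bit order (most significant first): P(GG) P(GB) P(BG) P(BB) | R1 in
# (context, action) order GG.C GG.D GB.C GB.D BG.C BG.D BB.C BB.D | R2 in the
# same order.  P occupies bits 19..16, R1 bits 15..8, R2 bits 7..0.


def encode_deterministic(norm: Norm) -> int:
    """Pack a deterministic norm into its 20-bit id."""
    if not norm.is_deterministic:
        raise ValueError("only deterministic norms have an integer encoding")
    bits = norm.entries().astype(int)
    nid = 0
    for b in bits:
        nid = (nid << 1) | int(b)
    return nid


def decode_deterministic(nid: int) -> Norm:
    """Inverse of :func:`encode_deterministic`."""
    if not 0 <= nid < N_DETERMINISTIC:
        raise ValueError(f"norm id must be in [0, 2^20), got {nid}")
    bits = [(nid >> (N_BITS - 1 - i)) & 1 for i in range(N_BITS)]
    return Norm(bits[0:4], np.reshape(bits[4:12], (4, 2)),
                np.reshape(bits[12:20], (4, 2)))


def swap_labels(norm: Norm) -> Norm:
    """Relabel good as bad and vice versa (an involution).

    The action rule permutes contexts, ``P'(X, Y) = P(X̄, Ȳ)``; assessments
    additionally invert the assigned label, ``Ri'(X, Y, A) = 1 - Ri(X̄, Ȳ, A)``.
    The reputation dynamics of the swapped norm mirror the original with
    ``h -> 1 - h``.
    """
    perm = list(_SWAP_CTX)
    return Norm(norm.P[perm], 1.0 - norm.R1[perm], 1.0 - norm.R2[perm],
                name=None if norm.name is None else f"swap({norm.name})")


def canonical_id(nid: int) -> int:
    """Representative of the G/B-relabeling orbit: ``min(id, swapped id)``."""
    return min(nid, encode_deterministic(swap_labels(decode_deterministic(nid))))


# -- named-norm catalog --------------------------------------------------------
#
# Leading eight: fully cooperative donor-only norms, stable for b/c > 1.
# Shared prescriptions: P = (1, 0, 1, †), R1(GG) = (1, 0), R1(GB.D) = 1,
# R1(BG) = (1, 0).  Rows differ in R1(GB.C) and the (B,B) column.
# (P(B,B) is pinned by the R1(B,B,·) entries: cooperate there only when
# cooperation is the sole way to be assessed as good.)
_LEADING_EIGHT = {
    # name: (R1_GB_C, P_BB, R1_BB_C, R1_BB_D)
    "L1": (1, 1, 1, 0),
    "L2": (0, 1, 1, 0),
    "L3": (1, 0, 1, 1),
    "L4": (1, 0, 0, 1),
    "L5": (0, 0, 1, 1),
    "L6": (0, 0, 0, 1),
    "L7": (1, 0, 0, 0),
    "L8": (0, 0, 0, 0),
}

# Secondary sixteen: lenient donor-only norms (bad donors defect against good
# recipients yet are re-assessed as good), stable for b/c > 2.  Shared:
# P = (1, 0, 0, †), R1(GG) = (1, 0), R1(GB.D) = 1, R1(BG.D) = 1.
_SECONDARY_SIXTEEN = {
    # name: (R1_GB_C, R1_BG_C, P_BB, R1_BB_C, R1_BB_D)
    "S1": (0, 0, 0, 0, 0),
    "S2": (0, 0, 0, 0, 1),
    "S3": (0, 0, 1, 1, 0),
    "S4": (0, 0, 0, 1, 1),
    "S5": (0, 1, 0, 0, 0),
    "S6": (0, 1, 0, 0, 1),
    "S7": (0, 1, 1, 1, 0),
    "S8": (0, 1, 0, 1, 1),
    "S9": (1, 0, 0, 0, 0),
    "S10": (1, 0, 0, 0, 1),
    "S11": (1, 0, 1, 1, 0),
    "S12": (1, 0, 0, 1, 1),
    "S13": (1, 1, 0, 0, 0),
    "S14": (1, 1, 0, 0, 1),
    "S15": (1, 1, 1, 1, 0),
    "S16": (1, 1, 0, 1, 1),
}

_ALIASES = {
    "CONSISTENT STANDING": "L2",
    "SIMPLE STANDING": "L3",
    "STERN JUDGING": "L6",
    "STAYING": "L7",
    "JUDGING": "L8",
    "FORGIVER": "S16",
}


def _pbb_from_r1bb(r1_bb_c: float, r1_bb_d: float) -> float:
    # Cooperate in the (B,B) context exactly when cooperation (and only
    # cooperation) restores a good reputation.
    return 1.0 if (r1_bb_c == 1.0 and r1_bb_d == 0.0) else 0.0


def _leading_eight_norm(name: str) -> Norm:
    gb_c, p_bb, bb_c, bb_d = _LEADING_EIGHT[name]
    P = [1, 0, 1, p_bb]
    R1 = [[1, 0], [gb_c, 1], [1, 0], [bb_c, bb_d]]
    return Norm(P, R1, passive_r2(), name=name)


def _secondary_sixteen_norm(name: str) -> Norm:
    gb_c, bg_c, p_bb, bb_c, bb_d = _SECONDARY_SIXTEEN[name]
    P = [1, 0, 0, p_bb]
    R1 = [[1, 0], [gb_c, 1], [bg_c, 1], [bb_c, bb_d]]
    return Norm(P, R1, passive_r2(), name=name)


def _prime_family_norm(kind: str, wildcards: Mapping[str, float] | None) -> Norm:
    """The L'/S'/S'' donor-rule variants (dual-update CESS families).

    Wildcard R1 entries default to 0; R2 defaults to the family's minimal
    choice (the fixed entries required for error recovery, wildcards 0).
    L': like a leading-eight norm but defection against a bad recipient is
    *not* justified (R1(G,B,D)=0); S': like a secondary-sixteen norm but a
    bad donor's defection against a good recipient is not forgiven by R1
    (R1(B,G,D)=0); S'': justified defection removed instead (R1(G,B,D)=0).
    All three rely on R2 to restore reputations.
    """
    wc = dict(wildcards or {})

    def take(key: str, default: float = 0.0) -> float:
        return float(wc.pop(key, default))

    if kind == "L'":
        r1 = [[1, 0], [0, 0], [1, 0], [take("R1.BB.C"), take("R1.BB.D")]]
        p_bg = 1.0
    elif kind == "S'":
        r1 = [[1, 0], [take("R1.GB.C"), 1], [0, 0],
              [take("R1.BB.C"), take("R1.BB.D")]]
        p_bg = 0.0
    elif kind == "S''":
        r1 = [[1, 0], [0, 0], [take("R1.BG.C"), 1],
              [take("R1.BB.C"), take("R1.BB.D")]]
        p_bg = 0.0
    else:  # pragma: no cover
        raise ValueError(kind)
    p_bb = _pbb_from_r1bb(r1[3][0], r1[3][1])
    # Fixed R2 entries demanded by recovery; the remaining five are wildcards.
    r2 = [[1, take("R2.GG.D")], [take("R2.GB.C"), 1],
          [1 if kind == "L'" else take("R2.BG.C"),
           take("R2.BG.D") if kind == "L'" else 1],
          [take("R2.BB.C"), take("R2.BB.D")]]
    if wc:
        raise ValueError(f"unknown wildcard entries for {kind}: {sorted(wc)}")
    return Norm([1, 0, p_bg, p_bb], r1, r2, name=kind)


def sl2_norm(p1: float, p2: float, p3: float, p4: float = 0.0) -> Norm:
    """Stochastic variant of L2 (Consistent Standing).

    ``p1 = R1(G,G,D)`` forgives accidental defection among good players,
    ``p2 = R1(G,B,D)`` is the respect paid to justified defection,
    ``p3 = R1(B,G,C)`` throttles reputation recovery through cooperation,
    and ``p4 = R2(G,B,D)`` lets a defected-against bad recipient recover.
    ``R2`` is otherwise recipient-passive.
    """
    R1 = [[1, p1], [0, p2], [p3, 0], [1, 0]]
    r2 = passive_r2().copy()
    r2[GB, D] = p4
    return Norm([1, 0, 1, 1], R1, r2, name="sL2")


def ss1_norm(p1: float, p2: float, p3: float) -> Norm:
    """Stochastic variant of S1: ``p1 = R1(G,G,D)``, ``p2 = R1(G,B,D)``,
    ``p3 = R1(B,G,D)`` (slow forgiveness of bad donors); recipient-passive."""
    R1 = [[1, p1], [0, p2], [0, p3], [0, 0]]
    return Norm([1, 0, 0, 0], R1, passive_r2(), name="sS1")


def generous_scoring_norm(b: float, c: float) -> Norm:
    """First-order Generous Scoring: cooperate with good recipients, assess by
    action only, and forgive defection with probability ``1 - c/b``."""
    if not b > c > 0:
        raise ValueError(f"require b > c > 0, got b={b}, c={c}")
    q = 1.0 - c / b
    R1 = [[1, q]] * 4
    return Norm([1, 0, 1, 0], R1, passive_r2(), name="GenerousScoring")


def catalog_names() -> list[str]:
    """All named catalog entries (parametric families listed by base name)."""
    return (list(_LEADING_EIGHT) + list(_SECONDARY_SIXTEEN)
            + ["L'", "S'", "S''", "sL2", "sS1", "GenerousScoring",
               "ALLC", "ALLD"])


def catalog_lookup(name: str, **params) -> Norm:
    """Look up a named norm; parametric families take keyword parameters.

    ``sL2(p1, p2, p3[, p4])``, ``sS1(p1, p2, p3)``,
    ``GenerousScoring(b, c)``; ``L'``/``S'``/``S''`` accept a ``wildcards``
    mapping selecting the free entries.  Catalog norms are recipient-passive
    unless the family fixes R2 entries.
    """
    key = name.strip()
    upper = key.upper()
    if upper in _ALIASES:
        key = _ALIASES[upper]
    if key in _LEADING_EIGHT:
        return _leading_eight_norm(key)
    if key in _SECONDARY_SIXTEEN:
        return _secondary_sixteen_norm(key)
    if key in ("L'", "S'", "S''"):
        return _prime_family_norm(key, params.get("wildcards"))
    if key == "sL2":
        return sl2_norm(params["p1"], params["p2"], params["p3"],
                        params.get("p4", 0.0))
    if key == "sS1":
        return ss1_norm(params["p1"], params["p2"], params["p3"])
    if key == "GenerousScoring":
        return generous_scoring_norm(params["b"], params["c"])
    if key == "ALLC":
        return Norm([1, 1, 1, 1], np.ones((4, 2)), passive_r2(), name="ALLC")
    if key == "ALLD":
        return Norm([0, 0, 0, 0], np.zeros((4, 2)), passive_r2(), name="ALLD")
    raise KeyError(f"unknown norm name: {name!r}")


# -- JSON schema ---------------------------------------------------------------


def norm_to_json(norm: Norm, **dumps_kwargs) -> str:
    return json.dumps(norm.to_dict(), **dumps_kwargs)


def norm_from_json(text_or_dict) -> Norm:
    """Parse the norm JSON schema with exact key-set validation.

    Schema: ``{"name": str?, "P": {"GG": x, ...}, "R1": {"GG.C": x, ...},
    "R2": {...}}``.
    """
    obj = (json.loads(text_or_dict) if isinstance(text_or_dict, str)
           else dict(text_or_dict))
    allowed = {"name", "P", "R1", "R2"}
    extra = set(obj) - allowed
    if extra:
        raise ValueError(f"unexpected top-level keys: {sorted(extra)}")
    for req in ("P", "R1", "R2"):
        if req not in obj:
            raise ValueError(f"missing required key: {req!r}")
    return make_norm(obj["P"], obj["R1"], obj["R2"], name=obj.get("name"))
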