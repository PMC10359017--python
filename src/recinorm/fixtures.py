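"""Reproducible random-norm generators for property tests and experiments."""

from __future__ import annotations

import numpy as np

from .norms import Norm, catalog_lookup

__all__ = ["generate_fixtures"]

#: Catalog entries perturbed by the "near-CESS" generator.
_NEAR_CESS_BASES = [f"L{i}" for i in range(1, 9)] + ["S1", "S16"]


def generate_fixtures(n: int, seed: int, kind: str = "stochastic",
                      noise: float = 0.05) -> list[Norm]:
    """Generate ``n`` reproducible norms.

    ``kind``:
      * ``"stochastic"`` — all 20 entries uniform on [0, 1];
      * ``"deterministic"`` — uniform over the 2^20 deterministic norms;
      * ``"near-CESS"`` — catalog norms (leading eight, S1, S16) with every
        entry shifted by uniform noise of magnitude at most ``noise`` and
        clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    norms: list[Norm] = []
    for i in range(n):
        if kind == "stochastic":
            e = rng.random(20)
        elif kind == "deterministic":
            e = rng.integers(0, 2, size=20).astype(float)
        elif kind == "near-CESS":
            base = catalog_lookup(_NEAR_CESS_BASES[i % len(_NEAR_CESS_BASES)])
            e = base.entries() + rng.uniform(-noise, noise, size=20)
            e = np.clip(e, 0.0, 1.0)
        else:
            raise ValueError(f"unknown fixture kind: {kind!r}")
        norms.append(Norm(e[:4], e[4:12].reshape(4, 2),
                          e[12:20].reshape(4, 2),
                          name=f"{kind}-{seed}-{i}"))
    return norms
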