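"""Independent oracles used by the acceptance battery.

These deliberately avoid the code paths they check: the Weir-Cockerham
oracle is plain scalar arithmetic, and the Fisher oracle enumerates every
2x2 table with the observed margins using exact integer binomials.
"""

from __future__ import annotations

from math import comb


def wc_oracle(counts):
    """Step-by-step 1984 variance components from per-population genotype
    counts (hom-ref, het, hom-alt), in pure Python floats."""
    r = len(counts)
    n = [c[0] + c[1] + c[2] for c in counts]
    p = [(c[1] + 2 * c[2]) / (2 * ni) for c, ni in zip(counts, n)]
    h = [c[1] / ni for c, ni in zip(counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else float("nan"))


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins.

    Table weights are exact integers C(r1, x) * C(r2, c1 - x); the p-value
    sums the weights of tables no more probable than the observed one (with
    the conventional 1 + 1e-7 relative tolerance) over the total C(n, c1).
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    kept = sum(w for w in weights.values() if w <= w_obs * (1 + 1e-7))
    return kept / total
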