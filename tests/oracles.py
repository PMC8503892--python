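"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy/lifelines so they can cross-check the
implementation: exact-arithmetic hypergeometric enumeration for the
two-sided Fisher test, and a hand-rolled product-limit estimator.
"""

from fractions import Fraction
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration over margin-consistent tables.

    Minimum-likelihood convention: sum the point probabilities of every
    table whose probability is no larger than the observed table's (with a
    1e-7 relative slack on the comparison, matching the standard
    convention for near-ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    scale = 10 ** 7
    total = sum(w for w in weights.values() if w * scale <= w_obs * (scale + 1))
    return float(Fraction(total, denom))


def km_oracle(durations, events):
    """Product-limit estimate over the event times; returns (times, survival)."""
    pairs = sorted(zip(durations, events))
    times = sorted({t for t, e in pairs if e})
    surv = []
    s = 1.0
    for t in times:
        at_risk = sum(1 for d, _ in pairs if d >= t)
        deaths = sum(1 for d, e in pairs if e and d == t)
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return times, surv
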