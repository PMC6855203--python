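"""Independent reference implementations used only to check the package.

These deliberately use the slowest, most literal formulation of each
quantity: exact integer arithmetic for binomial tails and explicit
genotype-pair x gamete enumeration for cross distributions.
"""

from __future__ import annotations

import math

from crossase.phs import Cross

#: P(transmit reference allele | genotype code 0/1/2)
_GAMETE_REF = (1.0, 0.5, 0.0)


def binom_two_sided_exact(k: int, n: int) -> float:
    """P(|X - n/2| >= |k - n/2|) under X ~ Binomial(n, 1/2), by exact integer
    summation of the probability mass function."""
    d = abs(2 * k - n)
    numerator = sum(math.comb(n, x) for x in range(n + 1) if abs(2 * x - n) >= d)
    return numerator / (1 << n)


def binom_two_sided_exact_row(n: int) -> list[float]:
    """Exact two-sided p-values for every k in 0..n at once (integer Pascal
    row with prefix sums, so the full n <= 500 sweep stays fast)."""
    row = [math.comb(n, x) for x in range(n + 1)]
    prefix = [0] * (n + 2)
    for x in range(n + 1):
        prefix[x + 1] = prefix[x] + row[x]
    total = prefix[n + 1]
    out = []
    for k in range(n + 1):
        lo = min(k, n - k)
        if 2 * lo == n:
            out.append(1.0)
        else:
            # symmetric null: lower tail equals upper tail
            out.append((2 * prefix[lo + 1]) / total)
    return out


def enumerate_offspring_distribution(node, genotype_triples: dict) -> tuple:
    """Genotype distribution of a cross node by brute-force enumeration.

    ``genotype_triples`` maps breed -> (p_homref, p_het, p_homalt). Every
    (sire genotype, dam genotype) pair of the mating is enumerated together
    with the gamete each transmits.
    """
    if not isinstance(node, Cross):
        return tuple(genotype_triples[node])
    ps = enumerate_offspring_distribution(node.sire, genotype_triples)
    pdam = enumerate_offspring_distribution(node.dam, genotype_triples)
    out = [0.0, 0.0, 0.0]
    for gs in range(3):
        for gd in range(3):
            w = ps[gs] * pdam[gd]
            ts, td = _GAMETE_REF[gs], _GAMETE_REF[gd]
            out[0] += w * ts * td
            out[1] += w * (ts * (1.0 - td) + (1.0 - ts) * td)
            out[2] += w * (1.0 - ts) * (1.0 - td)
    return tuple(out)
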