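"""Independent brute-force oracles used by several test modules.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct probability sums) without touching the package's own
counting or testing code paths.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data.CodonTable import standard_dna_table

CODE = dict(standard_dna_table.forward_table)
SENSE = sorted(CODE)

BRANCH_ORDER = ("human", "chimp", "hominoid_ancestor", "macaque", "mouse")


def _ham(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_single_change_column(h, c, m, o):
    """Average per-branch (nonsyn, syn) changes over all minimal sense
    ancestral assignments, for columns whose minimal change count is 1.

    Enumerates all 61 x 61 sense-codon assignments of the two internal
    nodes.  Each minimal assignment localises the single change to one
    edge; the change is classified by direct translation.
    """
    best = 99
    sols = []
    for x, y in itertools.product(SENSE, SENSE):
        cost = _ham(x, h) + _ham(x, c) + _ham(y, x) + _ham(y, m) + _ham(y, o)
        if cost < best:
            best, sols = cost, [(x, y)]
        elif cost == best:
            sols.append((x, y))
    assert best == 1, "oracle restricted to single-change columns"
    acc = {br: [0.0, 0.0] for br in BRANCH_ORDER}
    for x, y in sols:
        for parent, child, br in (
            (x, h, "human"),
            (x, c, "chimp"),
            (y, x, "hominoid_ancestor"),
            (y, m, "macaque"),
            (y, o, "mouse"),
        ):
            if parent != child:
                if CODE[parent] == CODE[child]:
                    acc[br][1] += 1.0
                else:
                    acc[br][0] += 1.0
    k = len(sols)
    return {br: (acc[br][0] / k, acc[br][1] / k) for br in BRANCH_ORDER}


def hypergeometric_tail_p(a, b, c, d):
    """One-sided (greater) Fisher p for the table [[a, b], [c, d]] by direct
    enumeration of all tables with the same margins."""
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2

    def log_hyper(k):
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(k + 1)
            - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(col1 - k + 1)
            - math.lgamma(r2 - col1 + k + 1)
            - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
        )

    lo = max(0, col1 - r2)
    hi = min(r1, col1)
    return sum(math.exp(log_hyper(k)) for k in range(a, hi + 1) if lo <= k)


def mutual_information_g(a, b, c, d):
    """Uncorrected G as 2 * N * (mutual information in nats) of the table."""
    n = a + b + c + d
    if n == 0:
        return 0.0
    p = [[a / n, b / n], [c / n, d / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if p[i][j] > 0:
                mi += p[i][j] * math.log(p[i][j] / (row[i] * col[j]))
    return 2.0 * n * mi


def binomial_upper_tail(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return min(1.0, total)
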