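"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: exact rational
arithmetic for hypergeometric tails and brute-force graph reachability for
ancestry, so agreement is meaningful.
"""

from fractions import Fraction
from math import comb


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k), X ~ Hypergeometric(N, K, n), as an exact rational."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def reachable_ancestors(parent_edges: dict[str, set[str]], term: str) -> set[str]:
    """Brute-force DFS over child->parents adjacency, excluding the start term."""
    seen: set[str] = set()
    stack = list(parent_edges.get(term, ()))
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(parent_edges.get(node, ()))
    return seen
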