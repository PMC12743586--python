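"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration or exact rational
arithmetic, independently of the library code path it checks.
"""
from __future__ import annotations

import itertools
import math
import re
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy.stats import rankdata


def wilcoxon_enum_p(values, mu=1.0, scale="log_ratio"):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    vals = np.asarray(values, dtype=float)
    d = np.log(vals) - math.log(mu) if scale == "log_ratio" else vals - mu
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    cnt_ge = cnt_le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        cnt_ge += w >= w_obs - 1e-12
        cnt_le += w <= w_obs + 1e-12
    return min(1.0, 2 * min(cnt_ge, cnt_le) / 2 ** n)


def hypergeom_tail_exact(k, N, K, n):
    """P[X >= k] for X ~ Hypergeom(N, K, n) as an exact fraction -> float."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def fisher_greater_exact(a, b, c, d):
    """One-sided (enrichment) Fisher p as a hypergeometric upper tail."""
    return hypergeom_tail_exact(a, a + b + c + d, a + c, a + b)


def match_starts_bruteforce(pattern, sequence):
    """1-based start positions where the regex matches, checked per position."""
    pat = re.compile(pattern)
    starts = []
    for i in range(len(sequence)):
        m = pat.match(sequence, i)
        if m is not None and m.end() > m.start():
            starts.append(i + 1)
    return starts


def best_connected_score(graph: nx.Graph, zmap):
    """Max sum(z)/sqrt(k) over every non-empty connected node subset."""
    nodes = list(graph.nodes())
    best = -math.inf
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if nx.is_connected(graph.subgraph(subset)):
                score = sum(zmap.get(g, 0.0) for g in subset) / math.sqrt(r)
                best = max(best, score)
    return best
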