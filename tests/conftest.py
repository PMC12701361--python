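"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
textbook formulas) so they stay independent of the vectorized library code
they check.
"""

from __future__ import annotations

import logging
import math

logging.getLogger("perturbscreen").setLevel(logging.ERROR)


# ---------------------------------------------------------------- oracles


def brute_force_es(genes, stats, members, weight):
    """Exhaustive running-sum ES: walk every gene, track the full path."""
    order = sorted(range(len(genes)), key=lambda i: (-stats[i], i))
    members = set(members)
    hits = [i for i in order if genes[i] in members]
    n, big_n = len(hits), len(genes)
    denom = sum(abs(stats[i]) ** weight for i in hits)
    cur, path = 0.0, []
    for i in order:
        if genes[i] in members:
            if denom > 0:
                cur += abs(stats[i]) ** weight / denom
            else:
                cur += 1.0 / n
        else:
            cur -= 1.0 / (big_n - n)
        path.append(cur)
    pos, neg = max(path), min(path)
    # positive extremum wins magnitude ties, matching the engine's convention
    return pos if pos >= -neg - 1e-9 else neg


def brute_force_bh(p):
    """Textbook step-up BH: sort, n*p/rank, cumulative minimum from the top."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def tau_b_oracle(x, y):
    """Kendall tau-b by explicit concordant/discordant/tied pair counts."""
    n = len(x)
    nc = nd = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            if prod > 0:
                nc += 1
            elif prod < 0:
                nd += 1
    n0 = n * (n - 1) / 2
    tied_x = sum(1 for i in range(n) for j in range(i + 1, n) if x[i] == x[j])
    tied_y = sum(1 for i in range(n) for j in range(i + 1, n) if y[i] == y[j])
    denom = math.sqrt((n0 - tied_x) * (n0 - tied_y))
    if denom == 0:
        return float("nan")
    return (nc - nd) / denom


def spearman_oracle(x, y):
    """Spearman rho via average ranks then the Pearson formula, by hand."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
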