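"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — double loops, explicit pair
counts, hand-rolled BFS, exact combinatorial sums — and shares no code
path with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_seed_scores(edges, seeds, universe):
    """S_i by a double loop over (gene, seed) pairs.

    ``edges`` is an iterable of (a, b, w) undirected edges.
    """
    weight = {}
    for a, b, w in edges:
        weight[(a, b)] = w
        weight[(b, a)] = w
    return {g: sum(weight.get((g, s), 0.0) for s in seeds) for g in universe}


def pairwise_auc(scores: dict, positives) -> float:
    """AUC by explicit (positive, negative) pair counting with half ties."""
    positives = set(positives)
    pos = [scores[g] for g in scores if g in positives]
    neg = [scores[g] for g in scores if g not in positives]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def trapezoid_auc(scores: dict, positives) -> float:
    """AUC by integrating the ROC curve with the trapezoidal rule,
    grouping tied scores into single cutoff steps."""
    positives = set(positives)
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    n_pos = sum(1 for g in scores if g in positives)
    n_neg = len(scores) - n_pos
    tpr = [0.0]
    fpr = [0.0]
    i = 0
    tp = fp = 0
    while i < len(items):
        j = i
        while j < len(items) and items[j][1] == items[i][1]:
            if items[j][0] in positives:
                tp += 1
            else:
                fp += 1
            j += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    area = 0.0
    for a in range(1, len(tpr)):
        area += (fpr[a] - fpr[a - 1]) * (tpr[a] + tpr[a - 1]) / 2.0
    return area


def positional_auc(labels) -> float:
    """Ranked-list AUC by pair counting over list positions (no ties)."""
    labels = list(labels)
    wins = total = 0
    for i, li in enumerate(labels):
        if not li:
            continue
        for j, lj in enumerate(labels):
            if lj:
                continue
            total += 1
            if i < j:
                wins += 1
    return wins / total


def bfs_neighbors(edges, seeds, depth):
    """Genes within ``depth`` hops of any seed, by hand-rolled BFS."""
    adj = {}
    for a, b, _ in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seeds = set(seeds)
    seen = set(seeds)
    frontier = set(s for s in seeds if s in adj)
    out = set()
    for _ in range(depth):
        nxt = set()
        for f in frontier:
            nxt |= adj.get(f, set())
        nxt -= seen
        out |= nxt
        seen |= nxt
        frontier = nxt
    return out


def exact_hypergeom_tail(n_universe, n_significant, n_labeled, overlap):
    """P(X >= overlap) by exact summation of hypergeometric pmf terms."""
    total = Fraction(0)
    denom = comb(n_universe, n_significant)
    hi = min(n_labeled, n_significant)
    for x in range(overlap, hi + 1):
        total += Fraction(comb(n_labeled, x)
                          * comb(n_universe - n_labeled, n_significant - x),
                          denom)
    return float(total)
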