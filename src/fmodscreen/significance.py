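"""Permutation nulls, empirical p-values and empirical FDR.

Compound-level significance is assessed against a null built by
redrawing the drug signature uniformly at random from the profile gene
universe (the module held fixed) and recomputing mutual predictability;
ranked-list AUC significance against a null of random positive-label
placements. p-values use the add-one permutation estimator
``(1 + #{null >= obs}) / (n_reps + 1)`` by default, which can never be
exactly zero at finite replication; the plug-in estimator is available
for fidelity with pipelines that used it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .disease import GeneModule
from .mp import seed_scores, retrieval_auc
from .network import WeightedGeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["NullDistribution", "mp_null", "empirical_p", "empirical_fdr",
           "empirical_fdr_for", "auc_significance"]

#: replication presets: `full` follows the published protocol, `test`
#: is sized for interactive runs and CI
N_REPS_PRESETS = {"full": 100_000, "test": 1_000}


@dataclass(frozen=True)
class NullDistribution:
    """Draws of a statistic under a permutation null."""

    statistic_name: str
    draws: np.ndarray
    seed: int
    generating_recipe: str

    def __post_init__(self):
        object.__setattr__(self, "draws", np.asarray(self.draws, dtype=float))

    @property
    def n_reps(self) -> int:
        return len(self.draws)

    def save(self, path: str | Path) -> None:
        """One number per line, with a JSON sidecar for audit."""
        path = Path(path)
        np.savetxt(path, self.draws, fmt="%.12g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "statistic": self.statistic_name,
            "seed": self.seed,
            "n_reps": self.n_reps,
            "recipe": self.generating_recipe,
        }, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NullDistribution":
        path = Path(path)
        draws = np.loadtxt(path, ndmin=1)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        return cls(meta["statistic"], draws, meta["seed"], meta["recipe"])


def mp_null(net: WeightedGeneNetwork, mag: GeneModule,
            universe: Iterable[str], n_drg: int, n_reps: int,
            seed: int) -> NullDistribution:
    """Null MP distribution: random drug signatures against a fixed module.

    Each draw picks ``n_drg`` genes uniformly without replacement from
    ``universe`` (the compound-profile gene universe — the frame real
    signatures are drawn from) and computes MP exactly as the screen
    does. The module-seeded score vector is fixed across draws and is
    computed once.
    """
    if n_drg < 1 or n_reps < 1:
        raise ValueError("n_drg and n_reps must be >= 1")
    pool = np.array(sorted(set(universe)))
    if n_drg > len(pool):
        raise ValueError(
            f"n_drg={n_drg} exceeds the universe of {len(pool)} genes")
    members = frozenset(mag.members)
    if not any(g in net and net.graph.degree(g) > 0 for g in members):
        raise ValueError(
            "module has no edges in the thresholded network; every null "
            "draw would be uninformative — review the linkage threshold")
    rng = np.random.default_rng(seed)

    # direction M-D: seeds fixed = module members; the scored universe is
    # the network plus any off-network profile genes, so it is identical
    # for every draw and the midranks can be computed once
    uni_md = sorted((net.nodes | set(pool)) - members)
    sv_md = seed_scores(net, members, uni_md)
    ranks_md = rankdata(sv_md.values)
    pos_md = {g: i for i, g in enumerate(sv_md.genes)}
    n_uni = len(uni_md)

    draws = np.empty(n_reps)
    n_missing = 0
    for r in range(n_reps):
        drg = pool[rng.choice(len(pool), size=n_drg, replace=False)]
        drg_set = frozenset(drg)
        positives = drg_set - members
        auc_md = None
        if positives and len(positives) < n_uni:
            idx = np.fromiter((pos_md[g] for g in positives), dtype=int)
            npos = len(idx)
            u = ranks_md[idx].sum() - npos * (npos + 1) / 2.0
            auc_md = u / (npos * (n_uni - npos))
        # direction D-M: seeds are the random signature
        pos_dm = set(mag.members) - drg_set
        uni_dm = (net.nodes | pos_dm) - drg_set
        auc_dm = None
        if pos_dm and pos_dm < uni_dm:
            sv = seed_scores(net, drg_set, uni_dm)
            auc_dm = retrieval_auc(sv, pos_dm)
        if auc_md is None or auc_dm is None:
            draws[r] = np.nan
            n_missing += 1
        else:
            draws[r] = math.sqrt(auc_md * auc_dm)
    if n_missing == n_reps:
        raise ValueError(
            "every null draw was degenerate (module has no usable network "
            "context); review the linkage threshold")
    if n_missing:
        logger.warning("%d/%d null draws degenerate, dropped", n_missing, n_reps)
        draws = draws[~np.isnan(draws)]
    return NullDistribution(
        "mutual_predictability", draws, seed,
        f"random {n_drg}-gene signatures from a {len(pool)}-gene universe, "
        f"module of {len(members)} fixed, {n_reps} reps")


def empirical_p(obs: float, null: NullDistribution,
                estimator: str = "add_one") -> float:
    """Upper-tail permutation p-value of an observation against a null.

    ``add_one``: (1 + #{draws >= obs}) / (n_reps + 1) — never exactly 0.
    ``plugin``:  #{draws >= obs} / n_reps.
    """
    if null.n_reps == 0:
        raise ValueError("empty null distribution")
    exceed = int(np.count_nonzero(null.draws >= obs))
    if estimator == "add_one":
        return (1 + exceed) / (null.n_reps + 1)
    if estimator == "plugin":
        return exceed / null.n_reps
    raise ValueError(f"unknown estimator {estimator!r}")


def _raw_fdr(observed: np.ndarray, null: NullDistribution,
             estimator: str) -> np.ndarray:
    """Storey-style plug-in FDR at each observed score (input order)."""
    m = len(observed)
    order = np.argsort(-observed, kind="stable")
    s = observed[order]
    # #{observed >= s_i} for the i-th largest score, handling ties
    n_obs_ge = m - np.searchsorted(np.sort(observed), s, side="left")
    tail = np.array([empirical_p(x, null, estimator) for x in s]) \
        if estimator == "add_one" else \
        np.array([np.count_nonzero(null.draws >= x) / null.n_reps for x in s])
    raw = np.minimum(1.0, m * tail / n_obs_ge)
    # monotonize: FDR non-increasing in the score; scanning from the
    # least significant score upward with a running minimum
    mono = np.minimum.accumulate(raw[::-1])[::-1][np.argsort(order)]
    return mono


def empirical_fdr(observed_scores: Sequence[float], null: NullDistribution,
                  estimator: str = "plugin") -> dict[float, float]:
    """Empirical FDR at each observed score.

    FDR(s) = min(1, M * Pr_null(X >= s) / #{observed >= s}), monotonized
    so that FDR never rises as the score threshold rises. Returns a map
    from (unique) observed score to FDR. ``estimator`` controls the null
    tail probability (plug-in by default; add-one available).
    """
    observed = np.asarray(list(observed_scores), dtype=float)
    if len(observed) == 0:
        raise ValueError("no observed scores")
    fdr = _raw_fdr(observed, null, estimator)
    return {float(s): float(f) for s, f in zip(observed, fdr)}


def empirical_fdr_for(observed_scores: Sequence[float],
                      null: NullDistribution,
                      estimator: str = "plugin") -> np.ndarray:
    """Like :func:`empirical_fdr` but aligned with the input order."""
    observed = np.asarray(list(observed_scores), dtype=float)
    if len(observed) == 0:
        raise ValueError("no observed scores")
    return _raw_fdr(observed, null, estimator)


def _placement_auc(positions: np.ndarray, n_total: int) -> float:
    """AUC when positives sit at 0-based ``positions`` from the top."""
    n_pos = len(positions)
    n_neg = n_total - n_pos
    # rank from the bottom: position 0 (top) has the highest rank
    ranks = n_total - positions
    u = ranks.sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_significance(ranked_labels: Sequence[int], n_reps: int = 1000,
                     seed: int = 0, mode: str = "sample") -> float:
    """Significance of a ranked-list AUC by random label placement.

    ``ranked_labels`` is the observed ordered 0/1 label vector (top of
    the list first). The null re-places the same number of positive
    labels uniformly at random; p is the add-one upper-tail probability
    of a null AUC >= the observed AUC. ``mode='exact'`` enumerates all
    placements (tiny lists only).
    """
    labels = np.asarray(list(ranked_labels), dtype=int)
    n = len(labels)
    n_pos = int(labels.sum())
    if not (0 < n_pos < n):
        raise ValueError("need at least one positive and one negative label")
    obs = _placement_auc(np.flatnonzero(labels), n)
    if mode == "exact":
        aucs = np.array([_placement_auc(np.array(c), n)
                         for c in combinations(range(n), n_pos)])
        exceed = int(np.count_nonzero(aucs >= obs - 1e-12))
        return (1 + exceed) / (len(aucs) + 1)
    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_reps):
        pos = rng.choice(n, size=n_pos, replace=False)
        if _placement_auc(pos, n) >= obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_reps + 1)
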