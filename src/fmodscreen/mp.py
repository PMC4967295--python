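"""Mutual predictability: the core drug-disease linkage statistic.

Given two gene sets on a weighted functional linkage network, each set
in turn is used as a seed set: every other gene *i* receives the seed
score

    S_i = sum over seeds j of w_ij        (0 without a seed connection)

and the area under the ROC for retrieving the *other* set from the
score-ranked list measures how predictable that set is from the seeds.
Mutual predictability (MP) is the geometric mean of the two directional
AUCs:

    MP = sqrt(AUC_D-M * AUC_M-D)

An MP near 1 means the disease module and the drug signature occupy the
same tightly linked neighborhood of the network; 0.5 in both directions
is chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import rankdata

from .disease import GeneModule
from .drugs import DrugSignature
from .network import WeightedGeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["SeedScoreVector", "MPResult", "seed_scores", "retrieval_auc",
           "mutual_predictability"]


@dataclass(frozen=True)
class SeedScoreVector:
    """Seed scores S_i over a gene universe (seeds excluded)."""

    genes: tuple[str, ...]
    values: np.ndarray              # aligned with genes, S_i >= 0
    seed_set: frozenset[str]

    @property
    def scores(self) -> dict[str, float]:
        return dict(zip(self.genes, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class MPResult:
    """Mutual predictability of one compound profile against one module.

    ``mp`` is None when the score is undefined (e.g. the positive set
    vanished after seed exclusion); ``reason`` then says why. Missing is
    deliberately distinct from 0 so that ranking never rewards or
    punishes absent data.
    """

    compound_id: str
    profile_id: str
    direction_pair: str | None = None      # 'UCDB' or 'DCUB'
    auc_m_to_d: float | None = None
    auc_d_to_m: float | None = None
    mp: float | None = None
    p_value: float | None = None
    fdr: float | None = None
    reason: str | None = None
    k_used: int | None = None

    @property
    def is_missing(self) -> bool:
        return self.mp is None


def seed_scores(net: WeightedGeneNetwork, seeds: Iterable[str],
                universe: Iterable[str]) -> SeedScoreVector:
    """Score every universe gene by its summed link weight to the seeds.

    The universe must exclude the seeds themselves. Universe genes
    without any thresholded edge to a seed (including genes absent from
    the network altogether) score exactly 0.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty scoring universe")
    overlap = seeds & set(universe)
    if overlap:
        raise ValueError(
            f"universe must exclude seeds; found {len(overlap)} overlapping")
    mat, index, order = net.adjacency()
    seed_idx = [index[s] for s in seeds if s in index]
    values = np.zeros(len(universe))
    if seed_idx:
        full = np.asarray(mat[:, seed_idx].sum(axis=1)).ravel()
        for i, g in enumerate(universe):
            j = index.get(g)
            if j is not None:
                values[i] = full[j]
    return SeedScoreVector(tuple(universe), values, seeds)


def retrieval_auc(scores: SeedScoreVector, positives: Iterable[str]) -> float:
    """AUC for retrieving ``positives`` from the score-ranked universe.

    Computed with the Mann–Whitney identity under half-credit ties:

        AUC = (#{(p,n): S_p > S_n} + 0.5 * #{S_p = S_n}) / (|pos| * |neg|)

    equivalent to sweeping a cutoff down the ranked list. The tie
    correction matters because seed scores have massive ties at 0.
    """
    positives = set(positives)
    universe = set(scores.genes)
    if not positives:
        raise ValueError("empty positive set: AUC undefined")
    if not positives <= universe:
        raise ValueError("positives must lie inside the scored universe")
    if positives == universe:
        raise ValueError("positives equal the whole universe: AUC undefined")
    mask = np.fromiter((g in positives for g in scores.genes),
                       dtype=bool, count=len(scores.genes))
    ranks = rankdata(scores.values)        # midranks, ascending
    n_pos = int(mask.sum())
    n_neg = len(ranks) - n_pos
    u = ranks[mask].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _directional_auc(net: WeightedGeneNetwork, seed_set: frozenset[str],
                     positive_genes: set[str],
                     drop_nonnetwork_positives: bool) -> tuple[float | None, str | None]:
    """One direction of MP: seed with one set, retrieve the other."""
    positives = positive_genes - seed_set
    dropped = len(positive_genes) - len(positives)
    if dropped:
        logger.debug("dropped %d positives overlapping the seed set", dropped)
    universe = net.nodes - seed_set
    if drop_nonnetwork_positives:
        positives &= universe
    else:
        # off-network positives are retrievable in principle: keep them
        # in the universe at score 0
        universe |= positives
    if not positives:
        return None, "no positives left after seed exclusion"
    if positives >= universe:
        return None, "positives cover the whole scoring universe"
    sv = seed_scores(net, seed_set, universe)
    return retrieval_auc(sv, positives), None


def mutual_predictability(net: WeightedGeneNetwork, mag: GeneModule,
                          drg: DrugSignature,
                          drop_nonnetwork_positives: bool = False,
                          md_seed_mode: str = "members") -> MPResult:
    """MP of a disease module and a drug signature on the network.

    Direction M-D seeds with the module members (or the raw mutated
    drivers when ``md_seed_mode='drivers'``) and retrieves the drug
    genes; direction D-M swaps the roles. In each direction the seed set
    is excluded from its own retrieval universe and positives that
    overlap the seeds are dropped (self-retrieval is uninformative).
    """
    if md_seed_mode not in ("members", "drivers"):
        raise ValueError(f"bad md_seed_mode {md_seed_mode!r}")
    if not mag.members or not drg.genes:
        raise ValueError("module and signature must be non-empty")
    md_seeds = frozenset(mag.members if md_seed_mode == "members"
                         else mag.seeds)
    drg_set = set(drg.genes)

    auc_md, why_md = _directional_auc(net, md_seeds, drg_set,
                                      drop_nonnetwork_positives)
    auc_dm, why_dm = _directional_auc(net, frozenset(drg_set),
                                      set(mag.members),
                                      drop_nonnetwork_positives)
    base = MPResult(drg.compound_id, drg.profile_id, k_used=drg.k_used)
    if auc_md is None or auc_dm is None:
        reasons = "; ".join(r for r in (why_md, why_dm) if r)
        return replace(base, reason=reasons)
    mp = math.sqrt(auc_md * auc_dm)
    return replace(base, auc_m_to_d=auc_md, auc_d_to_m=auc_dm, mp=mp)
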