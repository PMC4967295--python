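"""Disease gene modules: mutated drivers plus filtered network neighbors.

A mutation-associated gene module (MAG) starts from known mutated driver
genes for the disease, expands to their first (or first and second)
nearest neighbors on the thresholded functional linkage network, and
keeps only the neighbors that are (a) among the *m* most up- or
down-regulated genes in the disease expression profile and (b) members
of significantly perturbed disease pathways. Seeds are always retained;
the filters apply to neighbors only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import WeightedGeneNetwork, neighbors_within

logger = logging.getLogger(__name__)

__all__ = [
    "RankedExpressionProfile",
    "PathwayCollection",
    "GeneModule",
    "expression_gene_set",
    "m_grid",
    "pathway_member_set",
    "hypergeometric_pathway_enrichment",
    "build_mag",
]


@dataclass(frozen=True)
class RankedExpressionProfile:
    """A ranked differential-expression table: gene -> signed statistic.

    Larger statistic = more up-regulated in the condition of interest.
    The gene universe of the profile is whatever was measured upstream
    (chip probes, RNA-seq genes); differential expression itself is
    computed upstream — this class consumes ranks only.
    """

    genes: tuple[str, ...]
    stats: tuple[float, ...]

    def __post_init__(self):
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in expression profile")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, float]]) -> "RankedExpressionProfile":
        genes, stats = zip(*items) if items else ((), ())
        return cls(tuple(genes), tuple(float(s) for s in stats))

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedExpressionProfile":
        return cls(tuple(str(g) for g in s.index), tuple(float(v) for v in s.values))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedExpressionProfile":
        """Read a 2-column ``gene<TAB>statistic`` table (``#`` comments)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene", "stat"], dtype={"gene": str})
        return cls(tuple(df["gene"]), tuple(df["stat"].astype(float)))

    def to_series(self) -> pd.Series:
        return pd.Series(self.stats, index=list(self.genes), name="stat")

    def top(self, m: int, direction: str) -> list[str]:
        """The m most up- (or down-) regulated genes, in rank order.

        Ties on the statistic are broken by gene identifier so selection
        is deterministic.
        """
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
        if not (1 <= m <= len(self)):
            raise ValueError(
                f"m={m} outside [1, {len(self)}] for this profile")
        sign = -1.0 if direction == "up" else 1.0
        order = sorted(range(len(self)),
                       key=lambda i: (sign * self.stats[i], self.genes[i]))
        return [self.genes[i] for i in order[:m]]


@dataclass
class PathwayCollection:
    """Named gene sets with optional per-pathway significance (FDR)."""

    pathways: dict[str, frozenset[str]]
    significance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
        for name, fdr in self.significance.items():
            if not (0.0 <= fdr <= 1.0):
                raise ValueError(f"pathway {name!r}: FDR {fdr} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.pathways)

    @classmethod
    def from_gmt(cls, path: str | Path,
                 fdr_table: str | Path | None = None) -> "PathwayCollection":
        """Read GMT (name, description, genes...) plus optional 2-column
        ``pathway<TAB>FDR`` significance table."""
        pathways: dict[str, frozenset[str]] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        "and >=1 gene")
                pathways[parts[0]] = frozenset(g for g in parts[2:] if g)
        significance: dict[str, float] = {}
        if fdr_table is not None:
            df = pd.read_csv(fdr_table, sep="\t", header=None, comment="#",
                             names=["pathway", "fdr"], dtype={"pathway": str})
            significance = dict(zip(df["pathway"], df["fdr"].astype(float)))
        return cls(pathways, significance)

    def to_gmt(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for name in sorted(self.pathways):
                genes = "\t".join(sorted(self.pathways[name]))
                fh.write(f"{name}\tna\t{genes}\n")


@dataclass(frozen=True)
class GeneModule:
    """A direction-specific MAG: seeds plus surviving neighbors."""

    seeds: frozenset[str]
    members: frozenset[str]
    direction: str            # 'up' or 'down' in the disease
    depth: int                # 1 or 2 network hops
    m_used: int               # size of the expression filter applied

    def __post_init__(self):
        if not self.seeds <= self.members:
            raise ValueError("seeds must be a subset of members")
        if self.direction not in ("up", "down"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def n_neighbors(self) -> int:
        """Module size excluding seeds (the '237' of a '40 + 237' module)."""
        return len(self.members) - len(self.seeds)

    def __len__(self) -> int:
        return len(self.members)


def expression_gene_set(profile: RankedExpressionProfile, m: int,
                        direction: str) -> set[str]:
    """The m most up- or down-regulated genes of the profile."""
    return set(profile.top(m, direction))


def m_grid(universe_size: int) -> list[int]:
    """Expression-filter sizes: 1000, 3000, 5000, ... up to half the universe.

    Below a universe of 2000 genes (toy inputs) the grid degenerates to
    the single value ``universe_size // 2`` with a warning.
    """
    if universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    half = universe_size // 2
    if universe_size < 2000:
        logger.warning(
            "universe of %d genes is too small for the standard m grid; "
            "falling back to m=%d", universe_size, half)
        return [half]
    return list(range(1000, half + 1, 2000))


def pathway_member_set(pathways: PathwayCollection,
                       fdr_cutoff: float = 0.05) -> set[str]:
    """Union of genes in pathways significant at ``fdr < fdr_cutoff``.

    If the collection carries no significance values at all, the union
    of every pathway is returned.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    if not pathways.significance:
        names = list(pathways.pathways)
    else:
        names = [n for n in pathways.pathways
                 if pathways.significance.get(n, 1.0) < fdr_cutoff]
    out: set[str] = set()
    for n in names:
        out |= pathways.pathways[n]
    return out


def hypergeometric_pathway_enrichment(query: Iterable[str],
                                      pathways: PathwayCollection,
                                      universe: Iterable[str]
                                      ) -> PathwayCollection:
    """Over-representation test of a gene set against each pathway.

    For each pathway, the upper-tail hypergeometric probability of
    drawing at least the observed overlap when ``|query|`` genes are
    sampled from the universe; Benjamini–Hochberg FDR across pathways is
    stored as the returned collection's significance.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    names = sorted(pathways.pathways)
    pvals = []
    for name in names:
        pw = pathways.pathways[name] & universe
        overlap = len(query & pw)
        # P(X >= overlap), X ~ Hypergeom(N=|U|, K=|pw|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(pw),
                                     len(query)))
        pvals.append(min(p, 1.0))
    fdr = _benjamini_hochberg(np.asarray(pvals))
    return PathwayCollection(dict(pathways.pathways),
                             dict(zip(names, fdr.tolist())))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def build_mag(net: WeightedGeneNetwork, seeds: Iterable[str],
              profile: RankedExpressionProfile, m: int, direction: str,
              depth: int, pathway_genes: Iterable[str],
              filter_seeds: bool = False) -> GeneModule:
    """Build a direction-specific mutation-associated gene module.

    members = seeds ∪ { neighbors within ``depth`` hops that are both in
    the top-``m`` expression set for ``direction`` and in
    ``pathway_genes`` }. Seeds are retained unconditionally unless
    ``filter_seeds`` is set (off by default: the module is anchored on
    the mutated drivers themselves).

    The network is expected to be thresholded already; candidates are
    network neighbors only, so profile genes absent from the network can
    never become members.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    pathway_genes = set(pathway_genes)
    expr = expression_gene_set(profile, m, direction)
    neigh = neighbors_within(net, seeds, depth)
    survivors = {g for g in neigh if g in expr and g in pathway_genes}
    if filter_seeds:
        kept_seeds = frozenset(s for s in seeds
                               if s in expr and s in pathway_genes)
        if not kept_seeds:
            raise ValueError("filter_seeds removed every seed")
        members = frozenset(kept_seeds | survivors)
        return GeneModule(kept_seeds, members, direction, depth, m)
    return GeneModule(seeds, frozenset(seeds | survivors), direction, depth, m)
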