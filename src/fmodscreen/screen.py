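"""Screen orchestration: per-compound scoring, ranking, parameter
optimization, label evaluation and recall enrichment.

The workflow: build a direction-specific disease module for each
expression cutoff *m*; select each compound's drug signature at each
matched size *k* (keeping, per compound, the dose/time profile with the
maximal MP); rank compounds by MP; measure how well known drugs for the
disease rise to the top of the list (ranked-list AUC); pick the (m, k)
cell with the best AUC; and attach permutation p-values and empirical
FDRs to the winning list. Candidate drugs are the compounds below the
FDR cutoff.

Direction pairing is fixed by the repositioning hypothesis: genes up in
the disease should be down under a corrective drug (UCDB) and vice
versa (DCUB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .disease import (GeneModule, RankedExpressionProfile, build_mag,
                      _benjamini_hochberg)
from .drugs import CompoundProfile, DrugSignature, k_grid, select_drg
from .mp import MPResult, mutual_predictability
from .network import WeightedGeneNetwork
from .significance import (NullDistribution, auc_significance, empirical_fdr_for,
                           empirical_p, mp_null)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig", "RankedCompoundList", "OptimizationResult",
    "score_compound", "rank_compounds", "ranked_list_auc",
    "optimize_parameters", "recall_enrichment", "call_candidates",
    "both_direction_overlap", "drg_direction",
]

#: drug-signature direction implied by each landscape
_PAIRING = {"UCDB": ("up", "down"), "DCUB": ("down", "up")}


def drg_direction(direction_pair: str) -> str:
    """Drug direction for a landscape: 'down' for UCDB, 'up' for DCUB."""
    return _PAIRING[direction_pair][1]


def mag_direction(direction_pair: str) -> str:
    """Disease direction for a landscape: 'up' for UCDB, 'down' for DCUB."""
    return _PAIRING[direction_pair][0]


@dataclass
class ScreenConfig:
    """All tunables of one screen, serializable to/from YAML.

    ``m_values=None`` means the standard expression grid (1000, 3000,
    ... up to half the universe). The published protocol corresponds to
    ``fln_keep_fraction=0.05`` (or the absolute ``fln_min_weight=0.2``),
    ``pathway_fdr_cutoff=0.05``, ``compound_fdr_cutoff=0.05`` and the
    ``full`` (100,000-rep) null preset.
    """

    direction_pair: str = "UCDB"
    depth: int = 1
    fln_keep_fraction: float | None = 0.05
    fln_min_weight: float | None = None
    pathway_fdr_cutoff: float = 0.05
    m_values: list[int] | None = None
    k_step: int = 100
    k_floor: int = 100
    k_window: int = 500
    n_reps: int = 1000
    n_reps_auc: int = 1000
    seed: int = 0
    compound_fdr_cutoff: float = 0.05
    threads: int = 1
    filter_seeds: bool = False
    md_seed_mode: str = "members"
    drop_nonnetwork_positives: bool = False
    fdr_estimator: str = "plugin"

    def validate(self) -> None:
        errors = []
        if self.direction_pair not in _PAIRING:
            errors.append(f"direction_pair must be UCDB or DCUB, "
                          f"got {self.direction_pair!r}")
        if self.depth not in (1, 2):
            errors.append(f"depth must be 1 or 2, got {self.depth}")
        if self.fln_keep_fraction is not None and not (
                0 < self.fln_keep_fraction <= 1):
            errors.append(f"fln_keep_fraction {self.fln_keep_fraction} "
                          "outside (0, 1]")
        if self.fln_min_weight is not None and not (
                0 < self.fln_min_weight <= 1):
            errors.append(f"fln_min_weight {self.fln_min_weight} outside (0, 1]")
        for name in ("pathway_fdr_cutoff", "compound_fdr_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                errors.append(f"{name} {v} outside [0, 1]")
        for name in ("k_step", "k_floor", "k_window", "n_reps",
                     "n_reps_auc", "threads"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if self.m_values is not None and any(m < 1 for m in self.m_values):
            errors.append("m_values must all be >= 1")
        if self.md_seed_mode not in ("members", "drivers"):
            errors.append(f"bad md_seed_mode {self.md_seed_mode!r}")
        if self.fdr_estimator not in ("plugin", "add_one"):
            errors.append(f"bad fdr_estimator {self.fdr_estimator!r}")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))


@dataclass
class RankedCompoundList:
    """MP-ranked compounds at one (m, k) grid cell.

    Non-missing results are sorted by MP descending, ties broken by
    smaller p-value then compound identifier; missing results (no MP
    computable) trail the list unranked.
    """

    records: list[MPResult]
    m: int
    k: int
    direction_pair: str

    def __post_init__(self):
        ranked = [r for r in self.records if not r.is_missing]
        missing = [r for r in self.records if r.is_missing]
        ranked.sort(key=lambda r: (-r.mp,
                                   r.p_value if r.p_value is not None
                                   else float("inf"),
                                   r.compound_id))
        missing.sort(key=lambda r: r.compound_id)
        self.records = ranked + missing

    @property
    def ranked(self) -> list[MPResult]:
        return [r for r in self.records if not r.is_missing]

    @property
    def missing(self) -> list[MPResult]:
        return [r for r in self.records if r.is_missing]

    def compound_order(self) -> list[str]:
        return [r.compound_id for r in self.ranked]

    def to_dataframe(self, label_sets: Mapping[str, Iterable[str]] | None = None
                     ) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "compound": r.compound_id,
                "profile": r.profile_id,
                "direction_pair": self.direction_pair,
                "m": self.m,
                "k": self.k,
                "mp": r.mp,
                "auc_m_to_d": r.auc_m_to_d,
                "auc_d_to_m": r.auc_d_to_m,
                "p": r.p_value,
                "fdr": r.fdr,
                "reason": r.reason,
            }
            if label_sets:
                for name, ids in label_sets.items():
                    row[name] = r.compound_id in set(ids)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path, label_sets=None) -> None:
        self.to_dataframe(label_sets).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def score_compound(net: WeightedGeneNetwork, mag: GeneModule,
                   profiles: Sequence[CompoundProfile], k: int,
                   direction_pair: str,
                   drop_nonnetwork_positives: bool = False,
                   md_seed_mode: str = "members") -> MPResult:
    """Best MP over a compound's dose/time profiles at signature size k.

    The drug-signature direction is the opposite of the module's
    disease direction (down for UCDB, up for DCUB); the module must have
    been built with the matching direction. Profile ties on MP break
    toward the lexicographically smaller profile id.
    """
    if not profiles:
        raise ValueError("compound has no profiles")
    mag_dir, drg_dir = _PAIRING[direction_pair]
    if mag.direction != mag_dir:
        raise ValueError(
            f"{direction_pair} requires a module with direction "
            f"{mag_dir!r}, got {mag.direction!r}")
    cids = {p.compound_id for p in profiles}
    if len(cids) != 1:
        raise ValueError(f"profiles span several compounds: {sorted(cids)}")
    results = []
    for prof in sorted(profiles, key=lambda p: p.profile_id):
        if k > len(prof):
            results.append(MPResult(prof.compound_id, prof.profile_id,
                                    reason=f"k={k} exceeds profile length "
                                           f"{len(prof)}"))
            continue
        drg = select_drg(prof, k, drg_dir)
        r = mutual_predictability(
            net, mag, drg,
            drop_nonnetwork_positives=drop_nonnetwork_positives,
            md_seed_mode=md_seed_mode)
        results.append(replace(r, direction_pair=direction_pair))
    scored = [r for r in results if not r.is_missing]
    if not scored:
        reasons = "; ".join(r.reason or "degenerate" for r in results)
        return MPResult(profiles[0].compound_id, "-",
                        direction_pair=direction_pair, reason=reasons,
                        k_used=k)
    return max(scored, key=lambda r: (r.mp, ))  # profile order is stable


def rank_compounds(results: Iterable[MPResult], m: int, k: int,
                   direction_pair: str) -> RankedCompoundList:
    """Rank compounds by MP (descending) with deterministic tie-breaks."""
    records = list(results)
    if all(r.is_missing for r in records):
        raise ValueError("all compound results are missing; nothing to rank")
    return RankedCompoundList(records, m, k, direction_pair)


def ranked_list_auc(ranked: RankedCompoundList | Sequence[str],
                    positives: Iterable[str]) -> float:
    """AUC for known drugs rising to the top of the ranked compound list.

    Sweeping a cutoff position t down the list traces a ROC over the
    labeled (positive) and unlabeled compounds; the area equals the
    Mann–Whitney statistic on list positions. Missing (unranked)
    records are excluded.
    """
    order = (ranked.compound_order()
             if isinstance(ranked, RankedCompoundList) else list(ranked))
    positives = set(positives)
    labels = np.array([cid in positives for cid in order], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both labeled and unlabeled compounds in the list")
    # position 0 is the top; a positive above a negative is a win
    ranks_from_bottom = len(labels) - np.flatnonzero(labels)
    u = ranks_from_bottom.sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class OptimizationResult:
    """Outcome of the (m, k) grid sweep."""

    best_m: int
    best_k: int
    best_auc: float
    best_list: RankedCompoundList
    auc_table: pd.DataFrame          # one row per (m, k): auc, p, fdr
    mag_by_m: dict[int, GeneModule]
    null: NullDistribution | None = None


def _score_cell(net, mag, compounds, k, config) -> list[MPResult]:
    jobs = (delayed(score_compound)(
        net, mag, profs, k, config.direction_pair,
        config.drop_nonnetwork_positives, config.md_seed_mode)
        for _, profs in sorted(compounds.items()))
    return Parallel(n_jobs=config.threads, backend="threading")(jobs)


def optimize_parameters(net: WeightedGeneNetwork, seeds: Iterable[str],
                        profile: RankedExpressionProfile,
                        pathway_genes: Iterable[str],
                        compounds: Mapping[str, Sequence[CompoundProfile]],
                        positives: Iterable[str],
                        config: ScreenConfig) -> OptimizationResult:
    """Sweep the (m, k) grid, rank every cell, and keep the best one.

    For each expression cutoff m a disease module is built; the drug
    signature sizes k are matched to the module's neighbor count. Every
    cell's ranked list is scored against the known-drug labels
    (ranked-list AUC); the argmax wins, ties broken toward smaller m
    then smaller k. Per-cell AUC permutation p-values and BH FDRs are
    attached, and the winning cell's list receives per-compound
    permutation p-values and empirical FDRs from a shared MP null.

    ``net`` must already be thresholded; ``positives`` are compound ids
    (FDA-approved or trial drugs for the disease).
    """
    from .disease import m_grid as default_m_grid

    config.validate()
    seeds = frozenset(seeds)
    positives = set(positives)
    mag_dir = mag_direction(config.direction_pair)
    m_values = (config.m_values if config.m_values is not None
                else default_m_grid(len(profile)))

    rows = []
    lists: dict[tuple[int, int], RankedCompoundList] = {}
    mag_by_m: dict[int, GeneModule] = {}
    for m in sorted(set(m_values)):
        mag = build_mag(net, seeds, profile, m, mag_dir, config.depth,
                        pathway_genes, filter_seeds=config.filter_seeds)
        mag_by_m[m] = mag
        ks = k_grid(max(mag.n_neighbors, 1), step=config.k_step,
                    floor=config.k_floor, window=config.k_window)
        for k in ks:
            results = _score_cell(net, mag, compounds, k, config)
            if all(r.is_missing for r in results):
                logger.warning("grid cell (m=%d, k=%d): all compounds "
                               "degenerate; skipped", m, k)
                continue
            ranked = rank_compounds(results, m, k, config.direction_pair)
            auc = ranked_list_auc(ranked, positives)
            lists[(m, k)] = ranked
            rows.append({"m": m, "k": k, "auc": auc})
    if not rows:
        raise ValueError("no scorable grid cell")
    table = pd.DataFrame(rows)
    table["auc_p"] = [
        auc_significance(
            [cid in positives for cid in lists[(r.m, r.k)].compound_order()],
            n_reps=config.n_reps_auc, seed=config.seed + 1)
        for r in table.itertuples()]
    table["auc_fdr"] = _benjamini_hochberg(table["auc_p"].to_numpy())

    best = table.sort_values(["auc", "m", "k"],
                             ascending=[False, True, True],
                             kind="stable").iloc[0]
    best_m, best_k = int(best["m"]), int(best["k"])
    best_list = lists[(best_m, best_k)]

    # per-compound significance at the winning cell, one shared null
    profile_universe = _profile_universe(compounds)
    null = mp_null(net, mag_by_m[best_m], profile_universe,
                   n_drg=min(best_k, len(profile_universe) - 1),
                   n_reps=config.n_reps, seed=config.seed + 2)
    scored = best_list.ranked
    mps = [r.mp for r in scored]
    fdrs = empirical_fdr_for(mps, null, estimator=config.fdr_estimator)
    annotated = [replace(r, p_value=empirical_p(r.mp, null), fdr=float(f))
                 for r, f in zip(scored, fdrs)]
    best_list = RankedCompoundList(annotated + best_list.missing,
                                   best_m, best_k, config.direction_pair)
    return OptimizationResult(best_m, best_k, float(best["auc"]),
                              best_list, table, mag_by_m, null)


def _profile_universe(compounds: Mapping[str, Sequence[CompoundProfile]]
                      ) -> list[str]:
    genes: set[str] = set()
    for profs in compounds.values():
        for p in profs:
            genes.update(p.ranks.genes)
    return sorted(genes)


def recall_enrichment(n_universe: int, n_significant: int, n_labeled: int,
                      n_labeled_significant: int) -> float:
    """One-sided Fisher exact p for label enrichment among significant hits.

    The probability of at least ``n_labeled_significant`` labeled drugs
    among ``n_significant`` compounds drawn from a universe of
    ``n_universe`` containing ``n_labeled`` labeled drugs (the
    hypergeometric upper tail).
    """
    if not (0 <= n_labeled_significant
            <= min(n_labeled, n_significant)
            and max(n_labeled, n_significant) <= n_universe):
        raise ValueError("inconsistent counts")
    return float(stats.hypergeom.sf(n_labeled_significant - 1, n_universe,
                                    n_labeled, n_significant))


@dataclass
class CandidateReport:
    """Compounds called at an FDR cutoff, cross-tabulated against labels."""

    called: list[str]
    fdr_cutoff: float
    n_ranked: int
    label_counts: dict[str, int]          # label set -> called ∩ labeled
    label_totals: dict[str, int]          # label set -> labeled in the list
    enrichment_p: dict[str, float]        # Fisher exact per label set


def call_candidates(ranked: RankedCompoundList, fdr_cutoff: float,
                    label_sets: Mapping[str, Iterable[str]] | None = None
                    ) -> CandidateReport:
    """Call candidates at ``fdr < fdr_cutoff`` (strict) and tabulate labels."""
    scored = ranked.ranked
    if any(r.fdr is None for r in scored):
        raise ValueError("ranked list carries no FDR values; run the "
                         "significance step first")
    called = [r.compound_id for r in scored if r.fdr < fdr_cutoff]
    label_sets = {k: set(v) for k, v in (label_sets or {}).items()}
    universe = {r.compound_id for r in scored}
    counts, totals, enrich = {}, {}, {}
    for name, ids in label_sets.items():
        labeled = ids & universe
        hit = len(labeled & set(called))
        counts[name] = hit
        totals[name] = len(labeled)
        if labeled and called:
            enrich[name] = recall_enrichment(len(universe), len(called),
                                             len(labeled), hit)
        else:
            enrich[name] = 1.0
    return CandidateReport(called, fdr_cutoff, len(scored), counts, totals,
                           enrich)


def both_direction_overlap(report_a: CandidateReport,
                           report_b: CandidateReport,
                           label_set: Iterable[str] | None = None) -> int:
    """Count compounds called in both landscapes (optionally labeled only)."""
    overlap = set(report_a.called) & set(report_b.called)
    if label_set is not None:
        overlap &= set(label_set)
    return len(overlap)
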