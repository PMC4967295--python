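"""Synthetic study generator: networks, profiles, pathways and compounds
with planted, parameterized structure.

The generator emulates the statistical situation the screen assumes: a
functional linkage network containing dense modules, one of which is the
disease module — its *disease half* carries the mutated drivers and is
up-regulated in the disease expression profile, while its *drug half*
(the module's network neighborhood) is what corrective compounds
down-regulate. Effective drugs plant a fraction
(``drug_overlap_strength``) of the drug half at the bottom of their
signatures, underneath a handful of off-target "filler" genes (every
drug also does irrelevant things); decoy drugs carry filler and noise
only.

A third class of compounds, *bait decoys*, down-regulate genes that are
strongly linked to the driver genes themselves but not to the disease
module's drug half. They emulate the hub neighborhoods real driver
genes drag along, and they are what makes parameter choice matter: at a
poorly chosen module size or signature size the baits outscore the true
positives, so the grid search has a genuine optimum to find.

Everything is reproducible from (scenario, seed), and every output
round-trips through the package's standard-format readers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .disease import PathwayCollection, RankedExpressionProfile
from .drugs import CompoundProfile
from .network import WeightedGeneNetwork

__all__ = ["SyntheticScenario", "SyntheticBundle", "generate",
           "write_bundle", "load_bundle"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study. Defaults are the frozen
    high-signal condition used throughout the test suite.

    ``drug_overlap_strength`` is the fraction of the disease module's
    drug half that an effective drug plants at the bottom of its
    signature; 0 makes effective drugs statistically indistinguishable
    from decoys.
    """

    n_genes: int = 400
    n_modules: int = 2
    module_size: int = 50            # split: disease half + drug half
    within_module_edge_prob: float = 0.6
    within_weight_beta: tuple[float, float] = (8.0, 2.0)
    background_edge_prob: float = 0.35
    background_weight_beta: tuple[float, float] = (2.0, 8.0)
    n_seed_drivers: int = 5
    expression_effect: float = 5.0   # mean stat shift of disease-half genes
    expression_noise: float = 1.0
    n_effective_drugs: int = 6
    n_decoy_drugs: int = 27
    n_bait_decoys: int = 3
    n_bait_genes: int = 15
    bait_module_edge_prob: float = 0.15
    drug_overlap_strength: float = 0.8
    drug_effect: float = 6.0         # stat shift of planted drug genes
    n_filler: int = 10               # off-target genes below the signal
    n_profiles_per_compound: int = 2
    n_decoy_pathways: int = 3
    seed: int = 0

    # -- derived geometry ---------------------------------------------

    @property
    def disease_half(self) -> int:
        return self.module_size // 2

    @property
    def drug_half(self) -> int:
        return self.module_size - self.disease_half

    @property
    def n_planted(self) -> int:
        return int(round(self.drug_overlap_strength * self.drug_half))

    @property
    def m_star(self) -> int:
        """Expression cutoff that admits exactly the disease half."""
        return self.disease_half

    @property
    def k_star(self) -> int:
        """Signature size that captures filler plus all planted genes."""
        return self.n_filler + self.n_planted

    def validate(self) -> None:
        errors = []
        if self.module_size < 2:
            errors.append("module_size must be >= 2")
        if self.n_modules * self.module_size + self.n_bait_genes > self.n_genes:
            errors.append("modules plus bait genes exceed n_genes")
        if self.n_seed_drivers > self.disease_half:
            errors.append("n_seed_drivers exceeds the disease half")
        if not (0 <= self.drug_overlap_strength <= 1):
            errors.append("drug_overlap_strength outside [0, 1]")
        for name in ("within_module_edge_prob", "background_edge_prob",
                     "bait_module_edge_prob"):
            if not (0 <= getattr(self, name) <= 1):
                errors.append(f"{name} outside [0, 1]")
        n_bulk = (self.n_genes - self.n_modules * self.module_size
                  - self.n_bait_genes)
        if self.n_filler > n_bulk:
            errors.append("n_filler exceeds the bulk gene pool")
        if errors:
            raise ValueError("infeasible scenario: " + "; ".join(errors))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["within_weight_beta"] = list(self.within_weight_beta)
        d["background_weight_beta"] = list(self.background_weight_beta)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        for key in ("within_weight_beta", "background_weight_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticBundle:
    """In-memory result of one generated study."""

    scenario: SyntheticScenario
    network: WeightedGeneNetwork
    seeds: list[str]
    disease_profile: RankedExpressionProfile
    pathways: PathwayCollection
    compounds: dict[str, list[CompoundProfile]]
    effective: list[str]             # truth labels: genuinely corrective
    truth: dict                      # planted structure for recovery tests


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate(scenario: SyntheticScenario) -> SyntheticBundle:
    """Generate one synthetic study; reproducible from (scenario, seed)."""
    sc = scenario
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    genes = _gene_names(sc.n_genes)
    n = sc.n_genes

    # gene geography: [modules | baits | bulk]
    module_of = np.full(n, -1)
    for mod in range(sc.n_modules):
        module_of[mod * sc.module_size:(mod + 1) * sc.module_size] = mod
    in_disease_half = np.zeros(n, dtype=bool)
    for mod in range(sc.n_modules):
        lo = mod * sc.module_size
        in_disease_half[lo:lo + sc.disease_half] = True
    in_disease_half &= module_of >= 0
    bait_lo = sc.n_modules * sc.module_size
    is_bait = np.zeros(n, dtype=bool)
    is_bait[bait_lo:bait_lo + sc.n_bait_genes] = True
    is_seed = np.zeros(n, dtype=bool)
    is_seed[:sc.n_seed_drivers] = True          # drivers sit in module 0's
    bulk = np.flatnonzero((module_of < 0) & ~is_bait)  # disease half

    # ---- network ----------------------------------------------------
    iu, ju = np.triu_indices(n, k=1)
    same_module = (module_of[iu] == module_of[ju]) & (module_of[iu] >= 0)
    bait_seed = (is_bait[iu] & is_seed[ju]) | (is_seed[iu] & is_bait[ju])
    mod0_nonseed = (module_of == 0) & in_disease_half & ~is_seed
    bait_a0 = ((is_bait[iu] & mod0_nonseed[ju])
               | (mod0_nonseed[iu] & is_bait[ju]))
    prob = np.full(iu.shape, sc.background_edge_prob)
    prob[same_module] = sc.within_module_edge_prob
    prob[bait_a0] = sc.bait_module_edge_prob
    prob[bait_seed] = 1.0
    accept = rng.random(iu.shape) < prob
    strong = same_module | bait_seed | bait_a0   # functional links
    a_hi, b_hi = sc.within_weight_beta
    a_lo, b_lo = sc.background_weight_beta
    w = np.where(strong, rng.beta(a_hi, b_hi, size=iu.shape),
                 rng.beta(a_lo, b_lo, size=iu.shape))
    w = np.clip(w, 1e-9, 1.0)
    ii, jj, ww = iu[accept], ju[accept], w[accept]
    network = WeightedGeneNetwork(
        ((genes[a], genes[b], float(wt)) for a, b, wt in zip(ii, jj, ww)),
        nodes=genes)

    seeds = [genes[i] for i in np.flatnonzero(is_seed)]

    # ---- disease expression -----------------------------------------
    stats = rng.normal(0.0, 1.0, n)
    dis = np.flatnonzero((module_of == 0) & in_disease_half)
    stats[dis] += rng.normal(sc.expression_effect, sc.expression_noise,
                             dis.size)
    disease_profile = RankedExpressionProfile(
        tuple(genes), tuple(stats.tolist()))

    # ---- pathways ----------------------------------------------------
    pathways: dict[str, frozenset[str]] = {}
    significance: dict[str, float] = {}
    for mod in range(sc.n_modules):
        members = np.flatnonzero((module_of == mod) & in_disease_half)
        pathways[f"module{mod}_pathway"] = frozenset(genes[i] for i in members)
        significance[f"module{mod}_pathway"] = 0.005 * (mod + 1)
    for d in range(sc.n_decoy_pathways):
        members = rng.choice(n, size=sc.disease_half, replace=False)
        pathways[f"decoy{d}_pathway"] = frozenset(genes[i] for i in members)
        significance[f"decoy{d}_pathway"] = 0.5
    pathway_collection = PathwayCollection(pathways, significance)

    # ---- compounds ---------------------------------------------------
    drug_half_idx = np.flatnonzero((module_of == 0) & ~in_disease_half)
    bait_idx = np.flatnonzero(is_bait)
    n_total = sc.n_effective_drugs + sc.n_decoy_drugs + sc.n_bait_decoys
    width = max(3, len(str(n_total)))
    compounds: dict[str, list[CompoundProfile]] = {}
    effective: list[str] = []

    def make_profile(cid: str, pid: str, planted: np.ndarray,
                     with_filler: bool, attenuation: float) -> CompoundProfile:
        s = rng.normal(0.0, 1.0, n)
        if with_filler:
            filler = rng.choice(bulk, size=sc.n_filler, replace=False)
            s[filler] = -(sc.drug_effect + 6.0 + np.abs(
                rng.normal(0.0, 1.0, filler.size)))
        if planted.size:
            s[planted] = -attenuation * (
                sc.drug_effect + rng.normal(0.0, 0.5, planted.size))
        return CompoundProfile(cid, pid, RankedExpressionProfile(
            tuple(genes), tuple(s.tolist())))

    # compound ids must carry no information about the truth labels
    # (ranking breaks MP ties by id), so the kind order is shuffled
    kinds = (["effective"] * sc.n_effective_drugs
             + ["decoy"] * sc.n_decoy_drugs
             + ["bait"] * sc.n_bait_decoys)
    rng.shuffle(kinds)
    for idx, kind in enumerate(kinds):
        cid = f"cmpd_{idx:0{width}d}"
        if kind == "effective":
            effective.append(cid)
            planted = (rng.choice(drug_half_idx, size=sc.n_planted,
                                  replace=False)
                       if sc.n_planted else np.array([], dtype=int))
            with_filler = True
        elif kind == "decoy":
            planted, with_filler = np.array([], dtype=int), True
        else:
            planted, with_filler = bait_idx, False
        compounds[cid] = [
            make_profile(cid, f"p{p + 1}", planted, with_filler,
                         1.0 if p == 0 else 0.6)
            for p in range(sc.n_profiles_per_compound)]

    truth = {
        "m_star": sc.m_star,
        "k_star": sc.k_star,
        "effective": list(effective),
        "disease_module": [genes[i] for i in dis],
        "drug_neighborhood": [genes[i] for i in drug_half_idx],
        "bait_genes": [genes[i] for i in bait_idx],
        "modules": {
            f"module{mod}": [genes[i] for i in
                             np.flatnonzero(module_of == mod)]
            for mod in range(sc.n_modules)},
    }
    return SyntheticBundle(sc, network, seeds, disease_profile,
                           pathway_collection, compounds, effective, truth)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the package's standard plain-text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "fln.tsv"
    with p.open("w") as fh:
        fh.write("# geneA\tgeneB\tweight\n")
        for a, b, w in sorted(bundle.network.edges()):
            fh.write(f"{a}\t{b}\t{w:.17g}\n")
    paths["network"] = p

    p = out / "seeds.txt"
    p.write_text("".join(f"{s}\n" for s in bundle.seeds))
    paths["seeds"] = p

    p = out / "disease_ranks.tsv"
    with p.open("w") as fh:
        for g, s in zip(bundle.disease_profile.genes,
                        bundle.disease_profile.stats):
            fh.write(f"{g}\t{s:.9g}\n")
    paths["disease_profile"] = p

    p = out / "pathways.gmt"
    bundle.pathways.to_gmt(p)
    paths["pathways"] = p
    p = out / "pathway_fdr.tsv"
    with p.open("w") as fh:
        for name in sorted(bundle.pathways.significance):
            fh.write(f"{name}\t{bundle.pathways.significance[name]:.9g}\n")
    paths["pathway_fdr"] = p

    sig_dir = out / "signatures"
    sig_dir.mkdir(exist_ok=True)
    for cid, profs in sorted(bundle.compounds.items()):
        for prof in profs:
            fp = sig_dir / f"{cid}__{prof.profile_id}.tsv"
            with fp.open("w") as fh:
                for g, s in zip(prof.ranks.genes, prof.ranks.stats):
                    fh.write(f"{g}\t{s:.9g}\n")
    paths["signatures"] = sig_dir

    p = out / "labels_effective.txt"
    p.write_text("".join(f"{c}\n" for c in bundle.effective))
    paths["labels"] = p

    p = out / "truth.yaml"
    p.write_text(yaml.safe_dump(bundle.truth, sort_keys=True))
    paths["truth"] = p

    p = out / "scenario.yaml"
    bundle.scenario.to_yaml(p)
    paths["scenario"] = p
    return paths


def load_bundle(out_dir: str | Path) -> SyntheticBundle:
    """Re-read a written bundle through the package's standard readers."""
    from .drugs import load_compound_dir
    from .network import load_edge_list

    out = Path(out_dir)
    scenario = SyntheticScenario.from_yaml(out / "scenario.yaml")
    network = load_edge_list(out / "fln.tsv")
    seeds = [l for l in (out / "seeds.txt").read_text().splitlines() if l]
    profile = RankedExpressionProfile.from_tsv(out / "disease_ranks.tsv")
    pathways = PathwayCollection.from_gmt(out / "pathways.gmt",
                                          out / "pathway_fdr.tsv")
    flat = load_compound_dir(out / "signatures")
    compounds: dict[str, list[CompoundProfile]] = {}
    for prof in flat:
        compounds.setdefault(prof.compound_id, []).append(prof)
    effective = [l for l in
                 (out / "labels_effective.txt").read_text().splitlines() if l]
    truth = yaml.safe_load((out / "truth.yaml").read_text())
    return SyntheticBundle(scenario, network, seeds, profile, pathways,
                           compounds, effective, truth)
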