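# Methods

## Model and procedure

The screen assumes that a disease's mutated driver genes and the genes
a corrective drug perturbs occupy the same densely linked neighborhood
of a functional linkage network (FLN) — an undirected gene graph whose
edge weights in (0, 1] encode the likelihood of shared biological
function. The pipeline:

1. **Thresholding.** The FLN is restricted to its strongest links,
   either by an absolute weight cutoff or by keeping a fraction of
   edges by weight quantile (default: keep 5%, mirroring the protocol
   of discarding ~95% of each gene's neighbors; for the published FLN
   that corresponds to an absolute threshold of 0.2). Ties at the
   threshold are kept (inclusive ≥), and isolated nodes are retained so
   the scoring universe is identical across parameter settings.
2. **Disease module (MAG).** Mutated drivers are expanded to their
   first (or first and second) FLN neighbors; neighbors survive only if
   they are among the *m* most up- (or down-) regulated genes of the
   disease expression profile **and** belong to pathways significant at
   FDR < 0.05. Seeds are kept unconditionally (`filter_seeds` exists
   but defaults off): the module is anchored on the drivers.
3. **Drug signature (DRG).** Per compound and per dose/time profile,
   the k most down- (UCDB) or up- (DCUB) regulated genes, with k swept
   over multiples of 100 within ±500 of the module's neighbor count
   (floored at 100). The pairing is fixed by the repositioning
   hypothesis: disease-up pairs with drug-down and vice versa.
4. **Mutual predictability.** Each set seed-scores the network
   (S_i = Σ_j w_ij over seeds j); retrieval of the other set from the
   score-ranked universe is a Mann–Whitney AUC with half-credit ties;
   MP is the geometric mean of the two directions. The compound keeps
   its best profile's MP.
5. **Significance.** A per-module null redraws random signatures of the
   same size from the compound-profile gene universe; p-values use the
   add-one permutation estimator; empirical FDR is the expected false
   positive count over the observed count, monotonized (Benjamini–
   Hochberg on empirical p-values is available as an alternative).
6. **Optimization and calls.** Every (m, k) cell is ranked and scored
   by the ranked-list AUC against known drug labels; the argmax cell
   wins (ties: smaller m, then smaller k); candidates are compounds
   with FDR strictly below 0.05; recall enrichment is the one-sided
   Fisher exact (hypergeometric upper tail).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `fln_keep_fraction` / `fln_min_weight` | 0.05 / 0.2 | linkage threshold (quantile or absolute) |
| `depth` | 1 | neighbor expansion hops (1 or 2) |
| m grid | 1000, 3000, … to half the universe | expression-filter sizes for the module |
| k grid | multiples of 100 within ±500 of the module's neighbor count | signature sizes, matched per module |
| `pathway_fdr_cutoff` | 0.05 | pathway filter for module neighbors |
| `n_reps` | 100,000 (faithful preset) / 1,000 (test preset) | permutation replicates |
| `compound_fdr_cutoff` | 0.05 | candidate call threshold (strict <) |

The k grid is matched to the module size *excluding* seeds, following
the published pairing of 237 filtered neighbors with signature sizes
around 700. The m-grid floor assumes a genome-scale profile; below a
2000-gene universe it degenerates to a single value of half the
universe with a warning (toy inputs only).

## Design choices where the procedure was open

- **Scored universe.** Retrieval runs over all network nodes minus the
  current seed set, not just seed-adjacent genes; restricting to
  nonzero scores would inflate AUC. Positives overlapping the seed set
  are dropped (self-retrieval is uninformative); positives absent from
  the network stay in the universe at score 0 (configurable).
- **Ties.** Seed scores have massive ties at 0, so AUC uses the
  half-credit Mann–Whitney identity; any cutoff-sweep with arbitrary
  within-tie ordering would be nondeterministic. Rank ties in
  expression profiles break lexicographically by gene identifier.
- **Missing, not zero.** When a direction's positive set vanishes (e.g.
  the signature is swallowed by the module), MP is reported missing
  with a reason, never 0, so ranking cannot reward or punish data
  absence. Missing compounds trail the ranked list unranked.
- **Add-one p-values.** The plug-in permutation estimator can return
  exactly 0, which poisons downstream FDR; the add-one estimator
  (1 + exceedances)/(reps + 1) is the default, plug-in retained behind
  a flag.
- **Ranked-list AUC.** The label-evaluation curve is implemented as the
  standard position-based Mann–Whitney AUC (0.5 = random, 1 = perfect),
  which matches the sensitivity/specificity summary the screen
  optimizes.
- **M-D seeding.** Predictability M-D seeds with the full module
  membership (drivers + filtered neighbors); a `md_seed_mode='drivers'`
  switch restricts to drivers only.
- **Reproducibility.** One config seed drives every stage through
  derived substreams; results are independent of the worker count
  (scoring is parallelized over compounds with a threading backend and
  collected in input order, nulls are single-stream). Run manifests
  record config hash, input digests, seed and version; manifests are
  byte-identical when given the same explicit timestamp (wall clock by
  default).

## The synthetic study generator

`SyntheticScenario` plants, on a gene universe of 400 genes by default:

- **Modules** (2 × 50 genes) with dense internal links drawn from a
  high-mean Beta(8, 2); the background is a dense sea of weak links
  (probability 0.35, Beta(2, 8)) so that strong functional links are
  ~5% of all edges and the published keep-5% threshold is meaningful.
- **The disease module**, split into a *disease half* (25 genes: 5
  mutated drivers plus pathway members, mean expression shift +5) and a
  *drug half* — the module's network neighborhood, which effective
  drugs down-regulate.
- **Compound signatures** (2 dose/time profiles each; the second is
  attenuated so the best-profile rule has something to choose).
  Effective drugs plant `drug_overlap_strength` (default 0.8) of the
  drug half at the bottom of their profiles, beneath 10 off-target
  "filler" genes; decoys carry filler and noise only. Compound ids are
  shuffled across kinds so labels are not recoverable from id order
  (ranking breaks MP ties by id).
- **Bait genes** (15, strongly linked to every driver but not to the
  drug half) and bait-decoy compounds that down-regulate them. They
  emulate the hub neighborhoods real driver genes drag along, and they
  are what gives the (m, k) grid a genuine interior optimum: with too
  small a module or signature the baits outscore true positives, so
  parameter recovery is a real inference, not a tautology. The planted
  optimum is m* = 25 (the disease half) and k* = 30 (filler + planted
  genes).
- **Pathways**: one per planted module (disease halves, FDR 0.005 and
  0.01) plus random decoy pathways at FDR 0.5 that fail the filter.

What the generator does **not** emulate: dose–response structure,
transcriptomic covariance between genes, batch effects, scale (hundreds
of genes and dozens of compounds versus ~20,000 genes and thousands of
compounds), or gene-identifier namespaces. Passing tests therefore
demonstrate the statistical machinery — scoring, ranking, calibration,
optimization — not performance on real LINCS/TCGA inputs, which require
the original network and expression data.

Null-calibration runs use `drug_overlap_strength=0` **and**
`n_bait_decoys=0`: bait decoys are deliberately non-exchangeable with
other compounds, and E[AUC] = 0.5 under relabeling requires an
exchangeable compound panel. These runs also score a single fixed
(m*, k*) cell, because the max over a grid of null AUCs is biased
upward by construction.

## Problem sizes used in the tests

The suite runs screens on the default scenario (400 genes, ~28,000
edges pre-threshold, 36 compounds × 2 profiles, 7 grid cells):
planted-recovery over 100 seeds with 1,000-replicate nulls,
null-calibration over 50 seeds, oracle equivalence on 100 random
instances per statistic, and p-value uniformity at 10,000 draws. The
acceptance script uses 20 screens, 25 null-calibration replicates and
the same oracle and uniformity sizes.

## Numerical notes and degenerate inputs

- Quantile thresholding uses the `higher` method so the reported
  threshold is an actual edge weight and the inclusive rule keeps close
  to the nominal fraction.
- Duplicate edges collapse to the maximum weight; self-loops are
  dropped with a warning; malformed edge-list lines fail with the line
  number.
- A module with no edges in the thresholded network makes every null
  draw uninformative; `mp_null` raises and advises revisiting the
  threshold rather than emitting a degenerate null.
- Empirical FDR is monotonized so it never rises as the score threshold
  rises (step-up, as in Benjamini–Hochberg).
- Exact enumeration mode for ranked-list AUC significance is available
  for tiny lists and is used to cross-check the sampling mode.

## Known limitations

- Pathway significance is consumed as given (or computed by a plain
  hypergeometric over-representation test); topology-weighted pathway
  statistics are not reproduced.
- Differential expression is consumed as precomputed signed ranks; no
  count modeling is done.
- The two direction pairings are screened independently; the union /
  intersection reporting of candidates across pairings is provided but
  no joint statistic is defined.
- MP values on real published inputs (specific compounds' scores,
  screen-level AUCs of 0.8–0.9) are not reproducible without the
  original network, expression and signature data, and are out of scope
  for the test suite.
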