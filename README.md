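# fmodscreen

Network-based drug repositioning by functional modules. `fmodscreen`
screens compound expression signatures against a disease's
mutation-associated gene module on a weighted human functional linkage
network (FLN), looking for drugs that perturb the *same cellular
functions* as the disease, in the opposite direction.

## Who this is for

Computational biologists with (1) a weighted gene–gene functional
linkage network, (2) a list of mutated driver genes for a disease,
(3) a ranked disease differential-expression table, (4) per-compound
differential-expression signatures (LINCS/CMap-style), (5) pathway gene
sets with significance, and (6) optionally a list of known drugs for
the disease to optimize against. The package also ships a synthetic
study generator that emulates all six inputs with planted structure, so
every stage is testable without downloads.

## The statistic

Genes are scored against a seed set on the FLN by their summed linkage
weight,

    S_i = Σ_{j ∈ seeds} w_ij        (0 with no seed connection),

and the quality with which those scores retrieve a target gene set is a
Mann–Whitney ROC AUC (half credit on ties). The **mutual
predictability** of the disease module M (mutated drivers plus filtered
FLN neighbors, the MAG) and a drug signature D (top/bottom-k response
genes, the DRG) is the geometric mean of the two retrieval directions:

    MP(M, D) = sqrt(AUC_D-M × AUC_M-D)

Compounds are ranked by MP in two direction pairings — genes up in the
disease vs down under the drug (UCDB) and the reverse (DCUB). Per-compound
significance comes from a permutation null (random drug signatures
against the fixed module) with add-one p-values and empirical FDR; the
module-size (m) and signature-size (k) grid is optimized by the ranked
list's AUC against known drug labels; recall enrichment uses the
one-sided Fisher exact test.

## Worked example

`examples/04_full_screen.py` generates a synthetic study (400 genes, a
planted 50-gene disease module, 36 compounds of which 6 are genuinely
corrective), thresholds the FLN to its strongest 5% of links, and runs
the full screen:

```
 m  k      auc    auc_p  auc_fdr
 8 10 0.383333 0.810945 0.875622
 8 20 0.900000 0.004975 0.007960
25 10 0.350000 0.875622 0.875622
25 20 0.900000 0.004975 0.007960
25 30 1.000000 0.004975 0.007960
80 10 0.350000 0.875622 0.875622
80 20 0.900000 0.004975 0.007960
80 30 1.000000 0.004975 0.007960

best cell: m=25 k=30 ranked-list AUC=1.000 (planted: m*=25 k*=30)
9 candidates at FDR<0.05; recall 6/6 effective drugs, Fisher p=4.31e-05
```

Each row is one (m, k) grid cell: `auc` measures how well that cell's
MP-ranked compound list pushes the known drugs to the top, with a
permutation p-value and BH FDR. The best cell is the planted one
(ties break toward smaller m, then smaller k), all six corrective
compounds are recalled at FDR < 0.05, and the Fisher exact test says a
random draw of 9 compounds would almost never contain all six. The
other examples cover module construction, single-compound MP scoring,
permutation significance, recall enrichment from published-style screen
counts, and writing a study to disk.

A thin CLI wraps the same library calls:

```sh
fmodscreen simulate --seed 1 --out study/
fmodscreen screen --network study/fln.tsv --seeds study/seeds.txt \
    --profile study/disease_ranks.tsv --pathways study/pathways.gmt \
    --pathway-fdr study/pathway_fdr.tsv --signatures study/signatures \
    --labels study/labels_effective.txt --config cfg.yaml --out run/
fmodscreen enrich --universe 3678 --significant 2435 --labeled 20 --overlap 20
```

## Layout

- `src/fmodscreen/network.py` — FLN loading, quantile/absolute
  thresholding, neighborhood queries
- `src/fmodscreen/disease.py` — expression/pathway filters, m-grid,
  hypergeometric pathway enrichment, MAG construction
- `src/fmodscreen/drugs.py` — drug signature selection, matched k-grid
- `src/fmodscreen/mp.py` — seed scores, retrieval AUC, mutual
  predictability
- `src/fmodscreen/significance.py` — permutation nulls, empirical
  p/FDR, ranked-list AUC significance
- `src/fmodscreen/screen.py` — orchestration: scoring, ranking, grid
  optimization, candidate calls, recall enrichment
- `src/fmodscreen/simulate.py` — synthetic study generator
- `src/fmodscreen/config.py`, `cli.py` — YAML config, run manifests,
  command-line surface

See `docs/methods.md` for the model, parameter defaults, numerical
choices and limitations.
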