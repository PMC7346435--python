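# orthoquant

Cross-species comparison of bulk/single-cell transcriptomes through
**orthology-aware quantile mapping**. The motivating setting is the mature
(metaphase-II) oocyte: two human TPM datasets and one zebrafish dataset,
three replicates each, asked whether the two species express their
orthologous genes at concordant relative levels.

The toolkit is for computational biologists who have gene-level TPM matrices
and an Ensembl/BioMart-style ortholog table and want a reproducible,
scriptable version of this analysis — including a synthetic-data generator
so every stage can be exercised and validated without any downloads.

## Method

1. **Expression calls.** A gene is *expressed* in a dataset if TPM > 1 in
   every replicate; it is *highly expressed* if its per-replicate z-score —
   computed over the log TPM of the expressed genes within that replicate —
   exceeds 1.5 in at least 2 of 3 replicates.
2. **Quantile mapping.** The expressed genes of each dataset are ranked by
   mean TPM and split into ten deciles (quantile 1 = top 10 %). For two
   datasets, every high-confidence ortholog pair expressed in both is
   tabulated at its (row-decile, column-decile) cell; many-to-many pairs
   each count once. Extra row/column 11 holds genes whose high-confidence
   orthologs are all unexpressed on the other side, and row/column 12 genes
   with no high-confidence ortholog.
3. **Region enrichment.** Whether a block of cells (the top-left k × k
   corner, say) holds more pairs than a uniform spread N·k²/100 would give
   is tested with Fisher's exact test on the region-membership 2 × 2 table.
4. **Highly concordant orthologous genes.** Genes in the top 3 × 3 corner
   (top 30 % of expression in both species) for *every* human dataset,
   ranked by grand-mean TPM over all nine samples (zebrafish samples
   contribute through the ortholog's TPM).
5. **Sample similarity.** On the concordant genes: row-normalized UPGMA
   clustering with Pearson distance 1 − r, PCA, and ANOSIM / adonis
   (PERMANOVA) label-permutation tests on Euclidean distances over the PC
   scores, with automatic exhaustive enumeration for small designs.
6. **Over-representation.** Gene-set enrichment with Fisher's exact test and
   the conservative EASE score (Fisher with one hit removed), Bonferroni
   correction reported alongside, significance at EASE ≤ 0.05.

## Worked example

Simulate a study-shaped dataset pair (two "human" datasets, one "zebrafish",
~24k/26k genes, realistic zero-TPM fractions, planted high-expression genes)
and run the core analysis:

```python
from orthoquant import (SimulationConfig, simulate, make_call_set,
                        assign_quantiles, build_quantile_mapping,
                        region_enrichment, top_region_genes,
                        intersect_and_rank)

study = simulate(SimulationConfig(seed=42, planted_high_fraction=0.10))
calls = {d.dataset_id: make_call_set(d) for d in study.datasets}
for ds_id, cs in calls.items():
    print(f"{ds_id}: {len(cs.expressed)} expressed, "
          f"{len(cs.highly_expressed)} highly expressed")

quantiles = {k: assign_quantiles(v) for k, v in calls.items()}
top_sets = {}
for q in ("H1", "H2"):
    qm = build_quantile_mapping(quantiles[q], quantiles["ZF"],
                                om=study.orthology)
    res = region_enrichment(qm, [1, 2, 3], [1, 2, 3], alternative="greater")
    print(f"{q} vs ZF: {qm.n_grid_pairs} mapped pairs; top 3x3 corner "
          f"{res.observed} vs {res.expected:.1f} expected "
          f"(odds ratio {res.odds_ratio:.1f}, p = {res.p_value:.2e})")
    top_sets[q] = top_region_genes(qm, k=3)

result = intersect_and_rank(top_sets, study.datasets,
                            orthology=study.orthology)
print(f"{len(result.intersection)} highly concordant genes "
      f"({result.overlap_pct:.0f}% overlap); top gene "
      f"{result.ranking[0][0]} at {result.ranking[0][1]:.0f} TPM")
```

Output:

```
H1: 2732 expressed, 481 highly expressed
H2: 4213 expressed, 503 highly expressed
ZF: 8937 expressed, 1041 highly expressed
H1 vs ZF: 596 mapped pairs; top 3x3 corner 261 vs 53.6 expected (odds ratio 64.9, p = 1.00e-58)
H2 vs ZF: 827 mapped pairs; top 3x3 corner 314 vs 74.4 expected (odds ratio 13.4, p = 8.12e-59)
222 highly concordant genes (97% overlap); top gene GA019470 at 3211 TPM
```

The top corner holds five times the pairs a uniform spread would give:
the simulated cross-species concordance (rank correlation 0.7, boosted among
top-expressed genes) concentrates orthologous expression in the
high-expression corner, exactly the signature the quantile map is built to
expose. The concordant set is the intersection of both human datasets'
top-corner genes, and its ranking is led by the planted very-high-TPM genes.

The same workflow is available from the shell (`orthoquant simulate`,
`orthoquant calls`, `orthoquant quantile-map`, `orthoquant similarity`,
`orthoquant enrich`) or end-to-end from a YAML config with
`orthoquant run --config study.yaml`, which writes every stage artifact plus
a `MANIFEST.json` with SHA-256 checksums for reproducibility.

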