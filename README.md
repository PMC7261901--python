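# cernet

Inference pipeline for lncRNA–miRNA–mRNA competing-endogenous-RNA (ceRNA)
networks from two-group RNA-seq count data, with a seeded synthetic-data
generator for validation against planted ground truth.

The pipeline stages are:

1. **Differential expression** (`cernet.diffexpr`) — median-of-ratios
   normalization, Welch's t on log2 normalized counts, strict fold-change
   filters (> 1.2 up, < 0.83 down, p < 0.05), Benjamini–Hochberg FDR, and a
   2^–ΔΔCt helper for qPCR-style relative expression.
2. **Weighted co-expression network** (`cernet.coexpression`) — similarity
   S = |Pearson r|, soft-threshold adjacency a = S^β with integer β chosen
   by the scale-free topology criterion (signed R² of the log–log
   connectivity fit, mean-connectivity floor), topological overlap (TOM),
   average-linkage module clustering on 1 − TOM, thresholded lncRNA–mRNA
   edge network and hub-lncRNA sub-network extraction.
3. **ceRNA assembly** (`cernet.cerna`) — lncRNA–mRNA pairs screened by
   signed PCC (> 0.8, p < 0.05), retained when they share more than one
   differentially expressed miRNA in the target table and the overlap is
   significant under an exact hypergeometric test; the result is a
   tripartite graph with degree-centrality reporting and per-miRNA
   sub-network extraction.
4. **Synthetic data** (`cernet.simulate`) — negative-binomial count
   matrices (variance = μ + φμ²) with planted DE features, latent-factor
   co-expression modules, and sponge triples in which a shared miRNA
   activity raises the miRNA and lowers its lncRNA/mRNA targets.
5. **I/O and CLI** (`cernet.io`, `cernet.pipeline`, `cernet.cli`) — TSV
   tables, SIF/GraphML/TSV network export (Cytoscape-compatible), YAML
   pipeline configs, and a subcommand CLI.

## CLI

```sh
# write a synthetic fixture (counts, sample sheet, target table, truth)
cernet simulate --out fixture/ --seed 1 --n-cerna-triples 5 \
    --decoy-target-fraction 0.1

# differential expression on one class
cernet de --counts fixture/mrna_counts.tsv --samples fixture/samples.tsv \
    --out de_mrna.tsv --fc-up 1.2 --fc-down 0.83 --alpha 0.05

# co-expression network, modules, hub sub-network
cernet coexpress --lnc-counts fixture/lncrna_counts.tsv \
    --mrna-counts fixture/mrna_counts.tsv --out-dir coexp/ --beta auto

# ceRNA network from counts + target table
cernet cerna --lnc-counts fixture/lncrna_counts.tsv \
    --mrna-counts fixture/mrna_counts.tsv \
    --mirna-counts fixture/mirna_counts.tsv \
    --samples fixture/samples.tsv --targets fixture/targets.tsv \
    --out-dir cerna_out/

# or run everything from a YAML config
cernet run --config config.yaml --seed 1 --out run_out/
```

Input formats: counts are TSV with a `feature` column plus one column per
sample; the sample sheet is TSV with `sample` and `group`
(control/condition); the target table is TSV with `mirna`, `target`,
`target_class` (mRNA/lncRNA) and `mre_count`.

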