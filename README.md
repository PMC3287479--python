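# pleiomine

A toolkit for finding candidate pleiotropic loci through multivariate-phenotype
GWAS. The pipeline has two stages:

1. **Pattern mining** — an individual-by-trait table is discretized into
   quintile-coded items (`TG5` = highest fifth of TG, `LDL1` = lowest fifth of
   LDL), frequent itemsets are mined with APRIORI, association rules are
   generated with support/confidence/lift, filtered by rule-form constraints,
   and summarized as an undirected weighted trait-association graph.
2. **Association and pruning** — a composite case/control phenotype (e.g. case:
   LDL ≥ 130 **and** TG ≥ 180; control: LDL ≤ 100 **and** TG ≤ 100) is scanned
   with the 1-df allelic chi-square test, alongside the two single-trait
   designs. SNPs are then pruned with three filters: a composite-p threshold,
   the mOR statistic (`log10(p_single) − log10(p_multi) ≥ 1` against **both**
   single traits, i.e. the composite signal must be ≥10× stronger), and
   PLINK-style greedy LD clumping. Survivors are candidate pleiotropic loci.

A full synthetic-data module (`pleiomine.sim`) generates trait tables,
genotypes (Hardy–Weinberg draws with founder-copied LD blocks), and
transaction databases with planted structure, so the entire pipeline is
testable without external cohort data.

## CLI

All subcommands take one YAML config (see `tests/test_cli.py` for a complete
example):

```bash
pleiomine simulate config.yaml            # synthetic traits + .ped/.map + truth labels
pleiomine mine config.yaml                # transactions, rules.csv, trait graph
pleiomine gwas config.yaml                # three scans, mOR table, clumps, pruned.tsv
pleiomine replicate config.yaml --stratum AREA   # per-stratum re-tests of survivors
```

Key config sections: `traits` (missing marker, covariate/drop lists),
`mining` (`min_sup`, `min_conf`, `max_len`, `n_levels`), `constraints`
(rule-form filters: item, side, metric thresholds), `phenotype`
(case/control predicate conjunctions), `pruning` (`p_multi_max`, `mor_min`,
clump spec). Outputs carry a config-hash header; reruns with the same config
are byte-identical.

## File formats

Plain text throughout: trait tables as TSV (`NA` missing), genotypes as PLINK
text `.ped`/`.map`, transactions one-per-line, rules as CSV, graphs as GraphML
or TSV edge lists, scan results as PLINK-style TSV
(`CHR SNP BP A1 F_A F_U A2 CHISQ P OR`), phenotypes as `FID IID PHENO`
(2=case, 1=control, −9=excluded).

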