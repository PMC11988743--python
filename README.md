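# editlens

RNA editing analysis from RNA-seq variant candidates: editing-site
discovery by a two-stage filter cascade, editing-type / region /
consequence annotation, gene-level differential editing and differential
expression with a negative-binomial Wald test, nine-quadrant
editing-by-expression integration, enzyme-expression vs editing-level
correlation, and hypergeometric pathway enrichment.  A fully seeded
synthetic-study generator provides reference, gene models, VCF
candidates, expression counts, pathway tables and ground-truth tables so
every stage is testable without external data.

## Pipeline overview

1. **discover** — variant candidates (VCF with QD/FS/MQRankSum/
   ReadPosRankSum/MQ/SOR INFO keys and AD/DP per sample) pass GATK-style
   hard filters (QD ≥ 2, FS ≤ 60, MQRankSum ≥ −12.5, ReadPosRankSum ≥ −8,
   MQ ≥ 40, SOR ≤ 3, cohort-relative mean-depth window [mean/3, 3·mean]),
   then editing filters (base quality ≥ 25, biallelic, optional known-SNP
   exclusion; a per-sample measurement is valid at depth ≥ 5, alt depth
   ≥ 3 and frequency in [0.10, 1.00]).
2. **annotate** — strand-collapsed mismatch class (A-to-I = A>G / T>C,
   C-to-U = C>T / G>A), genomic region with fixed precedence, and coding
   consequence (synonymous / nonsynonymous / stopgain / stoploss).
3. **diff-edit / diff-expr** — per-gene editing-supporting read counts
   (sum of alt depths over the gene's sites) and expression counts tested
   with median-of-ratios normalization, moderated method-of-moments NB
   dispersion, and a two-sided Wald test with Benjamini–Hochberg
   adjustment.  Differential editing uses padj < 0.05; differential
   expression additionally requires |log2FC| ≥ 1.
4. **summarize** — TPM, sample–sample correlation on log2(TPM+1), PCA of
   editing frequencies, per-group frequency histograms, shared-event Venn
   counts.
5. **integrate** — nine-quadrant classification (editing × expression
   state), up/up candidates, and Pearson correlation between an enzyme
   gene's TPM and each candidate's mean editing frequency ("MAF").
6. **enrich** — upper-tail hypergeometric over-representation with BH
   FDR ≤ 0.05.

## CLI

```bash
editlens simulate --out study/ --seed 42 --n-genes 300
editlens discover --vcf study/candidates.vcf --design study/design.tsv \
    --known-snps snps.tsv --out sites.tsv
editlens annotate --sites sites.tsv --fasta study/reference.fa \
    --gff study/genes.gff3 --out annotated.tsv
editlens diff-edit --counts gene_editing_counts.tsv --design study/design.tsv --out de.tsv
editlens diff-expr --counts study/expression_counts.tsv --design study/design.tsv --out dx.tsv
editlens integrate --edit de.tsv --expr dx.tsv --out quadrants.tsv
editlens enrich --candidates cand.tsv --pathways study/pathways.tsv --out enr.tsv
editlens run-all --config pipeline.yaml
```

`run-all` reads a YAML file whose keys mirror `PipelineConfig`
(`vcf`, `fasta`, `gff`, `counts`, `lengths`, `pathways`, `design`,
`known_snps`, `out_dir`, thresholds, `enzyme_gene`, `seed`) and writes all
stage TSVs plus a JSON manifest with input checksums and per-stage counts;
reruns are byte-identical.

## Layout

- `src/editlens/simulate.py` — synthetic study generator (+ truth tables)
- `src/editlens/discovery.py` — filter cascade and editing frequencies
- `src/editlens/annotation.py` — type / region / consequence annotation
- `src/editlens/differential.py` — NB Wald engine, BH, gene aggregation
- `src/editlens/metrics.py` — TPM, correlation, PCA, Venn, histograms
- `src/editlens/integrate.py` — nine-quadrant + enzyme correlation
- `src/editlens/enrich.py` — hypergeometric enrichment
- `src/editlens/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O
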