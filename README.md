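# droughtmem

Tools for analysing **transcriptional drought memory**: how a plant's
response to a repeated dehydration differs from its response to the first
one. The package targets the standard recurring-drought design — a watered
control (R0), a first dehydration (S1) and a third dehydration (S3),
sampled with replicated bulk RNA-seq in two ecotypes (here AEX, of
semi-arid origin, and WW, of arid origin) — and is written for plant
stress-biology groups who have gene-level count matrices and want the full
chain from water-status physiology to regulator-switch inference.

## What it computes

**Trajectory categories.** With calls from two contrasts (S1 vs R0 and
S3 vs S1; a gene is called at BH-adjusted *p* < 0.05 and |log2FC| ≥ 1), each
gene gets one of nine categories. Drought-*memory* genes change again at
the repeated stress — [+/+], [−/−], [+/−], [−/+]; *non-memory* genes respond
once and hold — [+/=], [−/=]; *late-response* genes move only at S3 —
[=/+], [=/−]. The summary reproduces the field's tabulation with its exact
percentage bases (memory % of DEGs, subtype % of memory genes,
late-response % of all genes).

**Differential expression.** An internal negative-binomial caller:
median-of-ratios size factors, method-of-moments gene dispersion pooled
across treatment groups and moderated toward the median dispersion, and a
Wald-type statistic on log2 group means referred to a moderated-t
distribution. DESeq2-style contrast tables can be dropped in instead.

**TF molecular switches.** Memory genes are split into regulators (TFs/TRs)
and functional genes; Pearson co-expression across an ecotype's
replicate-level log2(FPKM+1) profiles is thresholded at |r| > 0.9 and
p < 0.05; functional genes sharing one signed TF signature that contains
both a positively and a negatively correlated regulator form a *switch
module* — a TF pair (or group) plausibly toggling the same gene set between
high and low expression across recurring drought.

**Cross-species hierarchy.** Orthogroups containing memory genes are
partitioned into a three-party Venn (ecotype A, ecotype B, all other
species pooled): shared, species-specific (both ecotypes), and
ecotype-unique tiers.

**Plus:** hypergeometric term enrichment with BH correction; interaction-
network hub ranking by degree and maximal clique centrality
(MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!); leaf water-status indices
RWC = (FW−DW)/(TW−DW)·100 and water loss = (FW−wilted)/DW with ANOVA/t-test
group comparisons; the 2^−ΔΔCt q-PCR utility; and a seeded synthetic-data
generator that plants known trajectory categories and switch modules so the
whole pipeline is testable without sequencing data.

## Worked example

Simulate a dataset with planted structure, call both contrasts, classify,
and tabulate:

```python
from droughtmem.simulate import SimulationConfig, simulate
from droughtmem.de import nb_test
from droughtmem.classify import classify_all, summarize

cfg = SimulationConfig(n_genes=2000, n_replicates=3, seed=7)
ds = simulate(cfg)
c1 = nb_test(ds.counts, "R0", "S1", ecotype="AEX")
c3 = nb_test(ds.counts, "S1", "S3", ecotype="AEX")
records = classify_all(c1, c3, "AEX")
print(summarize(records, total_genes=2000).to_dict())
```

prints (abridged):

```
deg: 381            deg_pct: 19.1
memory: 219         memory_pct: 57.5
non_memory: 162     non_memory_pct: 42.5
late: 82            late_pct: 4.1
by_category: {'[+/+]': 39, '[-/-]': 33, '[+/-]': 74, '[-/+]': 73, ...}
```

381 of 2,000 genes (19.1%) respond to the first drought; 219 of those DEGs
(57.5%) change again at the third drought and are memory genes; 82 genes
(4.1% of all genes) move only at S3. Comparing `records` against
`ds.truth_categories` shows 94.2% of the planted non-background labels are
recovered. The same flow continues into switch detection
(`droughtmem.switch`) and recovers the planted TF modules with their member
sets and regulator signs.

The command line mirrors the library one stage per subcommand:

```sh
droughtmem simulate --seed 7 --out sim/
droughtmem de --counts sim/counts.tsv --design sim/design.tsv \
    --ecotype AEX --baseline R0 --comparison S1 --out c1.tsv
droughtmem classify --s1 c1.tsv --s3 c3.tsv --total-genes 2000 --out records.tsv
droughtmem run-all --config pipeline.yaml     # everything from one YAML
```

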