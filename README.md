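# varburden

Integrative rare-variant burden meta-analysis toolkit. It combines two
independent evidence streams per gene — case/control burden of rare CNV
deletions and de novo variant (DNV) recurrence in trios — into a single
ranked candidate list, with downstream expression-stage and
protein-interaction-network enrichment analyses. Every input can be
generated synthetically with planted signal, so the full pipeline is
exercisable and testable offline.

## Pipeline stages

1. **CNV QC** (`varburden.qc`) — size gates (5 kb – 20 Mb), autosome-only,
   telomere/centromere/segmental-duplication mask coverage (> 50% removed),
   probe support (≥ 10), and internal frequency from reciprocal-overlap
   (> 50%) carrier counting in controls (MAF < 0.01 kept), with exact
   first-failure bookkeeping.
2. **CNV association** (`varburden.assoc`) — gene-wise (and region-wise)
   label-permutation tests of case-carrier excess: pointwise empirical
   p-values (emp1) and min-p family-wise adjusted values (emp2); locus
   merging via shared supporting case deletions; gene-set logistic burden
   regression with mean CNV size, segment count and study-ID covariates.
3. **DNV testing** (`varburden.dnv`) — consequence classification
   (PTV/missense/silent), population-MAF filtering, cohort rate
   comparison (exact two-rate Poisson), gene-wise Poisson recurrence test
   against per-gene mutation rates (expected count 2·N·μ, two nested
   classes), optional severity-weighted Monte-Carlo test and external
   per-gene p-values; the reported p per gene is the minimum component.
4. **Integration** (`varburden.integrate`) — Fisher combination
   (chi-square, 4 df) of the CNV and DNV p-values, Benjamini–Hochberg
   q-values, and a covariate-weighted Bonferroni correction that learns
   per-bin weights from a constraint covariate (LOEUF) by cross-validated
   grid search under the exact budget Σ m_b·w_b = m.
5. **Expression** (`varburden.expression`) — developmental-stage means and
   percentile ranks (early development 4–8 wpc, maturation 9–20 wpc,
   infant/adult), organ-contrast time-course differential expression
   (polynomial fit on log2(CPM+1), F-test of organ terms, DEG ⇔ R² > 0.5
   and Bonferroni p < 0.01), and binned rank-sum distribution contrasts.
6. **Network** (`varburden.network`) — strictly seed-restricted PPI graph,
   overlapping sub-clusters by k-clique percolation with
   degree-preserving-rewiring permutation significance (≥ 5 members,
   p < 0.05), per-cluster case/control CNV rank-sum contrast, and
   hypergeometric gene-set over-representation with |ln p|·z combined
   scores.
7. **Synthetic data** (`varburden.simulate`) — seeded generators for every
   input (annotation, masks, probes, CNV cohort with planted risk genes
   and explicit QC violators, trio DNVs, three-organ expression time
   course, PPI edge lists) emitting the exact TSV/BED/GMT dialects the
   loaders consume.

## CLI

```bash
# generate a seeded synthetic fixture + ready-to-run config
varburden simulate --seed 12 --out fixture/

# run everything (QC -> CNV tests -> DNV tests -> integration ->
# expression -> network); writes TSVs and a reproducibility manifest
varburden run-all --config fixture/pipeline_config.json

# individual stages
varburden cnv-qc   --cnv cnv.tsv --probes probes.tsv --segdups segdups.bed \
                   --n-controls 400 --out passed.tsv --report qc_report.tsv
varburden cnv-test --cnv passed.tsv --genes genes.tsv --samples samples.tsv \
                   --n-perm 10000 --seed 1 --out cnv_tests.tsv
varburden dnv-test --dnv dnv.tsv --rates rates.tsv --n-trios 2500 --out dnv_tests.tsv
varburden integrate --cnv-results cnv_tests.tsv --dnv-results dnv_tests.tsv \
                    --genes genes.tsv --out gene_results.tsv
```

`run-all` emits `gene_results.tsv` (gene, case/control carrier counts,
P_cnv, nsDNV, P_dnv, significance label, metaP, BH q, weighted-Bonferroni
p, LOEUF), `loci.tsv`, `burden.tsv`, `clusters.tsv`, `qc_report.tsv` and
`manifest.json` (config hash, seed, versions, timings); reruns with the
same config and seed are bit-identical.

## Layout

```
src/varburden/
  core.py        domain types + interval arithmetic
  io.py          TSV/BED/GMT readers and writers
  qc.py          CNV QC gates and internal-frequency filtering
  assoc.py       permutation association, loci, logistic burden
  dnv.py         DNV classification and recurrence testing
  integrate.py   Fisher combine, BH, covariate-weighted Bonferroni
  expression.py  stage summaries and time-course DE
  network.py     seed networks, sub-clusters, over-representation
  simulate.py    seeded synthetic data generators
  pipeline.py    orchestration + manifest
  cli.py         click-based CLI
```
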