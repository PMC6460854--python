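# refgene

Transcriptome-wide identification of candidate reference genes from RNA-Seq
expression matrices, plus RT-qPCR stability validation — packaged as a
tested Python library and CLI with a synthetic-data generator, so the whole
pipeline runs without any external downloads.

## What it does

- **ingest** — FASTQ quality filtering (drop reads with any `N` or more
  than 10 positions below Q20), raw-count → TPM conversion, linear-scale
  replicate averaging, and TSV I/O for expression and Ct matrices.
- **screen** — a four-criterion cascade on log2(TPM) over conditions:
  (I) expressed everywhere, (II) SD < 1, (III) no condition deviating from
  the gene mean by ≥ 2, (IV) mean > 5. Candidates are ranked by
  CV = sd/mean of log2(TPM); the II/IV thresholds imply CV < 0.2
  analytically. Includes Venn/core-set arithmetic across datasets.
- **stability** — geNorm M values with stepwise exclusion ranking and the
  V(n/n+1) pairwise-variation series; a model-based (NormFinder-style)
  stability with grouped and ungrouped modes; the comparative delta-Ct
  method; and a comprehensive ranking by geometric mean of the three
  per-method ranks. Also: amplification efficiency from two-fold dilution
  standard curves (E = 2^(−1/slope) − 1).
- **correlate** — OLS calibration Ct = slope·log2(TPM) + intercept with
  Pearson r / R² / p-value, and Ct prediction from expression level.
- **enrichment** — hypergeometric over-representation of a gene set against
  term annotations with Benjamini–Hochberg FDR.
- **simulate** — seeded generators for expression matrices with planted
  stable/variable/stage-specific/silent genes, Ct matrices coupled linearly
  to log2(TPM), and truth-labeled FASTQ files.

## CLI

```sh
refgene simulate expression --preset tissues --seed 1 -o sim/
refgene screen sim/expression.tsv -o screen.tsv --cascade cascade.json --top top10.tsv
refgene core-set early.txt tissues.txt gonad.txt -o venn.json
refgene filter-reads reads.fastq -o kept.fastq --log filter.json
refgene tpm counts.tsv lengths.tsv --average samples.tsv -o tpm.tsv
refgene stability ct.tsv --groups groups.tsv --efficiencies eff.tsv \
    -o stability.tsv --pairwise-variation pv.json
refgene calibrate pairs.tsv --exclude ACT,CYTC -o fit.json
refgene enrich query.txt annotations.tsv -o enrichment.tsv
```

All matrix inputs are plain TSV (first column = gene id, header row =
sample/condition labels). Maps (sample→condition, gene→term, gene→efficiency)
are two-column TSV.

## API sketch

```python
from refgene import (
    ExpressionSimSpec, gen_expression, screen_dataset, rank_by_cv,
    CtSimSpec, gen_ct, stability_report, fit_ct_tpm,
)

sim = gen_expression(ExpressionSimSpec(seed=1))
result = screen_dataset(sim.matrix)
top10 = rank_by_cv(result, top_k=10)

ct = gen_ct(sim.matrix.subset(result.candidates[:8]), CtSimSpec(seed=2))
report = stability_report(ct)
print(report.ordered().head())
```
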