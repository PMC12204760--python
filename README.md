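# fracloc

Estimate the nucleo-cytosolic distribution of RNA transcripts from matched
whole-cell, nuclear, and cytosolic RNA-seq quantifications.

Relative abundance units (FPKM/CPM) cannot be compared between cellular
fractions because each fraction is sequenced to an arbitrary depth from an
unknown amount of RNA. `fracloc` resolves this with two quantities:

- **beta** — the fraction of the total cellular RNA volume (nucleotides
  across all molecules) residing in the cytosol, estimated by Bayesian
  robust regression of whole-cell FPKM on the nuclear/cytosolic FPKMs:
  `FPKM_w(i) = (1-beta) FPKM_n(i) + beta FPKM_c(i) + e(i)` with Student-t
  errors, priors `beta ~ Beta(2,2)`, `nu ~ Gamma(2, 0.1)`,
  `sigma ~ Exponential(1/sd(FPKM_w))`, sampled by a built-in No-U-Turn
  sampler. The point estimate is the boundary-reflected KDE mode of the
  pooled draws. A box-constrained least-squares baseline is included.
- **LI (localization index)** — the estimated proportion of each
  transcript's molecules in the cytosol:
  `LI(i) = beta FPKM_c(i) / ((1-beta) FPKM_n(i) + beta FPKM_c(i))`.
  The commonly used "naive" ratio `FPKM_c/(FPKM_n+FPKM_c)` equals LI only
  when beta = 0.5 and is biased otherwise.

The package also provides the preprocessing filters (CPM >= 1,
mitochondrial removal, replicate presence, whole-cell-outside-range outlier
filter, beta > 0.95 sample exclusion), a fractionated-transcriptome
simulator with exactly calibrated ground-truth beta, localization
classification and cross-sample consistency summaries, transcript feature
computation from GTF/FASTA, and hypergeometric enrichment tests for
localization-specific exons/introns.

## CLI

```sh
# simulate a matched dataset with known beta
fracloc simulate --n-transcripts 5000 --molecules 100000 --beta 0.7 \
    --depth 1000000 --seed 1 --out sim/

# estimate beta (Bayesian; --method cls for the least-squares baseline)
fracloc estimate-beta --whole sim/whole_cell.quant.tsv \
    --nuclear sim/nuclear.quant.tsv --cytosolic sim/cytosolic.quant.tsv \
    --chains 4 --draws 6000 --warmup 2000 --seed 1 --out beta.json

# per-transcript localization index and classification
fracloc li --quant-set set.tsv --beta 0.72 --scheme threshold_04_06 --out li.tsv

# cross-sample consistency, enrichment, full pipeline from a TOML config
fracloc consistency --li-table K562 li_k562.tsv --li-table HepG2 li_hepg2.tsv --out cons.tsv
fracloc enrich --scores ir.tsv --score-column ir_ratio --hit-rule gt --specific-ids nuc.txt
fracloc run --config pipeline.toml --out out/
```

Input quantification tables are RSEM `isoforms.results`-style TSVs
(`transcript_id`, `effective_length`, `expected_count` required). Exit
codes: 0 success, 2 input/format error, 3 model/diagnostic failure.

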