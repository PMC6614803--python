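# pixulchip

Analysis toolkit for microplate chromatin-shearing / ChIP workflows:

- **gel** — quantitative agarose-gel smear analysis: lane detection, DNA-ladder
  calibration (semi-log migration), normalized best-fit smear curves, mean
  fragment size and the fraction of signal in a size window (default
  200–600 bp), and waterfall summaries across lanes.
- **sim** — a synthetic gel-image simulator (log-normal fragment-size
  mixtures, semi-log migration physics, Gaussian point spread, background
  gradient, camera noise) with exact quadrature ground truth, so every gel
  operation is testable without any real photograph.
- **qpcr** — ChIP-qPCR quantification: per-primer standard curves
  (Ct vs log10 concentration), amplification efficiency, Ct→quantity
  conversion from averaged replicates, fraction of input, and pairwise
  significance encoded as circle marks (small: p < 0.05, large: p < 0.01).
- **peaks** — broadPeak utilities: per-mark quality filtering (strict
  q-value / fold-enrichment thresholds), ≥1 bp interval-overlap concordance
  between two peak sets, TSS-window mark assignment and expression
  stratification of genes with/without a mark.

## CLI

One umbrella command (`pixulchip`; `gelquant` is an alias) with four
subcommands. Every tabular output carries a timestamp-free metadata header
(version, config hash, seed), so identical configurations reproduce
identical bytes.

```bash
# quantify a gel photograph (ladder in lane 1 of 13)
gelquant analyze --image gel.png --orientation wells_top --lanes 13 \
    --ladder-lane 1 --ladder 1500,1000,700,500,400,300,200,100 \
    --range 200:600 --out results.tsv --waterfall waterfall.png

# render a synthetic gel with known truth
gelquant simulate --config sim.json --out gel.png --truth truth.json

# standard curves + fraction of input for a plate
pixulchip qpcr --standards std.csv --plate plate.csv --out foi.tsv

# peak filtering / overlap / expression strata
pixulchip peaks filter --in x.broadPeak --mark H3K4m1 --out y.broadPeak
pixulchip peaks overlap --a a.broadPeak --b b.broadPeak
pixulchip peaks tss-strata --peaks y.broadPeak --tss tss.bed \
    --expr fpkm.tsv --window 2000 --out strata.tsv

# seeded fixture suite (gel + qPCR plate + peak files + manifest)
pixulchip make-fixtures --out-dir fixtures/ --seed 0
```

Input formats: 8/16-bit grayscale or RGB TIFF/PNG/JPEG gel images; ladder as
a comma-separated bp list or JSON `{name, sizes_bp}`; qPCR tables as CSV/TSV
(`primer_pair,concentration,ct` and
`sample_id,target,antibody,is_input,input_dilution,ct_1..ct_k`);
broadPeak (BED6+3), BED6 TSS annotations, and `gene_id`/`fpkm` TSV.

## Conventions

- Gel images are canonicalized to wells-top (row index = migration
  distance); orientation must be declared, never guessed.
- Migration model: `row = a − b·log10(bp)`, least-squares by default, with a
  monotone piecewise-linear alternative; extrapolation beyond the outer
  ladder bands is limited to half the end gaps.
- Re-indexing intensity from rows to bp applies **no** d(row)/d(bp) density
  correction by default (`--jacobian` opts in); simulator ground truth uses
  the same convention.
- Genomic intervals are 0-based half-open; overlap means sharing ≥ 1 bp;
  filter thresholds are strict inequalities.

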