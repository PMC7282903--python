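# exsitu

Accounting and optimization of wild allelic diversity held in *ex situ*
plant collections, built around diploid multilocus (microsatellite-style)
genotype data.

The package answers two questions for a taxon with genotyped wild
(*in situ*) and collection (*ex situ*) individuals:

1. **How much wild diversity is conserved now?**  Every distinct wild
   allele is tabulated, binned into frequency categories (all, very
   common >0.10, common >0.05, low frequency 0.01–0.10, rare <0.01), and
   the percentage carried at least once by the collection is reported —
   for the full dataset and for a "reduced" dataset that excludes
   alleles present in only one or two wild copies.
2. **How much could be conserved?**  Monte-Carlo resampling of the wild
   individuals over every subsample size 2..N estimates the capture
   curve per category, the minimum sample size whose mean capture
   exceeds a target (70% / 95% by default), and the *genetic
   conservation gap*: the fraction of the current collection size that
   random sampling would need for the same capture, and the capture
   gain possible at the current size.  An exact hypergeometric oracle
   independently verifies the Monte-Carlo engine.

Supporting modules provide pairwise Weir–Cockerham FST, allele-spectrum
summaries, log-size regression, one-way ANOVA with Benjamini–Hochberg
correction, and a Balding–Nichols synthetic-data generator with a
controllable rare-allele tail, so the whole pipeline is testable without
any empirical dataset.

## Layout

| module | contents |
| --- | --- |
| `exsitu.genotype_io` | CSV-dialect and GenePop readers/writers, `GenotypeMatrix` |
| `exsitu.allele_accounting` | allele tables, frequency categories, min-copy filter, capture percentages |
| `exsitu.resampling_engine` | capture curves, hypergeometric oracle, minimum sufficient size |
| `exsitu.gap_metrics` | conservation-gap ratios, attrition adjustment, copies↔frequency |
| `exsitu.explanatory_stats` | pairwise FST, spectrum summaries, log fit, ANOVA, BH correction |
| `exsitu.synthetic_data` | structured population generator, rare-tail shaping, collection simulators |
| `exsitu.cli_reports` | config, pipeline driver, table exports, `exsitu` CLI |

## CLI

Run the full pipeline on a synthetic taxon (no input files needed):

```sh
exsitu run --synthetic --replicates 2000 --seed 1 --out out/
```

or on your own files (CSV dialect `id,population,source,<locus>...` with
`a/b` allele cells and `-9/-9` missing, or GenePop):

```sh
exsitu run --name mytaxon --in-situ wild.csv --ex-situ garden.csv \
    --replicates 75000 --seed 1 --targets 70,95 --variants full,reduced \
    --out out/
```

A YAML config (`--config`) supports multiple taxa; flags override config
values.  Outputs per taxon: `curves.csv` (capture curve per category and
variant), `sufficiency.csv`, `summary.json` (capture, gap, FST,
spectrum), plus run-level `capture_table.{csv,json}`,
`gap_table.{csv,json}` and `manifest.json` recording the seed and
replicate count that reproduce every number.  `exsitu synth` writes
synthetic genotype fixtures.

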