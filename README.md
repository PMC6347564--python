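# genediv

Mutation-rate-normalized gene diversity from single diploid genomes,
with bootstrap confidence intervals and diversity-tail GO enrichment.

## The problem

How diverse are an individual's protein-coding genes — and are immune
genes more or less diverse than the rest of the genome?  With only a
handful of high-coverage ancient genomes (archaic humans such as
Neandertals and Denisovans), population-level estimators are
unavailable; diversity must be measured *within* one diploid genome.
Raw heterozygosity is confounded by mutation-rate variation along the
genome, so this package measures, per gene:

    SNP/FD  =  (# biallelic heterozygous sites) / (# fixed differences to an outgroup)

where a fixed difference (FD) is a site homozygous for an allele that
differs from the chimpanzee allele — a local mutation-rate proxy.
Gene sets are summarised by the pooled ratio Σsnp/Σfd, and a test set
(e.g. innate-immune genes, MHC genes) is *normalized* by the pooled
ratio of a non-immune background set:

    normalized gene diversity  =  (Σsnp/Σfd)_test / (Σsnp/Σfd)_background

reported as a fold change and on the log2 scale (0 = as diverse as
expected from the genome-wide baseline).  Confidence intervals come
from a gene-resampling percentile bootstrap (B = 5,000).  Sites enter
the counts only when callable: mapping quality > 25, depth > 10 and
within a GC-corrected 2.5%–97.5% coverage band, inside a uniqueness
mask, outside repeats; genes with < 2,000 callable sites are dropped.
Runs of homozygosity can be excluded to analyse inbred genomes.  A
tail analysis tests GO categories for overrepresentation among the
top/bottom 5% most/least diverse genes (exact hypergeometric test with
Bonferroni correction).

The package ships a synthetic-genome generator that emulates the
statistical structure of this kind of data (archaic-scale
heterozygosity ~1.6–1.8e-5, ~272 FDs per gene, an MHC-like set with
strongly elevated diversity, ROH tracts, GC-dependent coverage), so
every stage runs and is calibrated without any external download.

Audience: population geneticists and methods developers who want a
tested, reusable implementation of single-genome diversity estimation
— or a simulation sandbox for it.

## Worked example

```python
import genediv as gd

spec = gd.presets(seed=1)["archaic"]          # archaic-human preset: mu=1.6e-5, MHC-like x47
ds = gd.simulate_genome(spec, individual_ids=["altai", "vindija", "denisovan"])
res = ds.model("vindija").fit(B=5000, seed=1)
print(res.summary())
```

prints

```
Gene diversity (SNP/FD) results
==============================================
individual:        vindija
callable sites:    11,890,517
genes passing:     614 / 614
heterozygosity:    3.103e-05 per callable site
bootstrap:         B=5000, seed=1

             n_genes  sum_snp  sum_fd  mean_ratio  normalized  log2_normalized  ci_lower  ci_upper
set
background       500      165  115269    0.001431         NaN              NaN       NaN       NaN
innate_like      100       22   21989    0.001001      0.6989          -0.5167    0.3921     1.064
mhc_like          14      174    2886     0.06029       42.12            5.396     29.84     55.51
```

Reading it: over 11.9 Mb of callable gene territory this simulated
archaic genome has a background pooled SNP/FD of 0.0014 — low
diversity, as expected at heterozygosity 1.6e-5 against divergence
1.2e-2 (the genome-wide heterozygosity line mixes in the elevated
MHC-like territory).  The innate-like set is statistically
indistinguishable from background (normalized 0.70, 95% CI [0.39,
1.06] spans 1).  The MHC-like set is ~42-fold more diverse than
background (CI [30, 56]), recovering the generating 47× multiplier
within resampling noise.

The same analysis runs from files (`read_genotype_calls`, `read_genes`,
`read_mask`, `read_outgroup`, …) or end-to-end from a YAML config:

```bash
genediv simulate --preset archaic --seed 1 --out data/
genediv run-all config.yaml        # callable -> diversity -> bootstrap -> enrichment
genediv validate config.yaml       # fills defaults, rejects unknown keys
```

See `docs/methods.md` for the model, filtering scheme, bootstrap and
generator details.

## Acceptance script

`scripts/acceptance.py` regenerates synthetic data from the documented
presets and recomputes, from scratch, the pipeline's headline recovery
statistics: the mean normalized MHC-like diversity across three
archaic-preset individuals, the same for the present-day preset, and
the centre of the null-calibration experiment for the innate-like set
(200 generation replicates, each with a B=5,000 bootstrap CI).

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Progress goes to stderr; the JSON maps each statistic to its recomputed
value and problem size.  Runtime is dominated by the 200-replicate null
experiment (~10 minutes on one CPU).
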