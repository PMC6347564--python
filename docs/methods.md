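# Methods

## The statistic

Within one diploid genome, diversity at a locus can be read off the
genotype directly: a **SNP** is a biallelic heterozygous site; a
**fixed difference (FD)** is a site homozygous for an allele that
differs from the outgroup (chimpanzee) allele at the aligned position.
FD density is a proxy for the local mutation rate times divergence
time, so the ratio

    SNP/FD  =  (heterozygous sites) / (homozygous derived sites)

normalizes heterozygosity for mutation-rate heterogeneity along the
genome.  Computed per gene (gene body plus 1 kb of flanking sequence,
capturing adjacent regulatory elements) it is the package's *gene
diversity* measure.

Gene sets are summarised by the **pooled** ratio Σsnp/Σfd — summing
counts over member genes before dividing — which weights genes by their
divergence opportunity and is stable when individual genes have few
FDs.  A test set (innate-immune-like, MHC-like) is **normalized** by
dividing its pooled ratio by that of a background set of non-immune
genes at least 500 bp long; the result is reported as a fold change and
on the log2 scale, where 0 means "as diverse as expected given the
genome-wide baseline".

### Site classification rules

Exactly one class per site: non-SNV records and sites with more than
two observed alleles are `EXCLUDED` ("biallelic" is read strictly);
sites without a defined outgroup allele are `NO_OUTGROUP`; remaining
heterozygous sites are `SNP`; homozygous sites are `FD` or `MATCH`
against the outgroup allele.  Both SNP and FD counting are restricted
to callable sites with a defined outgroup allele, so numerator and
denominator share one opportunity set (`require_outgroup=False` relaxes
this for SNPs).  A heterozygote whose two alleles both differ from the
outgroup is a SNP, never an FD — the FD definition requires
homozygosity.

## Callable-site filtering

A site is callable iff all of the following hold (defaults in
parentheses; every threshold is configurable):

* mapping quality strictly greater than `mq_min` (25);
* depth strictly greater than `min_depth` (10);
* depth within the GC-corrected coverage band: per-GC-bin empirical
  2.5%/97.5% depth quantiles (inclusive), with GC measured in a
  centred 201 bp window, binned at 0.05 width; bins with fewer than
  100 sites inherit the genome-wide band;
* inside every keep-mask (e.g. 35-mer uniqueness) and outside every
  remove-mask (e.g. tandem repeats).

The band is estimated on sites that already pass the mapping-quality
cut and the masks, so repeat-driven pileups do not distort the
quantiles.  Quantiles are type-7 (linear interpolation), computed
exactly from depth histograms.  Genes with fewer than 2,000 callable
sites are excluded (a gene with exactly 2,000 is retained); callable
sites per gene are counted after mask intersection and before the
outgroup requirement.

Runs of homozygosity (ROH) can be subtracted from the callable mask to
analyse an inbred genome without its homozygous tracts (the "Altai*"
style analysis); heterozygosity strictly rises after exclusion because
ROH contribute callable sites but no heterozygotes.

## Bootstrap

Uncertainty in set-level quantities comes from gene composition, so the
resampling unit is the gene: each of B = 5,000 replicates draws N genes
with replacement (N = set size), re-pools Σsnp/Σfd, and the CI is the
percentile interval at the 2.5%/97.5% quantiles (plain percentile
bootstrap; no BCa).  For normalized diversity, test and background sets
are resampled independently within each replicate; the log2-scale CI is
the log2 of the ratio CI endpoints.  For across-individual means
(e.g. "archaic humans" as a group), each replicate resamples the sets
within every individual and averages the normalized ratios.  Replicates
with a zero FD sum are dropped and counted (vanishingly rare at
realistic FD counts).  Quantiles are type-7; identical seed and inputs
give bit-identical intervals.

## Tail enrichment

Genes are ranked by the SNP/FD ratio averaged over a chosen trio of
individuals; only genes that pass the callable filter and have fd > 0
in *every* individual are eligible.  The top and bottom
floor(0.05 × n) genes (ties broken by lexicographic gene id) are each
tested for GO-category overrepresentation against the eligible genes
outside both tails, with the exact hypergeometric upper-tail
probability and Bonferroni correction (FWER = min(1, p·k)).  k defaults
to the number of categories tested and can be overridden (e.g. the
fixed k = 17 used in published tables of this kind).  Annotations are
used as given — no GO-graph (true-path) propagation; pre-propagate if
needed.  This replaces randomization-based FWER machinery with a fully
specified exact test; the substitution is recorded in the output
metadata.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
so the whole pipeline can be exercised and calibrated without any
download.  Per territory site (the union of flanked gene bodies), with
probability m·μ the site is a biallelic heterozygous SNV (m = the
covering gene's diversity multiplier), else with probability d it is
homozygous derived, else it matches the outgroup.  The outgroup allele
is the reference base, shared across individuals; its missingness is
blockwise (as alignment gaps are).  Depth is a rounded Gaussian with a
GC-dependent mean and overdispersed variance; mapping quality is
Gaussian.  Uniqueness-mask gaps and repeat intervals are blocky random
tracks.  Rare multiallelic (1e-6) and non-SNV (2e-5) records exercise
the exclusion rules.

Defaults are the stated world of the study the package models:

| preset       | μ (het/site) | MHC-like ×m | innate ×m | notes                        |
|--------------|--------------|-------------|-----------|------------------------------|
| vindija      | 1.6e-5       | 1           | 1         | genome-wide het anchor       |
| denisovan    | 1.8e-5       | 1           | 1         | genome-wide het anchor       |
| altai_roh    | 1.6e-5       | 1           | 1         | +15% of the genome in ROH    |
| archaic      | 1.6e-5       | 47          | 1         | archaic MHC fold anchor      |
| african      | 1.9e-3       | 7           | 1         | pooled SNP/FD = 0.158        |
| non_african  | 9.6e-4       | 7           | 1         | pooled SNP/FD = 0.080        |
| null_immune  | 1.9e-3       | 1           | 1         | all immune multipliers = 1   |

Shared structure: one 20 Mb chromosome, 500 background genes, a
14-gene MHC-like set, a 100-gene innate-like set (a scaled-down stand-in
for the ~1,548-gene curated innate list), lognormal gene core lengths
with mean 20 kb (≈22 kb bodies with 1 kb flanks), divergence
d = 1.2e-2 calibrated so an average gene carries ≈272 FDs.

Design choices worth knowing:

* The het/divergence anchors (vindija, denisovan, altai_roh) keep all
  set multipliers at 1: in a 20–50 Mb toy genome the MHC-like set is
  ~3% of gene territory, so a 47× multiplier would visibly inflate
  genome-wide heterozygosity — unlike the real genome, where the MHC is
  <0.2%.  The fold anchors live in the `archaic`/`african` presets.
* Per-gene multipliers within an elevated set are lognormal around the
  set multiplier (σ = 0.3), mean-centred so the set multiplier is the
  recoverable truth, and drawn per individual (the per-individual
  generative step), so averaging across individuals reduces dispersion
  the way averaging the three archaic genomes does.  Multiplier-1 sets
  get no dispersion, keeping null sets exactly null.
* The `null_immune` baseline is present-day-scale (μ = 1.9e-3) so the
  bootstrap-calibration check probes the resampling procedure rather
  than count discreteness (at archaic scale the innate set would carry
  ~35 SNPs total).
* African/non-African baselines are calibrated to put the innate-set
  pooled SNP/FD inside the published ranges (0.154–0.167 and
  0.042–0.105); they support ordering comparisons, not exact targets.
* Sites are independent: no linkage, no recombination, no aDNA damage
  model, no read-level simulation.  Counts and ratios — the statistics
  measured — are insensitive to LD, but any analysis of haplotype
  structure or of correlated noise between neighbouring genes is out of
  reach of a green test here.
* When the 50 Mb heterozygosity-recovery world is generated, the
  background gene count scales with genome length (1,400 genes) so
  gene density stays constant.
* `simulate_genome` returns in-memory arrays; `write_dataset` exports
  standard formats (single-sample VCF 4.2 with an all-sites layout,
  BED3 masks and ROH tracts, 1-based outgroup TSV, gene/set/GO TSVs,
  reference FASTA, YAML manifest).  The file path is validated against
  the in-memory path by round-trip tests; large replicated experiments
  run in memory because a 13M-line text VCF per replicate would
  dominate the runtime.

## Numerical conventions

* Coordinates are 0-based half-open everywhere internally; VCF and the
  outgroup TSV are converted at the IO boundary; BED is native.
* Interval tracks are kept sorted, merged and non-overlapping; set
  operations are boundary sweeps (exact, linear in interval count).
* Quantiles everywhere are type-7 (numpy default), documented because
  quantile conventions differ between tools.
* Undefined ratios (fd = 0) stay NaN per gene: such genes are excluded
  from per-gene rankings but still contribute counts to pooled sums.
* Tie-breaks in tail selection are lexicographic by gene id; tail size
  is floor(fraction × n) — both for determinism.
* One global seed derives per-stage streams through a keyed hash
  (stage name, individual id), so adding a stage or individual never
  shifts another stream; identical config + seed reproduces
  byte-identical report tables.

## Known limitations

* Strand is recorded but ignored (diversity is strand-symmetric).
* Overlapping genes are counted independently; a site may contribute to
  several genes (the generator avoids overlap, real annotations need
  not).
* The GC correction is the simplest faithful reading ("per-GC-bin
  quantile band"); window size, bin width and per-bin vs genome-wide
  quantiles are configurable because the original processing did not
  pin them down.
* No nonsynonymous/synonymous annotation, no liftover, no BAM/CRAM
  processing, no genotype calling: the pipeline starts at genotype
  calls.
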