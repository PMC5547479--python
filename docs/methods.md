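# Methods

## The model

The workflow assumes a divergent-family pooled design: for each trait,
families are ranked by their family-average phenotype and the top-ranked
4 families are contrasted with the bottom-ranked 4 (3–5 per group is
treated as typical; group sizes outside 1–10 trigger a warning).  Each
family contributes one pooled RNA library (equal masses from 5 fish), so
the read counts at a biallelic site estimate the pool's allele
frequencies.  Counts are summed over the families of a group — the group
frequency is the frequency of the summed counts, not the mean of family
frequencies, which keeps the 2×2 chi-square on exact allele counts
coherent with the score.

The allelic-imbalance score is the allele-frequency odds ratio between
the high and low groups.  It is classified with reciprocal thresholds
(≥ 2.0 amplification, ≤ 0.5 loss of heterozygosity, both inclusive; an
`inclusive=False` switch gives the strict variant).  Sites where an
allele is absent from exactly one group are *exclusive* to the other
group; their score is undefined and they are reported as their own
class.  Sites monomorphic within both groups are rejected.

Significance: Pearson chi-square without continuity correction on
(group × allele) counts, 1 df, raw p < 0.05.  No multiple-testing
correction is applied to the classification; a Benjamini–Hochberg
q-value column is emitted for the reader.  A zero marginal makes the
statistic undefined; such sites (typically the exclusive ones) are kept
and flagged rather than dropped, and when the ratio/exclusive criterion
fires they remain in the imbalanced set on that criterion alone.

Because parental genotypes are unknown in this design, allele phase and
parent-of-origin are out of scope; "allele A" is fixed to the alternate
allele, which (reciprocal thresholds) affects only the naming of the two
imbalance directions.

## Filters

Site quality gates use the GATK-conventional failing directions — QD
below 2.0, FS above 60.0, MQ below 40.0 — with values exactly at a
threshold passing and missing annotations passing with a warning.  Pool
gates are strict as printed: total reads > 10, minor-allele count > 4,
minor-allele frequency > 0.05, all computed on counts summed across all
families in the run (per-trait refiltering is off by default; the
across-families scope is a design choice where the convention is
ambiguous).  Hard and pool filters commute.  Indels are excluded; SNP
identity is (chromosome, position, ref, alt), 1-based inclusive
coordinates everywhere.

## Functional annotation

Every SNP receives exactly one genomic-context class so the summary
table is an internally consistent partition (some published layouts of
this kind double-count; this artifact does not).  Precedence inside an
mRNA span is CDS > 5′UTR > 3′UTR > intron — most severe consequence
first, deterministic under overlapping transcripts, ties broken by
lowest gene id.  SNPs outside every protein-coding mRNA but inside an
lncRNA transcript are `lncRNA`.  Remaining intergenic SNPs within 5 kb
(inclusive) of an mRNA are `upstream_5kb`/`downstream_5kb` relative to
the *nearest* such mRNA's strand (upstream = 5′ of the transcription
start); beyond 5 kb they are `intergenic_far`.

Coding effects rebuild the codon containing the SNP from the spliced CDS
(reverse-complemented on the minus strand) and translate reference and
alternate codons with the standard genetic code: synonymous, missense,
stop_gain, stop_loss.  A genome base disagreeing with the SNP's ref
allele is recorded as a per-site error, and transcripts whose CDS length
is not a multiple of 3 are flagged and skipped, neither is fatal.  A
whole-CDS brute-force translation serves as the oracle in the tests.

## Validation analytics

Assay-design filtering uses flanks of up to 250 bp per side: a SNP is
removed when an assembly-gap base (run of N) lies strictly closer than
60 bp or another SNP strictly closer than 30 bp (base-to-base
distances; a neighbour exactly at a threshold is kept; truncated flanks
at contig ends are noted, not removed).  The validation success rate
excludes failed assays from the denominator — an assay can fail for
primer reasons unrelated to the SNP call — so rate =
polymorphic / (total − failed) × 100, printed to one decimal with ties
rounded away from zero.

DNA/cDNA concordance compares fish × SNP genotype matrices cell-wise; a
mono-allelic expression event is a pair with heterozygous DNA and
homozygous cDNA.  The published rate of such events leaves its
denominator unstated, so the denominator here is explicit and
configurable: comparable pairs with heterozygous DNA (default, the pairs
at which an event is observable) or all comparable pairs.  Mendelian
checks use biallelic gamete logic; segregation distortion is a
goodness-of-fit chi-square against the cross's expected ratios (1:2:1
for het × het, 1:1 for hom × het; hom × hom crosses are uninformative
and skipped), flagged at p < 0.01 and treated as assay failure.

## The synthetic study

The generator's defaults are the study conditions everything else is
measured under: 22 families; five traits (WBW g, muscle yield %, fat %,
shear force g/g, fillet whiteness from L*/a*/b*), each contrasting 4
high vs 4 low families, with families reused across traits; 5,000
biallelic sites at Poisson(100) pooled depth per family; 5% of sites
planted imbalanced at an odds ratio of 3 (applied symmetrically on the
log-odds scale around a base frequency p0 ~ U(0.1, 0.9)); 1% planted
exclusive (alternate allele removed from one group, the carrier
frequency clipped into [0.4, 0.7] so the pooled MAF gate is not starved);
2% of sites given a failing QD/FS/MQ annotation; and a 4.64% mono-allelic
event rate among heterozygous DNA calls in a 35-fish × 72-SNP panel.

Family frequencies are beta-distributed around their group value with
concentration 200, a mild family-to-family overdispersion.  No published
variance components exist for this; the value is a free knob chosen to
be realistic, not an inferred quantity.  Expression level is uniform
across sites (differential-expression effects on pooled frequencies are
treated as negligible); sites are placed 60% inside gene spans, mirroring
the transcribed origin of RNA-Seq variants, the rest uniform.  The toy
genome (three chromosomes with a karyotype-like length gradient,
multi-exon genes on both strands with UTRs and ≥10 kb intergenic gaps,
non-overlapping lncRNAs, short N-runs as assembly gaps) makes every
annotation class and the assay-gap filter reachable.

When one site is planted imbalanced for several traits whose family
groups overlap, later traits (in canonical trait order) take precedence
in the family-frequency assignment; the truth table records both the
planted class per trait and the realised expected group frequencies.
Consequently sensitivity is reported site-level (detected in at least
one planted trait) and the false-positive rate is measured on globally
null sites, which are free of cross-trait contamination.  Detection uses
the combined gate: ratio (or exclusive) criterion plus chi-square
p < 0.05 where the statistic is defined.

What the generator does *not* emulate — alignment artifacts, paralogy
from genome duplication, base-quality error, reference bias, depth
correlation along transcripts — bounds what passing tests show: they
validate the statistics and bookkeeping, not robustness to upstream
calling error.

Randomness: one master seed; named child streams (reference, designs,
phenotypes, pools, quality, panel) derived via `SeedSequence.spawn`, so
identical configs give byte-identical FASTA/GFF3/GTF/VCF/TSV outputs.

## Numerical and reporting choices

Printed percentages round half away from zero (one decimal for rates,
two for class percentages), matching table conventions rather than
banker's rounding.  Group phenotype summaries use the sample SD (n−1)
over family averages and Welch's t-test (the published comparison states
only a significance level; Welch is the stand-in).  Ranking ties in
family selection break by family id.  Chromosome densities are SNPs per
100,000 bases over whole sequences (no sliding windows), with unplaced
scaffolds aggregable into an "Unknown" bin by name pattern; the
count-versus-length Pearson correlation needs ≥ 3 chromosomes and
non-constant vectors.

Problem sizes in the test suite and acceptance script (5,000 sites, 22
families, 10,000-SNP partition checks, 200-transcript translation
oracles, 1,000-table chi-square cross-checks) were chosen so the whole
suite runs in well under a minute of statistics on a single CPU while
keeping binomial sampling error far from every asserted margin.

## Known limitations

* Two-pipeline reconciliation operates on SNP key sets; the artifact
  consumes caller output and does not re-run callers.
* Exclusive sites rest on exact zero counts; at low depth a sampling
  zero is indistinguishable from a structural one.
* The published mono-allelic percentage is reproduced as a definition
  (events / heterozygous-DNA pairs), not as a number, because its
  denominator is underdetermined in the source.
* The internally inconsistent published significant/non-significant
  split of the chi-square-tested SNPs is not used as a target anywhere.
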