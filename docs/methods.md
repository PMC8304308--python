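# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `qtlbsa`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic F2 bulk experiment

The generator (`qtlbsa.simdata`) emulates the experimental design the
analysis assumes, on one chromosome.

**Recombination.** A uniform genetic map converts physical to map distance
at a configurable rate, default 250 kb/cM — a typical plant-genome average
chosen once as a defensible simple model; no map interpolation is
attempted. Gametes are recombinant mosaics of the two parental haplotypes
under Haldane's model: crossover counts are Poisson in map length,
crossover positions uniform, no interference. Each individual combines two
independent gametes, so per-site genotype frequencies converge to the
Mendelian 1:2:1 and dose correlation between sites decays with map
distance as (1 − 2r).

**Phenotype.** Days to first flowering is
`baseline + effect_days · g(dose) + N(0, noise_sd)` with `g(0)=0`,
`g(2)=1`, `g(1)=(1−dominance)/2`. The default `dominance = 1` makes the
early P1 allele fully dominant, matching the observed behaviour of F1
plants flowering like the early parent; `dominance = 0` recovers the
additive model. Default baseline 80 d and an equal-day companion constant
of 98 d put synthetic phenotypes on the scale observed for the sensitive
parent under short-day vs equal-day light regimes, so day-range bulk
thresholds (e.g. an early pool at 36–40 d, a late pool beyond 52 d) are
meaningful numbers rather than abstract cutoffs.

**Design defaults.** 234 F2 individuals with tail bulks of 17, ~30×
expected pool depth, a 20-day homozygous effect and 2-day residual noise.
These are the study conditions the package is tested under; the parameter
recovery and calibration checks run at exactly these settings.

**Bulk selection.** `tails` mode takes the `bulk_size`
earliest/latest-flowering individuals; `thresholds` mode restricts
eligibility to day ranges first. Ties are broken by ascending individual
index (stable sort), which makes selection deterministic and the pools
provably disjoint — the exhaustive 3⁶-genotype enumeration test relies on
this.

**Read depths.** Per site and pool, total depth ~ Poisson(mean_depth) and
alternate reads ~ Binomial(depth, pool allele frequency), the pool
frequency being the mean genotype dose over bulk members divided by two.
This mimics shotgun sequencing of a DNA pool while ignoring sequencing
error, mapping bias and indels. A fixed-depth mode supports exact
enumeration tests. Parents are emitted as fixed opposite homozygotes.

**What the generator does not emulate.** Base-call errors, reference/
mapping bias, depth overdispersion beyond Poisson, segregation distortion,
multi-allelic sites, epistasis, and multiple chromosomes in one
population object. Passing tests therefore demonstrate correctness of the
statistical chain under idealized sampling, not robustness to artifacts of
real short-read data.

## SNP-index scan

Sites are polarized against the maternal parent: only opposite-homozygote
parental configurations are informative; reversed configurations are kept
with alleles and depth pairs swapped, everything else is rejected with a
reason code. The SNP-index is the continuous read fraction — the boundary
principles (0 = identical to P1, 1 = fully divergent) fix its ends, and
intermediate values are used as-is, since rounding to {0,1} would make
window averages degenerate. Sites with total pool depth below `min_depth`
(default 7, common practice for pool-seq; configurable) are missing.

Δ(SNP-index) defaults to L-pool minus E-pool, exposed as an
`orientation` switch since either subtraction order appears in the
literature. Windows are half-open `[start, start+W)` on 1-based
coordinates, default W = 1 Mb stepping 1 kb, restricted to windows fully
inside the chromosome; windows with fewer than `min_sites` (default 3)
usable sites are missing, never zero. Window means are computed by direct
summation over member sites so they equal a naive recomputation exactly.

## Null band

The no-QTL null is the standard QTL-seq simulation null: each pool's
allele frequency is the mean of `bulk_size` independent F2 doses —
equivalently Binomial(2·bulk_size, ½)/(2·bulk_size) — and reads are
binomial at the observed per-site depths. Two aggregation levels are
provided:

* `null_band` returns per-site two-sided quantiles, e.g. with one plant
  and one read per pool the Δ distribution is {−1, 0, +1} with
  probabilities ¼, ½, ¼ and the 95% band is the full [−1, 1].
* `window_profile` computes the band at the *window* level: each replicate
  draws one bulk-frequency pair shared by the sites of the chromosome
  (complete linkage at the window scale — within a 1 Mb window the F2 dose
  correlation is ≳0.95 at the default map density, so this is the regime
  the method operates in) plus independent per-site read noise, and the
  band is the quantile of the replicate *window means*. Averaging per-site
  bands over a window instead would overstate the spread of the windowed
  statistic, because read-sampling noise averages out across a window
  while the shared bulk-composition component does not; the window-level
  band keeps the nominal coverage, which the calibration test measures
  directly.

Empirical quantiles are clipped so the band always contains 0 (the null is
symmetric; sampling noise should never exclude it). Zero-depth sites get
the vacuous per-site band (−1, 1) and are excluded from window bands.
Defaults: 1000 replicates, 95% level, seeded and fully reproducible.

The calibration check simulates null crosses and counts window means
outside the band. Heavily overlapping 1 kb-step windows are strongly
correlated, so an exceedance *fraction* over them does not concentrate;
calibration is therefore measured on non-overlapping 1 Mb windows pooled
over 100 replicate null crosses (~10,000 windows, effectively independent
given selection is independent of genotype under the null).

## QTL calling

A QTL is a maximal run of at least `min_run` (default 10) non-missing
windows outside the band with a consistent sign. Runs separated only by
fewer than `min_run` missing windows are merged; a window back inside the
band always terminates a run. Intervals are reported 1-based inclusive,
from the first window's start to the last window's end, with the sign
(positive = late pool enriched for the P2 allele) and the peak window
mean. The default `min_run` suppresses isolated exceedances expected at
the 5% level without materially delaying detection of true intervals,
which at these design parameters span megabases.

## Interval algebra

QTL intervals are carried in Mb with 1-based inclusive endpoints as
conventionally printed, at full float precision internally, 2-decimal
printing. Intersection requires a common chromosome and is
order-invariant. Gene lookup uses any-overlap semantics (a gene straddling
the region boundary is included) — the inclusive choice where the
convention is unstated. Interval inputs given only in genetic coordinates
must be converted by the user; no cM→bp interpolation is performed.

## Candidate cascade

Stages, each strictly shrinking its input and audited with site and gene
counts: (1) Δ strictly greater than the threshold (default 0.7; applied to
per-site Δ by default, with window-averaged Δ usable by passing a
windowed site table); (2) protein-changing consequence — codons are
translated under the standard genetic code via Biopython, minus-strand
genomic alleles are reverse-complemented, and stop gains/losses count as
protein-changing; (3) overlap with the consensus region; (4) the
cross-variety pattern: every photoperiod-insensitive accession matches the
reference and all sensitive accessions share the same non-reference
allele. Heterozygous calls never match (inbred panels are expected
homozygous) and the default missing-data policy is `fail` — a site must be
fully observed to be a candidate; an `ignore` policy is available which
skips missing calls but requires at least one observed variant call in the
sensitive group. (5) An optional annotation-keyword stage surfaces
supplied functional annotations (e.g. "NF-YA"); the final functional
choice among pattern-passing genes is a human judgement, so this stage
only filters on user-provided metadata and is skipped when no keyword is
given.

Effect annotation handles single-nucleotide variants only, matching the
cascade's use of non-synonymous point mutations; indels and splice-site
effects are out of scope.

## Expression utilities

RPKM is `count / (CDS kb) / (mapped reads in millions)`; zero-length CDS
or empty libraries are errors. Benjamini–Hochberg adjustment (step-up,
capped at 1, delegated to statsmodels) is applied only when adjusted
values are absent from the input — the differential-expression model
itself is out of scope and its p-values are inputs. The DEG filter flags
`up`/`down` at `|log2FC| ≥ 1` and `FDR ≤ 0.001` with inclusive boundaries.
Relative qPCR expression uses 2^−ΔΔCt against a reference gene and a
calibrator sample (the mean calibrator ΔCt when several are flagged).

## Pipeline and I/O

`run_pipeline` executes simulate → scan → call → overlap → candidates,
writes every artifact atomically (temp file + rename) and always emits a
JSON manifest (version, seed, parameters, per-stage counts) sufficient to
re-run the configuration; manifests contain no timestamps so re-runs are
comparable byte-for-byte on the stage counts. When no external candidate
inputs are supplied, the candidates stage constructs demonstration gene
models, coding sequences, variety panel and annotations around the
observed scan sites (planting the variety pattern on the strongest-Δ
sites), so the default configuration exercises all five stages
self-contained. VCF is a minimal 4.2 subset (GT + AD) via pysam; GFF3 via
gffutils; FASTA via Biopython. TSV/VCF coordinates are 1-based, BED
0-based half-open, each stated in the file header.

## Problem sizes used by the checks

The statistical checks run at the study design (234 individuals, bulks of
17, depth 30, 1000 replicates, 95% level): calibration on 100 null crosses
× 100 non-overlapping 1 Mb windows (~10⁴ windows), recovery on 50 seeded
crosses of 1000 sites on a 10 Mb chromosome with the causal locus at 5 Mb.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping the whole suite around a minute.

## Known limitations

Single-chromosome populations; F2 design only (no RIL/backcross bulks);
Poisson–binomial depth without error model; no loess/tricube smoothing
variants; no genetic-to-physical map interpolation; annotation limited to
SNVs in single-CDS gene models.
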