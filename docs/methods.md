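# Methods

This note records the generative model, the detection and filtering
definitions, the parameter defaults (with units and rationale), and the
numerical/design choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic genome

The background sequence is an order-1 Markov chain: each base repeats the
previous one with probability `markov_persistence` (default 0.15) and is
otherwise drawn iid from the GC-balanced stationary distribution
(`gc_content`, default 0.41). The persistence term produces same-base runs
at realistic density, which keeps homopolymer filtering and cluster-spacing
behaviour non-trivial; a purely iid background would make homopolymers of
length ≥5 about four times rarer.

Annotated elements are drawn first (transcripts: 4–8 exons of 150–300 bp
separated by 200–1500 bp introns; pseudogene and duplicon copies;
homopolymer plants), packed onto chromosomes disjointly with
multinomially distributed gaps, and then written over the background:

* **Pseudogenes** are intronless (spliced) copies of multi-exon
  transcripts at 1–3% divergence — the processed-pseudogene artifact:
  high sequence similarity to a functioning gene, no introns, so spliced
  reads from the parent align to the copy seamlessly.
* **Duplicons** are contiguous copies of transcript-region sequence
  (default 500 bp at 98% identity, both knobs exposed; the divergence of
  real segmental duplications varies too widely to fix). The per-copy
  divergent offsets are recorded exactly, giving every homology analysis a
  ground truth. Copies are planted on the forward strand; the homology
  search itself is strand-aware and is tested on reverse-strand queries
  directly.
* **Homopolymers** are annotated by scanning the final sequence for runs
  ≥ `homopolymer_min_len` (default 5), so the annotation is complete, not
  just the planted runs.

Divergence is realised as an exact count (`round(rate × length)`) of
mutated positions rather than per-base Bernoulli draws, so recorded
identities are exact and construction invariants are testable without
tolerance.

A configuration whose annotated elements cannot fit the genome is rejected
with a clear message. Internally all coordinates are 0-based half-open;
GTF output is 1-based inclusive and BED 0-based half-open.

## Read simulation

Expression: an `expressed_fraction` (default 0.7) of transcripts receives
exponential relative abundances, normalised so that Poisson means sum to
the requested library size. Fragments are placed uniformly on the
(spliced or unspliced) transcript; fragment length is normal
(mean 330 bp, SD 50 bp — only the mean is a modelling target; the SD is a
plausible library width), truncated below at the read length and above at
the transcript length. Default exon counts/lengths keep spliced
transcripts ≥600 bp, so the truncation bias on the mean is ≪ 1 bp. Mates
are 100 bp, forward/reverse, with the physical mate order randomised
(non-strand-specific protocol).

Intronic signal: each fragment comes from unspliced pre-mRNA with a single
global probability *p*, calibrated once per run so that the expected
intronic share of read bases equals the target (default 30%). The
calibration computes, per transcript, the exact expected intronic fraction
of read bases for a pre-mRNA fragment (including the coverage ramps at the
transcript ends, at the mean fragment length) and solves for *p* from the
expression-weighted mean. The realised intronic fraction lands within a
fraction of a percentage point of target at ≥100k pairs.

Errors: substitutions are applied per base at rate 0.005, raised to 0.20 on
the last 10 *sequenced* bases of the 25% of reads flagged as degraded
(i.e. the first 10 stored bases of reverse-strand mates); the replacement
base is uniform on the three alternatives. The implied overall per-base
rate is 0.975·0.005 + 0.025·0.20 = 0.009875, which the suite verifies by
measurement. Indels are *sample polymorphisms*: planted once per
transcript pre-mRNA at 0.001 events per base (length 1–3, geometric,
capped), kept ≥5 bp from exon boundaries and non-overlapping so that truth
CIGAR ref-skips are unambiguously deletions (< 20 bp) or introns. Quality
strings are constant high-Q with low-Q degraded tails; nothing downstream
consumes them, they exist for FASTQ validity.

Reads are stored genome-forward with their aligned (M) segments; CIGAR
strings, truth SAM (`XE` error-count and `XT` exon/intron tags) and FASTQ
(reverse-complemented for reverse mates) are derived views. Clean mode
zeroes all four error mechanisms; its reads realign to the genome with
edit distance 0, which the suite asserts exactly.

## RDD planting

Covered sites are stratified by depth — quartiles by default, or a ≤10x
bin plus tertiles of the rest for skewed coverage; ties go to the lower
bin, and a boundary that would empty the top bin is dropped (degenerate
uniform coverage collapses to one bin with a warning). RDD counts are
split across bins equally within ±1. Each site draws an alt base uniform
over the three alternatives and a level *f* ~ U(0,1]; the realised
alt-read count is *k* = round(*f·c*) clamped to [1, *c*]. Deterministic
rounding (rather than binomial thinning) keeps the truth table exact: in a
clean truth-aligned pileup the alt count equals *k* at every site, which
is asserted, and at low coverage the realised levels are visibly discrete
(support ⊆ {1/c, …, 1}).

Hyperediting: 5% of sites seed clusters. Within ±100 bp of the seed,
every position sharing the seed's reference base and coverage bin — and
not already an RDD — becomes a same-type RDD with probability 0.5.
Recruitment adds new sites rather than retyping existing ones (the
alternative reading of the clustering description; adding sites keeps the
per-bin balance of the independent sites intact and the recruitment
fraction directly measurable). The realised same-type fraction is measured
afterwards by *replaying* eligibility from the truth table, strata and
genome in cluster order — the measurement shares no state with the
generator's draws.

Alt bases are written into exactly *k* uniformly chosen spanning reads, in
genome-forward orientation, so reverse-strand mates show the complement in
FASTQ while any pileup at truth placements shows the alt. Planted
known-variant (dbSNP-style) sites are not simulated; the exclusion path is
exercised with a synthetic VCF listing a subset of planted RDDs.

## Calling

Pileup counts aligned (M) bases only — clips, insertions and gap-spanning
reads contribute nothing; both mates count independently. A call requires
coverage ≥ C, alt count ≥ K and alt level ≥ F, all inclusive ("minimum"
thresholds), with the level denominator the full coverage *c*. Each
non-reference base can yield its own call at a site. Known-variant
exclusion matches by position by default (any alt), with an alt-matching
mode available. The caller is verified exactly against a brute-force
enumeration oracle on randomized pileups, and call sets are monotone under
threshold tightening.

## Misalignment surrogate

Rather than bundling aligners, the benchmark relocates truth alignments:
pairs wholly inside a duplicon source move to the homologous copy with
probability `p_move`, and all-exonic (spliced) pairs of pseudogene parents
move into the processed copy through the exon→spliced-offset map. The
divergent positions of each copy then appear as concentrated mismatch
pileups — the artifact the homology, pseudogene and concordance filters
target. External SAM/BAM call sets can be substituted anywhere downstream.

## Filters

The homology search is a from-scratch seed-and-extend: exact 12-mer seeds
tiled every 12 bp across the query, both strands, ungapped extension, with
mismatch cap ⌊(L+2)/12⌋−2 (the aligner-style allowance; 6 mismatches for
L=100). Because the cap is always below the number of non-overlapping
tiles, pigeonhole guarantees every in-cap locus shares an exact tile with
the query, so the seeded search provably returns the full hit set; the
suite confirms exact agreement with an exhaustive sliding-window Hamming
scan (shipped as the reference implementation) on megabase genomes.

* **Uniqueness**: flanks of total length 51/101/151 centred on the site;
  more than one hit for any flank ⇒ non-unique. Near chromosome ends
  flanks are truncated and still searched (a hit must cover the truncated
  query; the cap keeps its nominal-length value).
* **Explanation filter**: flanks of 25/50/75 bp ending (upstream) or
  starting (downstream) at the site, the site base included; a non-origin
  hit whose aligned base at the site offset equals the call's alt
  "explains" the difference and removes the call (complemented on minus-
  strand hits; an optional ±1 offset tolerance exists). The two flank
  conventions differ because the two analyses are defined independently;
  both are implemented as stated.
* **Pseudogene / junction / homopolymer**: interval membership; intronic
  sites within 6 bp (1-based distance into the intron) of a splice
  junction; sites inside or within 1 bp of a same-base run ≥5 ("adjacent
  to homopolymer" is not defined more precisely anywhere authoritative —
  run length and adjacency are conservative defaults and configurable).
* **Concordance**: a call must be matched (chrom, pos, alt) in ≥
  `min_other` other call sets.

Filters only remove calls; the composed pipeline's survivor set is the
intersection of per-filter survivor sets.

## Evaluation

Truth sites passing the truth-side restrictions (coverage and level, on
the realised level by default; the simulated level is selectable) are TPs
when matched by a call with the same alt, else FNs. Calls at non-truth
positions or with the wrong alt are FPs; calls matching truth sites that
fail the restriction count in neither class (they are real differences,
just outside the denominator of interest). Sensitivity = TP/(TP+FN),
FDR = FP/(TP+FP), and FPR divides FPs by the number of non-truth sites
meeting the coverage threshold (a reasonable denominator; none is
canonical). Level agreement reports the Pearson correlation of observed vs
simulated levels over matched TPs and the fractions deviating by >5, ≥10
and >30 percentage points (with the underestimating share among ≥10-point
deviators); cutoffs carry a 1e-9 guard against float noise at exact
decimal deviations.

## Sequencing-error analysis

Per-site error level = non-template reads / coverage above a coverage
cutoff; the overall rate ê is the coverage-weighted mean. The nonrandom-
error test compares observed levels to a null built by drawing
Binomial(c_i, ê) counts conditioned on the observed coverages (sorted, so
site order cannot matter) via the two-sample KS statistic. Two caveats are
deliberate and documented: the levels are discrete, and ê is a plug-in
estimate from the same data, which together make the asymptotic p-value
conservative — a calibration simulation in the suite shows near-zero
rejection under a true binomial null. A parametric-bootstrap p-value
(`n_bootstrap`) restores nominal calibration (rejection ≈ α) and is what
the calibration test asserts; an analytic backend computes the statistic
against the exact binomial-mixture CDF with a discrete-safe supremum over
the pooled support. Power against planted systematic errors (1% of sites
at level 0.5) is verified at p < 0.001.

## Problem sizes and defaults

The package's standard benchmark (`desk_scale_config`) uses a 2 Mb
two-chromosome genome (250 transcripts, 20 duplicons, 10 pseudogenes),
400k read pairs and 20k RDDs — large enough that every recovered rate sits
within three binomial SDs of its target while a full pipeline run stays
around a minute on one CPU. Unit tests use 150–600 kb genomes and
4k–40k-pair libraries for the same reason. With truth alignments and no
misalignment injection, sequencing error alone cannot assemble four
same-base alt reads at ≥20% of coverage ≥20, so FDR and FNR at the
standard thresholds are ~0, comfortably inside the ≤10% bound the
benchmark asserts; the interesting structure appears when `p_move` > 0.

## What the generator does not emulate

Real repeat families (Alu and friends), ADAR sequence-context preferences,
allele-specific expression, PCR duplicates, GC bias, strand-specific
protocols, quality-score-correlated errors, and real aligners' scoring
heuristics. Passing benchmarks here demonstrate that the detection and
filtering machinery is correct and well-calibrated under the stated
generative model — not that any particular aligner will achieve the same
rates on a real transcriptome.
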