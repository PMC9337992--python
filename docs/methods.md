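# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screen normalization and hit calling

Raw confluence wells are divided by the per-line mean DMSO confluence,
replicates are averaged, and both the normalized matrix and its log2 are
emitted. The hit rule uses a strict inequality on the effect ("more than
50%" growth reduction ⇒ normalized confluence < 0.5) and a non-strict one
on breadth ("at least one third" ⇒ responsive-line fraction ≥ 1/3); a
compound sitting exactly at 0.5 in every line is therefore not a hit.
These inequality directions are a package choice — prose descriptions of
such rules never fix the boundary cases — and are pinned by tests.

## Dose–response model

Viability follows the descending three-parameter Hill curve
E(d) = E∞ + (1 − E∞)/(1 + (d/EC₅₀)^h) with E∞ ∈ [0,1], h ∈ (0,10],
EC₅₀ ∈ [min dose/10, max dose·10]. Fitting is bounded least squares
(`scipy.optimize.least_squares`) on log₁₀-dose, multi-started from five
log-spaced EC₅₀ initials with the plateau initialized at the observed
minimum; the best residual sum wins, so the fit is deterministic. Working
in log-EC₅₀ keeps the Jacobian well-scaled across the four-decade dose
range.

AAC integrates (1 − E), with viability clipped to [0,1] first, by
trapezoids on the log₁₀-dose axis and normalizes by the log-dose span.
The trapezoid rule is exact for log-linear viability (hence the 0.5
closed-form check) and on nine log-spaced points stays within 0.05 of a
1,000-point grid over the Hill family — both computed by the tests.

IC₅₀ is *absolute* (fitted curve crossing 50% of control), not relative
to the curve's own asymptotes; this choice is recorded in the fit
metadata. It is censored when E∞ ≥ 0.5 (no crossing exists) or when the
crossing falls above the top tested dose — reported as a flag, never
extrapolated.

Doubling time is ln 2 divided by the slope of ln(confluence) against
time, using only points below a saturation cutoff (default 0.8) where
exponential growth is a defensible assumption; non-positive slopes are
reported as non-growing rather than as a negative time.

## Biomarker ranking and preranked GSEA

Pearson correlations between each gene's log expression and the per-line
sensitivity vector are computed over shared lines (≥3 required).
Zero-variance genes get r = 0 by convention and sort after all informative
genes; exact ties break lexicographically so the ranking is total and
reproducible. The sensitivity metric defaults to AAC; IC₅₀ can be
selected and the choice is recorded in the output metadata, since the two
are interchangeable ranking phenotypes for this analysis.

The enrichment statistic is the classic weighted Kolmogorov–Smirnov
running sum (weight exponent p = 1 by default; p = 0 gives the
analytically checkable unweighted case): members add |r|^p normalized
over member weights, non-members subtract 1/(N − |S|); ES is the
running-sum extremum. Because the input is a preranked list, the only
available null permutes gene labels (phenotype permutation would need the
underlying matrix). Null configurations are sampled with a seeded
generator — or enumerated exhaustively whenever C(N, |S|) ≤ n_perm, which
makes the small worked cases exact. p-values are computed within the sign
class of the observed ES, p = (1 + #{same-sign null ≥ |ES|}) /
(#same-sign + 1), because the positive and negative extrema have
different null scales and pooling them makes p anti-conservative by about
a factor of two (the calibration test demonstrates validity under a
shuffled ranking). NES divides ES by the mean magnitude of same-sign null
scores; FDR is Benjamini–Hochberg across the tested sets
(`scipy.stats.false_discovery_control`).

Group summaries (sensitive vs resistant, treated vs control) use Welch's
unequal-variance t-test per gene on log-scale input, so the group-mean
difference is the log2 fold change directly; zero-variance ties yield
t = 0, p = 1 rather than NaN.

## Differential splicing

PSI uses junction-normalized counts: inc/n_inc_junctions and
exc/n_exc_junctions put multi-junction events on a per-junction scale
before PSI = inc_norm/(inc_norm + exc_norm). The posterior is
Beta(round(inc_norm)+1, round(exc_norm)+1) — a uniform Beta(1,1) prior
updated with the rounded normalized counts.

For a two-condition comparison, replicates are pooled within condition
after normalization (the simplest defensible replicate model; a
hierarchical alternative would need information the count tables do not
carry). ΔPSI is sampled from the two independent posteriors
(default 10,000 draws, seeded); with s the sign of the median draw,
MV95 = max(0, 5th percentile of s·ΔPSI) is the minimum effect size
supported at 95% posterior confidence. An event passes when every sample
carries ≥ min_reads (default 10) total reads, |ΔPSI point estimate| ≥ 0.2
and MV95 ≥ 0.05. MV95 values under a 0.01 floor are reported as 0 — below
the minimum effect the method distinguishes — which cannot change a pass
decision since the gate is 0.05. The Monte-Carlo MV95 is validated
against numeric integration of the beta-difference density (an
independent convolution-based oracle) to within 0.01, and the double
threshold keeps the empirical null pass rate well under 5% at coverage 50
(both computed in the tests and the acceptance script).

Event types: a variable segment equal to a full intron is IR; equal to an
internal exon, EX; sharing exactly one boundary with an intron, a splice-
site shift, assigned A5SS/A3SS in transcript orientation (the genomic-left
intron edge is the donor on the plus strand but the acceptor on the
minus strand). Anything else is labeled `other` with a warning.

ORF impact builds the inclusion isoform (exon chain ∪ segment, merging
adjacent pieces) and the exclusion isoform (chain − segment), maps the
annotated start codon into each, translates, and applies the
premature-termination-codon rule standard in the
nonsense-mediated-decay literature: a stop upstream of the annotated stop
counts as a PTC when it lies more than 55 nt before the final exon–exon
junction of that isoform. A PTC present only in the inclusion isoform is
*deleterious* when the segment is intronic in the annotation (retention
introduces it) and *protective* when the segment is an annotated exon
(skipping removes it); a PTC only in the exclusion isoform (e.g. a
frame-shifting skip) is deleterious; otherwise the event is neutral, as
are events entirely outside the CDS. Coordinates are 0-based half-open
internally; GTF I/O converts to and from 1-based inclusive.

The qPCR intron-retention ratio is 2^−(Ct_intron − Ct_spliced), assuming
100% amplification efficiency.

## IR-Alu pairing and intersection

Alu-family repeats at least min_len = 100 bp long (most genomic Alu
copies are truncated fragments below this) are scanned left to right per
chromosome; each unpaired element pairs with its nearest downstream
opposite-strand partner within max_gap = 5,000 bp, each element joining
at most one pair. Greedy nearest-neighbor matching is deterministic and
checkable against an O(n²) enumeration oracle, which the tests do on 50
random instances; an all-pairs mode is available behind a flag. Neither
the gap cutoff nor the length filter is dictated by the underlying
biology with any precision — both are exposed on the CLI and echoed in
reports.

"First" in a pair means genomically upstream. A retained intron's
relationship to a pair is classified by ≥1 bp half-open overlap with each
member: both / first_only / second_only / none; a mirror-symmetry test
(coordinate flip + strand flip) guards the convention by requiring
first_only and second_only to swap. A pair is *bidirectionally
transcribed* when both members lie within the transcribed span of the
intron's transcript — being on opposite genomic strands, the two copies
are then read in sense and antisense within one pre-mRNA, the
configuration that can fold into dsRNA. Introns with no parent transcript
are excluded from the bidirectional denominator and logged.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and write
byte-identical files for identical seeds.

* **Genome** (`gen_genome`): one chromosome, four-exon transcripts with
  exon lengths in {90,120,150,180} (multiples of 3, so the CDS — which
  spans the whole mature transcript — is frame-clean by construction) and
  a stop-free codon stream placed strand-aware between the annotated ATG
  and terminal TAA. The middle intron (1.6–2.6 kb) is the designated
  retained intron. A fraction `ir_pair_fraction` (default 0.62, the
  Alu-dense sensitive condition) of these receive an inverted Alu pair:
  with probability `bidirectional_fraction` (default 0.8) both members
  sit inside the intron 100–1,500 bp apart; otherwise the second member
  is placed just past the last exon, so the pair intersects the intron
  without being bidirectionally transcribed (roughly five of eight
  intersecting introns end up bidirectional, i.e. ~50% of all designated
  introns at the defaults). Alu sequence is a fixed synthetic 281-bp
  pseudo-consensus with 10% point mutation — decorative, since pairing
  uses coordinates and strand only. Flanking introns receive decoy
  truncated Alu fragments (60–95 bp, below the length filter) and
  occasional non-Alu elements, exercising both filters without perturbing
  the planted pairs.
* **Screen** (`gen_screen`): 36 compounds × 15 lines × 4 replicates by
  default; planted hits get normalized confluence U(0.15, 0.45) in half
  the lines, everything else sits near 1 with σ = 0.05 noise (floored at
  0.55 so noise cannot fabricate a responsive line).
* **Dose–response** (`gen_dose_response`): Hill viability on the nine-dose
  0.04–10 µM grid plus N(0, σ) noise, clipped to [0, 1.2] — wells can
  exceed control (over-confluence) but not go negative.
* **Expression** (`gen_expression`): signature genes are
  strength·z(sensitivity) + √(1−strength²)·ε rescaled to the background
  mean/sd, so their expected Pearson correlation with sensitivity equals
  `strength` exactly (and is exactly 1 at strength 1); background genes
  are independent Gaussians.
* **Junction counts** (`gen_junction_counts`): per replicate,
  psi* ~ Beta centered on the planted PSI with intra-class correlation
  0.01 (mild overdispersion — nonzero so posterior intervals are
  honest, small enough that recovery tests are sharp), then
  inclusion ~ Binomial(coverage, psi*).

What the generators do **not** emulate: real read alignment, junction
discovery, GC/length biases, correlated gene–gene structure, batch
effects, realistic genome content, or Alu secondary-structure
thermodynamics. Passing tests therefore demonstrate that the statistics
recover what was planted under their own model assumptions — correctness
of the machinery, not performance on real sequencing data.

## Problem sizes and defaults

The bundled demo and the acceptance script use desk-scale sizes chosen as
the package's own defaults: 40 (pipeline) or 100 (recovery checks)
transcripts, 1,000-gene expression matrices, 200 GSEA permutations for
decoy comparisons, 2,000–100,000 posterior draws depending on the
precision a check needs. The statistical conclusions (calibration,
power, oracle agreement) are insensitive to these sizes beyond the quoted
tolerances.

## Known limitations

* The replicate model pools counts within condition; true
  between-replicate biological variance beyond the beta-binomial
  dispersion is not modeled.
* ORF classification considers the single annotated transcript per event;
  isoform-aware impact (multiple transcripts per gene) is out of scope.
* The greedy one-pair-per-Alu matching can differ from a globally optimal
  matching in dense Alu clusters; the all-pairs mode exists for
  sensitivity analysis.
* Bidirectional transcription is operationalized as both pair members
  within one transcript's span; overlapping antisense transcription units
  are not considered.
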