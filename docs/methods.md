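# Methods

This note documents the models, rules, and numerical choices implemented in
`planarian_triage`, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Coordinate and threshold conventions

External formats keep their native conventions (tabular BLAST and
RepeatMasker `.out` are 1-based inclusive); internally everything is 0-based
half-open, converted at a single boundary (`io_formats.to_internal` /
`to_external`). Comparators follow the quoted phrasing of each rule: E-value
cutoffs "at X" are inclusive (≤ X), identity/coverage "cutoff of X %" are
inclusive (≥ X), "> 100 amino acids" and "> 200 bp" are strict, "≥ 25
unmapped bases" is inclusive. Where a rule's source gives no comparator, the
inclusive reading is used.

## Tiered triage

Transcripts are classified by the first matching tier in the precedence
order rRNA > mitochondrial > nuclear (a tier fires when any hit of its
database tag passes its E-value cutoff: 1e-65, 1e-08, 1e-05 respectively),
then by an externally supplied coding prediction (the error-tolerant HMM
predictor is an external tool; its calls enter as a per-transcript flag),
and finally the built-in six-frame longest-ORF fallback.

Retention: homology tiers retain when the deciding hit covers at least two
thirds of the reference. The phrase defining this rule is ambiguous between
query and subject coverage; the package defaults to subject (reference)
coverage, configurable via `TriageThresholds.ref_cov_side`. Prediction tiers
retain on the conjunction of a > 100-aa predicted protein and genome
co-location (a GENOME-tagged alignment at ≥ 93 % identity, ≥ 93 % coverage,
> 200 bp, overlapping a known transcript locus — the aligner itself is
external and its output is consumed). A transcript failing its primary rule
is retained if any secondary support fires: conserved eukaryotic gene sets
(≤ 1e-08), helminth ESTs (≤ 1e-15), protein domains (≤ 1e-03), or genome
co-location. Every firing rule is recorded in the decision's `reasons`.

Contamination (checked before retention; a flag vetoes retention): vector
match, then a foreign nucleotide hit at ≥ 95 % identity and ≥ 95 % query
coverage, then a best protein hit that is non-metazoan at ≥ 80 % identity.
Taxonomy labels (foreign/self/vector; metazoan or not) are supplied by the
caller — the package does not infer taxonomy from subject ids.
Mis-assembly: ≥ 25 zero-coverage positions in the per-base read-coverage
vector. The alternative reading of "unmapped bases" (soft-clipped bases in a
transcript-to-transcriptome mapping) is not implemented.

ORF calling uses the standard genetic code; codons containing N translate to
X and do not interrupt a segment. Equal-length segments tie-break by frame
order (+1, +2, +3, −1, −2, −3) and then by smallest forward-strand start —
the choice is arbitrary but fixed for determinism.

## Expression profiles

`RPKM = reads / (L/1000 · T/10⁶)` with the per-sample total `T` summed only
over transcripts with ≥ 10 reads in that sample. RPKM is computed for every
transcript (including sub-threshold ones, which are reported at low values),
but sub-threshold entries are excluded from denominators and summaries;
"expressed in sample j" is defined as ≥ 10 reads there, aligning the summary
rule with the denominator rule. Per-transcript mean, standard deviation
(population divisor, n), and median are taken over expressed samples only.
Bins use the descending-rank reading — HIGH = mean ≥ 80th value-percentile
of expressed means (top 20 %), LOW = mean < 50th percentile (bottom 50 %),
MEDIUM otherwise — because the top-x %/bottom-x % language is the coherent
reading of the contradictory as-printed thresholds; the literal reading is
retained behind `percentile_bins(..., convention="literal")` for comparison.
Percentiles use linear interpolation (numpy default); ties share a bin
because binning is by value against the percentile, not by rank.

## Enzyme consensus, pathway conservation, TFs, GO transfer

Per-source filters: DETECT keeps ILS ≥ 0.9 with ≥ 5 positive hits (both
inclusive); BLASTP keeps top hits at E ≤ 1e-10 (top hit = highest bitscore,
ties by lower E-value then lexicographic subject id); PRIAM keeps
probability > 0.5 and profile coverage > 70 % (both strict). Consensus:
a (transcript, EC) pair survives iff supported by PRIAM and BLASTP jointly,
or by DETECT alone. EC strings match exactly at four fields; wildcard fields
('-') never satisfy the pathway intersection, so partially specified calls
are retained in output but never counted toward conservation. Pathway
conservation = 100 · |pathway ECs ∩ distinct consensus ECs| / |pathway ECs|;
distinct ECs count once regardless of how many transcripts carry them.

TF consolidation unions three criteria per transcript: a domain-scan
description containing "transcription factor" (case-insensitive), a
Pfam-source family in the curated DNA-binding-domain (DBD) Pfam list, or a
Superfamily-source family in the DBD Superfamily list. Output reports both
the transcript set and the per-criterion sets, since a per-transcript count
and a per-call count can differ.

GO transfer copies every non-IEA annotation of a transcript's 1:1 ortholog;
many-to-many ortholog rows are rejected, duplicate (transcript, term,
aspect) transfers are collapsed. No ancestor closure is applied — enrichment
uses terms as annotated.

## Repeat activity

Each annotated repeat copy is extracted with 1000-bp flanks (clipped at
contig bounds; complement-strand hits reverse-complemented) and its core —
not the flank-extended sequence — is aligned to the family consensus by
default, since flanks would systematically inflate divergence; the
flank-extended region is selectable (`region="extended"`). The aligner is an
affine-gap global aligner (Gotoh) with match +5, mismatch −4, gap open 10,
gap extend 0.5 (a length-k gap costs open + k·extend). Identity is computed
over the full alignment length with gap columns in the denominator;
divergence = 100 − identity; copies at divergence ≤ 5 % (inclusive) are
classified likely active. End gaps are penalized by default: with free end
gaps the optimal alignment of near-identical sequences of unequal length
shifts to terminal-gap forms (e.g. `ACGT-`/`ACGGT`), which misstates
identity for the divergence use case; the free-end-gap variant remains
available via `AlignmentParams(end_gaps_penalized=False)`. Traceback is
deterministic (diagonal, then up, then left); all scores are multiples of
0.5, so traceback comparisons are exact. The histogram uses half-open 1 %
bins. Kimura-style CpG-adjusted divergence is out of scope.

## Single-cell markers and enrichment

QC drops cells with library < 500 reads, then genes with < 10 total reads or
detected in < 5 cells (that order, fixed). The built-in differential
expression engine normalizes each cell to the median library size, computes
`log2((mean_a + 1)/(mean_b + 1))` per gene for each cluster pair, and
obtains p-values by permuting cluster labels within the pair (default 1000
permutations, seeded, add-one estimator (b+1)/(n_perm+1) so p is never 0);
Benjamini–Hochberg adjustment is applied within each cluster pair. The
engine is deliberately simple — the package's contribution is the consensus
and enrichment logic layered on pairwise DE, and external engine output
(e.g. a Bayesian single-cell DE model) is ingested verbatim through the same
table schema. A gene marks cluster c when up-significant (q ≤ 0.05,
log2fc > 0) in at least k of c's pairwise comparisons; k defaults to
n_pairs − 1 and is exposed because the two published phrasings of the rule
imply different k. The test-free fraction/ratio criteria (expressed in
≥ 25 % of cluster cells; cluster mean ≥ 1.25× the mean elsewhere, both
inclusive, on median-library-normalized counts) are provided separately.

Enrichment is an upper-tail hypergeometric test (log-space via scipy's
survival function). The population is the annotated, tested genes of one
comparison; the up (down) set is significant genes with log2fc > 1 (< −1).
Pathway mode calls a term enriched at p < 0.05; ontology mode additionally
requires more upregulated than downregulated members and ≥ 2 upregulated.

## Synthetic data

Generators are pure functions of `SimConfig`; sub-generators draw from
independent child streams of the one seed.

*Transcripts.* Each transcript embeds one planted ORF framed by in-frame
stop codons. Flanks tile the palindromic motif TTAA, which carries stop
codons in all six frames within every 12-nt window; inside the ORF a 5-codon
cassette (peptide LIISY, codons CTA-ATC-ATT-AGT-TAC) planted every 10 random
codons places stops in the five non-ORF frames at most 45 nt apart. Planted
lengths (30–180 aa, with forced cases at exactly 100 and 101) therefore
dominate every other stop-free run, making the planted segment provably the
unique longest. Planted amino-acid lengths straddle the > 100-aa boundary.

*Evidence.* Hits are sampled so the planted tier's threshold passes and all
stricter tiers fail; 20 % of transcripts (configurable) receive hits exactly
at threshold boundaries (E-value equal to the cutoff, coverage exactly
200/3 %, identities exactly 80/93/95 %). Retention outcomes are planted
first (primary coverage, secondary rescue, or none) and evidence generated
to match. Contaminants receive foreign/vector/non-metazoan hits; the
non-metazoan protein hit is given the highest bitscore but an E-value above
the nuclear-tier cutoff so it triggers the contamination rule without
changing the planted tier.

*Bulk counts.* Log-normal per-transcript levels with Poisson noise across 6
samples (a desk-scale stand-in for the 58 experiments the full study used);
the first 5 % of transcripts are forced below 10 reads in sample 1 to
exercise the restricted denominator.

*Single-cell counts.* Negative binomial (variance μ + φμ², φ = 0.5) with
log-normal cell size factors (σ = 0.3), Bernoulli dropout (rate 0.2), 6
clusters × 30 cells and 5 planted markers per cluster shifted by
log2fc = 3 in their cluster (50 cells/cluster in power runs). This targets
the properties the QC and consensus rules test — overdispersion, library
variation, dropout, cluster structure — and does not emulate UMI/barcode
chemistry, doublets, batch effects, or continuous differentiation
trajectories; passing recovery tests therefore demonstrates correctness of
the rules, not robustness to those real-data phenomena.

*Repeats.* Copies mutate from a 500-bp consensus by per-base substitution
only (default rate 2 %), making expected divergence analytically binomial;
indels are excluded by default so measured divergence equals the realized
substitution fraction exactly. Copies are embedded in a genome with ≥ 1-kb
spacers; the first copy sits 100 bp from the contig edge to exercise flank
clipping.

*Annotation fixtures* plant consensus outcomes per EC (two-source route,
DETECT-only route, and single-source / sub-threshold foils), TF criteria,
and GO transfers, recorded in the ground truth.

## Problem sizes and tolerances

Recovery tests run at n = 500 transcripts (≥ 50 exact-boundary cases),
100 repeat copies × 500 bp, 6 × 30 (null) and 6 × 50 (power) cells with 500
genes and 1000 permutations. Deterministic stages are checked for exact
(0-mismatch) recovery; the stochastic repeat-divergence mean is checked
within 3 standard errors of the planted rate; marker calibration requires
≤ 1 % null calls, ≥ 90 % recovery, and ≤ 10 % empirical FDR. Alignment and
hypergeometric routines are checked against independent references
(Biopython's dynamic-programming aligner; exhaustive enumeration for all
populations N ≤ 12). The pipeline runner is byte-deterministic for a fixed
seed; the run manifest's wall-clock field is the only non-deterministic
output.

## Known limitations

- External tools (BLAST, Spaln, ESTScan, InterProScan, RepeatMasker, Seurat,
  SCDE) are consumed as evidence tables, never executed; their format
  dialects are normalized TSVs.
- The built-in permutation DE engine has resolution 1/(n_perm+1) and ignores
  gene-specific dispersion; it is a calibration-grade stand-in, not a
  replacement for a dedicated single-cell DE model.
- GO enrichment does not propagate annotations to ancestor terms.
- Percent divergence is raw mismatch divergence; no multiple-hit or CpG
  correction.
- The headline counts of the original study (tens of thousands of
  transcripts, full genome, versioned databases) are outside desk scale;
  correctness is established on planted synthetic data instead.
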