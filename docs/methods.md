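# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
the STAR `SJ.out.tab` dialect are converted only at file boundaries.  All
biological vocabulary — upstream/downstream, exon 3′ end, "first intronic
bases" — follows transcription orientation; for minus-strand genes motif
logic runs on the reverse complement and window/offset arithmetic is
mirrored.  The `rs_point` of a candidate is the genomic boundary between the
YAG acceptor and the regenerated NN donor: the junction's acceptor-side
coordinate on either strand.

## Detection model

A candidate RSS is a junction whose donor coincides *exactly* with an
annotated exon 3′ end (recursive donors are exon-terminal 5′ splice sites,
so no tolerance is allowed) and whose acceptor lies strictly inside the
following intron, at least `min_margin` (default 20 nt, configurable) from
either boundary to exclude boundary artifacts.  Junction strand comes from
the strand column, never from motif inference; junctions with undetermined
strand are dropped (counted) unless explicitly kept.  Only uniquely mapped
junction reads are used; multimapping counts are ignored.  Introns are
deduplicated per gene by (interval, donor); a junction acceptor hosted by
several isoform introns is assigned to the longest (most inclusive) one.

An acceptor that coincides with the 5′ start of an annotated host-gene exon
is vetoed as an ordinary alternative 3′ splice site — *unless* that exon is
fully contained within the host intron.  The distinction is structural: an
alternative-acceptor exon extends to (or beyond) the intron's downstream
boundary, whereas an exon contained in the intron and starting at the
acceptor is precisely a putative RS-/cryptic exon, which must not veto its
own RS site.  Without this rule, every RSS whose RS-exon happens to be
annotated on some isoform would be undetectable.  The veto is restricted to
the host gene's annotation.

Candidates failing the `[CT]AG` motif check (including any N in the 5-nt
window) are retained in catalogs with a `motif` fail flag for auditability
but can never pass filtering.

## Filter criteria

* **Conservation**: arithmetic mean of per-base PhastCons over the 5 motif
  nucleotides (YAG + NN); pass requires mean > 0.5 strictly.  The 5-nt
  window is also used for the later 0.45 conservation stratification — the
  motif is the only window the method defines, so both thresholds share it.
  Track positions absent from the bedGraph contribute 0 and raise a
  per-candidate gap flag.
* **Overhang**: the junction's maximum alignment overhang must exceed 5 nt
  (i.e. ≥ 6).
* **Sawtooth**: windows `W` = 500 nt upstream/downstream of the RS point in
  transcription orientation, truncated to the intron (minimum usable window
  50 nt, otherwise the candidate is `untestable`).  The statistic is
  S = (mean_up + ε)/(mean_down + ε) with pseudo-count ε = 0.5 guarding
  against empty windows on sparse introns.  The null redraws the breakpoint
  uniformly from the intron interior (respecting the minimum window) and
  recomputes S on the *same* coverage, preserving the positional
  autocorrelation of the signal; label-shuffling nulls would not.  The
  add-one estimator P = (1 + #{S_null ≥ S_obs})/(n_perm + 1) is bounded
  below by 1/(n_perm+1) and never returns 0.  Pass requires S > 2 strictly
  and P < 0.01.  Fixed-size windows (rather than whole-intron halves) were
  chosen so the statistic is comparable across intron lengths; both W and
  the thresholds are configurable.  No FDR correction is applied across
  candidates — the criterion is a per-site cutoff.
* **Poly(A) subtraction**: any candidate whose (gene, rs_point) is detected
  (≥ 1 read, configurable) in any poly(A)-enriched library is flagged and
  excluded; recursive intermediates are nascent-RNA species and their
  presence in mature-RNA libraries marks an artifact.

Filtering is per sample on that sample's coverage; catalogs are merged
downstream into the final site set (union of per-sample passes), matching a
per-cell-type quantification design.  One seeded generator drives all
permutations in a run; the seed is recorded in every output header.

## Usage and differential testing

Default usage of an RSS in a sample is
`rs_reads / Σ reads over all junctions sharing the RSS's upstream-exon
donor` — this denominator includes the RS junction itself and bounds usage
in [0, 1].  The alternative `flanking_exons` mode divides by the canonical
junction joining the exons flanking the host intron instead; both
definitions appear in the field and they differ (5/20 vs 5/15 on the same
fixture), so both are implemented and the bounded one is the default.

A site with zero RS reads in a sample gets usage 0 only when its donor
still carries ≥ `min_donor_reads` (default 10) junction reads — evidence of
power to detect splicing at that donor; otherwise the sample is untestable
for that site.  This distinguishes absence of recursion from absence of
coverage.

Differential usage uses the two-sample pooled-variance Student's t
(two-tailed, since both gains and losses are of interest) at P < 0.05,
without multiple-testing correction, requiring ≥ 2 defined replicates per
condition.  Gained means higher usage in the perturbed condition.

## Annotation statistics

* RS-exon association: an annotated host-gene exon starting exactly at the
  RS point (tolerance configurable, default 0 nt) and ending before the
  intron's downstream exon.  Sites without one are "zero-length" RS sites.
* Cryptic-exon evidence: coverage fold of the RS-exon over equal-width
  intronic flanks (ε = 0.5 on both means), cryptic if > 2.  The pipeline
  scores this on poly(A) coverage when a poly(A) sample is available,
  because cryptic exons are by definition retained in mature transcripts;
  otherwise the first control replicate's coverage is used.
* Conservation strata at 0.45: sites exactly at the threshold go to "low"
  (the strata are defined by strict inequalities on both sides; the point
  mass needs a deterministic rule and is counted in the log).
* Donor-class enrichment: per dinucleotide pattern (IUPAC letters N and
  V supported; default patterns GT, GV, AT, AV, CN, TN plus composites GN,
  AN) and per direction, a two-tailed Fisher exact test of
  [direction vs unchanged] × [pattern match vs not].
* AS-event overlap: one-tailed hypergeometric over-representation of
  RS-gene sets within each AS type, with the universe taken as all genes in
  the supplied AS table (the most defensible choice when the tested-gene
  set is not otherwise recorded).

## Synthetic data generator

The generator emulates: long-intron genes on both strands across two
chromosomes; planted YAG|NN motifs (one true site per intron at ~40% of the
intron along transcription, decoys at ~70%); conservation tracks with low
background (clipped Normal, mean 0.08, sd 0.05) and stratum-specific motif
means (0.85 / 0.65, both above the 0.5 filter); RS-exon isoforms for 90% of
true sites with 25% of those cryptic; and a replicate design of two
conditions × 3 replicates plus one poly(A) library.

Intronic coverage is `base_coverage · exp(−decay_rate·d)` (30×, 10⁻⁴ per
nt) with a multiplicative drop of `step_fold^min(1, u/u_sat)` at each
upstream RS point, Poisson-sampled per base.  The saturation constant
`u_sat` = 0.2 encodes that recursion acts co-transcriptionally on nascent
RNA: even a site with moderate steady-state junction usage has largely
completed its recursive step by the time downstream intron sequence is
made, so the coverage step saturates at the full `step_fold` (default 4)
while an unused site (u = 0) leaves no step.  Junction counts per intron
draw a Poisson(200) donor total; each RS junction draws
Binomial(total, usage) with per-replicate Normal(0, 0.03) noise on usage
(planted means 0.25 control / 0.05 knockout for differential sites), the
remainder going to the canonical junction.  Cryptic-exon signal is planted
only in the poly(A) library's coverage, consistent with inclusion in mature
transcripts.

Twenty decoys (four per type) each violate exactly one criterion: a non-YAG
acceptor, motif conservation ~0.2, overhang ≤ 5, a planted site without a
coverage step, or presence in the poly(A) junction file.  All randomness
stems from one seed; per-sample substreams are derived by CRC32 of the
sample id, so any sample regenerates independently and byte-identically.

What the generator does *not* model — and what passing tests therefore do
not establish for real data: alignment and mappability artifacts, GC and
fragment-length bias, overlapping genes and antisense signal, intron
lariat/branch-point signal, expression differences between conditions, and
junction-calling errors upstream of the SJ table.  Detection performance on
the synthetic study characterizes the pipeline's statistical behaviour
under its own generative assumptions, not genome-scale sensitivity.

## Problem sizes and numerical choices

The default study (20 genes, 40 true sites, 20 decoys, 7 samples,
n_perm = 1000) runs in a few seconds and is the size used by the test suite
and the acceptance script; the permutation calibration uses 500 flat
Poisson introns.  Ties in the permutation statistic count toward the null
(S_null ≥ S_obs), making P conservative.  Strict inequalities are used at
every published threshold (0.5 conservation, 5 nt overhang, 2-fold, 0.45
strata), so boundary values fail.  Degenerate inputs (zero-length windows,
empty tracks, zero denominators) are flagged untestable rather than
silently passed.

## Known limitations

Detection requires the junction table to contain the RS junction — there is
no read-level rescue.  The acceptor veto consults only the host gene, so a
hybrid junction into an overlapping gene's exon start is not excluded.  The
sawtooth test loses power on introns shorter than ~2 windows and on sites
whose downstream window contains strong cryptic-exon signal in the same
library.  Minor-spliceosome (AT–AC) introns and branch-point modelling are
out of scope.
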