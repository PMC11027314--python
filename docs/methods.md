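# Methods

This note documents the models, algorithms and numerical choices behind
`refbias`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reading was
defensible.

## Balance measures

All three balances are fractions REF/(REF+ALT) at a HET site; "ALT
fraction" plots use 1 − balance.

* **Simulation balance (SB)** counts simulated reads whose *true* origin
  interval overlaps the variant's reference footprint, split by
  haplotype of origin. Undefined (reported as missing) when no read
  overlaps.
* **Mapping balance (MB)** counts reads that both truly originated
  overlapping the site and aligned overlapping it. Reads that aligned
  there but originated elsewhere (mismapped arrivals) are excluded, as
  are reads lost by the aligner — the loss is exactly what MB measures
  relative to SB.
* **Assignment balance (AB)** = n_ref/(n_ref+n_alt) from an assignment
  algorithm's calls; BOTH (undecidable) and OTHER (matching nothing)
  reads are excluded. AB is the only measure available on real reads.

A site's variant footprint is [pos, pos + len(REF) − 1]; insertions
occupy only their anchor base (VCF convention). All coordinates inside
the package are 1-based inclusive; BED output is converted to 0-based
half-open at the boundary.

## Site preparation

Variants whose reference footprints intersect cannot vary independently
(a deletion can erase an SNV), so every such group is removed whole,
along with variants carrying missing ("./.") or unphased genotypes —
which also knock out anything they overlap. The kept set has pairwise
disjoint footprints; removal is idempotent.

**Allelic contexts.** Each HET site gets a REF and an ALT context:
flank_len (default 5) bases of the allele-carrying haplotype, the
allele, and flank_len more bases. Phased neighbors within the flank are
substituted so each appears, correctly phased, in the other's flanking
sequence. Neighbor application uses a window padded by flank_len + 20 bp
so neighboring indels cannot starve a flank; variants farther away than
that cannot affect a 5 bp flank unless they are longer than the pad,
which overlap-removal screening makes irrelevant at these scales.

**Effective variants.** In a tandem repeat the two contexts can be
prefix/suffix/substring of one another; the variant is then extended —
right while one context is a prefix of the other, left for a suffix,
and for an interior substring on whichever side resolves in fewer steps
(both directions are simulated; ties go left). Each step appends or
prepends one reference base to both contexts (outside the variant, both
haplotypes equal the reference between the site and its phased
neighbors, which are already inside the flanks). Extension terminates
when the contexts are no longer in relation, when the effective
reference span exceeds effective_len_limit (default 70 bp; the site is
then disregarded), or when it runs past a contig end (also
disregarded). The step loop is additionally bounded so degenerate
repeats terminate.

**Cohorts.** Sites whose footprints are within cohort_distance (default
25 bp, measured end-to-start) chain transitively into cohorts. Each
cohort carries two combined haplotype strings spanning its reference
interval plus flank_len anchor bases per side; members may have opposite
phase, so matching is by haplotype string, translated per member into a
REF or ALT call. A read containing one full haplotype string (and not
the other) is tallied for every member — it necessarily overlaps them
all, since the string spans the cohort. Reads that do not match a full
cohort string fall back to single-variant assignment.

## Assignment

**Naive.** A CIGAR walk extracts the read bases the aligner placed at
the variant's exact reference coordinates (plus any insertion anchored
inside the footprint); an exact match to REF or ALT is required,
anything else is OTHER. This reproduces what a pileup-reading tool
would conclude and is deliberately sensitive to gap placement.

**Context-aware.** Only the read *sequence* is examined. A context that
occurs in full anywhere in the read is a full match. A read that
truncates the context can only do so at one of its ends, so truncated
matching is end-anchored: a prefix of the context at the read's right
end (window anchored at the left variant boundary) or a suffix at the
read's left end (right boundary) — the two anchorings that make the
comparison independent of where the aligner placed gaps. An
end-anchored match is *decisive* only if it (a) covers the whole
anchored-side flank plus at least one allele base and (b) extends past
the first position where the two contexts diverge. Requirement (b) is
what enforces effective-variant coverage in repeats: there the contexts
share a long prefix, so only a read reaching through the tract can
decide, and anything shorter is undecidable. Calls: both matched →
BOTH; exactly one → that allele; only sub-decisive end overlaps → BOTH;
nothing at all despite the alignment spanning the effective interval →
OTHER (a sequencing error broke every match). Full matches outrank
end-anchored ones so a coincidental few-base collision at a read end
cannot override an exact context occurrence (at 150 bp reads a 6-mer
end collision occurs at the ~10⁻³/read level).

Matching is exact — no mismatches are tolerated inside the context
window — so sequencing errors attenuate evidence rather than corrupt
it; this is why long indels remain harder (more bases, more chances for
a disrupted match).

Per-site evidence records n_ref/n_alt/n_both/n_other, the number of
overlapping reads whose truth interval lies elsewhere (simulation
only), and the mean MAPQ of *all* overlapping reads — MAPQ
characterizes the locus, not the called subset.

## Bias classification

With NMB = MB − SB and NAB = AB − SB, rule order (ties resolve to the
earlier rule): balanced if √(NMB² + NAB²) ≤ 0.1 (boundary inclusive);
loss if NMB and NAB share sign and |NMB|/2 ≤ |NAB| ≤ 2|NMB| (wedge
boundaries inclusive; both upper-right and the rare lower-left
quadrant); else flux/local if |NAB| > 0.1, split by whether more than 5
overlapping reads are mismapped; else outlier. Undefined measures give
"unclassifiable", excluded from evaluation. The flux/local band is
keyed on |NAB| because those events are vertical displacements —
near-zero NMB with nonzero NAB; a configuration switch
(`blue_region_axis="nmb"`) implements the alternative |NMB| reading for
comparison. The mismap count uses reads *overlapping* the site (not the
assigned subset).

The bias-by-length summary stratifies ALT fractions by len(ALT) −
len(REF), clamped to ±25 (longer gaps collapse into the extreme
strata), reporting median and quartiles per stratum, optionally
normalized by subtracting the per-stratum median SB ALT fraction.

## Prediction on real data

Sites are first screened for phasing/representation artifacts: a site
is "affected" (excluded) when more than 90% of overlapping reads are
OTHER, or when one HET allele is entirely absent and more than 40% are
OTHER, or when coverage is zero. The remaining sites are ranked by

    score_mul = (MAPQ̄ − M)/M × AB
    score_add = (MAPQ̄ − M)/M × 1.5 + AB

with M the aligner's MAPQ ceiling (default 42; 60 for aligners scaled
to 60). Lower scores rank more biased — biased sites pair REF-skewed AB
with depressed mean MAPQ; a flip option inverts the orientation for
ALT-skew investigations. The 1.5 weight is exposed as configuration.
ROC curves and AUC use trapezoidal integration; the PR summary is
step-wise average precision, because trapezoids on a PR curve are
ill-defined when recalls tie.

## Scan mode

Pileup columns (from mpileup text or generated in-process from
alignments) are profiled: bases above 15% of counted A/C/G/T bases are
alleles; ≥ 2 alleles make an SNV column; a column is non-diploid when
more than two alleles pass, or when two or more pass and the top allele
is more than twice the runner-up. The dominance rule applies only with
≥ 2 passing alleles — a pure homozygous column carries no non-diploid
evidence. N and ambiguity codes are excluded from counts and
denominators; deletion placeholders count toward depth only.

Windows (default 400 bp, stride 100 bp) compute RD = mean depth, VD and
ND = fractions of SNV / non-diploid positions — fractions, not counts,
so the measures are depth- and window-length-invariant. Each becomes a
Z-score against a baseline of window means and standard deviations
sampled at random window starts: by default 1/1000 of possible windows
but at least 30, so small fixtures still get a usable baseline
(configurable; a user-supplied baseline skips sampling). Standard
deviations are floored at 10⁻⁹ and a window exactly at a degenerate
baseline mean scores Z = 0. The combined score truncates at 1 for RD
(only substantial depth *excess* counts) and at 0 for VD and ND.
Windows ≥ 5 are biased, [3, 5) suspicious (half-open, so labels
partition); qualifying windows merge per label, and same-label regions
within 1 kbp chain into one. A final shorter-than-window placement is
scored over the remaining positions and flagged truncated.

**Two-workflow comparison.** Both pileups are scored against one joint
baseline (half the sample from each) so neither workflow's scale
advantages it. A region biased in workflow A is "improved" by B when at
least 25% of its bases in B are simultaneously well covered (depth
above 1/5 of B's overall mean) and outside B's biased regions. Regions
whose mean depth in B falls below 1/20 of B's overall mean are excluded
as uninterpretable; the 1/20 factor is this package's quantification of
"low or no read depth".

## The synthetic-data generator

The generator is the package's study-condition source, not a fixture:
random uniform references, uniformly placed phased HET SNVs (optionally
on a jittered grid with a minimum spacing, for experiments where
per-site effects must not interact through shared reads), alternating
insertions/deletions up to a length cap, consensus construction for
both haplotypes with a coordinate map, and single-end read simulation —
Poisson read counts per haplotype at the configured coverage (default
15× per haplotype ≈ 30× total), uniform starts, i.i.d. substitution
errors (default rate 0.002), read length 150 bp, independent seeds per
haplotype so the two coverage profiles are uncorrelated. Defaults for
read length and error rate are the package's stand-ins for a NovaSeq-
class error profile and are exposed as configuration.

It deliberately does **not** emulate: quality strings or
position-dependent error rates, indel sequencing errors, paired-end
fragments, GC/PCR bias, or a real aligner's failure modes. The *oracle
aligner* places every read at its true interval with the maximum MAPQ,
deriving the CIGAR from the coordinate map (unanchored inserted read
ends are soft-clipped, mirroring how reads that only partially overlap
an insertion align in practice). Consequently, passing tests show the
measurement and classification machinery is correct *given* an
alignment; they say nothing about any specific aligner's bias, which is
exactly the separation the tool needs — bias is introduced only through
the controlled injections:

* **loss** — each ALT-haplotype read overlapping a target site is
  dropped with probability f. With SB = 0.5 the expected MB is
  1/(2 − f); sites cross from balanced into loss once the diagonal
  displacement exceeds the 0.1 circle, analytically at f ≈ 0.26.
  Nearby target sites with opposite phase thin both haplotypes through
  shared reads and cancel — loss experiments therefore space their
  target sites beyond read length.
* **flux** — n foreign reads (default MAPQ 0) are added at the site,
  carrying the local reference sequence and a truth interval on a
  synthetic decoy contig: AB is displaced REF-ward while MB is
  untouched, and the mismap counter sees them.
* **gap_shift** — for gap-bearing reads over target sites, the single
  internal gap is re-placed to the leftmost/rightmost score-equivalent
  position (equal mismatch count against the reference), sequence
  unchanged. This realizes gap-placement ambiguity: naive assignment
  degrades, context-aware assignment is unaffected.

One honest caveat, visible in the tests: when an SNV borders a
homopolymer and an error-free read starts or ends exactly at the
variant, the read's sequence fits both haplotypes and *no* sequence-only
assigner can decide it. Such reads are called BOTH and drop out of AB
only, so AB can differ from SB/MB in the last read at a handful of
sites even in a perfect null; the null tests assert exact equality
wherever no read was excluded, balance everywhere, and medians at 0.5.

## Problem sizes and determinism

The bundled experiments run at desk scale by design: the unbiased
headline run uses a 1 Mbp donor with ~1,000 SNVs (~200k reads,
seconds); loss analytics use 50 spaced sites at 100× per haplotype so
every site sees ≥ 200 reads; scan fixtures use 60–200 kbp tracks.
Every stochastic component takes an explicit seed and all pipelines are
pure functions of (inputs, seeds); CLI runs with identical inputs and
seeds produce byte-identical reports.

## Known limitations

Biallelic variants only (split multi-allelics upstream); no star
alleles; no CRAM; single-chromosome pipelines are orchestrated
per-chromosome by the CLI; no base-quality weighting or realignment;
long reads untested (scan mode is the natural fit there); the
prediction model uses exactly the two printed features and is weaker
for gaps, where local bias dominates and neither feature captures it
fully.
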