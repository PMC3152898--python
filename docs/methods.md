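# Methods

This note records the model behind each stage, the conventions and numerical
choices that were genuinely open, and what the synthetic-data tests do and do
not establish about real libraries.

## Virtual-tag geometry

A virtual tag is defined per mapping-enzyme site (`GAGCTC`) and side. On
each side, the candidate anchor is the *nearest* fragmenting-enzyme site
(`CATG`) by anchor start; the tag is the 21 bases beginning at that anchor
and reading toward the mapping site, stored CATG-first (minus-strand tags
reverse-complemented). The tag is emitted only when its 21-bp footprint
does not overlap the mapping site — touching it is allowed, so an anchor
starting exactly 21 bp upstream of the site still yields a tag. When the
nearest anchor is too close (including anchors overlapping the site
boundary) the side is skipped with a log message; there is **no fallback**
to a farther anchor, mirroring the physical protocol in which the nearest
site is the one that cuts. Tags containing N are dropped. Any consistent
orientation convention would work as long as extraction and the database
agree; this one (anchor + 17 bases toward the site) follows the
SAGE/digital-karyotyping convention that the 21 bp include the CATG.

`unique` is computed by exact genome-wide occurrence counting of the
21-mer on both strands (a 21-mer is never its own reverse complement, so
the two strand counts add without double-counting). Non-unique tags are
retained in the database and excluded at mapping time, which keeps the
mapped-fraction semantics of the report explicit.

Coordinates are 0-based half-open internally; every emitted file is
1-based.

## Ditag extraction

Reads are scanned greedily left to right over their CATG anchors. From the
current anchor, successive anchors are examined until the internal span
(bases strictly between the two CATGs) reaches the accepted window
[32, 36] — bracketing the canonical 2·(21−4) = 34 by ±2, configurable; an
in-window anchor yields a ditag and becomes the shared starting anchor of
the next one, an over-window span abandons the current anchor. Given a
well-formed ditag, no spurious CATG can occur at internal offsets 32–33
(it would have to disagree with the true terminal anchor's own bases), so
greedy first-fit segmentation of error-free concatemers is exactly
lossless; anchors inside tags produce only sub-window spans, which are
passed over harmlessly.

Deduplication (default on) counts each distinct ditag sequence once,
treating a ditag and its reverse complement as the same molecule — the
standard guard against PCR duplicates in tag libraries. The original
software's exact length bounds and duplicate policy are not documented;
both are exposed (`min_internal`/`max_internal`, `--no-dedup`).

## Mapping and the fold-change scan

An observed tag is assigned iff its sequence matches exactly one virtual
tag with `unique=True`; everything else counts toward the total only.
Conservation (mapped + unmapped + non-unique-excluded = total) holds
exactly and is asserted in tests. Matching is exact — no one-mismatch
rescue — because error-tolerant matching would change what the mapped
percentage means.

The detector slides a window of W = 20 consecutive unique virtual tags,
advancing one tag at a time (the window size is fixed by the assay
convention; a step was never published, and step 1 is the maximal-overlap
choice). The expected count is uniform genome-wide, E = W·F/U; a
per-chromosome expectation is available as an option since the original
viewer's normalization is undocumented. Amplification requires FC ≥ 3 and
deletion FC ≤ 0.1. A single qualifying window suffices for a call
(`min_windows` configurable): published amplicon tables contain
sub-kilobase entries, which rules out a multi-window requirement. Maximal
runs of *consecutive* qualifying windows of one direction merge into one
call; two qualifying windows separated by a non-qualifying one are two
calls. Call boundaries are the outer footprint of the run's constituent
tags, reported 1-based with size = end − start — the convention that
reproduces all fifty printed sizes of the bundled chromosome-7 amplicon
table exactly.

Note one consequence of genome-wide normalization: a spiked segment
contributes its own excess tags to F, so the measured fold of a lesion
covering a fraction φ of the genome's tags is fold·U/(U + L·(fold−1)) —
noticeably below the nominal fold when φ is large. Simulated genomes in
tests keep lesions small relative to the genome, as real lesions are.

## Power and PPV

The depth question ("how many tags to see a 3-fold, 38 kb lesion?") is
answered by explicit simulation rather than the closed-form calculation
cited in the source literature (whose formula is not restated there and is
deliberately not reproduced): a background of uniformly spaced unique tags
(default 4 kb, matching the assay's ~0.004 Mb theoretical resolution), one
planted lesion, multinomial sampling of T tags, and the same window scan
and run merging as the detector. Power is the fraction of replicates with
a lesion-overlapping call of the right direction; PPV is reported both at
region level (true calls / all calls) and window level, because "PPV" is
ambiguous between the two. Binomial Monte-Carlo standard errors accompany
every estimate, and `solve_depth` searches the smallest depth meeting a
target PPV — its answer is a property of this null model and need not
match depth figures computed by other methods.

Power is monotone in fold, lesion size and depth *away from the calling
threshold*. At a fold whose true window FC sits at the threshold, power is
a knife-edge probability driven by sampling noise and genuinely decreases
with depth (deeper libraries fluctuate less across the threshold); the
monotonicity test therefore uses clearly sub- and supra-threshold folds.
The acceptance script reports power/PPV for a 3-fold, 40,584-bp lesion at
depth 821,252 with 1 kb tag spacing: at the default 4 kb spacing such a
lesion spans only ~10 of the 20 tags a window needs, the measured fold
saturates near 2, and the question is vacuous — detection of lesions this
size presupposes locally denser unique tags, as in gene-rich regions.

## qPCR statistics

Relative level = 2^(mean Ct_ref − mean Ct_target), replicates averaged per
channel before exponentiation; the estimator is invariant under any
constant Ct shift applied to both channels. A tumor is amplified when its
level strictly exceeds the normal cohort's mean + 2 SD; the SD uses the
n−1 denominator (the source does not say which; n−1 is the sample-statistic
default). Frequencies are rounded to the nearest integer percent, the
convention under which 23/52 → 44 and 11/52 → 21.

Cohort tests default to Student's pooled-variance two-sided t test (the
named test of the protocol), with Welch available by flag. DNA cohorts
(unrelated normal individuals vs tumors) are compared unpaired; expression
comparisons of tumor vs adjacent tissue from the same patients default to
the paired test — the pairing was never stated in the protocol and is
documented here as this package's choice. Bonferroni adjustment is
min(1, m·p) with m defaulting to the number of genes in the run.

Note that the mean + 2 SD rule carries an intrinsic per-sample false-call
rate of a few percent on near-threshold non-carriers, so a simulated
cohort in which 23 of 52 tumors truly carry a 3-fold amplification is
typically called at 44–52% — the calling rule, not an estimator bias.

## Synthetic data: what it emulates and what it does not

Genomes are i.i.d. uniform ACGT with every chance GAGCTC/CATG scrubbed
(single-base mutations, iterated to convergence) before sites are planted
explicitly, so ground truth is exact: planted coordinates are returned for
oracle tests. Each mapping site gets one flanking CATG per side at 21–51 bp
(guaranteeing two valid tags per site); background CATGs are planted at the
configured mean spacing but kept ≥90 bp from mapping sites so the flank
geometry survives. Stray motifs created at planting boundaries are scrubbed
in a final pass that never touches planted bases.

Reads are error-free by default (`error_rate` adds uniform substitutions);
the original extraction step does not model errors either. Tag sampling is
multinomial over virtual loci with weights equal to the covering segment's
fold — the simplest model consistent with tag counting. Defaults:
100,000-tag depth for unit-scale runs (the reference library's 821,252-tag
scale is used where a test is about that scale), mapping sites every 4 kb
(two tags per site), triplicate Ct tables with 0.2-cycle replicate noise —
the level at which simulated normal cohorts have the ~10% level SD seen in
real normal panels.

Because simulated duplicate ditags are genuine independent resamples (and
collide often inside high-fold spikes at realistic depths), quantitative
count tests run extraction with deduplication off; with real PCR
duplicates the default stays on.

What passing tests therefore show: the geometry, extraction, mapping
arithmetic, window statistics, merging rules and cohort statistics are
correct on data obeying the stated model. What they do not show: behavior
under sequencing error profiles, GC or restriction-site density bias,
repeat-driven non-unique tag structure, or adaptor contamination — none of
which the generator emulates.

## Degenerate inputs and tie-breaks

Chromosomes with fewer unique tags than W yield no windows (logged).
A zero-tag extraction is a valid result, not an error. Mapping with zero
total tags is rejected. A lesion spanning zero virtual tags returns power 0
with a warning. Thresholds must satisfy del < 1 < amp at configuration
time. Malformed tabular inputs (tag DB, counts, BED, Ct tables) are
rejected with line numbers. All randomness flows from a single seed per
run; reruns are byte-identical, and the pipeline manifest checksums every
output to make that checkable.
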