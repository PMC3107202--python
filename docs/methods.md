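# Methods

## Reference model

A cut locus is a top-strand sequence with two nick coordinates (0-based,
half-open): `nick_top` for the top strand and `nick_bottom` for the
top-strand position of the bottom-strand nick. The 5′ overhang spans
`[nick_top, nick_bottom)`; it defaults to 4 nt (FokI-type nuclease) but is
configurable per locus, since overhang geometry differs between enzymes.
Fill-in of 5′ overhangs is assumed, so the retained left fragment of a
derivative ends at `nick_bottom`, the retained right fragment starts at
`nick_top`, and a perfect join duplicates the overhang bases on both
reciprocal derivatives. The filled-in blunt end is the zero-deletion state
from which all deletions are measured. `N` is legal in references but
never matches during annotation.

## Annotation conventions

Reads are anchored by an exact seed (default 15 nt, both orientations: a
read is reverse iff only its reverse complement seeds to both flanks) and
extended maximally with exact matching — no mismatch tolerance, reflecting
Sanger-grade amplicon consensus reads; quality trimming, if needed, is an
upstream concern. The left match never extends past the left blunt end
and the right match never before the right blunt start, so deletions are
never negative.

Because exact prefix/suffix matches are downward closed, the decomposition
maximizing total matched length is attained at the two maximal extensions;
ties among seed placements prefer the longer extension, then the smaller
left start / right start. If the matches overlap by `m` read positions,
those bases fit both flanks and are reported as microhomology; breakpoint
ambiguity inside the microhomology is canonicalized by measuring each
deletion to the microhomology's **outer** edge, charging the shared bases
to neither end. Whether the original scoring charged them inward or
outward is not documented for the data this mirrors; the outer-edge rule
is this package's convention, chosen because it makes `del_total`
well-defined and reconstruction exact. If the matches leave a gap, the
gap is the insertion and microhomology is 0: microhomology is scored only
at direct joints, and insertion-bearing junctions are excluded from
microhomology distributions (their `flanking_mh` is recorded separately by
the insertion-derivation step).

Ends with variable cleavage are handled by a per-locus
`variable_terminal_bases = v`: a putative insertion consisting solely of
≤ v copies of the right fragment's terminal base is attributed to cleavage
variability, absorbed into the bookkeeping, and flagged
(`terminal_rule_applied`) rather than scored as an insertion. This
generalizes the terminal-G case seen with one common nuclease geometry
instead of hard-coding the base.

Every annotation is verified internally by reconstruction: retained left
prefix + insertion + retained right suffix (microhomology written once)
must equal the read byte-for-byte; failure raises rather than returning a
wrong record.

Insertion derivation (inserts ≥7 nt by default) searches both strands of
both parental loci, optionally within a window of the cuts, for an exact
full-length copy; ties resolve left locus before right, forward before
inverted, smallest start. `flanking_mh` is the summed exact repeat length
between each insert edge and the retained parental sequence adjacent to it
— the classic primer-realignment signature of templated inserts.

## Summary statistics

Per genotype: `pct_without_mh` and `pct_with_insertions` are percentages
of **all** junctions (the denominator choice is ambiguous in comparable
published tables; totals suggest insertion junctions are included, and
they count as "without microhomology" here since mh is only scored at
direct joints). The microhomology distribution and median combined
deletion are over simple-deletion junctions only; the median insertion
length is over insertion-bearing junctions; `pct_long_insertions` counts
inserts >50 nt (configurable) over all junctions.

## Chance null

With per-position match probability `m = Σ p_b²`, the two-sided null
`P(k) = (k+1)(1−m)² m^k` is the convolution of the two independent
geometric runs the annotator's bidirectional extension produces, so
null-vs-annotation consistency is a testable property, verified by
chi-square on 10⁵ simulated unbiased junctions. The two-sided variant is
the default because it matches the annotation convention; the one-sided
`(1−m)m^k` is provided since published chance calculations do not always
state their convention. The pmf carries an open tail bin at `max_len`
(default 10) holding the remaining mass, and sums to 1 by construction.

When comparing a genotype to the null with a rank test, the null is
represented by a seeded Monte-Carlo cohort (default 10,000 draws) scored
by the same two-run rule, so both samples live on the same discrete scale.

## Statistical tests

Mann-Whitney U is two-tailed with `p = 2·min(one-sided)` capped at 1.
When `C(n_x+n_y, n_x) ≤ 2·10⁵` the p-value is exact by enumerating all
group assignments of the pooled multiset (ties handled exactly);
otherwise scipy's tie-corrected normal approximation is used. Fisher's
exact test is the standard two-sided hypergeometric sum. The t-test is
pooled-variance Student by default — matching the common "two-tailed
unpaired t-test" phrasing — with Welch behind a flag.

## Frequency estimation

For a plate with `w` wells at `c` cells/well and `k` positive wells,
`naive = k/(w·c)` and `poisson = −ln(1 − k/w)/c`. The naive estimator is
the default report (it matches the magnitudes such assays usually quote);
the Poisson correction accounts for multiple events per well, matters
little at the frequencies involved (~10⁻⁴ at 208 cells/well), and is
undefined at saturation, which raises with advice to dilute. Fold-change
recovery across replicate plates is evaluated as the ratio of mean
estimates (pooled), not the mean of per-plate ratios: single plates at
~3 positive wells make per-plate ratios wildly biased (Jensen's
inequality) and undefined whenever the denominator plate has zero
positives.

Surveyor: `% indel = 100(1 − √(1 − f))` with exact inverse
`f = 1 − (1 − indel/100)²`; colony hybridization: percent of colonies
hybridizing with neither unmodified-locus probe.

## Synthetic generator

Defaults (one choice, applied throughout): resection per end is
`resection_min + Geometric(p)` with `resection_min = 5`, `p = 0.05` (mean
≈ 24 nt/end) — short-range resection on the scale implied by observed
combined deletions (tens of nt), with a minimum reflecting that
annealing-mediated joining requires some exposed single strand. The
minimum also keeps the annotator's boundary truncation of chance
microhomology runs negligible (< 10⁻⁴ per junction), so unbiased cohorts
follow the analytic null. Joints anneal at the longest microhomology
exposed in the resected windows with probability `w/(1+w)`
(`mh_bias_weight = 4` for Lig3-proficient-like cohorts, 0 for deficient
ones, 9 as the strong-bias setting in discrimination checks), ties
resolved deterministically toward the unresected ends. Insertions occur
with total probability 0.20 (0.25 in the long-insert-prone preset), of
which an absolute 0.028 (0.135 in that preset) are long templated inserts
of ≥51 nt with geometric excess (mean 24); short inserts are templated
with probability 0.5 from within 100 nt of a cut (inverted half the time)
or untemplated with geometric length (mean 4 nt). These rates echo the
insertion percentages and long-insert fractions reported for comparable
genotype panels. Truth records are produced by passing each constructed
sequence through the annotator itself, because intended parameters are
not always recoverable (an insert edge can coincide with reference
sequence, resected ends can expose coincidental identity); independence
of the verification chain comes from the exhaustive-decomposition oracle
in the test suite, which shares no code with the annotator.

What the generator does **not** emulate: sequencing error and chimeric
reads (annotation is exact-match), locus-specific base composition (the
chance null assumes the supplied composition), canonical-NHEJ competition
kinetics, multi-breakpoint rearrangements, and cell-to-cell variability
in cutting. Passing tests therefore demonstrate correctness of the
decomposition and statistics under the generative model, not robustness
to real-read artifacts. One known internal tension: deterministic
closest-to-end tie-breaking concentrates annealed joints near the blunt
ends, so strongly biased cohorts show smaller median deletions than
unbiased ones, whereas observed deletion distributions are similar across
genotypes; the tie-break is kept for reproducibility and the discrepancy
confined to the deletion (not microhomology) margin.

Plate simulation draws each well positive with probability
`1 − exp(−f·c)`, the exact Poisson-sampling model the corrected estimator
inverts.

## Numerical and size choices

Chi-square tests pool trailing bins below 5 expected counts. Exact
Mann-Whitney tolerates 1e-9 when comparing U values to handle float ties.
Fold changes round half-up (`decimal`), as printed ratios usually are.
The consistency suites use 10⁵ junctions (10 per random reference pair,
so reference-specific match-run correlations average out), 1,000-junction
oracle suites on ≤200-nt references, 100-repetition power checks with
200-junction cohorts, and 2,000-plate estimator checks — sizes at which
every stochastic margin is several standard errors wide while the whole
suite runs in well under a minute.
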