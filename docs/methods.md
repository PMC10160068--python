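# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what each computation assumes,
which knobs matter, and what the synthetic validation does and does not
demonstrate.

## Abundance model

Relative abundance is quantified as TPM over all contigs in a sample:
`TPM_i = (c_i/L_i) / Σ_j (c_j/L_j) × 10⁶`, where `c_i` counts alignment
records surviving the minimum aligned-length filter and `L_i` is contig
length in bp. Conventions:

* **Aligned-length filter.** The default is *inclusive*, `aligned_length ≥
  30 bp` (matching a 30 bp minimum seed), with a `strict` flag for the `>`
  reading. The filter operates on the aligned block length, not query
  coverage.
* **Multi-mapping.** Every alignment record counts once; no fractional
  weighting. This is the simplest auditable rule and is what the tests pin.
* Column sums are exactly 10⁶ whenever at least one read survives;
  otherwise the column is all-zero and flagged in the log, never NaN.

## Dereplication

Greedy longest-first clustering: sequences sorted by length (ties broken
lexicographically by id, making results order-independent), each joining the
first representative with alignment identity ≥0.95 and coverage of the
shorter sequence ≥0.8, else founding a new cluster. Identity comes from the
best local alignment (match +1, mismatch −1, gap −2; all configurable) with
the denominator counting aligned columns *including internal gaps* — an
explicit convention so tests can be exact; replicating any particular tool's
internal identity definition bit-for-bit is a non-goal. A shared-16-mer
prefilter skips hopeless pairs; for sequences of ≳200 bp any pair clearing
the default thresholds must share an exact 16-mer run (pigeonhole on ≤5%
errors over ≥160 aligned columns), so the prefilter cannot change results at
those sizes, which the oracle-equivalence test verifies. Comparison is
forward-strand; reverse-complement clustering is left to the caller.

## Viral taxonomy voting

Per-gene hits are reduced to the single lowest-E-value hit per gene (the
rule counts genes, not hits; default E-value ceiling 10⁻⁵). A contig is
eligible when ≥20% of its genes have hits, or — for contigs with fewer than
ten genes — when at least two genes have hits. Both thresholds are
inclusive. The lineage ranks of the hit genes are then walked from most to
least specific and the contig is assigned at the deepest rank where a single
taxon (lineage prefix) collects ≥60% of *all* hit genes — the denominator is
genes-with-any-hit, not genes resolvable at that rank. If no rank qualifies
the contig stays unassigned; there is deliberately no fallback to a root
taxon. Two taxa can never both reach 60%, so ties cannot arise at the
assignment threshold.

## CRISPR arrays and the spacer burden

The detector finds maximal chains of ≥3 exact copies of a direct repeat
(length 23–55 bp) separated by gaps of 20–60 bp (the spacers). Candidate
(repeat, chain) pairs are ranked repeat-length descending, then start
position, then repeat text, and accepted greedily without overlap —
deterministic by construction. Successors in a chain are the *nearest*
next occurrence within the gap window. Exact matching (0 repeat mismatches)
is the default and the only implemented mode; the tolerance exists as a
parameter so the interface does not change if degenerate-repeat support is
added. N never matches in any exact-match operation.

The spacer burden of a sample is `M = Σ (N/L · A)` over CRISPR-carrying
contigs, with `N` the spacer count summed over all arrays on the contig
(the literal reading of "spacers in contig"), `L` the contig length, and
`A` the contig's TPM in that sample. M is computed per sample; condition
summaries are means over samples. M is linear in the abundance column.

## Host linkage

* **CRISPR channel:** a spacer (≥18 bp; shorter ones are rejected with a
  warning) links its contig to every viral contig containing it on either
  strand with ≤`max_mismatch` mismatches, no indels; default 0. Matching is
  at the nucleotide level — the standard protospacer convention — and
  self-contained, rather than delegating to protein-level spacer tools.
* **tRNA channel:** full-length, 100%-identity match (either strand)
  between a viral and a prokaryotic tRNA gene; "perfect match" is read as
  full-length identity, the conservative interpretation.
* **Prophage channel:** the contig a prophage is embedded in is its host;
  intervals are validated against contig bounds (0-based, half-open, as all
  internal coordinates).
* Merging deduplicates on (phage, host contig, channel) — the same pair
  found by two channels keeps both rows, and phages linked by ≥2 distinct
  channels are counted. Genus-level summaries use only links whose host has
  a genus annotation. The ex-situ channels are the same two matchers applied
  to a user-supplied reference table; no database ships with the package.

A phage is **polyvalent** when linked to ≥2 distinct host genera. The
count-basis fraction divides by host-linked phages; the abundance basis
weights each linked phage by a TPM column. Both are `None` (reported
not-applicable) when nothing is linked.

## Defense profiling semantics

"Relative abundance of contigs with system X" means the summed TPM of the
*contigs* carrying X, not per-gene copy abundance: a contig with three RM
systems contributes its TPM once to RM; a contig with RM and Abi contributes
once to each. Carrier fractions count each carrying contig once. Family
proportions normalise by total defense TPM within a grouping and sum to 1
whenever the denominator is positive, as do subtype shares within a family
(mass without a subtype label is reported as `unknown`). Condition-level
profiles are means over per-sample profiles — not pooled reads — so that
group comparisons go through per-sample t-tests. "Lysogenized prokaryote"
means a prokaryotic contig listed as a prophage host.

## Statistics

Implemented directly in numpy with explicit conventions (scipy supplies
only reference distributions; scipy/scikit-bio serve as independent
cross-checks in the test suite):

* Shannon uses the natural log (`H = −Σ p ln p` over positive entries).
* Bray–Curtis `d = 1 − 2Σmin(x,y)/(Σx+Σy)`; bounded in [0,1]; the triangle
  inequality is not asserted.
* PCoA is raw classical scaling (double-centred `−D²/2`, symmetric
  eigendecomposition). Negative eigenvalues are reported, never folded into
  coordinates; variance explained is over positive eigenvalues; each axis's
  first non-zero loading is made positive, fixing the sign convention. No
  Cailliez/Lingoes correction by default.
* Mantel correlates upper-triangle vectors, Spearman by default (the ρ
  convention of the field), permuting one matrix's row/column labels
  jointly; one-sided "greater"; `p = (1+#{perm ≥ obs})/(1+n_perm)`, so
  p ≥ 1/(n_perm+1). An exhaustive mode enumerates all n! permutations for
  small n. The permutation count is a free parameter (999 in the analysis
  scripts), not an inference about any particular study's settings.
* t-tests: pooled-variance Student by default, Welch optional; two samples
  with zero variance and equal means give t=0, p=1; with unequal means this
  is an error rather than an infinite statistic.
* Where many tests are screened together, Benjamini–Hochberg q-values are
  reported alongside raw p — a package convention, not a claim about how
  any prior analysis corrected.

## Synthetic communities and what they show

The generator emulates the *data layout* and *statistical structure* of a
two-condition drinking-water study: genus-structured prokaryotic contigs
(lognormal genus and contig effects), i.i.d.-uniform viral contigs ≥1.5 kb
(so spurious 32-mer spacer matches have negligible probability), verbatim
prophage insertions, CRISPR arrays with exact repeats whose viral-sourced
spacers occur verbatim on a recorded strand in exactly one viral contig,
shared tRNAs, defense annotations drawn from configurable family weights,
and per-sample multinomial reads with counts ∝ abundance × length.

Condition effects: carrier/lifestyle status is a per-contig property, so
the configured per-condition rates (defense-carrier abundance, lysogeny) are
realised as *abundance tilts* — flagged contigs are rescaled so their
expected TPM-weighted share in a sample of that condition equals the
configured rate. Defaults keep the directions and effect sizes of the
motivating setting: defense-carrier rates 0.14 vs 0.02 (a ~7-fold
disinfection effect), lysogeny 0.3 vs 0.1, virome share 1.4% vs 0.3%,
defense family weights RM .51 / CRISPR-Cas .15 / BREX .08 / Abi .06 /
CBASS .05 / other .15. Community sizes are desk-scale by design (8 genera ×
12 contigs, 60 viral contigs, 10 samples per condition, 2×10⁴ reads per
sample) so a full run takes seconds; the statistical-power loop uses a
further reduced community (16 viral contigs, 1 500 reads, 20 samples per
condition, 200 replicates).

Spacer flanks are guarded during generation: adjacent spacers always differ
in their first and in their last character, which provably prevents a chain
of single-base-extended repeats from outranking the planted repeat, so
planted arrays detect exactly as planted without ever mutating a
viral-sourced spacer.

What passing tests show: the pipeline's bookkeeping is exact (perfect
precision/recall against planted truth at zero noise, conservation laws,
oracle equivalences) and its tests are calibrated (type-I error ≈5%, power
≥0.9 for the planted lysogeny contrast). What they do not show: robustness
to real-data phenomena the generator deliberately omits — sequencing error,
chimeric assembly, degenerate CRISPR repeats, partial prophages, strain
mixtures, compositional biases, database incompleteness. Absolute synthetic
values (e.g. Shannon ≈4.4 at ~150 contigs) are not comparable to survey
values computed over tens of thousands of contigs.

## Degenerate inputs and numerical choices

Validation errors, not silent coercion, for: duplicate ids, non-IUPAC
characters (ambiguity codes other than N are mapped to N with a warning),
negative aligned lengths, out-of-bounds prophage intervals, unknown contig
references, empty group labels, all-zero diversity input, asymmetric or
non-finite distance matrices. Distance-matrix symmetry tolerance is 1e-12
with an exactly-zero diagonal. PCoA treats eigenvalues above a 1e-10
relative floor as positive. Mantel's ≥ comparison uses a 1e-12 slack so
exact ties count as "as extreme". All randomness flows from explicit seeds;
the generator derives fixed per-stage child streams from the master seed so
stages are independently reproducible, and pipeline reruns with the same
config are byte-identical.

## Known limitations

* The CRISPR detector requires exact repeats; real arrays with degenerate
  repeats will be fragmented or missed. It is a validation stand-in with a
  clean definition, not a replacement for dedicated detectors.
* Spacer↔protospacer matching is nucleotide-exact by default; distant
  protospacers found by protein-level tools will not be recovered.
* Dereplication is greedy and forward-strand; clusters depend on the
  length ordering exactly as in the underlying greedy strategy.
* TPM columns are compositional; no compositional-data correction is
  applied anywhere, and Pearson correlations between shares should be read
  with that in mind.
* The pipeline consumes upstream annotations (defense systems, lifestyles,
  prophage coordinates, gene hits) as given; it does not re-derive them
  from sequence.
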