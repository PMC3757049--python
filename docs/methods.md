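# Methods and design notes

This note records the statistical conventions, the genuinely open design
choices and the limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Site classification

Alignments are annotated per column as exon / intron / UTR / intergenic,
with a reading frame (codon position of the block's first column) on
every exon block. Two masks drive all downstream statistics:

* **ungapped** — complete deletion: any column containing `-` or `N` in
  any sequence is dropped. `N` is treated as a gap because a miscalled
  base would otherwise fabricate polymorphism. Pairwise deletion is
  deliberately not offered; one behavior keeps every statistic's
  denominator unambiguous.
* **silent** — ungapped non-coding columns plus exon columns whose
  observed variants are all synonymous. The synonymy rule is strict: a
  column qualifies only if every observed base leaves the amino acid
  unchanged in *every* sequence's codon context (codons containing gaps
  are skipped). Monomorphic exon columns qualify trivially. This differs
  from fractional synonymous-site counting (as in DnaSP or the NG86
  machinery below): silent-site counts and hence per-site rates are not
  numerically interchangeable with tools using fractional sites. Exon
  columns whose codon is truncated by a block edge cannot be assessed
  and are excluded, conservatively.

Coordinates are 1-based inclusive in every file and report; internals
are 0-based numpy indices.

## Diversity and differentiation

* π is the mean number of pairwise differences per masked site,
  uncorrected. Its SD is a 1000-replicate site bootstrap with an
  explicit seed — an analytic variance would be an alternative, so SDs
  are not expected to match tools that use one.
* Tajima's D uses total (not per-site) pairwise differences, S from the
  masked columns, and the standard constants; S = 0 or n < 4 yields an
  explicit "undefined" flag rather than NaN. No p-value approximation is
  provided.
* d_XY applies the Jukes–Cantor correction to the *mean* between-group
  p-distance (not per pair, matching the common d_XY convention and
  stabler on small panels); d_A = d_XY − (JC(π₁)+JC(π₂))/2 holds as an
  identity. F_ST is Hudson–Slatkin–Maddison 1 − H_w/H_b with H_w =
  (π₁+π₂)/2 and H_b the uncorrected mean between-group p-distance. This
  estimator was chosen because it admits the small negative values that
  unstructured panels genuinely produce. π itself is reported
  JC-uncorrected.

## Conversion-tract detection

Informative sites are polymorphic positions where the two groups'
majority alleles differ, each at frequency ≥ `min_fixation` (majority
ties break lexicographically). The default 1.0 demands fixed
differences; detecting tracts requires relaxing it below 1 − 1/n_rec,
since a converted site is by construction not fixed in the recipient
group (2 carriers among 6 recipients leave the majority at 2/3).

Runs are maximal stretches of *consecutive informative sites* (other
polymorphisms in between do not interrupt them) at which the same
non-empty subset of recipient isolates carries the donor group's
majority allele; when the carrier set changes the run is split, so each
tract names one recipient subset. A run of k ≥ 2 sites is reported iff
p = ∏ψ_i ≤ α (default 0.05), ψ_i being the carrier frequency in the
recipient group. Both directions are scanned. Indel events appear in
the polymorphism table (one row per maximal gap run with an identical
gapped-taxon set) but never participate in tract scoring.

The polymorphism-table specificity classes extend the natural four
(group-specific and segregating-within, for each group) with `fixed`
(both groups monomorphic for different alleles) and `shared` (both
segregate); without an outgroup the polarity of a fixed difference is
unknowable, so it gets its own class rather than an arbitrary side.

## Parsimony splits

Candidate non-trivial splits are enumerated exhaustively (2^(n−1)−n−1
of them; guarded at 20 distinct sequences) rather than built
incrementally — at panel sizes around a dozen taxa this is trivially
affordable and much easier to verify. The quartet index used is

    w(A|B) = min over a,a'∈A, b,b'∈B of [ s(aa'|bb') − min(s(ab|a'b'), s(ab'|a'b)) ]

with s counting clean xx|yy columns; a split is accepted iff w > 0.
Subtracting the *smaller* cross-pairing is a deliberate choice: it lets
two equally supported conflicting characters yield both splits — the
boxes that make split networks informative — while on homoplasy-free
tree data the accepted set is still exactly the generating tree's
splits, and at most two of a quartet's three pairings can score
positive, which guarantees weak compatibility (verified exhaustively in
tests via the four-taxon restriction criterion). Trivial splits are
always included, weighted by the taxon's private-state column count.

Identical sequences are collapsed before analysis (and before
bootstrapping) and re-expanded in the output with node sizes; bootstrap
support is the fraction of site-resampling replicates whose split set
contains the same bipartition. Layout/rendering is out of scope; the
NEXUS export is viewer-compatible.

## Divergence statistics

* Tamura 3-parameter: θ is the mean GC fraction of the two sequences
  over the jointly ungapped columns; gaps are removed pairwise (the
  natural choice for two-sequence comparisons); SEs are 1000-replicate
  site bootstraps (saturated replicates skipped). Indels are counted as
  events (one maximal gap run = one indel) for reporting only.
* dN/dS is Nei–Gojobori 1986 by construction: fractional site counts
  per codon (changes to stop codons count as non-synonymous, keeping
  sites_syn + sites_nonsyn = 3 × codons), site totals averaged over the
  two sequences, multi-difference codons averaged over all minimal
  mutational pathways with stop-crossing pathways discarded (all kept
  if every one is blocked), and separate Jukes–Cantor corrections. A
  maximum-likelihood codon model (the yn00 style of analysis) would
  give modestly different values; NG86 was chosen as deterministic and
  desk-checkable, and it cross-checks exactly against an independent
  implementation in the test suite.
* CAI is the geometric mean of relative adaptiveness w = usage/max-in-
  family over scored codons, excluding Met, Trp and stops; zero-usage
  codons are floored at a configurable ε (default 0.01) with a warning.

## Cross analysis

Diploid/aneuploid progeny — any progeny scored "both" at any marker —
are removed from numerator and denominator before frequencies are
computed. No mapping function is applied (cM = 100 × rf): at the ≤ 5 %
frequencies these experiments produce, interference corrections are
negligible. The chi-squared test is the two-class goodness of fit
(recombinant vs non-recombinant, 1 df, no continuity correction) of the
observed count against n × (region_kb/kb_per_cM)/100; this convention
reproduces 14.75 for 0 observed vs 14.4 expected in 600. The companion
expectation at 511 kb/cM recomputes to 2.831 (p = 0.0924) where 2.81
(p = 0.093) is the printed value — consistent with ~1 % rounding of the
region length in the source; the discrepancy is documented rather than
absorbed. Crossover intervals use the fewest-switches interpretation;
unscored markers inside a switch widen the interval and flag it
ambiguous.

## Synthetic data

The generator sprinkles sites parametrically rather than simulating
genealogies: tests need exact control over fixed, group-private,
pool-wide and converted site structure, not coalescent realism. Site
classes are disjoint by construction. Defaults mirror the emulated
study design: 7 + 6 isolates; locus lengths of a few kb; per-site rates
of order 10⁻²–10⁻³ giving the tens-of-segregating-sites regime of real
loci.

* Within-group and pool-wide variants draw a *minor-allele* carrier
  count in 1..n/2. The default spectrum is the folded neutral spectrum
  P(c) ∝ 1/c + 1/(n−c), under which θ_π and θ_W agree in expectation
  (so Tajima's D nulls centre on zero) while the group's majority
  allele always stays ancestral — within-group variation can therefore
  never fabricate informative sites, and planted tracts stay contiguous
  in the informative-site ordering.
* `theta_shared` (carriers drawn across both groups) exists because
  group-private sprinkling alone cannot emulate panmixia: private
  polymorphism contributes more to between-group than to within-group
  heterozygosity, biasing F_ST upward even with no fixed differences.
  The panmictic/autosomal regime is `delta_fixed = 0` with only shared
  polymorphism.
* Conversion plants copy the donor group's alleles into chosen
  recipients over k consecutive fixed-difference sites nearest a target
  location.

What the generator does *not* model — genealogical correlation between
sites, recombination within a locus, recurrent mutation, sequencing
error, indel evolution — bounds what passing tests show about real
data: estimator correctness and planted-signal recovery, not robustness
to homoplasy or alignment error. In particular the tract-detection
false-positive null is structurally clean (recipients can only carry
donor alleles through planting), so the measured null rate tests the
scanner's bookkeeping, not its behavior under recurrent mutation.

## Problem sizes and determinism

Test and acceptance runs use panels of 6–13 taxa and loci of 0.4–5 kb,
null ensembles of 100–200 replicates, and bootstraps of 20–200
replicates (1000 remains the production default) — sizes chosen to keep
the full suite fast while leaving Monte-Carlo error well inside the
asserted bands. Every stochastic routine takes an explicit seed and is
bit-reproducible; statistics that are undefined on degenerate input
(S = 0, H_b = 0, saturated distances) return explicit flags or typed
errors rather than NaN.
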