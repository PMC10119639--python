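# Methods

This note documents the models implemented in genomedyn, the defaults and
why they hold, the synthetic-data generators and what passing recovery
tests do and do not establish, and the numerical choices made where the
design was genuinely open.

## k-mer genome sizing

The estimator is the survey identity `genome size = total k-mer
instances / peak depth`. The procedure reads a depth histogram (distinct
k-mers per depth), finds the *valley* — the first local minimum of count
against depth, which separates the sequencing-error tail from genomic
k-mers — and the *peak* — the count argmax at depths beyond the valley.
Instances at depths at or below the valley are excluded from the total.
Peak finding operates on the raw histogram; an optional 3-bin moving
average (off by default) is available for ragged histograms. A histogram
that only decreases has no identifiable coverage peak and is rejected with
advice to supply a manual cutoff; a single-depth histogram needs no cutoff.

Whether the error tail should be excluded from the instance total is not
settled usage, so the cutoff is a reported, configurable parameter
(`excluded_low_depth` in the output). Heterozygosity estimation from the
two-peak structure is deliberately not implemented: it requires a mixture
model this package does not claim.

## LTR-RT insertion dating

At insertion the 5′ and 3′ terminal repeats of an LTR retrotransposon are
identical; each then accumulates substitutions independently. The pipeline
globally aligns the two repeats, computes the proportion *p* of differing
gap- and N-free columns (gap and N columns are excluded from numerator and
denominator alike), corrects for multiple hits with Jukes–Cantor
*K* = −¾ ln(1 − 4p/3), and dates the insertion as *T = K/(2r)*.

* **Alignment.** An in-repo Gotoh/Needleman–Wunsch with match +1, mismatch
  −1, gap open −2, gap extend −0.5 and fully deterministic tie-breaking
  (diagonal, then vertical gap, then horizontal). A fixed, specified
  aligner keeps the whole dating chain reproducible and oracle-testable;
  the kernel is numba-compiled with rolling score rows so 5-kb repeats
  align in well under a second. Raw *p*-distance is available via
  `correction="raw"` for comparison with uncorrected pipelines.
* **Rate.** *r* defaults to 1.33×10⁻⁹ substitutions per site per *year*,
  the unit in which the formula *T = K/2r* is conventionally applied. For
  rates quoted per generation the CLI accepts `--per-generation` together
  with `--generation-years` (default 3), which differ three-fold for a
  3-year generation time — the choice is surfaced rather than silently
  made.
* **Saturation.** *p* ≥ 0.75 is outside the JC domain; such elements are
  reported undatable rather than clamped.
* **Solo-LTR screen.** Candidates are intervals (the upstream homology
  search is out of scope); a candidate is solo iff it overlaps no
  full-length element by ≥ 1 bp. Intervals are half-open, so touching does
  not count as overlap. The solo:paired ratio is reported to two decimals.
* **Rate curves.** Insertions are counted in half-open 0.1-My bins over a
  10-My horizon (both configurable); the accumulation curve is the
  cumulative count running from the present into the past. "Net increase"
  is implemented as insertions-per-bin of surviving elements: deaths are
  unobservable from a single genome snapshot, so this is the only reading
  computable from one assembly.

## Ks estimation and WGD detection

* **NG86.** *Ks*/*Ka* follow Nei & Gojobori (1986): per-codon fractional
  synonymous sites averaged over the two sequences, differences counted by
  averaging over all orderings of the changed positions, and JC correction
  of the proportions. Conventions (documented because usage varies):
  synonymous-site fractions are counted out of 3 per position with changes
  to stop codons treated as nonsynonymous; pathways through stop codons are
  excluded from the average, falling back to all pathways when every one is
  blocked. Codons containing a gap or ambiguous base in either sequence,
  and stop codons, are skipped. *ps* or *pn* ≥ 0.75 sets a saturation flag
  instead of a number. The 61×61 site/pathway tables are enumerated once at
  first use and are checked exhaustively against an independent enumeration
  oracle in the test suite. NG86 was chosen over ML codon-model estimators
  because it is fully specifiable and oracle-testable; for the proportional
  dating and peak-position uses here the difference is immaterial, but
  absolute *Ks* values are not interchangeable with ML estimates at high
  divergence.
* **Tandem filtering.** A pair is tandem iff both genes lie on one
  chromosome within 5 gene-order ranks (configurable). The rank-gap rule is
  a documented stand-in for the various definitions in circulation.
* **Chaining.** Anchors (gene pairs located by order rank) are chained
  into blocks that are strictly increasing in one genome and strictly
  monotone (either direction) in the other, with consecutive anchors within
  25 ranks on both axes. Extraction is greedy: the single best chain by
  O(n²) longest-chain DP (both orientations; ties prefer "same"
  orientation, then the earliest anchors) is removed and the search
  repeats while chains of ≥ 5 anchors remain. Anchors join at most one
  block. The first extracted chain is provably maximal and is checked
  against a brute-force oracle.
* **Block medians and peaks.** Each block's *Ks* is the median over its
  anchors (saturated values excluded; an even count takes the mean of the
  middle two; all-saturated blocks are undatable). Peak detection runs a
  Gaussian KDE (Silverman bandwidth unless overridden) on values in
  (0, *Ks*max = 2.0], and reports strict local maxima on a 512-point grid
  with height ≥ 5% of the global maximum — the floor suppresses ripple.
  Peak weight is the density mass of the basin between flanking minima.
  KDE-plus-maxima was chosen over mixture fitting because it matches how
  *Ks* peaks are read off distribution plots; reported locations are grid
  maxima, not fitted means. A degenerate all-identical sample returns a
  single peak at that value.
* **Proportional dating.** *t_event = t_cal · Ks_event / Ks_cal*, two
  decimals, calibrated by default against the core-eudicot γ triplication
  (*Ks* 1.51 at 117 Mya). The linearity assumes a constant synonymous
  clock across the interval — the standard, and acknowledged, caveat.
* **Syntenic depth.** Per-gene depth is the number of blocks whose rank
  span covers the gene on its own axis; the ratio reported is the mode of
  nonzero depths on each side.

## SNP filtering, inbreeding, selfing, diversity

* **Cascade order** (fixed, logged per rule): (1) keep biallelic SNPs with
  QUAL ≥ 20; (2) per-call masking — depth outside (site-mean/3, 3 ×
  site-mean) or GQ < 10 becomes missing; (3) drop sites at or within 5 bp
  of an indel; (4) drop sites with > 30% missing calls (the vcftools
  `max-missing 0.7` convention; an alternative reading of the missingness
  threshold as 20% is rejected as internally inconsistent with that
  setting); (5) drop MAF < 0.05; (6) drop sites failing the exact
  conditional HWE test at α = 0.001 (Wigginton-style; implemented in-repo
  and oracle-tested by direct enumeration, since no installed library
  exposes it); (7) drop sites inside the repeat mask. Site-mean depth in
  rule 2 is taken over calls that are currently non-missing, which makes
  the cascade idempotent on clean and on fully filtered tables; pathological
  depth configurations could in principle re-trigger rule 2 on a second
  pass, and the per-rule log makes that visible. Note the HWE rule is
  *expected* to remove most sites in strongly selfing populations — see
  `examples/05`.
* **Inbreeding.** Per individual, *F* = 1 − *O*/*E* with *O* the observed
  heterozygous-call count over the individual's non-missing sites and *E*
  the sum of 2p̂(1−p̂) over the same sites (p̂ from all non-missing calls at
  the site). This moment estimator stands in for SNP-based relationship
  estimators; individuals with no informative site are flagged, not forced.
  *F* = −1 (heterozygous everywhere) is a valid excess-heterozygosity
  bound. The conversion *s* = 2F/(1+F) is exact at inbreeding equilibrium
  and is applied per individual.
* **Diversity.** Per site, π = c(m−c)/C(m,2) with c alternate alleles
  among m non-missing alleles; window π sums site π over a 50-kb window
  and divides by the window length (monomorphic and unobserved positions
  contribute zero — the vcftools windowed-π convention). Windows start at
  25-kb multiples and must fit entirely on the chromosome; the window must
  be a positive multiple of the step.

## Synthetic data: what it emulates, and what it does not

All generators draw from a single numpy Generator per invocation, so equal
seeds give byte-identical outputs, and every emitted element/pair/individual
appears in its truth table exactly once.

* **LTR landscapes** place non-overlapping elements into a uniform-random
  genome; each element's two repeats evolve from one ancestral repeat by
  substitution-only JC69 for its age (per-branch divergence *rt*). Defaults
  are the recovery-study conditions: 500 elements, 5-kb repeats, 2-kb
  internal regions, ages uniform on [0, 5 My], *r* = 1.33×10⁻⁹/site/year,
  on a 15-Mb genome. A `solo_fraction` of elements is emitted as single
  repeats absent from the element table. Not emulated: indels (excluded by
  design so alignment and distance have closed-form expectations — indel
  handling is exercised by hand-built fixtures instead), nested insertions,
  rate heterogeneity among sites, and GC bias; recovery results bound
  estimator error under the substitution model only.
* **Paralog pairs** sample a target *Ks* from a mixture of Gaussian peaks
  (defaults: 0.13 and 0.6, sd 0.03, equal weight, 300 codons — the planted
  two-cohort benchmark) and apply synonymous-only single-nucleotide codon
  substitutions until the NG86-measured *Ks* first reaches the target, so
  truth and estimator share a scale and recovery tests carry no estimator
  bias. Unreachable targets (synonymous saturation) trigger regeneration
  with a warning. Not emulated: nonsynonymous divergence, codon-usage
  bias, alignment error.
* **Selfing genotypes** draw, per site of frequency *p*, genotypes with
  P(hom-ref) = (1−p)² + Fp(1−p), P(het) = 2p(1−p)(1−F),
  P(hom-alt) = p² + Fp(1−p); frequencies uniform on (0.05, 0.95) by
  default; 30 individuals × 50k sites, F = 0.84, matching the study-scale
  sampling. Sites are exchangeable — no linkage, population structure, or
  genotyping error — so F-recovery tests validate the estimator, not
  robustness to real panel artefacts.
* **k-mer histograms** give each of `genome_size` distinct genomic k-mers
  a Poisson(coverage) depth; error k-mers (default 20% of distinct k-mers)
  sit at depth 1 or 2 with P(depth 2) = 0.2 — the error-tail shape is this
  package's own assumption, stated because survey tools do not publish
  one. Repetitive k-mers (depth multiples of the peak) are not emulated.
* **Gene orders** plant non-overlapping strictly-monotone anchor runs
  (given as `(start_a, start_b, n_anchors[, inverted])`) plus uniform noise
  anchors that never duplicate a position. Uniform noise *can* by chance
  form a chainable run of ≥ 5 anchors; tests therefore judge spurious
  blocks against the brute-force oracle rather than assuming none.

## Problem sizes and tolerances

The recovery benchmarks run at the sizes stated above (500 elements / 5-kb
repeats; 1000 pairs × 300 codons; 30 × 50k genotypes; 1-Mb genome at 20×;
100 random chaining instances ≤ 200 anchors). Insertion-time recovery is
judged on the mean over elements — |mean T̂ − mean T|/mean T ≤ 5% — because
per-element relative error at young ages is dominated by binomial noise in
*p* (at *t* ~ 1 My and 5-kb repeats, 2rt ≈ 2.7×10⁻³, so a single repeat
pair carries only ~13 expected differences). F recovery is ±0.03 on the
mean across individuals; genome size within 2%; planted *Ks* peaks within
one KDE bandwidth. Floating-point ties in the KDE degenerate case (all
values identical) are resolved by returning the value itself.

## Known limitations

* NG86, not an ML codon model: absolute *Ks* beyond ~1.5 is increasingly
  conservative; peak *positions* shift little in the range used here.
* The aligner is global with fixed scores; terminal-repeat boundary errors
  in the input annotation propagate into *K*.
* The HWE filter is inappropriate for strongly selfing panels (by
  construction it removes inbred sites); it is kept because it belongs to
  the standard cascade, and it can be disabled via `hwe_alpha=0`.
* Proportional WGD dating inherits the γ calibration's uncertainty
  wholesale; reported dates are as good as *t_cal* and the clock
  assumption.
* The depth-band rule uses the site-mean of the currently non-missing
  calls; cascades on data with extreme depth bimodality may not be exactly
  idempotent (the log exposes this).
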