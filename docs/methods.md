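# Methods

This note documents the models, conventions and design choices behind
`introscan`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and call conventions

All genomic coordinates are 1-based inclusive basepairs internally, matching
the barley physical-map convention; conversion to 0-based half-open intervals
happens only in the BED writers/readers, so there is exactly one place where
an off-by-one could live. Genetic positions are centiMorgans from the top of
each chromosome, related to bp by per-chromosome linear interpolation (the
simulator's maps are built that way; imported maps may be arbitrary monotone
bp→cM tables).

Raw array calls use Illumina-style A/B allele notation (`AA`, `AB`, `BB`,
`NC`). Encoded graphical genotypes use `A` = recurrent-parent homozygote,
`B` = donor homozygote, `H` = heterozygote, `NA` = missing.

## Marker triage

A marker is informative only when both parents give opposite homozygous calls
and the marker has a map position. Exclusion categories are assigned with a
fixed precedence — monomorphic, then single-parent, then unmapped, then
parent-heterozygous — because a marker can satisfy several (e.g. monomorphic
*and* unmapped) while only the partition totals are observable. Both-parents-
missing markers are folded into single-parent ("insufficient parental
information") with a logged warning; they have no category of their own in
array practice. No call-rate or Hardy–Weinberg filters are applied: triage is
strictly a parental-informativeness screen.

## Segment calling

Donor introgressions are maximal runs of `B`/`H` calls along the map order of
one chromosome. Two policies matter:

* **Missing never breaks a run.** `NA` is absence of evidence; breaking
  segments on array dropouts would shatter real introgressions.
* **`A` breaks a run unless an interruption budget absorbs it.**
  `max_interruptions` (default 0) is the number of interior `A` calls a run
  may absorb; it exists to tolerate isolated miscalls inside a genuine
  segment at realistic array error rates. Runs are greedy and
  leftmost-maximal; segment bounds are reported at the supporting markers
  (first/last `B`/`H`), not extrapolated to recombination midpoints.

Segment counts are monotone non-increasing in the interruption budget
(property-tested), and at zero genotyping error the called segments equal the
simulator's latent donor intervals sampled at the marker positions
(round-trip-tested per sample and marker).

## Phenotype-contrast mapping

The trait model is binary and fully penetrant. A marker is **concordant**
when every non-missing transformable call carries donor chromatin and every
non-missing non-transformable call is `A`; heterozygous support is accepted
by default because a dominant locus segregates as `H` in many carriers
(`require_homozygous=True` gives the strict mode). A marker where either
class is entirely missing, or exceeds `max_missing_fraction` (default 0.1)
missing within a class, is *non-evaluable* — reported distinctly from
discordant and transparent to run merging, again so that array missingness
cannot shatter a region. Candidate regions are maximal concordant runs
(sharing the segment-caller's interruption budget), ranked by concordant
marker count with physical span as tie-break.

This is deterministic set logic, not hypothesis testing; no multiple-testing
correction is meaningful. A label-permutation scan is provided as a
diagnostic only.

**Delimitation.** The minimal region is the intersection, over transformable
samples, of each sample's donor span overlapping the region; the samples
attaining the left/right bounds are the boundary recombinants. That
intersection is clipped to the discordant-free window around the run: under a
fully penetrant model a marker at which a recalcitrant line carries donor
cannot lie inside the candidate interval, and without the clip the
intersection of (long) transformable spans can overrun contradicted markers.
The clip is invisible for a well-behaved causal region, where the concordant
run and the span intersection coincide. Outer bounds are the nearest markers
beyond the inner bounds at which *any* transformable sample is `A` (or the
chromosome ends) — an uncertainty bound, deliberately defined only by
transformable-side evidence. Both intervals are always reported; gene
counting defaults to the outer interval because flank-defined spans are the
common convention for candidate regions.

With several transformable lines whose breakpoints straddle the locus, the
region set typically contains exactly the causal region. A second, genuinely
concordant region can appear *flanking the selection locus*: lines that went
through more backcross rounds carry systematically shorter selected segments,
so all non-transformable (late-generation) segments can end before all
transformable (early-generation) ones. This is a real confound of
selection-assisted backcross designs, not an artifact; it is why recovery is
judged against the full reported region set and why the selection locus
itself can never fall inside a region's inner interval (its markers are
structurally discordant).

## The simulator

The generator exists to produce data with the statistical structure the
pipeline assumes, with known latent truth.

* **Genome/map.** Seven chromosomes with barley-like physical lengths
  (4.58 Gbp total) and cM lengths proportional to bp, 600 cM genome-wide by
  default; markers placed uniformly at random. Denser maps only change
  resolution, not logic.
* **Meiosis.** Crossover counts are Poisson with mean `length_cM/100`
  (Haldane: no interference, no obligate chiasma), positions uniform,
  starting haplotype a fair coin, chromosomes assorting independently.
  Genomes are origin-segment lists on the cM axis; every meiosis preserves
  exact tiling of each chromosome (validated).
* **Breeding chain.** Donor × recurrent F1, then per backcross round: cross
  to the recurrent parent, followed by `selfing_generations_after_last_cross`
  selfings (default 2, i.e. F3) each screened at the selection locus —
  homozygous-donor offspring always pass, heterozygotes pass with
  `selection_misclassification_rate` (default 0.1; the grain screen is
  imperfect but the rate is a free parameter, not an estimate), homozygous
  recurrent never pass. The screened plant parents the next backcross, as in
  a real program where only lines retaining the tracked locus are advanced.
  A selfing whose candidates all fail raises an extinct-lineage error; the
  population generator resows (bounded retries).
* **Loci.** Selection locus at 5H:50 cM, causal locus at 2H:85 cM (distal
  long arm), dominant by default. Positions are arbitrary within their
  chromosomes and configurable.
* **Phenotype and assay.** A line's class is determined by its causal-locus
  genotype; per-embryo stochasticity appears only in assay counts
  (`Binomial(n_embryos, te_if_carrier)` for carriers, 0 for non-carriers,
  defaults 50 embryos and 13% per-embryo success — the efficiency scale of a
  good non-model donor line). Lines, not embryos, carry the class, matching
  how transformability cohorts are scored.
* **Array panel.** Category counts default to the real 44,040-marker
  accounting (9,456 informative / 31,925 monomorphic / 2,535 single-parent /
  45 unmapped / 79 parent-het). Informative progeny calls derive
  deterministically from haplotype origins at the marker position;
  non-informative categories are emitted with plausible filler so a full
  array export can be triaged. Noise: each call is independently corrupted
  to a uniformly random *different* call with `genotyping_error_rate` and
  set to `NC` with `missing_rate` (both default 0).
* **Cohort assembly.** `simulate_mapping_study` recruits transformable lines
  from BC1/BC2 and non-transformable embryo donors from BC3/BC4 by rejection
  sampling on the assigned class — mirroring the fact that a transformation
  assay only ever yields transgenic plants from carrier lines.

What the generator does **not** emulate: linkage-map error, segregation
distortion, crossover interference, marker ascertainment bias, clustered
(non-independent) genotyping failures, phenotyping error (misclassified
lines), and incomplete penetrance. Passing tests therefore demonstrate the
pipeline's logic under its stated model, not robustness to every pathology of
real array data — though the missing-call and interruption policies are
designed for exactly the commonest ones.

## Problem sizes and numerical choices

The simulation suites use 7 × 500-marker maps with cohorts of 12
transformable and 4 non-transformable lines, 50 replicate cohorts per
condition, 500 lines per generation for backcross-fraction checks, and
1,000 random rows for oracle-equivalence checks — sizes at which the Monte
Carlo standard errors are far below the asserted margins (statistical checks
use 3·SE bands). Ties in region ranking break by physical span, then by
scan order (chromosome, then position). Degenerate inputs are explicit
errors: TE with zero embryos, donor fraction with all-missing rows,
delimitation with an empty span intersection, zero-length maps.

## Known limitations

* Exact concordance is brittle when recombination breakpoints crowd the
  causal locus: if the true intersection is a single marker, one miscall
  there erases the region (observed as the rare zero-region cohort under
  noise). Hidden-Markov smoothing or imputation would help and is
  deliberately out of scope.
* The selection-flank confound described above means region lists should be
  read with the breeding design in mind; the package reports all concordant
  regions rather than silently suppressing any.
* `GeneticMap` assumes markers within a chromosome are totally ordered by bp;
  markers sharing a bp position are kept in stable order but are
  indistinguishable to the segment caller.
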