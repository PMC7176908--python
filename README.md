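# introscan

Introgression mapping of binary traits in backcross populations genotyped on
SNP arrays — with a breeding-program simulator that makes the whole pipeline
testable without any external data.

## The problem

Barley (*Hordeum vulgare*) is stubbornly genotype-dependent for
*Agrobacterium*-mediated transformation: a handful of genotypes transform
well, elite cultivars mostly do not. When a transformable donor line is
repeatedly backcrossed to a recalcitrant recurrent cultivar, each progeny line
carries a few residual donor chromosome segments in an otherwise
recurrent-parent genome. If transformability is controlled by a single, fully
penetrant locus, that locus must lie in a donor segment that is **present in
every transformable line and absent from every non-transformable line**. With
a dense SNP array, finding it is deterministic set logic rather than QTL
statistics:

1. **Triage** the array against the two parents. Only markers with opposite
   homozygous parental calls trace parental origin; monomorphic,
   single-parent-call, unmapped and parent-heterozygous markers are excluded.
2. **Encode** each progeny call as a graphical genotype:
   `A` (recurrent homozygote), `B` (donor homozygote), `H` (heterozygote).
3. **Call segments**: maximal runs of `B`/`H` markers along a chromosome are
   donor introgressions; missing calls never break a run.
4. **Contrast**: a marker is *concordant* when every transformable line
   carries donor chromatin (`B` or `H` — one allele suffices under a dominant
   model) and every non-transformable line is `A`. Runs of concordant markers
   are the candidate regions.
5. **Delimit**: intersecting the donor spans of the transformable lines
   identifies the boundary recombinants and the minimal region; the nearest
   flanking markers at which some transformable line is `A` bound it from
   outside.
6. **Annotate**: intersect the candidate interval with a GFF3/BED gene
   annotation to get the candidate gene list.

Phenotypes come from embryo transformation assays; transformation efficiency
(TE) is the percentage of cultured immature embryos yielding at least one
independent transgenic plant.

Because such studies rarely deposit their raw array data, the package includes
a first-class simulator (`introscan.simulate`): Poisson/Haldane meiosis on a
seven-chromosome barley-like map, a backcross-with-selfing breeding chain with
an imperfect phenotypic screen at a 5H selection locus, a dominant causal
locus on 2H, array panels with realistic exclusion-category structure, and
binomial embryo assays. Every stage of the pipeline is tested against that
generator's latent truth.

## Worked example

Simulate a mapping cohort (12 transformable BC1/BC2 lines, 4 recalcitrant
BC3/BC4 embryo donors, 300 markers per chromosome) and run the pipeline:

```bash
introscan simulate --seed 42 --out study --markers-per-chromosome 300
# simulated 16 lines × 2100 markers → study

cat > pipeline.yaml <<EOF
seed: 42
inputs:
  panel: study/panel.tsv
  map: study/map.tsv
  genotypes: study/genotypes.tsv
  phenotypes: study/phenotypes.tsv
output_dir: run
options:
  max_interruptions: 0
EOF
introscan pipeline --config pipeline.yaml
# pipeline finished: 1 candidate region(s) → run
```

`run/report.json` then contains exactly one candidate region:

```json
{"chrom": "2H",
 "inner_start_bp": 629606172, "inner_end_bp": 649986714,
 "outer_start_bp": 624636273, "outer_end_bp": 652345992,
 "n_markers": 10,
 "boundary_samples": {"start": ["BC1-06"], "end": ["BC2-04"]}}
```

The planted causal locus in `study/truth.json` is `2H:649,258,333` — inside
the reported interval. The inner bounds are set by the two boundary
recombinants (BC1-06 on the left, BC2-04 on the right); the outer bounds are
the nearest markers at which some transformable line is homozygous recurrent.

Marker triage at the scale of a real 44k array (the library surface):

```python
>>> import numpy as np, introscan as isc
>>> rng = np.random.default_rng(0)
>>> gmap = isc.build_map(isc.barley_chromosomes(), 6285, rng)
>>> panel = isc.build_marker_panel(isc.PanelConfig(), gmap, rng)
>>> retained, report = isc.triage_panel(panel, gmap)
>>> report.to_dict()
{'total': 44040,
 'counts': {'retained': 9456, 'monomorphic': 31925, 'single_parent': 2535,
            'unmapped': 45, 'parent_het': 79},
 'n_retained': 9456}
```

Of 44,040 array SNPs, 9,456 are informative for origin tracing; the rest are
excluded by category.

The matrix-shaped stages are also exposed as scikit-learn style estimators
(`MarkerTriage`, `GenotypeEncoder`, `SegmentCaller` as transformers,
`IntrogressionMapper` as the final `fit(X, y)` estimator with a `regions_`
attribute), so they compose with sklearn pipelines and `clone`.

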