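"""Backcross-population simulator.

Generates the inputs the mapping pipeline consumes — a marker panel with the
category structure of a real SNP array, array genotypes of backcross progeny,
phenotypes and transformation assays — from an explicit genetic model:

* meiosis with Poisson crossover counts (mean = map length / 100, i.e. Haldane,
  no interference) and uniformly placed crossovers;
* a breeding chain donor × recurrent → F1, then per backcross round a cross to
  the recurrent parent followed by selfing generations with a phenotypic screen
  at a selection locus (the large-embryo / shrunken-endosperm proxy used to
  track the 5H *lys3* region in the real program);
* a dominant (or recessive) causal transformability locus on 2H, and a binomial
  embryo-assay model on top of the line's class.

Genomes are stored as origin segments (donor vs recurrent) on the cM axis, the
latent truth behind graphical genotypes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assaystats import AssayResult
from .calls import (
    HET,
    HOM_A,
    HOM_B,
    NO_CALL,
    NON_TRANSFORMABLE,
    TRANSFORMABLE,
)
from .genmap import UNMAPPED, ChromosomeSpec, GeneticMap, barley_chromosomes, build_map

RECURRENT = 0
DONOR = 1

# triage ground-truth categories as produced by the panel generator; values
# match introscan.triage.MarkerCategory
CAT_INFORMATIVE = "retained"
CAT_MONOMORPHIC = "monomorphic"
CAT_SINGLE_PARENT = "single_parent"
CAT_UNMAPPED = "unmapped"
CAT_PARENT_HET = "parent_het"


# ---------------------------------------------------------------------------
# genomes and meiosis
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """One chromosome copy as origin segments tiling [0, length_cM].

    ``breaks`` has n+1 monotone entries starting at 0; segment i spans
    ``[breaks[i], breaks[i+1])`` with parental origin ``origins[i]``
    (DONOR / RECURRENT).  Adjacent segments differ in origin.
    """

    breaks: np.ndarray
    origins: np.ndarray

    def validate(self, length_cM: float) -> None:
        b, o = self.breaks, self.origins
        if len(b) != len(o) + 1 or len(o) < 1:
            raise ValueError("haplotype: breaks/origins length mismatch")
        if b[0] != 0.0 or abs(b[-1] - length_cM) > 1e-9:
            raise ValueError("haplotype does not tile the chromosome")
        if np.any(np.diff(b) < 0):
            raise ValueError("haplotype breaks not monotone")
        if len(o) > 1 and np.any(o[1:] == o[:-1]):
            raise ValueError("adjacent segments share an origin")

    def origin_at(self, pos_cM) -> np.ndarray:
        """Parental origin at one or more cM positions (vectorised)."""
        pos = np.atleast_1d(np.asarray(pos_cM, dtype=float))
        idx = np.clip(np.searchsorted(self.breaks, pos, side="right") - 1, 0, len(self.origins) - 1)
        return self.origins[idx]

    def donor_cM(self) -> float:
        seg = np.diff(self.breaks)
        return float(seg[self.origins == DONOR].sum())


def _uniform_haplotype(length_cM: float, origin: int) -> Haplotype:
    return Haplotype(np.array([0.0, length_cM]), np.array([origin], dtype=np.int8))


@dataclass
class DiploidGenome:
    """Two haplotypes per chromosome, keyed by chromosome name."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    @classmethod
    def pure(cls, genetic_map: GeneticMap, origin: int) -> "DiploidGenome":
        return cls(
            {
                c.name: (_uniform_haplotype(c.length_cM, origin), _uniform_haplotype(c.length_cM, origin))
                for c in genetic_map.chromosomes
            }
        )

    def validate(self, genetic_map: GeneticMap) -> None:
        for c in genetic_map.chromosomes:
            for hap in self.haplotypes[c.name]:
                hap.validate(c.length_cM)

    def donor_dosage(self, chrom: str, pos_cM) -> np.ndarray:
        """Number of donor alleles (0/1/2) at positions on one chromosome."""
        h1, h2 = self.haplotypes[chrom]
        return (h1.origin_at(pos_cM) == DONOR).astype(np.int8) + (
            h2.origin_at(pos_cM) == DONOR
        ).astype(np.int8)

    def donor_fraction(self, genetic_map: GeneticMap) -> float:
        """cM-weighted fraction of the diploid genome that is donor-derived."""
        total = sum(c.length_cM for c in genetic_map.chromosomes)
        if total == 0:
            raise ValueError("zero-length map")
        donor = sum(h.donor_cM() for pair in self.haplotypes.values() for h in pair)
        return donor / (2.0 * total)

    def donor_intervals(self, chrom: str) -> list[tuple[float, float]]:
        """Union of cM intervals where at least one haplotype is donor."""
        ivals = []
        for hap in self.haplotypes[chrom]:
            for i, o in enumerate(hap.origins):
                if o == DONOR:
                    ivals.append((float(hap.breaks[i]), float(hap.breaks[i + 1])))
        ivals.sort()
        merged: list[list[float]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def _recombine(h0: Haplotype, h1: Haplotype, xpos: np.ndarray, first: int, length_cM: float) -> Haplotype:
    """Assemble a gamete haplotype alternating between h0/h1 at crossover points."""
    haps = (h0, h1)
    if length_cM == 0 or len(xpos) == 0:
        src = haps[first]
        return Haplotype(src.breaks.copy(), src.origins.copy())
    edges = np.concatenate(([0.0], np.sort(xpos), [length_cM]))
    out_breaks = [0.0]
    out_origins: list[int] = []
    cur = first
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            h = haps[cur]
            i0 = int(np.searchsorted(h.breaks, a, side="right")) - 1
            i1 = int(np.searchsorted(h.breaks, b, side="left"))
            for j in range(max(i0, 0), i1):
                end = min(float(h.breaks[j + 1]), b)
                o = int(h.origins[j])
                if out_origins and out_origins[-1] == o:
                    out_breaks[-1] = end
                else:
                    out_origins.append(o)
                    out_breaks.append(end)
        cur ^= 1
    out_breaks[-1] = length_cM
    return Haplotype(np.asarray(out_breaks), np.asarray(out_origins, dtype=np.int8))


def _gamete_chromosome(
    parent: DiploidGenome, spec: ChromosomeSpec, rng: np.random.Generator
) -> Haplotype:
    h0, h1 = parent.haplotypes[spec.name]
    k = int(rng.poisson(spec.length_cM / 100.0))
    xpos = rng.uniform(0.0, spec.length_cM, size=k) if k else np.empty(0)
    first = int(rng.integers(2))
    return _recombine(h0, h1, xpos, first, spec.length_cM)


def simulate_gamete(
    parent: DiploidGenome, genetic_map: GeneticMap, rng: np.random.Generator
) -> dict[str, Haplotype]:
    """One meiotic product per chromosome.

    Crossover count ~ Poisson(length_cM / 100); positions uniform on the cM
    axis; the starting haplotype is a fair coin.  No interference and no
    obligate chiasma; chromosomes assort independently.
    """
    return {spec.name: _gamete_chromosome(parent, spec, rng) for spec in genetic_map.chromosomes}


def make_offspring(
    mother: DiploidGenome,
    father: DiploidGenome,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
) -> DiploidGenome:
    """Fuse one gamete from each parent (mother == father is a selfing)."""
    if set(mother.haplotypes) != set(father.haplotypes):
        raise ValueError("parents carry different chromosome sets")
    gm = simulate_gamete(mother, genetic_map, rng)
    gf = simulate_gamete(father, genetic_map, rng)
    return DiploidGenome({c: (gm[c], gf[c]) for c in gm})


# ---------------------------------------------------------------------------
# breeding scheme
# ---------------------------------------------------------------------------


class ExtinctLineageError(RuntimeError):
    """The selection screen rejected every candidate offspring of a selfing."""

    def __init__(self, generation: str):
        super().__init__(f"lineage extinct: no offspring passed the screen at {generation}")
        self.generation = generation


@dataclass(frozen=True)
class BreedingConfig:
    """Parameters of the simulated breeding program.

    ``selection_locus`` is the (chromosome, cM) position screened phenotypically
    at each selfing generation (the large-embryo proxy); homozygous-donor
    offspring always pass, heterozygotes pass with
    ``selection_misclassification_rate`` (the screen is imperfect), homozygous
    recurrent never pass.  ``causal_locus`` is the transformability locus;
    under the dominant model one donor allele suffices.
    """

    n_backcrosses: int = 4
    selfing_generations_after_last_cross: int = 2
    selection_locus: tuple[str, float] | None = ("5H", 50.0)
    selection_misclassification_rate: float = 0.1
    causal_locus: tuple[str, float] = ("2H", 85.0)
    dominance_mode: str = "dominant"
    te_if_carrier: float = 0.13
    n_embryos_per_line: int = 50
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name, p in [
            ("selection_misclassification_rate", self.selection_misclassification_rate),
            ("te_if_carrier", self.te_if_carrier),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_backcrosses < 0 or self.selfing_generations_after_last_cross < 0:
            raise ValueError("generation counts must be >= 0")
        if self.dominance_mode not in ("dominant", "recessive"):
            raise ValueError("dominance_mode must be 'dominant' or 'recessive'")
        if self.n_embryos_per_line < 1:
            raise ValueError("n_embryos_per_line must be >= 1")

    def validate_loci(self, genetic_map: GeneticMap) -> None:
        for locus in filter(None, [self.selection_locus, self.causal_locus]):
            chrom, cm = locus
            spec = genetic_map.chromosome(chrom)
            if not 0 <= cm <= spec.length_cM:
                raise ValueError(f"locus {locus} outside chromosome {chrom}")


@dataclass
class Sample:
    """One line of the population: final selfed plant plus provenance."""

    sample_id: str
    genome: DiploidGenome
    generation: str
    n_backcrosses: int


def _passes_screen(n_donor: int, config: BreedingConfig, rng: np.random.Generator) -> bool:
    if n_donor == 2:
        return True
    if n_donor == 1:
        return bool(rng.random() < config.selection_misclassification_rate)
    return False


def _self_with_screen(
    plant: DiploidGenome,
    config: BreedingConfig,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    generation: str,
    max_candidates: int = 200,
) -> DiploidGenome:
    if config.selection_locus is None:
        return make_offspring(plant, plant, genetic_map, rng)
    chrom, cm = config.selection_locus
    spec = genetic_map.chromosome(chrom)
    # chromosomes assort independently, so the screened chromosome pair can be
    # drawn (and accepted/rejected) before the rest of the genome is simulated
    for _ in range(max_candidates):
        pair = (_gamete_chromosome(plant, spec, rng), _gamete_chromosome(plant, spec, rng))
        dosage = int(pair[0].origin_at(cm)[0] == DONOR) + int(pair[1].origin_at(cm)[0] == DONOR)
        if _passes_screen(dosage, config, rng):
            haps = {
                other.name: (
                    _gamete_chromosome(plant, other, rng),
                    _gamete_chromosome(plant, other, rng),
                )
                for other in genetic_map.chromosomes
                if other.name != chrom
            }
            haps[chrom] = pair
            return DiploidGenome(haps)
    raise ExtinctLineageError(generation)


def simulate_line(
    config: BreedingConfig,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    sample_id: str = "line",
) -> Sample:
    """One full breeding chain: F1, then per backcross round a cross to the
    recurrent parent followed by screened selfing generations.

    The screened plant of each round is the parent of the next backcross, as in
    a real program where only lines retaining the tracked locus are advanced.
    Raises :class:`ExtinctLineageError` if a selfing screen rejects every
    candidate (possible when a misclassified heterozygote loses the donor
    allele in a later cross).
    """
    config.validate_loci(genetic_map)
    recurrent = DiploidGenome.pure(genetic_map, RECURRENT)
    donor = DiploidGenome.pure(genetic_map, DONOR)
    plant = make_offspring(donor, recurrent, genetic_map, rng)  # F1
    generation = "F1"
    for b in range(1, config.n_backcrosses + 1):
        plant = make_offspring(plant, recurrent, genetic_map, rng)
        generation = f"BC{b}F1"
        for s in range(1, config.selfing_generations_after_last_cross + 1):
            generation = f"BC{b}F{s + 1}"
            plant = _self_with_screen(plant, config, genetic_map, rng, generation)
    return Sample(sample_id, plant, generation, config.n_backcrosses)


def run_breeding_scheme(
    config: BreedingConfig,
    genetic_map: GeneticMap,
    n_lines: int,
    rng: np.random.Generator,
    retry_extinct: bool = True,
) -> list[Sample]:
    """Simulate ``n_lines`` independent lines of the configured generation.

    Extinct lineages are discarded and replaced (a breeder sows another grain)
    unless ``retry_extinct`` is false, in which case the error propagates.
    """
    samples: list[Sample] = []
    attempts = 0
    max_attempts = max(10 * n_lines, n_lines + 50)
    while len(samples) < n_lines:
        attempts += 1
        if attempts > max_attempts:
            raise ExtinctLineageError(f"BC{config.n_backcrosses}")
        sid = f"BC{config.n_backcrosses}-{len(samples) + 1:02d}"
        try:
            samples.append(simulate_line(config, genetic_map, rng, sid))
        except ExtinctLineageError:
            if not retry_extinct:
                raise
    return samples


def assign_transformability(genome: DiploidGenome, config: BreedingConfig) -> str:
    """Phenotype class from the causal-locus genotype.

    Dominant mode: one donor allele makes the line transformable; recessive
    mode requires two.
    """
    chrom, cm = config.causal_locus
    dosage = int(genome.donor_dosage(chrom, cm)[0])
    needed = 1 if config.dominance_mode == "dominant" else 2
    return TRANSFORMABLE if dosage >= needed else NON_TRANSFORMABLE


def simulate_assay(
    sample_class: str,
    config: BreedingConfig,
    rng: np.random.Generator,
    line_id: str = "line",
    experiment_id: str = "exp1",
) -> AssayResult:
    """Embryo assay: transformable lines yield Binomial(n_embryos, te) transgenic
    embryos; non-transformable lines yield none."""
    n = config.n_embryos_per_line
    if sample_class == TRANSFORMABLE:
        k = int(rng.binomial(n, config.te_if_carrier))
    else:
        k = 0
    return AssayResult(line_id, experiment_id, n, k)


# ---------------------------------------------------------------------------
# marker panel and array genotyping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelConfig:
    """Composition and noise of the simulated SNP array panel."""

    n_informative: int = 9_456
    n_monomorphic: int = 31_925
    n_single_parent: int = 2_535
    n_unmapped: int = 45
    n_parent_het: int = 79
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("n_") and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
            if f.name.endswith("_rate") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1]")

    @property
    def total(self) -> int:
        return (
            self.n_informative
            + self.n_monomorphic
            + self.n_single_parent
            + self.n_unmapped
            + self.n_parent_het
        )

    @property
    def n_mapped(self) -> int:
        return self.total - self.n_unmapped


PANEL_COLUMNS = ["chrom", "bp", "cM", "call_recurrent", "call_donor", "true_category"]


def build_marker_panel(
    config: PanelConfig, genetic_map: GeneticMap, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign array categories to map markers and synthesise parental calls.

    Mapped categories (informative / monomorphic / single-parent / parent-het)
    are assigned to a random subset of the map's markers; unmapped markers are
    created fresh with no chromosome.  Informative markers get opposite
    homozygous parental calls with random allele labelling.  The ground-truth
    category is stored per marker so triage can be checked against construction.
    """
    mapped = genetic_map.mapped_markers
    if config.n_mapped > len(mapped):
        raise ValueError(
            f"panel needs {config.n_mapped} mapped markers but the map has {len(mapped)}"
        )
    order = rng.permutation(len(mapped))[: config.n_mapped]
    chosen = mapped.iloc[np.sort(order)]
    cats = np.concatenate(
        [
            np.full(config.n_informative, CAT_INFORMATIVE, dtype=object),
            np.full(config.n_monomorphic, CAT_MONOMORPHIC, dtype=object),
            np.full(config.n_single_parent, CAT_SINGLE_PARENT, dtype=object),
            np.full(config.n_parent_het, CAT_PARENT_HET, dtype=object),
        ]
    )
    rng.shuffle(cats)

    n = len(chosen)
    flip = rng.integers(2, size=n).astype(bool)  # which allele label the donor carries
    call_rec = np.where(flip, HOM_B, HOM_A).astype(object)
    call_don = np.where(flip, HOM_A, HOM_B).astype(object)

    mono = cats == CAT_MONOMORPHIC
    shared = np.where(rng.integers(2, size=n).astype(bool), HOM_A, HOM_B).astype(object)
    call_rec[mono] = shared[mono]
    call_don[mono] = shared[mono]

    single = cats == CAT_SINGLE_PARENT
    drop_rec = rng.integers(2, size=n).astype(bool)
    call_rec[single & drop_rec] = NO_CALL
    call_don[single & ~drop_rec] = NO_CALL

    het = cats == CAT_PARENT_HET
    which = rng.integers(3, size=n)  # 0: recurrent het, 1: donor het, 2: both
    call_rec[het & (which != 1)] = HET
    call_don[het & (which != 0)] = HET

    panel = pd.DataFrame(
        {
            "chrom": chosen["chrom"].to_numpy(),
            "bp": chosen["bp"].to_numpy(),
            "cM": chosen["cM"].to_numpy(),
            "call_recurrent": call_rec,
            "call_donor": call_don,
            "true_category": cats,
        },
        index=chosen.index,
    )

    if config.n_unmapped:
        k = config.n_unmapped
        uflip = rng.integers(2, size=k).astype(bool)
        unmapped = pd.DataFrame(
            {
                "chrom": UNMAPPED,
                "bp": np.nan,
                "cM": np.nan,
                "call_recurrent": np.where(uflip, HOM_B, HOM_A),
                "call_donor": np.where(uflip, HOM_A, HOM_B),
                "true_category": CAT_UNMAPPED,
            },
            index=[f"snp_{UNMAPPED}_{i:05d}" for i in range(k)],
        )
        panel = pd.concat([panel, unmapped])
    return panel


_CALL_STR = np.array([HOM_A, HET, HOM_B], dtype=object)
_CALL_CODE = {HOM_A: 0, HET: 1, HOM_B: 2, NO_CALL: -1}


def genotype_population(
    population: list[Sample],
    panel: pd.DataFrame,
    genetic_map: GeneticMap,
    config: PanelConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Array genotypes (raw AA/AB/BB/NC calls) of a population on a panel.

    Informative-marker calls derive from the two haplotype origins at the
    marker's cM position (donor/donor → the donor parent's call, mixed → AB,
    recurrent/recurrent → the recurrent parent's call).  Non-informative
    categories are emitted with plausible plumbing values (monomorphic: the
    shared call; single-parent: the called parent's value; parent-het and
    unmapped: a random genotype) so a full array export can be triaged.  Every
    call is then independently corrupted to a uniformly random different call
    with ``genotyping_error_rate`` and set to NC with ``missing_rate``.
    """
    if not population:
        raise ValueError("empty population")
    markers = panel.index.to_numpy()
    n_s, n_m = len(population), len(markers)
    cats = panel["true_category"].to_numpy()
    rec_code = panel["call_recurrent"].map(_CALL_CODE).to_numpy()
    don_code = panel["call_donor"].map(_CALL_CODE).to_numpy()

    codes = np.full((n_s, n_m), -1, dtype=np.int8)

    informative = cats == CAT_INFORMATIVE
    chrom_col = panel["chrom"].to_numpy()
    cm_col = panel["cM"].to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genetic_map.chromosome_names:
        idx = np.flatnonzero(informative & (chrom_col == chrom))
        if idx.size:
            by_chrom[chrom] = (idx, cm_col[idx])
    for i, sample in enumerate(population):
        for chrom, (idx, pos) in by_chrom.items():
            dosage = sample.genome.donor_dosage(chrom, pos)
            col = np.where(
                dosage == 2, don_code[idx], np.where(dosage == 0, rec_code[idx], 1)
            )
            codes[i, idx] = col

    mono = cats == CAT_MONOMORPHIC
    codes[:, mono] = rec_code[mono]
    single = cats == CAT_SINGLE_PARENT
    present = np.where(rec_code >= 0, rec_code, don_code)
    codes[:, single] = present[single]
    randomish = (cats == CAT_PARENT_HET) | (cats == CAT_UNMAPPED)
    k = int(randomish.sum())
    if k:
        codes[:, randomish] = rng.choice(3, size=(n_s, k), p=[0.25, 0.5, 0.25]).astype(np.int8)

    if config.genotyping_error_rate > 0:
        err = (rng.random((n_s, n_m)) < config.genotyping_error_rate) & (codes >= 0)
        shift = rng.integers(1, 3, size=(n_s, n_m)).astype(np.int8)
        codes = np.where(err, (codes + shift) % 3, codes)
    if config.missing_rate > 0:
        codes[rng.random((n_s, n_m)) < config.missing_rate] = -1

    out = np.where(codes >= 0, _CALL_STR[np.clip(codes, 0, 2)], NO_CALL)
    return pd.DataFrame(out, index=[s.sample_id for s in population], columns=markers)


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class MappingStudy:
    """A complete simulated dataset plus the latent truth behind it."""

    genetic_map: GeneticMap
    panel: pd.DataFrame
    genotypes: pd.DataFrame  # raw calls, samples x markers
    phenotypes: pd.DataFrame  # index sample; columns phenotype, generation
    assays: pd.DataFrame
    samples: list[Sample]
    breeding: BreedingConfig
    panel_config: PanelConfig

    @property
    def causal_chrom(self) -> str:
        return self.breeding.causal_locus[0]

    @property
    def causal_bp(self) -> int:
        chrom, cm = self.breeding.causal_locus
        return self.genetic_map.cm_to_bp(chrom, cm)


def simulate_mapping_study(
    seed,
    genetic_map: GeneticMap | None = None,
    n_markers_per_chromosome: int = 500,
    breeding: BreedingConfig | None = None,
    panel_config: PanelConfig | None = None,
    n_transformable: int = 12,
    n_non_transformable: int = 4,
    n_experiments: int = 2,
) -> MappingStudy:
    """Simulate a mapping cohort mirroring the real study design.

    Transformable samples are recruited from BC1/BC2 lines (the plants a
    transformation assay recovers are exactly the causal-locus carriers) and
    non-transformable embryo donors from BC3/BC4 lines, by rejection sampling
    on the assigned class.  ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genetic_map is None:
        genetic_map = build_map(barley_chromosomes(), n_markers_per_chromosome, rng)
    if breeding is None:
        breeding = BreedingConfig()
    if panel_config is None:
        n = len(genetic_map.mapped_markers)
        panel_config = PanelConfig(
            n_informative=n, n_monomorphic=0, n_single_parent=0, n_unmapped=0, n_parent_het=0
        )
    panel = build_marker_panel(panel_config, genetic_map, rng)

    quotas = [
        (1, TRANSFORMABLE, n_transformable - n_transformable // 2),
        (2, TRANSFORMABLE, n_transformable // 2),
        (3, NON_TRANSFORMABLE, n_non_transformable - n_non_transformable // 2),
        (4, NON_TRANSFORMABLE, n_non_transformable // 2),
    ]
    samples: list[Sample] = []
    phen_rows = []
    for n_bc, wanted, quota in quotas:
        cfg = dataclasses.replace(breeding, n_backcrosses=n_bc)
        got = 0
        attempts = 0
        while got < quota:
            attempts += 1
            if attempts > 500 * max(quota, 1):
                raise RuntimeError(
                    f"could not recruit {quota} {wanted} lines at BC{n_bc}; "
                    "check locus/dominance configuration"
                )
            try:
                line = simulate_line(cfg, genetic_map, rng, f"BC{n_bc}-{got + 1:02d}")
            except ExtinctLineageError:
                continue
            if assign_transformability(line.genome, cfg) != wanted:
                continue
            got += 1
            samples.append(line)
            phen_rows.append(
                {"sample": line.sample_id, "phenotype": wanted, "generation": f"BC{n_bc}"}
            )
    phenotypes = pd.DataFrame(phen_rows).set_index("sample")

    genotypes = genotype_population(samples, panel, genetic_map, panel_config, rng)

    assay_rows = []
    for line in samples:
        cls = phenotypes.loc[line.sample_id, "phenotype"]
        for e in range(1, n_experiments + 1):
            r = simulate_assay(cls, breeding, rng, line.sample_id, f"exp{e}")
            assay_rows.append(
                {
                    "line": r.line_id,
                    "experiment": r.experiment_id,
                    "n_embryos": r.n_embryos,
                    "n_transgenic": r.n_transgenic,
                }
            )
    assays = pd.DataFrame(assay_rows)

    return MappingStudy(
        genetic_map, panel, genotypes, phenotypes, assays, samples, breeding, panel_config
    )
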