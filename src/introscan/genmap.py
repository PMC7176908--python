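"""Genetic maps: ordered marker panels with physical (bp) and genetic (cM) positions.

A :class:`GeneticMap` holds an ordered set of chromosomes and an ordered marker
table.  Physical coordinates are 1-based inclusive basepairs (the convention of
the barley physical map); genetic positions are centiMorgans from the top of the
chromosome.  Markers without a chromosome assignment carry the sentinel
:data:`UNMAPPED` and NaN positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosome label used for markers not placed on any chromosome
UNMAPPED = "UN"

MARKER_COLUMNS = ["chrom", "bp", "cM"]


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic length of one chromosome."""

    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.length_cM < 0:
            raise ValueError(f"chromosome {self.name}: length_cM must be >= 0")


# Approximate barley (Hordeum vulgare) chromosome sizes, Mbp, 1H..7H.
_BARLEY_MBP = {"1H": 558, "2H": 768, "3H": 700, "4H": 647, "5H": 670, "6H": 583, "7H": 657}


def barley_chromosomes(total_cM: float = 600.0) -> list[ChromosomeSpec]:
    """Seven barley chromosomes with cM lengths proportional to physical size.

    ``total_cM`` defaults to a compact 600 cM genome-wide map; real barley maps
    are longer, but recombination density only rescales expected crossover
    counts and every consumer takes the map as input.
    """
    total_bp = sum(_BARLEY_MBP.values())
    return [
        ChromosomeSpec(name, mbp * 1_000_000, total_cM * mbp / total_bp)
        for name, mbp in _BARLEY_MBP.items()
    ]


@dataclass
class GeneticMap:
    """Ordered chromosomes plus an ordered marker table.

    ``markers`` is a DataFrame indexed by marker name with columns
    ``chrom`` (str, or :data:`UNMAPPED`), ``bp`` (float, 1-based) and ``cM``.
    Mapped markers are sorted by (chromosome order, bp); unmapped markers sort
    last.  Within a chromosome cM must be monotone non-decreasing in bp.
    """

    chromosomes: list[ChromosomeSpec]
    markers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MARKER_COLUMNS))

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        if self.markers.index.has_duplicates:
            dupes = self.markers.index[self.markers.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker names: {dupes[:5]}")
        self.markers = self._sorted(self.markers)
        self._validate_positions()

    # -- construction helpers -------------------------------------------------

    def _sorted(self, markers: pd.DataFrame) -> pd.DataFrame:
        order = {c.name: i for i, c in enumerate(self.chromosomes)}
        order[UNMAPPED] = len(order)
        unknown = set(markers["chrom"]) - set(order)
        if unknown:
            raise ValueError(f"markers on undeclared chromosomes: {sorted(unknown)}")
        key = markers["chrom"].map(order)
        return markers.iloc[np.lexsort((markers["bp"].to_numpy(), key.to_numpy()))]

    def _validate_positions(self) -> None:
        for spec in self.chromosomes:
            sub = self.markers[self.markers["chrom"] == spec.name]
            if sub.empty:
                continue
            bp = sub["bp"].to_numpy(float)
            cm = sub["cM"].to_numpy(float)
            if np.any(bp < 1) or np.any(bp > spec.length_bp):
                raise ValueError(f"marker bp outside chromosome {spec.name}")
            if np.any(cm < 0) or np.any(cm > spec.length_cM + 1e-9):
                raise ValueError(f"marker cM outside chromosome {spec.name}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not monotone in bp on chromosome {spec.name}")

    # -- queries --------------------------------------------------------------

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}; known: {self.chromosome_names}")

    @property
    def mapped_markers(self) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] != UNMAPPED]

    def markers_on(self, chrom: str) -> pd.DataFrame:
        self.chromosome(chrom)
        return self.markers[self.markers["chrom"] == chrom]

    def cm_to_bp(self, chrom: str, cm: float) -> int:
        """Linear interpolation of a genetic position onto the physical axis."""
        spec = self.chromosome(chrom)
        if spec.length_cM == 0:
            return 1
        return max(1, int(round(cm / spec.length_cM * spec.length_bp)))

    def subset(self, marker_names) -> "GeneticMap":
        return GeneticMap(self.chromosomes, self.markers.loc[list(marker_names)])


def build_map(
    chromosomes: list[ChromosomeSpec],
    n_markers_per_chromosome: int,
    rng: np.random.Generator,
) -> GeneticMap:
    """Place markers uniformly at random on each chromosome.

    Basepair positions are drawn uniformly (without replacement) on
    ``[1, length_bp]`` and sorted; genetic positions follow by linear bp→cM
    scaling per chromosome.  Marker names are ``snp_<chrom>_<k>`` in map order.
    """
    if n_markers_per_chromosome < 1:
        raise ValueError("n_markers_per_chromosome must be >= 1")
    frames = []
    for spec in chromosomes:
        if n_markers_per_chromosome > spec.length_bp:
            raise ValueError(f"more markers than basepairs on {spec.name}")
        positions = np.unique(rng.integers(1, spec.length_bp + 1, size=n_markers_per_chromosome))
        while len(positions) < n_markers_per_chromosome:
            extra = rng.integers(1, spec.length_bp + 1, size=n_markers_per_chromosome)
            positions = np.unique(np.concatenate([positions, extra]))
        bp = np.sort(rng.permutation(positions)[:n_markers_per_chromosome]).astype(float)
        cm = bp * (spec.length_cM / spec.length_bp)
        names = [f"snp_{spec.name}_{i:05d}" for i in range(n_markers_per_chromosome)]
        frames.append(
            pd.DataFrame({"chrom": spec.name, "bp": bp, "cM": cm}, index=names)
        )
    return GeneticMap(chromosomes, pd.concat(frames))
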