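"""Phenotype-contrast introgression mapping.

The causal locus of a fully penetrant binary trait must lie where donor
chromatin is present in every affected line and absent from every unaffected
line.  Each marker is tested for that exact co-segregation (concordance):
every non-missing call in the transformable class is donor-carrying (B, or H
under the dominance-compatible default) and every non-missing call in the
non-transformable class is the recurrent homozygote A.  Maximal runs of
concordant markers become candidate regions, and the strongest region is
refined by intersecting the donor spans of the transformable samples — the
boundary recombinants define the minimal region, and the nearest flanking
markers at which some transformable sample is A bound it from outside.

This is deterministic set logic, not hypothesis testing; no multiple-testing
correction applies.  A label-permutation sanity check is available as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._runs import find_runs
from .calls import DON, HET_ENC, MISSING, NON_TRANSFORMABLE, REC, TRANSFORMABLE
from .genmap import GeneticMap
from .segments import call_segments


class MarkerStatus(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    NON_EVALUABLE = "non_evaluable"


class InconsistentRegionError(RuntimeError):
    """Region refinement found an empty intersection of donor spans."""


def marker_concordance(
    calls: pd.Series,
    phenotypes: pd.Series,
    max_missing_fraction: float = 0.1,
    require_homozygous: bool = False,
) -> tuple[MarkerStatus, dict[str, int]]:
    """Concordance of one marker column with the phenotype classes.

    Unknown-class samples are ignored.  A marker is non-evaluable (rather than
    discordant) when either class has no non-missing call or exceeds the
    missing-fraction budget.
    """
    status = _concordance_codes(
        calls.to_frame(name="marker"),
        phenotypes,
        max_missing_fraction,
        require_homozygous,
    )
    cls = phenotypes.reindex(calls.index)
    t_mask = (cls == TRANSFORMABLE).to_numpy()
    n_mask = (cls == NON_TRANSFORMABLE).to_numpy()
    values = calls.to_numpy(dtype=object)
    counts = {
        "n_transformable_support": int(((values != MISSING) & t_mask).sum()),
        "n_non_transformable_support": int(((values != MISSING) & n_mask).sum()),
    }
    return MarkerStatus(status[0]), counts


def _concordance_codes(
    matrix: pd.DataFrame,
    phenotypes: pd.Series,
    max_missing_fraction: float,
    require_homozygous: bool,
) -> np.ndarray:
    """Vectorised per-marker status over a samples × markers matrix."""
    cls = phenotypes.reindex(matrix.index)
    if cls.isna().any():
        missing = matrix.index[cls.isna()].tolist()
        raise ValueError(f"samples without phenotype records: {missing[:5]}")
    t_rows = (cls == TRANSFORMABLE).to_numpy()
    n_rows = (cls == NON_TRANSFORMABLE).to_numpy()
    if t_rows.sum() == 0 or n_rows.sum() == 0:
        raise ValueError(
            "need at least one transformable and one non-transformable sample"
        )
    values = matrix.to_numpy(dtype=object)
    is_missing = values == MISSING
    carries = (values == DON) if require_homozygous else ((values == DON) | (values == HET_ENC))
    is_rec = values == REC

    def class_stats(rows):
        nm = (~is_missing[rows]).sum(axis=0)
        miss_frac = is_missing[rows].mean(axis=0)
        return nm, miss_frac

    t_nonmiss, t_missfrac = class_stats(t_rows)
    n_nonmiss, n_missfrac = class_stats(n_rows)
    evaluable = (
        (t_nonmiss > 0)
        & (n_nonmiss > 0)
        & (t_missfrac <= max_missing_fraction)
        & (n_missfrac <= max_missing_fraction)
    )
    t_ok = (carries[t_rows] | is_missing[t_rows]).all(axis=0)
    n_ok = (is_rec[n_rows] | is_missing[n_rows]).all(axis=0)

    out = np.full(matrix.shape[1], MarkerStatus.DISCORDANT.value, dtype=object)
    out[t_ok & n_ok] = MarkerStatus.CONCORDANT.value
    out[~evaluable] = MarkerStatus.NON_EVALUABLE.value
    return out


@dataclass
class CandidateRegion:
    """An interval whose donor state co-segregates with transformability.

    ``inner`` bounds are the first/last concordant marker (after refinement:
    the intersection of the transformable samples' donor spans); ``outer``
    bounds are the nearest flanking positions where the donor state is
    contradicted (or the chromosome ends).  1-based inclusive bp.
    """

    chrom: str
    inner_start_bp: int
    inner_end_bp: int
    outer_start_bp: int
    outer_end_bp: int
    markers: list[str]
    n_transformable: int
    n_non_transformable: int
    boundary_samples: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("candidate region without concordant markers")
        if self.inner_start_bp > self.inner_end_bp:
            raise ValueError("inner bounds inverted")
        if not (
            self.outer_start_bp <= self.inner_start_bp
            and self.inner_end_bp <= self.outer_end_bp
        ):
            raise ValueError("outer interval must contain inner interval")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def inner_span_bp(self) -> int:
        return self.inner_end_bp - self.inner_start_bp + 1

    @property
    def outer_span_bp(self) -> int:
        return self.outer_end_bp - self.outer_start_bp + 1

    def contains(self, chrom: str, bp: int, which: str = "outer") -> bool:
        if chrom != self.chrom:
            return False
        if which == "inner":
            return self.inner_start_bp <= bp <= self.inner_end_bp
        return self.outer_start_bp <= bp <= self.outer_end_bp

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "inner_start_bp": self.inner_start_bp,
            "inner_end_bp": self.inner_end_bp,
            "outer_start_bp": self.outer_start_bp,
            "outer_end_bp": self.outer_end_bp,
            "inner_span_bp": self.inner_span_bp,
            "outer_span_bp": self.outer_span_bp,
            "n_markers": self.n_markers,
            "markers": list(self.markers),
            "n_transformable": self.n_transformable,
            "n_non_transformable": self.n_non_transformable,
            "boundary_samples": {k: list(v) for k, v in self.boundary_samples.items()},
        }


def scan_genome(
    matrix: pd.DataFrame,
    phenotypes: pd.Series,
    genetic_map: GeneticMap,
    max_missing_fraction: float = 0.1,
    max_interruptions: int = 0,
    require_homozygous: bool = False,
) -> list[CandidateRegion]:
    """Concordant regions over the whole genome, strongest first.

    Non-evaluable markers never break a run; discordant markers do, up to the
    interruption budget.  Regions are ranked by concordant-marker count, ties
    broken by physical span (both descending).
    """
    status = pd.Series(
        _concordance_codes(matrix, phenotypes, max_missing_fraction, require_homozygous),
        index=matrix.columns,
    )
    cls = phenotypes.reindex(matrix.index)
    n_t = int((cls == TRANSFORMABLE).sum())
    n_n = int((cls == NON_TRANSFORMABLE).sum())
    regions: list[CandidateRegion] = []
    onchrom = genetic_map.markers.loc[matrix.columns.intersection(genetic_map.markers.index)]
    for spec in genetic_map.chromosomes:
        sub = onchrom[onchrom["chrom"] == spec.name].sort_values("bp")
        if sub.empty:
            continue
        st = status.reindex(sub.index).to_numpy(dtype=object)
        bp = sub["bp"].to_numpy()
        support = st == MarkerStatus.CONCORDANT.value
        breaker = st == MarkerStatus.DISCORDANT.value
        for i0, i1 in find_runs(support, breaker, max_interruptions):
            names = sub.index[i0 : i1 + 1][support[i0 : i1 + 1]].tolist()
            left = np.flatnonzero(breaker[:i0])
            right = i1 + 1 + np.flatnonzero(breaker[i1 + 1 :])
            outer_start = int(round(bp[left[-1]])) if left.size else 1
            outer_end = int(round(bp[right[0]])) if right.size else spec.length_bp
            regions.append(
                CandidateRegion(
                    spec.name,
                    int(round(bp[i0])),
                    int(round(bp[i1])),
                    outer_start,
                    outer_end,
                    names,
                    n_t,
                    n_n,
                )
            )
    regions.sort(key=lambda r: (-r.n_markers, -r.inner_span_bp))
    return regions


def delimit_minimal_region(
    region: CandidateRegion,
    matrix: pd.DataFrame,
    phenotypes: pd.Series,
    genetic_map: GeneticMap,
    max_interruptions: int = 0,
    segments_by_sample: dict | None = None,
    max_missing_fraction: float = 0.1,
    require_homozygous: bool = False,
) -> CandidateRegion:
    """Refine a region from the boundary recombinants.

    Inner bounds: the intersection, over transformable samples, of each
    sample's donor-carrying span overlapping the region, clipped to the
    discordant-free window around the region (a marker at which a
    non-transformable sample carries donor contradicts the fully penetrant
    model and can never lie inside the candidate interval).  The samples whose
    span ends attain the bounds are the boundary recombinants.  Outer bounds:
    the nearest marker positions beyond the inner bounds at which any
    transformable sample carries the recurrent homozygote (or the chromosome
    ends).  ``segments_by_sample`` may supply pre-computed donor segments per
    sample (as from :func:`~introscan.segments.call_segments` at the same
    interruption tolerance) to avoid recomputation.
    """
    cls = phenotypes.reindex(matrix.index)
    t_samples = matrix.index[(cls == TRANSFORMABLE).to_numpy()]
    spec = genetic_map.chromosome(region.chrom)

    spans: dict[str, tuple[int, int]] = {}
    for sid in t_samples:
        if segments_by_sample is not None and sid in segments_by_sample:
            sample_segments = segments_by_sample[sid]
        else:
            sample_segments = call_segments(
                matrix.loc[sid], genetic_map, max_interruptions, sample_id=str(sid)
            )
        segs = [
            s
            for s in sample_segments
            if s.chrom == region.chrom
            and s.end_bp >= region.inner_start_bp
            and s.start_bp <= region.inner_end_bp
        ]
        if not segs:
            raise InconsistentRegionError(
                f"transformable sample {sid!r} has no donor span over "
                f"{region.chrom}:{region.inner_start_bp}-{region.inner_end_bp}"
            )
        best = max(
            segs,
            key=lambda s: min(s.end_bp, region.inner_end_bp)
            - max(s.start_bp, region.inner_start_bp),
        )
        spans[str(sid)] = (best.start_bp, best.end_bp)

    span_start = max(s for s, _ in spans.values())
    span_end = min(e for _, e in spans.values())
    if span_start > span_end:
        raise InconsistentRegionError(
            "donor spans of transformable samples do not intersect; "
            "discordance missed upstream"
        )
    start_samples = [sid for sid, (s, _) in spans.items() if s == span_start]
    end_samples = [sid for sid, (_, e) in spans.items() if e == span_end]

    onchrom = genetic_map.markers.loc[matrix.columns.intersection(genetic_map.markers.index)]
    sub = onchrom[onchrom["chrom"] == region.chrom].sort_values("bp")
    bp = sub["bp"].to_numpy()

    # clip the span intersection to the discordant-free window around the run
    status = _concordance_codes(
        matrix[sub.index], phenotypes, max_missing_fraction, require_homozygous
    )
    disc_bp = bp[status == MarkerStatus.DISCORDANT.value]
    left_disc = disc_bp[disc_bp < region.inner_start_bp]
    right_disc = disc_bp[disc_bp > region.inner_end_bp]
    inner_start = int(max(span_start, left_disc[-1] + 1 if left_disc.size else 1))
    inner_end = int(
        min(span_end, right_disc[0] - 1 if right_disc.size else spec.length_bp)
    )
    if inner_start > inner_end:
        raise InconsistentRegionError(
            "span intersection does not overlap the concordant window"
        )

    any_rec = (matrix.loc[t_samples, sub.index].to_numpy(dtype=object) == REC).any(axis=0)
    left = np.flatnonzero(any_rec & (bp < inner_start))
    right = np.flatnonzero(any_rec & (bp > inner_end))
    outer_start = int(round(bp[left[-1]])) if left.size else 1
    outer_end = int(round(bp[right[0]])) if right.size else spec.length_bp

    in_inner = (bp >= inner_start) & (bp <= inner_end)
    markers = sub.index[in_inner].tolist() or list(region.markers)

    return CandidateRegion(
        region.chrom,
        inner_start,
        inner_end,
        outer_start,
        outer_end,
        markers,
        region.n_transformable,
        region.n_non_transformable,
        {"start": start_samples, "end": end_samples},
    )


def permutation_scan(
    matrix: pd.DataFrame,
    phenotypes: pd.Series,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    n_permutations: int = 20,
    **scan_kwargs,
) -> list[int]:
    """Diagnostic: number of candidate regions under permuted labels."""
    counts = []
    labels = phenotypes.reindex(matrix.index).to_numpy(dtype=object)
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(labels), index=matrix.index)
        counts.append(len(scan_genome(matrix, perm, genetic_map, **scan_kwargs)))
    return counts


class IntrogressionMapper(BaseEstimator):
    """Estimator: fit a genotype matrix against phenotype labels.

    Parameters mirror the functional interface; after ``fit`` the ranked,
    refined candidate regions are in ``regions_`` and per-marker concordance
    status in ``marker_status_``.
    """

    def __init__(
        self,
        genetic_map: GeneticMap | None = None,
        max_missing_fraction: float = 0.1,
        max_interruptions: int = 0,
        require_homozygous: bool = False,
        refine: bool = True,
    ):
        self.genetic_map = genetic_map
        self.max_missing_fraction = max_missing_fraction
        self.max_interruptions = max_interruptions
        self.require_homozygous = require_homozygous
        self.refine = refine

    def fit(self, X: pd.DataFrame, y):
        if self.genetic_map is None:
            raise ValueError("IntrogressionMapper needs a genetic_map")
        phenotypes = pd.Series(np.asarray(y, dtype=object), index=X.index)
        self.marker_status_ = pd.Series(
            _concordance_codes(
                X, phenotypes, self.max_missing_fraction, self.require_homozygous
            ),
            index=X.columns,
        )
        regions = scan_genome(
            X,
            phenotypes,
            self.genetic_map,
            self.max_missing_fraction,
            self.max_interruptions,
            self.require_homozygous,
        )
        self.refinement_errors_: dict[int, str] = {}
        if self.refine:
            t_samples = X.index[(phenotypes == TRANSFORMABLE).to_numpy()]
            seg_cache = {
                sid: call_segments(
                    X.loc[sid], self.genetic_map, self.max_interruptions, sample_id=str(sid)
                )
                for sid in t_samples
            }
            refined = []
            for i, r in enumerate(regions):
                try:
                    refined.append(
                        delimit_minimal_region(
                            r,
                            X,
                            phenotypes,
                            self.genetic_map,
                            self.max_interruptions,
                            segments_by_sample=seg_cache,
                            max_missing_fraction=self.max_missing_fraction,
                            require_homozygous=self.require_homozygous,
                        )
                    )
                except InconsistentRegionError as exc:
                    # keep the unrefined run; typical for weak regions whose
                    # support rests on partially missing columns
                    self.refinement_errors_[i] = str(exc)
                    refined.append(r)
            regions = refined
        self.regions_ = regions
        self.n_features_in_ = X.shape[1]
        return self

    def top_region_(self) -> CandidateRegion | None:
        if not hasattr(self, "regions_"):
            raise ValueError("IntrogressionMapper is not fitted")
        return self.regions_[0] if self.regions_ else None
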