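"""Graphical genotypes and introgression-segment calling.

Progeny array calls are encoded against the two parents into A (recurrent
homozygote), B (donor homozygote), H (heterozygote) and NA — the colour code of
a graphical genotype.  Donor-carrying introgression segments are then maximal
runs of consecutive B/H markers along a chromosome.  Missing calls are absence
of evidence and never break a run; an A call does, unless an interruption
budget absorbs it (for tolerating isolated miscalls inside a real segment).

Coordinates are 1-based inclusive bp at the supporting markers; conversion to
0-based half-open BED happens only in the writers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._runs import find_runs
from .calls import DON, HET, HET_ENC, HOM_CALLS, MISSING, NO_CALL, REC
from .genmap import GeneticMap


def encode_genotypes(
    raw: pd.DataFrame,
    call_recurrent: pd.Series,
    call_donor: pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Encode raw progeny calls to A/B/H/NA against the parental phase.

    ``raw`` is samples × markers with AA/AB/BB/NC cells; the two series give
    each marker's parental calls and must be opposite homozygotes (i.e. the
    markers passed triage).  Cells matching neither parent and not
    heterozygous are counted, set to NA, and the count returned.
    """
    markers = raw.columns
    rec = call_recurrent.reindex(markers)
    don = call_donor.reindex(markers)
    if rec.isna().any() or don.isna().any():
        missing = markers[rec.isna() | don.isna()].tolist()
        raise ValueError(f"parental calls missing for markers {missing[:5]}")
    bad = ~(rec.isin(HOM_CALLS) & don.isin(HOM_CALLS) & (rec != don))
    if bad.any():
        raise ValueError(
            f"markers without opposite homozygous parents (run triage first): "
            f"{markers[bad].tolist()[:5]}"
        )
    values = raw.to_numpy(dtype=object)
    rec_v = rec.to_numpy(dtype=object)
    don_v = don.to_numpy(dtype=object)
    out = np.full(values.shape, MISSING, dtype=object)
    out[values == rec_v] = REC
    out[values == don_v] = DON
    out[values == HET] = HET_ENC
    known = (values == rec_v) | (values == don_v) | (values == HET) | (values == NO_CALL)
    n_discordant = int((~known).sum())
    return pd.DataFrame(out, index=raw.index, columns=markers), n_discordant


@dataclass(frozen=True)
class IntrogressionSegment:
    """A contiguous donor-carrying interval in one sample.

    Bounds are the bp positions of the first and last supporting (B or H)
    marker, 1-based inclusive; ``n_markers`` counts supporting markers only.
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    contains_donor_hom: bool

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("segment start after end")
        if self.n_markers < 1:
            raise ValueError("segment without supporting markers")

    @property
    def state(self) -> str:
        return "contains_donor_hom" if self.contains_donor_hom else "het_only"


def call_segments(
    row: pd.Series,
    genetic_map: GeneticMap,
    max_interruptions: int = 0,
    sample_id: str | None = None,
) -> list[IntrogressionSegment]:
    """Donor segments of one sample row (index = retained marker names).

    Per chromosome, maximal runs of B/H calls; NA is skipped; each run may
    absorb up to ``max_interruptions`` interior A calls.
    """
    sid = sample_id if sample_id is not None else str(row.name)
    markers = genetic_map.markers.loc[row.index.intersection(genetic_map.markers.index)]
    if len(markers) != len(row):
        unknown = row.index.difference(genetic_map.markers.index).tolist()
        raise ValueError(f"markers absent from the map: {unknown[:5]}")
    segments: list[IntrogressionSegment] = []
    for spec in genetic_map.chromosomes:
        names = markers.index[markers["chrom"] == spec.name]
        if names.empty:
            continue
        sub = genetic_map.markers.loc[names].sort_values("bp")
        calls = row.reindex(sub.index).to_numpy(dtype=object)
        bp = sub["bp"].to_numpy()
        support = (calls == DON) | (calls == HET_ENC)
        breaker = calls == REC
        for i0, i1 in find_runs(support, breaker, max_interruptions):
            in_run = support[i0 : i1 + 1]
            segments.append(
                IntrogressionSegment(
                    sid,
                    spec.name,
                    int(round(bp[i0])),
                    int(round(bp[i1])),
                    int(in_run.sum()),
                    bool((calls[i0 : i1 + 1][in_run] == DON).any()),
                )
            )
    return segments


def donor_fraction(row: pd.Series) -> float:
    """Donor allele fraction of one encoded row: (B + H/2) / non-missing."""
    calls = row.to_numpy(dtype=object)
    n_b = int((calls == DON).sum())
    n_h = int((calls == HET_ENC).sum())
    n_a = int((calls == REC).sum())
    n = n_a + n_b + n_h
    if n == 0:
        raise ValueError("donor fraction undefined: all calls missing")
    return (n_b + 0.5 * n_h) / n


def segments_to_frame(segments) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_markers": s.n_markers,
            "state": s.state,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start_bp", "end_bp", "n_markers", "state"]
    )


class GenotypeEncoder(BaseEstimator, TransformerMixin):
    """Transformer: raw AA/AB/BB/NC matrix → A/B/H/NA graphical genotypes.

    ``fit`` learns the parental phase from a panel table with
    ``call_recurrent`` / ``call_donor`` columns (post-triage).
    """

    def fit(self, X: pd.DataFrame, y=None):
        for col in ("call_recurrent", "call_donor"):
            if col not in X.columns:
                raise ValueError(f"panel table lacks column {col!r}")
        self.call_recurrent_ = X["call_recurrent"].copy()
        self.call_donor_ = X["call_donor"].copy()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "call_recurrent_"):
            raise ValueError("GenotypeEncoder is not fitted")
        encoded, n_discordant = encode_genotypes(X, self.call_recurrent_, self.call_donor_)
        self.n_discordant_ = n_discordant
        return encoded


class SegmentCaller(BaseEstimator, TransformerMixin):
    """Transformer: encoded matrix → table of per-sample donor segments."""

    def __init__(self, genetic_map: GeneticMap | None = None, max_interruptions: int = 0):
        self.genetic_map = genetic_map
        self.max_interruptions = max_interruptions

    def fit(self, X=None, y=None):
        if self.genetic_map is None:
            raise ValueError("SegmentCaller needs a genetic_map")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        segs: list[IntrogressionSegment] = []
        for sid, row in X.iterrows():
            segs.extend(
                call_segments(row, self.genetic_map, self.max_interruptions, sample_id=str(sid))
            )
        return segments_to_frame(segs)
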