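"""Marker triage: classify array SNPs by parental informativeness.

A marker is informative for tracing parental origin only when the two parents
carry opposite homozygous calls and the marker has a map position.  Everything
else is excluded, in a fixed precedence order: monomorphic (both parents
called, identical homozygous), single-parent (a call from only one parent —
including the degenerate both-missing case, which is logged), unmapped, and
parent-heterozygous.  Only the partition sums are observable downstream, so
the precedence is a documented convention, not a claim about the assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .calls import HET, HOM_CALLS, NO_CALL, RAW_CALLS
from .genmap import UNMAPPED, GeneticMap

logger = logging.getLogger(__name__)


class MarkerCategory(str, Enum):
    RETAINED = "retained"
    MONOMORPHIC = "monomorphic"
    SINGLE_PARENT = "single_parent"
    UNMAPPED = "unmapped"
    PARENT_HET = "parent_het"


def classify_marker(parent1_call: str, parent2_call: str, has_chromosome: bool) -> MarkerCategory:
    """Classify one marker from its two parental calls and mappedness.

    Precedence when several exclusions apply: MONOMORPHIC, then SINGLE_PARENT,
    then UNMAPPED, then PARENT_HET; RETAINED means mapped with opposite
    homozygous parental calls.
    """
    for call in (parent1_call, parent2_call):
        if call not in RAW_CALLS:
            raise ValueError(f"unknown call symbol {call!r}; expected one of {RAW_CALLS}")
    p1, p2 = parent1_call, parent2_call
    if p1 in HOM_CALLS and p1 == p2:
        return MarkerCategory.MONOMORPHIC
    if p1 == NO_CALL or p2 == NO_CALL:
        # includes both-missing: insufficient parental information
        return MarkerCategory.SINGLE_PARENT
    if not has_chromosome:
        return MarkerCategory.UNMAPPED
    if p1 == HET or p2 == HET:
        return MarkerCategory.PARENT_HET
    return MarkerCategory.RETAINED


@dataclass
class TriageReport:
    """Partition of a panel into triage categories."""

    total: int
    counts: dict[str, int]
    retained_markers: list[str]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("triage counts do not partition the panel")
        if self.counts.get(MarkerCategory.RETAINED.value, 0) != len(self.retained_markers):
            raise ValueError("retained count disagrees with retained marker list")

    @property
    def n_retained(self) -> int:
        return self.counts[MarkerCategory.RETAINED.value]

    def per_chromosome(self, panel: pd.DataFrame) -> pd.Series:
        """Optional summary: retained markers per chromosome."""
        sub = panel.loc[self.retained_markers]
        return sub.groupby("chrom").size()

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": dict(self.counts),
            "n_retained": self.n_retained,
        }


def _classify_frame(panel: pd.DataFrame) -> pd.Series:
    """Vectorised classification of a panel table.

    ``panel`` is indexed by marker name with columns ``chrom``,
    ``call_recurrent`` and ``call_donor``.
    """
    p1 = panel["call_recurrent"].to_numpy(dtype=object)
    p2 = panel["call_donor"].to_numpy(dtype=object)
    bad = ~np.isin(p1, RAW_CALLS) | ~np.isin(p2, RAW_CALLS)
    if bad.any():
        name = panel.index[bad][0]
        raise ValueError(
            f"unknown call symbol at marker {name!r}: "
            f"({panel.loc[name, 'call_recurrent']!r}, {panel.loc[name, 'call_donor']!r})"
        )
    mapped = panel["chrom"].to_numpy(dtype=object) != UNMAPPED
    hom1 = np.isin(p1, HOM_CALLS)
    mono = hom1 & (p1 == p2)
    single = (p1 == NO_CALL) | (p2 == NO_CALL)
    het = (p1 == HET) | (p2 == HET)

    cats = np.full(len(panel), MarkerCategory.RETAINED.value, dtype=object)
    cats[het] = MarkerCategory.PARENT_HET.value
    cats[~mapped] = MarkerCategory.UNMAPPED.value
    cats[single] = MarkerCategory.SINGLE_PARENT.value
    cats[mono] = MarkerCategory.MONOMORPHIC.value

    n_both_missing = int(((p1 == NO_CALL) & (p2 == NO_CALL)).sum())
    if n_both_missing:
        logger.warning(
            "%d markers have no call from either parent; classified single_parent",
            n_both_missing,
        )
    return pd.Series(cats, index=panel.index, name="category")


def triage_panel(
    panel: pd.DataFrame, genetic_map: GeneticMap | None = None
) -> tuple[pd.DataFrame, TriageReport]:
    """Classify every marker and return the informative subset plus a report.

    The retained panel is ordered by (chromosome, bp).  Input order never
    affects the report; duplicate marker names are rejected.
    """
    if panel.index.has_duplicates:
        dupes = panel.index[panel.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate marker names: {dupes[:5]}")
    cats = _classify_frame(panel)
    counts = {c.value: int((cats == c.value).sum()) for c in MarkerCategory}
    retained = panel[cats == MarkerCategory.RETAINED.value]
    if genetic_map is not None:
        chrom_order = {c.name: i for i, c in enumerate(genetic_map.chromosomes)}
        key = retained["chrom"].map(chrom_order).to_numpy()
    else:
        key = retained["chrom"].astype(str).to_numpy()
    retained = retained.iloc[np.lexsort((retained["bp"].to_numpy(), key))]
    report = TriageReport(len(panel), counts, list(retained.index))
    logger.info(
        "triage: %d markers, retained %d (%s)",
        report.total,
        report.n_retained,
        ", ".join(f"{k}={v}" for k, v in counts.items() if k != "retained"),
    )
    return retained, report


class MarkerTriage(BaseEstimator, TransformerMixin):
    """Transformer view of marker triage.

    ``fit`` takes the panel table (marker-indexed, with ``chrom``,
    ``call_recurrent``, ``call_donor``); ``transform`` subsets a samples ×
    markers call matrix to the retained, map-ordered markers.
    """

    def __init__(self, genetic_map: GeneticMap | None = None):
        self.genetic_map = genetic_map

    def fit(self, X: pd.DataFrame, y=None):
        retained, report = triage_panel(X, self.genetic_map)
        self.report_ = report
        self.categories_ = _classify_frame(X)
        self.retained_panel_ = retained
        self.retained_markers_ = list(retained.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "retained_markers_"):
            raise ValueError("MarkerTriage is not fitted")
        missing = [m for m in self.retained_markers_ if m not in X.columns]
        if missing:
            raise ValueError(f"matrix lacks {len(missing)} retained markers, e.g. {missing[:3]}")
        return X[self.retained_markers_]
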