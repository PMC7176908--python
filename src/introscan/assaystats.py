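"""Transformation-efficiency statistics and cohort summaries.

Transformation efficiency (TE) is the percentage of cultured immature embryos
that give rise to at least one independent transgenic plant.  A line with no
recovered plants has TE = 0% by definition, however many embryos were cultured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .calls import NON_TRANSFORMABLE, TRANSFORMABLE, UNKNOWN

logger = logging.getLogger(__name__)


def compute_te(n_embryos: int, n_transgenic: int) -> float:
    """TE in percent: 100 * embryos yielding >=1 transgenic plant / embryos cultured.

    The exact value is returned; round only for display.
    """
    if n_embryos == 0:
        raise ValueError("TE undefined for zero cultured embryos")
    if n_embryos < 0 or n_transgenic < 0 or n_transgenic > n_embryos:
        raise ValueError(
            f"invalid counts: {n_transgenic} transgenic of {n_embryos} embryos"
        )
    return 100.0 * n_transgenic / n_embryos


@dataclass(frozen=True)
class AssayResult:
    """One transformation experiment on one line."""

    line_id: str
    experiment_id: str
    n_embryos: int
    n_transgenic: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_transgenic <= self.n_embryos:
            raise ValueError(
                f"{self.line_id}/{self.experiment_id}: "
                f"{self.n_transgenic} transgenic of {self.n_embryos} embryos"
            )

    @property
    def te_percent(self) -> float:
        return compute_te(self.n_embryos, self.n_transgenic)


def assays_to_frame(results) -> pd.DataFrame:
    rows = [
        {
            "line": r.line_id,
            "experiment": r.experiment_id,
            "n_embryos": r.n_embryos,
            "n_transgenic": r.n_transgenic,
            "te_percent": r.te_percent,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["line", "experiment", "n_embryos", "n_transgenic", "te_percent"])


def aggregate_te(assays: pd.DataFrame) -> pd.DataFrame:
    """Per-line TE: one column per experiment plus a pooled-count value.

    "Mean TE" across experiments is ambiguous (mean of percentages vs pooled
    counts), so both views are emitted: per-experiment TEs and
    ``te_pooled_percent`` = 100 * sum(transgenic) / sum(embryos).
    """
    required = {"line", "experiment", "n_embryos", "n_transgenic"}
    if not required.issubset(assays.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    per_exp = assays.assign(
        te_percent=[compute_te(e, t) for e, t in zip(assays["n_embryos"], assays["n_transgenic"])]
    ).pivot_table(index="line", columns="experiment", values="te_percent")
    per_exp.columns = [f"te_percent_{c}" for c in per_exp.columns]
    pooled = assays.groupby("line")[["n_embryos", "n_transgenic"]].sum()
    pooled["te_pooled_percent"] = 100.0 * pooled["n_transgenic"] / pooled["n_embryos"]
    pooled["te_mean_of_experiments"] = assays.assign(
        te=[compute_te(e, t) for e, t in zip(assays["n_embryos"], assays["n_transgenic"])]
    ).groupby("line")["te"].mean()
    return pooled.join(per_exp)


def summarize_cohort(phenotypes: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Counts per phenotype class and generation.

    ``phenotypes`` is indexed by sample id with a ``phenotype`` column and an
    optional ``generation`` column.  ``samples`` (e.g. the genotype-matrix
    sample ids) may add samples absent from the table; those are counted as
    unknown and a warning is logged.  Unknown-class samples are excluded from
    the informative class totals.
    """
    if "phenotype" not in phenotypes.columns:
        raise ValueError("phenotype table needs a 'phenotype' column")
    pheno = phenotypes.copy()
    if samples is not None:
        missing = [s for s in samples if s not in pheno.index]
        if missing:
            logger.warning("%d samples lack phenotype records: %s", len(missing), missing[:10])
            extra = pd.DataFrame({"phenotype": UNKNOWN}, index=missing)
            pheno = pd.concat([pheno, extra])
    if "generation" not in pheno.columns:
        pheno["generation"] = "all"
    pheno["generation"] = pheno["generation"].fillna("all")
    table = (
        pheno.groupby(["phenotype", "generation"])
        .size()
        .unstack(fill_value=0)
        .reindex([TRANSFORMABLE, NON_TRANSFORMABLE, UNKNOWN], fill_value=0)
    )
    table["total"] = table.sum(axis=1)
    return table
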