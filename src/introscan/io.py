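"""Readers and writers for the pipeline's tab-delimited interchange formats.

Canonical formats (all plain text, tab-delimited unless noted):

* genotype matrix — first column ``sample``, header of marker names, cells
  either raw array calls (AA/AB/BB/NC) or encoded calls (A/B/H/NA);
* marker map — columns ``marker``, ``chrom``, ``bp``, ``cM`` (chrom ``UN`` and
  empty positions for unmapped markers);
* parent-call panel — columns ``marker``, ``chrom``, ``bp``, ``cM``,
  ``call_recurrent``, ``call_donor`` (plus optional ``true_category``);
* phenotype table — columns ``sample``, ``phenotype``, optional ``generation``;
* assay table — columns ``line``, ``experiment``, ``n_embryos``, ``n_transgenic``;
* regions/segments — BED (0-based half-open, converted here from the internal
  1-based inclusive convention) plus a JSON report.

VCF import is an optional convenience for sequencing-derived calls; the
tab-delimited matrix is canonical because the data source is an array.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calls import ENCODED_CALLS, PHENOTYPE_CLASSES, RAW_CALLS
from .genmap import UNMAPPED, ChromosomeSpec, GeneticMap

_VOCABULARIES = {"raw": set(RAW_CALLS), "encoded": set(ENCODED_CALLS)}


def _check_table(path: Path, n_fields: int) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            got = line.rstrip("\n").count("\t") + 1
            if got != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({got} fields, expected {n_fields})"
                )


def read_genotype_table(path, vocabulary: str | None = None) -> pd.DataFrame:
    """Read a samples × markers call matrix.

    ``vocabulary`` is ``"raw"``, ``"encoded"`` or None (accept either, but not
    a mixture).  Duplicate sample or marker names and unknown call tokens are
    rejected, naming the offending cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    markers = header[1:]
    if len(set(markers)) != len(markers):
        dupes = sorted({m for m in markers if markers.count(m) > 1})
        raise ValueError(f"duplicate marker columns: {dupes[:5]}")
    _check_table(path, len(header))
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index.name = None
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids: {df.index[df.index.duplicated()].tolist()[:5]}")
    vocabularies = [_VOCABULARIES[vocabulary]] if vocabulary else list(_VOCABULARIES.values())
    values = df.to_numpy(dtype=object)
    for vocab in vocabularies:
        ok = np.isin(values, list(vocab))
        if ok.all():
            return df
    bad = ~np.isin(values, list(set().union(*vocabularies)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown call token {values[i, j]!r} at sample {df.index[i]!r}, "
            f"marker {df.columns[j]!r}"
        )
    raise ValueError("matrix mixes raw (AA/AB/BB/NC) and encoded (A/B/H/NA) vocabularies")


def write_genotype_table(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample")


def read_map_table(path, chromosomes: list[ChromosomeSpec] | None = None) -> GeneticMap:
    """Read a marker map; chromosome lengths default to the observed extrema."""
    path = Path(path)
    _check_table(path, 4)
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    required = ["marker", "chrom", "bp", "cM"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: map table must have columns {required}")
    df = df.set_index("marker")
    df.index.name = None
    if chromosomes is None:
        chromosomes = []
        for chrom, sub in df[df["chrom"] != UNMAPPED].groupby("chrom", sort=True):
            chromosomes.append(
                ChromosomeSpec(str(chrom), int(sub["bp"].max()), float(sub["cM"].max()))
            )
    return GeneticMap(chromosomes, df[["chrom", "bp", "cM"]])


def write_map_table(genetic_map: GeneticMap, path) -> None:
    genetic_map.markers.to_csv(path, sep="\t", index_label="marker")


def read_panel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str}, keep_default_na=False, na_values=[""])
    if "marker" not in df.columns:
        raise ValueError(f"{path}: panel table needs a 'marker' column")
    for col in ("chrom", "call_recurrent", "call_donor"):
        if col not in df.columns:
            raise ValueError(f"{path}: panel table needs a {col!r} column")
    df = df.set_index("marker")
    if df.index.has_duplicates:
        raise ValueError("duplicate marker names in panel table")
    return df


def write_panel_table(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index_label="marker")


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs 'sample' and 'phenotype' columns")
    bad = ~df["phenotype"].isin(PHENOTYPE_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown phenotype class {df.loc[bad, 'phenotype'].iloc[0]!r}; "
            f"expected one of {PHENOTYPE_CLASSES}"
        )
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in phenotype table")
    return df


def write_phenotype_table(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample")


def read_assay_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "experiment": str})
    required = {"line", "experiment", "n_embryos", "n_transgenic"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: assay table needs columns {sorted(required)}")
    return df


def write_assay_table(assays: pd.DataFrame, path) -> None:
    assays.to_csv(path, sep="\t", index=False)


# -- BED and reports ---------------------------------------------------------


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Per-sample donor segments as BED6-like lines (name = sample, score = markers)."""
    with open(path, "w") as fh:
        for _, row in segments.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start_bp']) - 1}\t{int(row['end_bp'])}\t"
                f"{row['sample']}\t{int(row['n_markers'])}\t.\t{row['state']}\n"
            )


def write_region_bed(regions, path, which: str = "outer") -> None:
    """Candidate regions as BED (0-based half-open), one line per region."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            if which == "inner":
                start, end = r.inner_start_bp, r.inner_end_bp
            else:
                start, end = r.outer_start_bp, r.outer_end_bp
            fh.write(f"{r.chrom}\t{start - 1}\t{end}\tregion_{i}\t{r.n_markers}\t.\n")


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """BED lines as (chrom, start_bp, end_bp, name) with 1-based inclusive bounds."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with fewer than 3 fields")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            out.append((fields[0], int(fields[1]) + 1, int(fields[2]), name))
    return out


def write_report(report: dict, path) -> None:
    """Structured JSON report; always stamped with the package version."""
    payload = {"introscan_version": __version__, **report}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def load_config(path) -> dict:
    """Structured run configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


# -- optional VCF import -----------------------------------------------------


def read_genotype_vcf(path, samples: list[str] | None = None) -> pd.DataFrame:
    """Import biallelic VCF genotypes as a raw AA/AB/BB/NC matrix.

    GT 0/0 → AA, 1/1 → BB, 0/1 → AB, missing → NC.  Marker names come from the
    ID column (or chrom:pos when absent).  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    sample_ids = list(vcf.samples)
    names: list[str] = []
    columns: list[np.ndarray] = []
    code_to_call = np.array(["AA", "AB", "BB", "NC"], dtype=object)
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(variant.gt_types)
        code = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=3)
        names.append(name)
        columns.append(code_to_call[code])
    matrix = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=object),
        index=sample_ids,
        columns=names,
    )
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate variant ids in VCF")
    return matrix
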