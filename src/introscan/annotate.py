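"""Candidate-gene lookup: intersect a mapped region with a gene annotation.

Gene models come from GFF3 (feature type ``gene`` only, via gffutils) or BED.
All coordinates are normalised to 1-based inclusive internally; BED's 0-based
half-open convention is converted at the reader/writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneRecord:
    """One gene-level annotation record (1-based inclusive bp)."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."
    confidence: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start after end")


_CONFIDENCE_KEYS = ("primary_confidence_class", "confidence", "biotype_confidence")


def _read_gff3(path: Path) -> list[GeneRecord]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    records = []
    for feat in db.features_of_type("gene"):
        conf = None
        for key in _CONFIDENCE_KEYS:
            if key in feat.attributes:
                conf = feat.attributes[key][0]
                break
        records.append(
            GeneRecord(feat.id, feat.seqid, feat.start, feat.end, feat.strand or ".", conf)
        )
    return records


def _read_bed(path: Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with fewer than 3 fields")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start0 < 0 or end0 <= start0:
                raise ValueError(f"{path}:{lineno}: invalid BED interval {start0}-{end0}")
            name = fields[3] if len(fields) > 3 and fields[3] else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            records.append(GeneRecord(name, fields[0], start0 + 1, end0, strand))
    return records


def read_annotation(path, fmt: str | None = None) -> list[GeneRecord]:
    """Read gene records from a GFF3 or BED file.

    ``fmt`` is ``"gff3"`` or ``"bed"``; by default it is inferred from the
    file extension.  GFF3 keeps only features of type ``gene``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gff": "gff3", "gff3": "gff3", "bed": "bed"}.get(suffix.lstrip("."))
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    fmt = fmt.lower()
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed(path)
    raise ValueError(f"unsupported annotation format {fmt!r}")


def genes_in_region(
    region,
    genes: list[GeneRecord],
    overlap_rule: str = "any",
    which: str = "outer",
    high_confidence_only: bool = False,
) -> tuple[list[GeneRecord], int, int]:
    """Genes intersecting a candidate region.

    ``region`` is a :class:`~introscan.contrast.CandidateRegion` or a
    ``(chrom, start_bp, end_bp)`` tuple (1-based inclusive).  ``which``
    selects the outer (default) or inner interval of a CandidateRegion.
    ``overlap_rule`` is ``"any"`` (≥1 bp overlap) or ``"contained"`` (gene
    fully inside).  Returns (gene list ordered by start, count, span_bp).
    """
    if isinstance(region, tuple):
        chrom, start, end = region
    else:
        chrom = region.chrom
        if which == "inner":
            start, end = region.inner_start_bp, region.inner_end_bp
        elif which == "outer":
            start, end = region.outer_start_bp, region.outer_end_bp
        else:
            raise ValueError("which must be 'inner' or 'outer'")
    if overlap_rule not in ("any", "contained"):
        raise ValueError("overlap_rule must be 'any' or 'contained'")
    if high_confidence_only:
        genes = [g for g in genes if (g.confidence or "").upper().startswith("HC")]
    known = sorted({g.chrom for g in genes})
    if genes and chrom not in known:
        raise ValueError(
            f"chromosome {chrom!r} absent from annotation; known chromosomes: {known}"
        )
    tree = IntervalTree()
    for g in genes:
        if g.chrom == chrom:
            # interval tree is half-open; widen the inclusive end by one
            tree.addi(g.start_bp, g.end_bp + 1, g)
    hits = [iv.data for iv in tree.overlap(start, end + 1)]
    if overlap_rule == "contained":
        hits = [g for g in hits if g.start_bp >= start and g.end_bp <= end]
    hits.sort(key=lambda g: (g.start_bp, g.end_bp, g.gene_id))
    span = end - start + 1
    return hits, len(hits), span
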