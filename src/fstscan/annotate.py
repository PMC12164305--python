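"""Map detected selection regions onto gene intervals from a GFF3 annotation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from gffutils import feature as gff_feature
from intervaltree import IntervalTree

from .dsrscan import DSRegion


class GffParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """One gene interval (1-based inclusive) from a GFF3 annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gff_genes(path) -> list[GeneRecord]:
    """Read gene-type features from a GFF3 file.

    Only records whose feature type is ``gene`` are retained; the ID attribute
    is required and must be unique; Name is optional. Output is sorted by
    (chromosome, start).
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = gff_feature.feature_from_line(line)
        except Exception as exc:
            raise GffParseError(f"{path}:{lineno}: {exc}") from exc
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID", [])
        if not ids:
            raise GffParseError(f"{path}:{lineno}: gene feature without ID attribute")
        gid = ids[0]
        if gid in seen:
            raise GffParseError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
        seen.add(gid)
        names = feat.attributes.get("Name", [])
        genes.append(
            GeneRecord(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                gene_id=gid,
                gene_name=names[0] if names else None,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def map_regions_to_genes(
    regions: Iterable[DSRegion], genes: Iterable[GeneRecord]
) -> tuple[dict[int, list[str]], list[str]]:
    """Assign genes to regions by any-bp interval intersection (strand ignored).

    Returns (region id -> sorted gene ids, deduplicated union of gene ids).
    Both regions and genes use 1-based inclusive coordinates, so intervals
    [a1, a2] and [b1, b2] intersect iff a1 <= b2 and b1 <= a2.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneRecord] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
        by_id[g.gene_id] = g
    per_region: dict[int, list[str]] = {}
    union: set[str] = set()
    for r in regions:
        tree = trees.get(r.chrom)
        hits = sorted(iv.data for iv in tree.overlap(r.start, r.end + 1)) if tree else []
        per_region[r.id] = hits
        union.update(hits)
    return per_region, sorted(union)


def gene_map_to_frame(
    regions: list[DSRegion], per_region: dict[int, list[str]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.name,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "genes": ",".join(per_region.get(r.id, [])),
            }
            for r in regions
        ],
        columns=["region", "chrom", "start", "end", "genes"],
    )
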