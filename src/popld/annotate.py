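"""Positional SNP classification from gene models, and region tagging.

Sites are assigned one of four genomic-context classes with precedence
coding > intronic > flank > intergenic:

* ``coding`` — inside a CDS interval;
* ``intronic`` — inside a gene span but not in CDS (exonic UTR bases
  fold into this within-gene non-coding bucket);
* ``flank`` — within a fixed distance (default 5 kb) of a gene span,
  up- or downstream symmetrically, but outside every gene;
* ``intergenic`` — everything else.

This is a deliberately simple positional classifier — no codon-level
consequence calling — sufficient for the four-bucket summary of where
SNPs fall relative to genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .vcf_io import RegionSet

logger = logging.getLogger(__name__)

CLASSES = ("coding", "intronic", "flank", "intergenic")


@dataclass
class GeneModel:
    """One gene: its span, strand, and exon/CDS intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in self.exons + self.cds:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"feature [{s},{e}) outside gene span of {self.gene_id}")


class GeneIndex:
    """Interval-tree index over gene models for point classification."""

    def __init__(self, genes: Iterable[GeneModel], flank: int = 5000):
        self.flank = flank
        self.genes = list(genes)
        self._cds: Dict[str, IntervalTree] = {}
        self._span: Dict[str, IntervalTree] = {}
        self._flank: Dict[str, IntervalTree] = {}
        self._warned: set = set()
        for g in self.genes:
            self._span.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
            self._flank.setdefault(g.chrom, IntervalTree()).addi(
                max(0, g.start - flank), g.end + flank
            )
            for s, e in g.cds:
                self._cds.setdefault(g.chrom, IntervalTree()).addi(s, e)

    def classify(self, chrom: str, pos: int) -> str:
        """Class of a 0-based position; intergenic (with one warning per
        chromosome) when the chromosome has no annotation."""
        if chrom not in self._span:
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from gene annotation", chrom)
                self._warned.add(chrom)
            return "intergenic"
        if chrom in self._cds and self._cds[chrom].overlaps(pos):
            return "coding"
        if self._span[chrom].overlaps(pos):
            return "intronic"
        if self._flank[chrom].overlaps(pos):
            return "flank"
        return "intergenic"


def read_gff3(path: str) -> List[GeneModel]:
    """Load gene models (gene spans with exon/CDS children) from GFF3."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons: List[Tuple[int, int]] = []
        cds: List[Tuple[int, int]] = []
        for child in db.children(g, featuretype=("exon", "CDS")):
            iv = (child.start - 1, child.end)  # GFF3 1-based closed -> half-open
            (exons if child.featuretype == "exon" else cds).append(iv)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return genes


def classify_site(
    chrom: str, pos: int, genes: GeneIndex, *, one_based: bool = True
) -> str:
    """Genomic-context class of a site (1-based position by default)."""
    return genes.classify(chrom, pos - 1 if one_based else pos)


def class_summary(
    sites: Sequence[Tuple[str, int]],
    genes: GeneIndex,
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Per-class counts and percentages for (chrom, 1-based pos) sites."""
    rows = []
    groups: Dict[str, Counter] = {}
    for chrom, pos in sites:
        key = chrom if per_chromosome else "all"
        groups.setdefault(key, Counter())[classify_site(chrom, pos, genes)] += 1
    for key in sorted(groups):
        counts = groups[key]
        total = sum(counts.values())
        for cls in CLASSES:
            rows.append(
                {
                    "group": key,
                    "class": cls,
                    "count": counts.get(cls, 0),
                    "percent": 100.0 * counts.get(cls, 0) / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["group", "class", "count", "percent"])


def tag_regions(
    sites: Sequence[Tuple[str, int]], regions: RegionSet
) -> List[List[str]]:
    """All enclosing region names per (chrom, 1-based pos) site."""
    return [regions.containing(chrom, pos - 1) for chrom, pos in sites]


def stratify_values(
    sites: Sequence[Tuple[str, int]],
    values: Sequence[float],
    regions: RegionSet,
) -> pd.DataFrame:
    """Mean of a per-site value inside each named region vs outside all.

    Used e.g. to contrast mean F_ST or r² inside an inversion with the
    collinear background.
    """
    labels = tag_regions(sites, regions)
    rows = []
    for name in regions.names():
        inside = [v for v, labs in zip(values, labels) if name in labs]
        rows.append(
            {
                "region": name,
                "n": len(inside),
                "mean": sum(inside) / len(inside) if inside else float("nan"),
            }
        )
    outside = [v for v, labs in zip(values, labels) if not labs]
    rows.append(
        {
            "region": "outside_all",
            "n": len(outside),
            "mean": sum(outside) / len(outside) if outside else float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["region", "n", "mean"])
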