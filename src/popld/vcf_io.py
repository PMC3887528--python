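"""VCF, BED and population-table I/O.

All statistics in this package operate on a sites-by-samples dosage
matrix (:class:`GenotypeMatrix`).  This module converts between that
representation and the on-disk formats: multi-sample VCF v4.2 with
GATK-style INFO annotations, BED 3+ region files, and a two-column
sample-to-population TSV.

Coordinates are 0-based half-open internally; VCF positions are 1-based
on disk, per the standard.  Genotypes are treated as unphased
throughout: ``/`` and ``|`` separators are read identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

#: INFO/site annotations carried on a SiteRecord.  QUAL comes from the
#: VCF QUAL column, the rest from INFO.  DP is an integer tag.
ANNOTATION_TAGS = (
    "QUAL",
    "QD",
    "MQ",
    "FS",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
    "DP",
)

#: Dosage value marking a missing genotype.
MISSING = -1


class VcfParseError(ValueError):
    """Raised when a VCF or region file cannot be parsed."""


@dataclass
class SiteRecord:
    """One VCF site: alleles, per-sample genotypes and annotations.

    ``genotypes`` holds one ``(a, b)`` pair of allele indices per sample
    (0 = REF); either index may be ``None`` for a missing call.
    ``annotations`` maps tag name to float (DP to int); a tag that was
    absent from the record is absent from the map — absent is not 0.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: Tuple[str, ...]
    genotypes: List[Tuple[Optional[int], Optional[int]]]
    annotations: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.alts) < 1:
            raise ValueError("at least one ALT allele required")
        self.alts = tuple(self.alts)
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            for a in gt:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"allele index {a} out of range at {self.chrom}:{self.pos}"
                    )

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity key; biallelic records only."""
        if len(self.alts) != 1:
            raise ValueError("key is defined for biallelic records only")
        return (self.chrom, self.pos, self.ref, self.alts[0])

    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def n_called(self) -> int:
        return sum(1 for a, b in self.genotypes if a is not None and b is not None)

    def dosages(self) -> np.ndarray:
        """Alt-allele count per sample (biallelic records), MISSING if uncalled."""
        if len(self.alts) != 1:
            raise ValueError("dosages are defined for biallelic records only")
        out = np.full(len(self.genotypes), MISSING, dtype=np.int8)
        for i, (a, b) in enumerate(self.genotypes):
            if a is not None and b is not None:
                out[i] = a + b
        return out


@dataclass
class GenotypeMatrix:
    """Sites-by-samples alt-allele dosage matrix with population labels.

    ``dosages`` is an ``(n_sites, n_samples)`` integer array over
    {0, 1, 2, MISSING}; ``sites`` holds ``(chrom, pos, ref, alt)`` in
    strictly increasing (chrom, pos) order.
    """

    sites: List[Tuple[str, int, str, str]]
    dosages: np.ndarray
    samples: List[str]
    populations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        keys = [(c, p) for c, p, _, _ in self.sites]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be strictly sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> List[str]:
        seen: List[str] = []
        for c, _, _, _ in self.sites:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for c, p, _, _ in self.sites if c == chrom], dtype=np.int64)

    def chrom_slice(self, chrom: str) -> "GenotypeMatrix":
        idx = [i for i, (c, _, _, _) in enumerate(self.sites) if c == chrom]
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            dosages=self.dosages[idx],
            samples=list(self.samples),
            populations=dict(self.populations),
        )

    def population_columns(self, label: str) -> np.ndarray:
        cols = [j for j, s in enumerate(self.samples) if self.populations.get(s) == label]
        if not cols:
            raise KeyError(f"no samples labelled {label!r}")
        return np.array(cols, dtype=int)

    def dosages_by_population(self) -> Dict[str, np.ndarray]:
        """Dosage sub-matrices keyed by population label (column order kept)."""
        labels: List[str] = []
        for s in self.samples:
            lab = self.populations.get(s)
            if lab is None:
                raise KeyError(f"sample {s!r} has no population label")
            if lab not in labels:
                labels.append(lab)
        return {lab: self.dosages[:, self.population_columns(lab)] for lab in labels}


@dataclass
class RegionSet:
    """Named genomic intervals (inversions, centromeres, telomeres).

    Intervals are 0-based half-open; within a name they are normalized:
    sorted, and overlapping or touching intervals merged.
    """

    regions: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)

    def add(self, name: str, chrom: str, start: int, end: int) -> None:
        if start < 0:
            raise ValueError(f"negative start {start} for region {name}")
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end}) for region {name}")
        self.regions.setdefault(name, []).append((chrom, int(start), int(end)))
        self._normalize(name)

    def _normalize(self, name: str) -> None:
        ivs = sorted(self.regions[name])
        merged: List[Tuple[str, int, int]] = []
        for c, s, e in ivs:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                pc, ps, pe = merged[-1]
                merged[-1] = (pc, ps, max(pe, e))
            else:
                merged.append((c, s, e))
        self.regions[name] = merged

    def names(self) -> List[str]:
        return sorted(self.regions)

    def intervals(self, name: str) -> List[Tuple[str, int, int]]:
        return list(self.regions[name])

    def containing(self, chrom: str, pos: int) -> List[str]:
        """Names of all regions enclosing 0-based position ``pos``."""
        out = []
        for name, ivs in self.regions.items():
            if any(c == chrom and s <= pos < e for c, s, e in ivs):
                out.append(name)
        return sorted(out)


# ---------------------------------------------------------------------------
# VCF reading / writing (pysam-backed)
# ---------------------------------------------------------------------------

def read_vcf(path: str, samples: Optional[Sequence[str]] = None) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a VCF v4.x file, in file order.

    ``samples`` restricts to a subset (error listing any id absent from
    the header).  Missing genotypes are preserved as missing; the
    annotation tags in :data:`ANNOTATION_TAGS` are parsed when present.
    """
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    try:
        header_samples = list(vf.header.samples)
        if samples is not None:
            missing = [s for s in samples if s not in header_samples]
            if missing:
                raise VcfParseError(
                    f"samples not in VCF header: {', '.join(missing)}"
                )
            vf.subset_samples(list(samples))
        use_samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue  # monomorphic reference block; nothing to convert
            genotypes: List[Tuple[Optional[int], Optional[int]]] = []
            for s in use_samples:
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or len(gt) == 0:
                    gt = (None, None)
                if len(gt) == 1:
                    gt = (gt[0], None)
                genotypes.append((gt[0], gt[1]))
            ann: Dict[str, float] = {}
            if rec.qual is not None:
                ann["QUAL"] = float(rec.qual)
            for tag in ANNOTATION_TAGS:
                if tag in ("QUAL",):
                    continue
                if tag in rec.info:
                    val = rec.info[tag]
                    if isinstance(val, tuple):
                        val = val[0]
                    if tag == "DP":
                        ann[tag] = int(val)
                    else:
                        ann[tag] = float(val)
            yield SiteRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts),
                genotypes=genotypes,
                annotations=ann,
            )
    finally:
        vf.close()


def read_contig_lengths(path: str) -> Dict[str, int]:
    """Contig name -> length from a VCF header (contigs without a
    declared length are omitted)."""
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    try:
        return {
            name: contig.length
            for name, contig in vf.header.contigs.items()
            if contig.length is not None
        }
    finally:
        vf.close()


def _build_header(
    samples: Sequence[str], contigs: Dict[str, int]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    info_defs = [
        ("QD", "Float", "Variant confidence normalized by depth"),
        ("MQ", "Float", "RMS mapping quality"),
        ("FS", "Float", "Strand bias Fisher phred score"),
        ("HaplotypeScore", "Float", "Haplotype consistency score"),
        ("MQRankSum", "Float", "Mapping quality rank-sum z"),
        ("ReadPosRankSum", "Float", "Read position rank-sum z"),
        ("DP", "Integer", "Combined depth across samples"),
    ]
    for tag, typ, desc in info_defs:
        header.add_meta(
            "INFO",
            items=[("ID", tag), ("Number", "1"), ("Type", typ), ("Description", desc)],
        )
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path: str,
    records: Iterable[SiteRecord],
    samples: Sequence[str],
    contigs: Dict[str, int],
) -> None:
    """Write SiteRecords to an uncompressed VCF v4.2 file.

    Float annotations are stored at VCF single precision; values already
    representable at that precision round-trip exactly through
    :func:`read_vcf`.
    """
    header = _build_header(samples, contigs)
    vf = pysam.VariantFile(path, "w", header=header)
    try:
        for rec in records:
            out = vf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
            )
            if "QUAL" in rec.annotations:
                out.qual = rec.annotations["QUAL"]
            for tag in ANNOTATION_TAGS:
                if tag == "QUAL":
                    continue
                if tag in rec.annotations:
                    val = rec.annotations[tag]
                    out.info[tag] = int(val) if tag == "DP" else float(val)
            for s, gt in zip(samples, rec.genotypes):
                out.samples[s]["GT"] = gt
                out.samples[s].phased = False
            vf.write(out)
    finally:
        vf.close()


def records_to_matrix(
    records: Iterable[SiteRecord], populations: Dict[str, str], samples: Sequence[str]
) -> GenotypeMatrix:
    """Convert biallelic SiteRecords to a sorted GenotypeMatrix.

    Raises on multiallelic records (the filter cascade must have removed
    them) and on duplicate (chrom, pos).
    """
    recs = list(records)
    for r in recs:
        if len(r.alts) != 1:
            raise ValueError(
                f"multiallelic record at {r.chrom}:{r.pos}; "
                "run the filter cascade before matrix conversion"
            )
        if len(r.genotypes) != len(samples):
            raise ValueError(
                f"record at {r.chrom}:{r.pos} has {len(r.genotypes)} genotypes "
                f"for {len(samples)} samples"
            )
    recs.sort(key=lambda r: (r.chrom, r.pos))
    for a, b in zip(recs, recs[1:]):
        if (a.chrom, a.pos) == (b.chrom, b.pos):
            raise ValueError(f"duplicate site {a.chrom}:{a.pos}")
    sites = [(r.chrom, r.pos, r.ref, r.alts[0]) for r in recs]
    if recs:
        dosages = np.vstack([r.dosages() for r in recs])
    else:
        dosages = np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        sites=sites, dosages=dosages, samples=list(samples), populations=dict(populations)
    )


# ---------------------------------------------------------------------------
# Region and population tables
# ---------------------------------------------------------------------------

def read_regions(path: str, default_name: Optional[str] = None) -> RegionSet:
    """Read a BED 3+ file into a RegionSet.

    Column 4, when present, names the region (e.g. an inversion label);
    otherwise ``default_name`` (or the file stem) is used.  Coordinates
    are 0-based half-open, per BED.
    """
    fallback = default_name or os.path.splitext(os.path.basename(path))[0]
    rs = RegionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise VcfParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VcfParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise VcfParseError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise VcfParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) >= 4 else fallback
            rs.add(name, chrom, start, end)
    return rs


def write_regions(path: str, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for name in regions.names():
            for chrom, start, end in regions.intervals(name):
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_populations(path: str) -> Dict[str, str]:
    """Read a two-column sample<TAB>population table."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise VcfParseError(f"{path}:{lineno}: expected sample and population")
            out[fields[0]] = fields[1]
    return out


def write_populations(path: str, populations: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")
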