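"""Nucleotide diversity, SNP density and Weir-Cockerham F_ST.

Per-site nucleotide diversity uses the unbiased heterozygosity
pi = 2 j (n - j) / (n (n - 1)) for j alternate-allele copies among n
called alleles, i.e. the probability that two alleles drawn without
replacement differ.  Windowed pi divides the summed per-site values by
the full window length in bases, so monomorphic or unascertained bases
contribute zero to the numerator — the convention of windowed-diversity
tools operating on SNP-only VCFs.

F_ST follows Weir & Cockerham's (1984) variance-component estimator for
diploid, biallelic data: per site, components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from per-population sample sizes, allele frequencies and
observed heterozygote frequencies; the multi-site ("weighted") estimate
is sum(a) / sum(a + b + c).  Negative per-site components are retained
in the sums — truncating them would bias the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .vcf_io import MISSING, GenotypeMatrix
from .windows import WindowStat

logger = logging.getLogger(__name__)


@dataclass
class SitePi:
    chrom: str
    pos: int
    pi: float
    n_alleles: int


@dataclass
class FstComponents:
    """Weir-Cockerham per-site variance components.

    a + b + c can be <= 0 at (near-)monomorphic sites; such sites are
    skipped when forming ratios but kept in component lists.
    """

    chrom: str
    pos: int
    a: float
    b: float
    c: float

    @property
    def denominator(self) -> float:
        return self.a + self.b + self.c


def site_pi(dosages: np.ndarray, chrom: str = "", pos: int = 0) -> Optional[SitePi]:
    """Unbiased per-site heterozygosity from a dosage vector.

    Missing genotypes are dropped.  Returns None (site skipped) when
    fewer than two alleles are called.
    """
    d = np.asarray(dosages)
    called = d[d != MISSING]
    n = 2 * len(called)
    if n < 2:
        logger.debug("site %s:%s skipped for pi: <2 called alleles", chrom, pos)
        return None
    j = int(called.sum())
    pi = 2.0 * j * (n - j) / (n * (n - 1))
    return SitePi(chrom=chrom, pos=pos, pi=pi, n_alleles=n)


def matrix_site_pi(matrix: GenotypeMatrix) -> List[SitePi]:
    out = []
    for (chrom, pos, _, _), row in zip(matrix.sites, matrix.dosages):
        sp = site_pi(row, chrom, pos)
        if sp is not None:
            out.append(sp)
    return out


def windowed_pi(
    site_pis: Sequence[SitePi],
    windows,
    min_values: int = 0,
) -> List[WindowStat]:
    """Per-window pi: summed site values divided by window length (bp).

    ``windows`` is a per-chromosome dict of (start, end) lists or a
    single list applied to every chromosome seen.  An empty window has
    pi 0 — diversity is defined over all bases, not just variant ones.
    """
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    last = None
    for sp in site_pis:
        if last is not None and sp.chrom == last[0] and sp.pos < last[1]:
            raise ValueError("site_pis must be sorted by (chrom, pos)")
        last = (sp.chrom, sp.pos)
        by_chrom.setdefault(sp.chrom, ([], []))  # type: ignore[arg-type]
        by_chrom[sp.chrom][0].append(sp.pos)  # type: ignore[attr-defined]
        by_chrom[sp.chrom][1].append(sp.pi)  # type: ignore[attr-defined]

    out: List[WindowStat] = []
    chroms = list(windows) if isinstance(windows, dict) else list(by_chrom)
    for chrom in chroms:
        ivs = windows[chrom] if isinstance(windows, dict) else windows
        pos_list, pi_list = by_chrom.get(chrom, ([], []))
        pos = np.asarray(pos_list, dtype=np.int64) - 1  # 1-based site -> 0-based
        pival = np.asarray(pi_list, dtype=float)
        for start, end in ivs:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            n = int(hi - lo)
            if n < min_values:
                out.append(WindowStat(chrom, start, end, math.nan, n, excluded=True))
                continue
            value = float(pival[lo:hi].sum()) / (end - start)
            out.append(WindowStat(chrom, start, end, value, n))
    return out


def snp_density(n_snps: int, span_bp: int) -> float:
    """Span per SNP: the X of "one SNP per X bases".  NaN when no SNPs."""
    if span_bp <= 0:
        raise ValueError("span must be positive")
    if n_snps == 0:
        return math.nan
    return span_bp / n_snps


def wc_fst_site(
    dosages_by_population: Sequence[np.ndarray],
    chrom: str = "",
    pos: int = 0,
) -> Optional[FstComponents]:
    """Weir-Cockerham (1984) variance components at one biallelic site.

    Each element of ``dosages_by_population`` is that population's
    dosage vector (missing genotypes dropped per population).  Returns
    None when any population has no called genotype.
    """
    ns: List[float] = []
    ps: List[float] = []
    hs: List[float] = []
    for d in dosages_by_population:
        d = np.asarray(d)
        called = d[d != MISSING]
        n = len(called)
        if n == 0:
            logger.debug("site %s:%s skipped for fst: empty population", chrom, pos)
            return None
        ns.append(float(n))
        ps.append(float(called.sum()) / (2 * n))
        hs.append(float(np.count_nonzero(called == 1)) / n)
    r = len(ns)
    if r < 2:
        raise ValueError("need at least two populations")
    n_arr = np.array(ns)
    p_arr = np.array(ps)
    h_arr = np.array(hs)
    nbar = n_arr.mean()
    if nbar <= 1:
        return None  # single individual per population: components undefined
    nc = (r * nbar - (n_arr**2).sum() / (r * nbar)) / (r - 1)
    if nc == 0:
        return None
    pbar = (n_arr * p_arr).sum() / (r * nbar)
    s2 = (n_arr * (p_arr - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_arr * h_arr).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return FstComponents(chrom=chrom, pos=pos, a=a, b=b, c=c)


def matrix_fst_components(matrix: GenotypeMatrix) -> List[FstComponents]:
    by_pop = matrix.dosages_by_population()
    pops = list(by_pop)
    out = []
    for i, (chrom, pos, _, _) in enumerate(matrix.sites):
        comp = wc_fst_site([by_pop[p][i] for p in pops], chrom, pos)
        if comp is not None:
            out.append(comp)
    return out


def wc_fst_aggregate(components: Iterable[FstComponents]) -> float:
    """Ratio-of-sums F_ST: sum(a) / sum(a+b+c) over usable sites.

    Sites whose total variance a+b+c is not positive carry no
    information about the ratio and are skipped.  NaN when no usable
    site remains.  Not clamped: small or negative values are reported
    as computed.
    """
    num = 0.0
    den = 0.0
    for comp in components:
        d = comp.denominator
        if d > 0:
            num += comp.a
            den += d
    if den == 0:
        return math.nan
    return num / den


def windowed_fst(
    components: Sequence[FstComponents],
    windows,
    min_values: int = 100,
) -> List[WindowStat]:
    """Per-window ratio-of-sums F_ST; windows under min_values excluded."""
    by_chrom: Dict[str, List[FstComponents]] = {}
    for comp in components:
        by_chrom.setdefault(comp.chrom, []).append(comp)
    out: List[WindowStat] = []
    chroms = list(windows) if isinstance(windows, dict) else list(by_chrom)
    for chrom in chroms:
        ivs = windows[chrom] if isinstance(windows, dict) else windows
        comps = sorted(by_chrom.get(chrom, []), key=lambda c: c.pos)
        pos = np.array([c.pos for c in comps], dtype=np.int64) - 1
        a = np.array([c.a for c in comps])
        d = np.array([c.denominator for c in comps])
        usable = d > 0
        for start, end in ivs:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            use = usable[lo:hi]
            n = int(use.sum())
            if n < min_values or d[lo:hi][use].sum() == 0:
                out.append(WindowStat(chrom, start, end, math.nan, n, excluded=True))
                continue
            value = float(a[lo:hi][use].sum() / d[lo:hi][use].sum())
            out.append(WindowStat(chrom, start, end, value, n))
    return out


def fst_by_chromosome(matrix: GenotypeMatrix) -> Dict[str, float]:
    """Weighted F_ST estimated independently for each chromosome arm."""
    comps = matrix_fst_components(matrix)
    by_chrom: Dict[str, List[FstComponents]] = {}
    for c in comps:
        by_chrom.setdefault(c.chrom, []).append(c)
    return {chrom: wc_fst_aggregate(cl) for chrom, cl in by_chrom.items()}
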