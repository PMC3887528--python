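"""Genotype-based linkage disequilibrium: pairwise r², decay curves,
and windowed LD for pairs 1-10 kb apart.

r² is the squared Pearson correlation between the two sites'
alt-allele dosage vectors (0/1/2), computed directly from genotypes —
no phasing involved.  Samples missing at either site are dropped
pairwise; a pair where either restricted vector is constant is skipped,
not counted as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .vcf_io import MISSING, GenotypeMatrix
from .windows import WindowStat, make_windows

logger = logging.getLogger(__name__)


@dataclass
class LDDecayCurve:
    """Mean r² by pairwise-distance bin.

    ``bin_edges`` has one more element than ``mean_r2``; bin i covers
    distances [bin_edges[i], bin_edges[i+1]).  Bins with no pairs carry
    mean_r2 = nan.
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    pair_count: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.mean_r2)

    def bin_mean(self, lo: int, hi: int) -> float:
        """Pair-weighted mean r² over bins covering [lo, hi)."""
        sel = (self.bin_edges[:-1] >= lo) & (self.bin_edges[1:] <= hi)
        cnt = self.pair_count[sel]
        if cnt.sum() == 0:
            return math.nan
        vals = np.where(cnt > 0, np.nan_to_num(self.mean_r2[sel]), 0.0)
        return float((vals * cnt).sum() / cnt.sum())


def genotype_r2(d1: np.ndarray, d2: np.ndarray) -> Optional[float]:
    """Squared dosage correlation over samples called at both sites.

    None when fewer than two complete cases remain or either restricted
    vector is constant (r² undefined).
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    ok = (d1 != MISSING) & (d2 != MISSING)
    if ok.sum() < 2:
        return None
    x = d1[ok].astype(float)
    y = d2[ok].astype(float)
    x -= x.mean()
    y -= y.mean()
    sx = (x * x).sum()
    sy = (y * y).sum()
    if sx == 0 or sy == 0:
        return None
    r = (x * y).sum() / math.sqrt(sx * sy)
    return r * r


def _pairwise_r2_block(
    dosages: np.ndarray, positions: np.ndarray, max_dist: int
) -> Tuple[np.ndarray, np.ndarray]:
    """All intra-chromosome pair (distance, r²) with 0 < distance <= max_dist.

    Fast centred-dot-product path when no genotypes are missing;
    otherwise falls back to pairwise complete-case computation.
    Monomorphic/undefined pairs are dropped.
    """
    n_sites = len(positions)
    dists: List[np.ndarray] = []
    r2s: List[np.ndarray] = []
    no_missing = not np.any(dosages == MISSING)
    if no_missing:
        x = dosages.astype(float)
        x -= x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x * x).sum(axis=1))
        for i in range(n_sites):
            hi = np.searchsorted(positions, positions[i] + max_dist, side="right")
            lo = np.searchsorted(positions, positions[i], side="right")  # skip dist 0
            if hi <= lo or norms[i] == 0:
                continue
            block = x[lo:hi]
            bnorms = norms[lo:hi]
            valid = bnorms > 0
            if not valid.any():
                continue
            r = (block[valid] @ x[i]) / (bnorms[valid] * norms[i])
            dists.append((positions[lo:hi][valid] - positions[i]).astype(np.int64))
            r2s.append(r * r)
    else:
        for i in range(n_sites):
            hi = np.searchsorted(positions, positions[i] + max_dist, side="right")
            lo = np.searchsorted(positions, positions[i], side="right")
            for j in range(lo, hi):
                r2 = genotype_r2(dosages[i], dosages[j])
                if r2 is None:
                    continue
                dists.append(np.array([positions[j] - positions[i]]))
                r2s.append(np.array([r2]))
    if not dists:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(dists), np.concatenate(r2s)


def ld_decay(
    matrix: GenotypeMatrix,
    max_dist: int = 5000,
    bin_width: int = 10,
    per_chromosome: bool = True,
) -> Dict[str, LDDecayCurve]:
    """Distance-binned mean r² per chromosome (pooled under key "all").

    Every intra-chromosomal site pair with 0 < distance <= max_dist
    contributes its r² to the bin containing the distance.
    """
    if max_dist < bin_width:
        raise ValueError("max_dist must be >= bin_width")
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=np.int64)
    nb = len(edges) - 1
    curves: Dict[str, LDDecayCurve] = {}
    pooled_sum = np.zeros(nb)
    pooled_cnt = np.zeros(nb, dtype=np.int64)
    any_pairs = False
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_slice(chrom)
        dists, r2s = _pairwise_r2_block(sub.dosages, sub.positions(chrom), max_dist)
        idx = np.minimum((dists - 1) // bin_width, nb - 1)  # dist in (0, max_dist]
        cnt = np.bincount(idx, minlength=nb)
        ssum = np.bincount(idx, weights=r2s, minlength=nb)
        if cnt.sum() > 0:
            any_pairs = True
        pooled_sum += ssum
        pooled_cnt += cnt
        if per_chromosome:
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
            curves[chrom] = LDDecayCurve(edges, mean, cnt)
    with np.errstate(invalid="ignore"):
        mean = np.where(pooled_cnt > 0, pooled_sum / np.maximum(pooled_cnt, 1), np.nan)
    curves["all"] = LDDecayCurve(edges, mean, pooled_cnt)
    if not any_pairs:
        logger.warning("ld_decay: no eligible site pairs within %d bp", max_dist)
    return curves


def windowed_ld(
    matrix: GenotypeMatrix,
    min_sep: int = 1000,
    max_sep: int = 10000,
    bin: int = 100_000,
    step: int = 50_000,
    min_pairs: int = 100,
    chrom_lengths: Optional[Dict[str, int]] = None,
    anchor: str = "midpoint",
) -> List[WindowStat]:
    """Sliding-window mean r² for site pairs min_sep-max_sep apart.

    Each qualifying pair contributes its r² at the pair midpoint (or
    left site with ``anchor="left"``); windows with fewer than
    ``min_pairs`` contributing pairs are excluded.  Chromosome lengths
    default to the last site position per chromosome.
    """
    if min_sep > max_sep:
        raise ValueError("min_sep must be <= max_sep")
    if anchor not in ("midpoint", "left"):
        raise ValueError(f"unknown anchor {anchor!r}")
    out: List[WindowStat] = []
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_slice(chrom)
        positions = sub.positions(chrom)
        if len(positions) == 0:
            continue
        length = (chrom_lengths or {}).get(chrom, int(positions[-1]))
        windows = make_windows(length, bin, step)
        # collect qualifying pairs with their anchor coordinate
        dos = sub.dosages
        anchors: List[np.ndarray] = []
        r2s: List[np.ndarray] = []
        no_missing = not np.any(dos == MISSING)
        x = dos.astype(float)
        x -= x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x * x).sum(axis=1))
        for i in range(len(positions)):
            lo = np.searchsorted(positions, positions[i] + min_sep, side="left")
            hi = np.searchsorted(positions, positions[i] + max_sep, side="right")
            if hi <= lo:
                continue
            if no_missing:
                if norms[i] == 0:
                    continue
                bnorms = norms[lo:hi]
                valid = bnorms > 0
                if not valid.any():
                    continue
                r = (x[lo:hi][valid] @ x[i]) / (bnorms[valid] * norms[i])
                pair_pos = positions[lo:hi][valid]
                rr = r * r
            else:
                vals = []
                ppos = []
                for j in range(lo, hi):
                    r2 = genotype_r2(dos[i], dos[j])
                    if r2 is not None:
                        vals.append(r2)
                        ppos.append(positions[j])
                if not vals:
                    continue
                rr = np.array(vals)
                pair_pos = np.array(ppos, dtype=np.int64)
            if anchor == "midpoint":
                coord = (positions[i] + pair_pos) // 2
            else:
                coord = np.full(len(pair_pos), positions[i], dtype=np.int64)
            anchors.append(coord)
            r2s.append(rr)
        if anchors:
            coord = np.concatenate(anchors) - 1  # 1-based -> 0-based
            rr = np.concatenate(r2s)
            order = np.argsort(coord, kind="stable")
            coord = coord[order]
            rr = rr[order]
        else:
            coord = np.empty(0, dtype=np.int64)
            rr = np.empty(0)
        for start, end in windows:
            lo = np.searchsorted(coord, start, side="left")
            hi = np.searchsorted(coord, end, side="left")
            n = int(hi - lo)
            if n < min_pairs:
                out.append(WindowStat(chrom, start, end, math.nan, n, excluded=True))
            else:
                out.append(WindowStat(chrom, start, end, float(rr[lo:hi].mean()), n))
    return out


def mean_r2_in_regions(
    matrix: GenotypeMatrix,
    intervals: Sequence[Tuple[str, int, int]],
    min_sep: int = 1000,
    max_sep: int = 10000,
    invert: bool = False,
) -> Tuple[float, int]:
    """Mean r² over pairs whose midpoint falls inside (or, with
    ``invert``, outside) the given 0-based intervals.

    Used to contrast LD inside inversions against the collinear
    background.  Returns (mean, n_pairs); mean is nan when no pair
    qualifies.
    """
    total = 0.0
    count = 0
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in matrix.chromosomes:
        sub = matrix.chrom_slice(chrom)
        positions = sub.positions(chrom)
        dos = sub.dosages
        x = dos.astype(float)
        x -= x.mean(axis=1, keepdims=True)
        norms = np.sqrt((x * x).sum(axis=1))
        no_missing = not np.any(dos == MISSING)
        ivs = by_chrom.get(chrom, [])
        for i in range(len(positions)):
            lo = np.searchsorted(positions, positions[i] + min_sep, side="left")
            hi = np.searchsorted(positions, positions[i] + max_sep, side="right")
            if hi <= lo:
                continue
            if no_missing:
                if norms[i] == 0:
                    continue
                bnorms = norms[lo:hi]
                valid = bnorms > 0
                r = (x[lo:hi][valid] @ x[i]) / (bnorms[valid] * norms[i])
                rr = r * r
                pair_pos = positions[lo:hi][valid]
            else:
                vals, ppos = [], []
                for j in range(lo, hi):
                    r2 = genotype_r2(dos[i], dos[j])
                    if r2 is not None:
                        vals.append(r2)
                        ppos.append(positions[j])
                rr = np.array(vals)
                pair_pos = np.array(ppos, dtype=np.int64)
            if len(rr) == 0:
                continue
            mid = (positions[i] + pair_pos) // 2 - 1
            inside = np.zeros(len(mid), dtype=bool)
            for s, e in ivs:
                inside |= (mid >= s) & (mid < e)
            sel = ~inside if invert else inside
            total += float(rr[sel].sum())
            count += int(sel.sum())
    return (total / count if count else math.nan), count
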