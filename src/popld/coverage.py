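"""Per-base depth summaries and windowed coverage profiles.

Input is a sparse 3-column TSV (chrom, 1-based pos, depth); positions
absent from the table have depth 0 over a declared chromosome length.
"Combined" coverage means depth already summed across samples (or
supplied as per-sample columns, which are summed on load).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .windows import WindowStat


@dataclass
class DepthSummary:
    pct_zero: float
    pct_ge_threshold: float
    combined_total: int
    n_bases: int
    threshold: int


def depth_summary(depths: np.ndarray, threshold: int = 30) -> DepthSummary:
    """Fraction of bases at 0x and at/above threshold, plus total depth.

    A base exactly at the threshold counts toward the >=threshold
    bucket.  The three fractions (zero, intermediate, >=threshold)
    partition the genome exactly.
    """
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("empty depth array")
    if (d < 0).any():
        raise ValueError("depths must be non-negative")
    n = d.size
    return DepthSummary(
        pct_zero=100.0 * int((d == 0).sum()) / n,
        pct_ge_threshold=100.0 * int((d >= threshold).sum()) / n,
        combined_total=int(d.sum()),
        n_bases=n,
        threshold=threshold,
    )


def windowed_depth(depths: np.ndarray, windows: List[Tuple[int, int]], chrom: str = "") -> List[WindowStat]:
    """Per-window summed depth over [start, end) base intervals."""
    d = np.asarray(depths, dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(d)])
    out = []
    for start, end in windows:
        end_c = min(end, len(d))
        start_c = min(start, len(d))
        total = int(csum[end_c] - csum[start_c])
        out.append(WindowStat(chrom, start, end, float(total), end_c - start_c))
    return out


def read_depth_table(path: str, chrom_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Dense per-base depth arrays from a sparse TSV.

    Columns: chrom, 1-based pos, then one or more depth columns (summed
    when several).  Bases absent from the table get depth 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected chrom, pos and >=1 depth column")
    out: Dict[str, np.ndarray] = {
        chrom: np.zeros(length, dtype=np.int64) for chrom, length in chrom_lengths.items()
    }
    depth = df.iloc[:, 2:].sum(axis=1).to_numpy(dtype=np.int64)
    for chrom, grp_idx in df.groupby(0).groups.items():
        if chrom not in out:
            raise ValueError(f"{path}: chromosome {chrom!r} has no declared length")
        pos = df.loc[grp_idx, 1].to_numpy(dtype=np.int64) - 1
        if (pos < 0).any() or (pos >= len(out[chrom])).any():
            raise ValueError(f"{path}: position outside declared length of {chrom}")
        out[chrom][pos] = depth[np.asarray(grp_idx, dtype=int)]
    return out


def write_depth_table(path: str, depths: Dict[str, np.ndarray]) -> None:
    """Sparse TSV of non-zero depths (chrom, 1-based pos, depth)."""
    with open(path, "w") as fh:
        for chrom in depths:
            d = depths[chrom]
            for pos in np.nonzero(d)[0]:
                fh.write(f"{chrom}\t{pos + 1}\t{d[pos]}\n")
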