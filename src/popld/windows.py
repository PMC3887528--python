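"""Generic sliding-window engine shared by coverage, pi, F_ST and LD summaries.

Windows are fixed-size bins advanced by a step (overlapping when
step < bin).  A window with fewer contributing values than a
``min_values`` threshold is flagged excluded and reported as NA — the
rule used for the differentiation and linkage window scans, where
windows with fewer than 100 values are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd


@dataclass
class WindowStat:
    """One window with its aggregated statistic.

    start/end are 0-based half-open internally; reports print 1-based
    starts.  ``excluded`` windows carry ``value = nan``.
    """

    chrom: str
    start: int
    end: int
    value: float
    n_values: int
    excluded: bool = False


def make_windows(chrom_length: int, bin: int, step: int) -> List[Tuple[int, int]]:
    """Sliding windows over [0, chrom_length).

    Windows start at 0 and advance by ``step``; generation stops with
    the first window reaching the chromosome end (truncated there if
    needed), so every base is covered at least once and no window is
    fully redundant.
    """
    if bin <= 0 or step <= 0:
        raise ValueError("bin and step must be positive")
    if step > bin:
        raise ValueError("step must not exceed bin")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    windows: List[Tuple[int, int]] = []
    start = 0
    while True:
        end = min(start + bin, chrom_length)
        windows.append((start, end))
        if end >= chrom_length:
            break
        start += step
    return windows


def aggregate(
    values: Sequence[Tuple[str, int, float]],
    windows: Union[Dict[str, List[Tuple[int, int]]], List[Tuple[int, int]]],
    statistic: str = "mean",
    min_values: int = 0,
) -> List[WindowStat]:
    """Aggregate (chrom, pos, value) points into windows.

    ``windows`` is either a per-chromosome dict of interval lists or a
    single interval list applied to every chromosome present.  A point
    contributes to every window overlapping its (0-based) position.
    Windows with fewer than ``min_values`` points are flagged excluded.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    by_chrom: Dict[str, List[Tuple[int, float]]] = {}
    last_key = None
    for chrom, pos, val in values:
        key = (chrom, pos)
        if last_key is not None and chrom == last_key[0] and key < last_key:
            raise ValueError("values must be sorted by (chrom, pos)")
        last_key = key
        by_chrom.setdefault(chrom, []).append((pos, val))

    out: List[WindowStat] = []
    chroms = list(by_chrom) if not isinstance(windows, dict) else list(windows)
    for chrom in chroms:
        ivs = windows[chrom] if isinstance(windows, dict) else windows
        pts = by_chrom.get(chrom, [])
        pos = np.array([p for p, _ in pts], dtype=np.int64)
        val = np.array([v for _, v in pts], dtype=float)
        for start, end in ivs:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            n = int(hi - lo)
            if n < min_values:
                out.append(WindowStat(chrom, start, end, math.nan, n, excluded=True))
                continue
            if n == 0:
                stat = 0.0 if statistic == "sum" else math.nan
                out.append(
                    WindowStat(chrom, start, end, stat, 0, excluded=statistic == "mean")
                )
                continue
            window_vals = val[lo:hi]
            stat = float(window_vals.sum() if statistic == "sum" else window_vals.mean())
            out.append(WindowStat(chrom, start, end, stat, n, excluded=False))
    return out


def window_table(stats: Iterable[WindowStat]) -> pd.DataFrame:
    """Report table: chrom, 1-based start, end, n, value (NA when excluded)."""
    rows = []
    for w in stats:
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start + 1,
                "end": w.end,
                "n": w.n_values,
                "value": float("nan") if w.excluded else w.value,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "value"])
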