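"""Population differentiation: weighted Weir-Cockerham F_ST.

Overall and per-arm estimates, the 100 kb / 50 kb sliding-window scan
(windows with under 100 usable sites excluded), and the contrast of
mean window F_ST inside the inversion against the collinear background.
"""

import argparse
import os

import pandas as pd

from popld.annotate import stratify_values
from popld.popgen_stats import (
    fst_by_chromosome,
    matrix_fst_components,
    wc_fst_aggregate,
    windowed_fst,
)
from popld.vcf_io import read_regions
from popld.windows import make_windows, window_table

HERE = os.path.dirname(__file__)
SIM = os.path.join(HERE, "..", "results", "sim")
OUT = os.path.join(HERE, "..", "results")


def main() -> None:
    argparse.ArgumentParser().parse_args()
    from importlib import import_module
    import sys

    sys.path.insert(0, HERE)
    load_retained_matrix = import_module("03_diversity").load_retained_matrix
    matrix, contigs = load_retained_matrix()

    comps = matrix_fst_components(matrix)
    overall = wc_fst_aggregate(comps)
    per_arm = fst_by_chromosome(matrix)
    windows = {c: make_windows(length, 100_000, 50_000) for c, length in contigs.items()}
    wstats = windowed_fst(comps, windows, min_values=100)
    window_table(wstats).to_csv(
        os.path.join(OUT, "fst_windows.tsv"), sep="\t", index=False, na_rep="NA"
    )
    pd.DataFrame(
        [{"chrom": c, "fst": v} for c, v in per_arm.items()]
        + [{"chrom": "all", "fst": overall}]
    ).to_csv(os.path.join(OUT, "fst_summary.tsv"), sep="\t", index=False)

    regions = read_regions(os.path.join(SIM, "regions.bed"))
    kept = [w for w in wstats if not w.excluded]
    strata = stratify_values(
        [(w.chrom, (w.start + w.end) // 2 + 1) for w in kept],
        [w.value for w in kept],
        regions,
    )
    strata.to_csv(os.path.join(OUT, "fst_by_region.tsv"), sep="\t", index=False)

    print(f"weighted F_ST (all sites) = {overall:.4f}")
    for chrom, v in per_arm.items():
        print(f"  {chrom}: {v:.4f}")
    print("\nmean window F_ST by region:")
    print(strata.to_string(index=False))
    print(
        "\nthe inversion does not by itself elevate F_ST here: divergence is "
        "drawn site-wise, so elevated differentiation inside inversions in "
        "real data reflects selection and restricted gene flux, which the "
        "neutral generator deliberately does not model"
    )


if __name__ == "__main__":
    main()
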