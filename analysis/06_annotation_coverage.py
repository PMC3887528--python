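"""Genomic-context classification of the retained SNPs and coverage
profiling.

Gene models are synthetic (generated here with a fixed seed, since the
simulator produces genotypes, not annotation): genes of realistic size
tiled over the arm so the four context classes are all populated.
Coverage comes from the simulated per-base depth profile with its
centromeric dip.
"""

import argparse
import os
from importlib import import_module
import sys

import numpy as np
import pandas as pd

from popld.annotate import GeneIndex, GeneModel, class_summary
from popld.coverage import depth_summary, windowed_depth
from popld.simulate import SimulationConfig, simulate_depth
from popld.windows import make_windows, window_table

HERE = os.path.dirname(__file__)
SIM = os.path.join(HERE, "..", "results", "sim")
OUT = os.path.join(HERE, "..", "results")


def synthetic_genes(chrom: str, length: int, rng: np.random.Generator):
    """Synthetic gene models: ~8 kb genes with 2-5 exons, first/last
    exon partly untranslated, spaced so flank and intergenic space both
    exist."""
    genes = []
    pos = 2000
    i = 0
    while pos + 12_000 < length:
        span = int(rng.integers(4000, 12_000))
        n_exons = int(rng.integers(2, 6))
        cuts = np.sort(rng.choice(np.arange(200, span - 200), size=2 * n_exons, replace=False))
        exons = [(pos + int(cuts[2 * k]), pos + int(cuts[2 * k + 1])) for k in range(n_exons)]
        exons[0] = (pos, exons[0][1])
        exons[-1] = (exons[-1][0], pos + span)
        cds = exons[1:-1] if n_exons > 2 else [exons[0]]
        genes.append(
            GeneModel(
                gene_id=f"gene{i:03d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=pos,
                end=pos + span,
                exons=exons,
                cds=cds,
            )
        )
        pos += span + int(rng.integers(8000, 30_000))
        i += 1
    return genes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    sys.path.insert(0, HERE)
    load_retained_matrix = import_module("03_diversity").load_retained_matrix
    matrix, contigs = load_retained_matrix()
    cfg = SimulationConfig.from_yaml(os.path.join(SIM, "config.yaml"))

    rng = np.random.default_rng(args.seed + 60_000)
    chrom = cfg.chrom
    genes = synthetic_genes(chrom, cfg.chrom_length, rng)
    index = GeneIndex(genes, flank=5000)
    classes = class_summary([(c, p) for c, p, _, _ in matrix.sites], index)
    classes.to_csv(os.path.join(OUT, "snp_classes.tsv"), sep="\t", index=False)
    print(f"{len(genes)} synthetic genes; SNP context classes:")
    print(classes.to_string(index=False))

    cent = (int(cfg.centromere[0]), int(cfg.centromere[1])) if cfg.centromere else None
    depth = simulate_depth(cfg.chrom_length, 50.0, cfg.stream("depth"), centromere=cent)
    s = depth_summary(depth, threshold=30)
    pd.DataFrame(
        [{
            "chrom": chrom,
            "pct_zero": s.pct_zero,
            "pct_ge_30x": s.pct_ge_threshold,
            "combined_total": s.combined_total,
        }]
    ).to_csv(os.path.join(OUT, "coverage_summary.tsv"), sep="\t", index=False)
    wins = make_windows(cfg.chrom_length, 100_000, 50_000)
    window_table(windowed_depth(depth, wins, chrom)).to_csv(
        os.path.join(OUT, "coverage_windows.tsv"), sep="\t", index=False, na_rep="NA"
    )
    print(
        f"\ncoverage: {s.pct_zero:.1f}% of bases at 0x, "
        f"{s.pct_ge_threshold:.1f}% at >=30x, total {s.combined_total:,}; "
        "windowed sums drop toward the centromere"
    )


if __name__ == "__main__":
    main()
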