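"""Two-tier SNP filtering with full per-stage accounting.

Tier one builds a high-confidence reference site set from the jointly
called high-coverage samples: biallelic SNPs passing the GATK-style
hard filters (QD < 2.0, MQ < 40, FS > 60, HaplotypeScore > 13,
MQRankSum < -12.5, ReadPosRankSum < -8.0 all fail), with QUAL > 30 and
combined depth DP > 30.  All inequalities are strict, exactly as
printed in the GATK hard-filter recommendations; an absent annotation
never fails a filter (rank-sum tags are legitimately missing at
homozygous sites).

Tier two filters the jointly called low-coverage sample set: the same
hard filters with the QUAL threshold reduced to 4 and no depth filter,
followed by four exclusion rules applied in a fixed order —
(1) the site was not called in every sample; (2) the site is not in the
high-confidence set; (3) the minor allele is carried by fewer than five
individuals; (4) the site is multiallelic, including sites biallelic
for two non-reference alleles.  A site failing several rules is charged
to the first failing stage only, so the ledger conserves counts:
input = retained + sum of per-stage exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from .vcf_io import SiteRecord

SiteKey = Tuple[str, int, str, str]

#: Cascade stage names, in application order.
CASCADE_STAGES = (
    "non_snp",
    "hard_filter",
    "not_called_in_all",
    "not_in_high_confidence",
    "minor_carriers",
    "multiallelic",
)


@dataclass
class HardFilterThresholds:
    """Hard-filter cutoffs; defaults are the printed GATK recommendations.

    ``qual_min`` and ``depth_min`` are the strict lower bounds on QUAL
    and combined DP (site retained only when strictly above); None
    disables that check.
    """

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    qual_min: Optional[float] = None
    depth_min: Optional[float] = None


#: (tag, threshold attribute, direction); "lt" fails when value < threshold,
#: "gt" fails when value > threshold, "le" when value <= threshold.
_TAG_RULES = (
    ("QD", "qd_min", "lt"),
    ("MQ", "mq_min", "lt"),
    ("FS", "fs_max", "gt"),
    ("HaplotypeScore", "haplotype_score_max", "gt"),
    ("MQRankSum", "mq_rank_sum_min", "lt"),
    ("ReadPosRankSum", "read_pos_rank_sum_min", "lt"),
    ("QUAL", "qual_min", "le"),
    ("DP", "depth_min", "le"),
)


def hard_filter(
    record: SiteRecord, thresholds: HardFilterThresholds
) -> Tuple[bool, List[str]]:
    """Evaluate the hard filters on one site.

    Returns (passes, failed tag names).  A tag absent from the record's
    annotations never fails; every violated tag is listed.
    """
    reasons: List[str] = []
    for tag, attr, direction in _TAG_RULES:
        cutoff = getattr(thresholds, attr)
        if cutoff is None or tag not in record.annotations:
            continue
        value = record.annotations[tag]
        if isinstance(value, bool) or not isinstance(value, (int, float, np.floating, np.integer)):
            raise TypeError(
                f"non-numeric value {value!r} for tag {tag} at {record.chrom}:{record.pos}"
            )
        failed = (
            value < cutoff
            if direction == "lt"
            else value > cutoff
            if direction == "gt"
            else value <= cutoff
        )
        if failed:
            reasons.append(tag)
    return (len(reasons) == 0, reasons)


@dataclass
class FilterLedger:
    """Ordered per-stage accounting: stage -> (sites in, sites excluded)."""

    stages: List[Tuple[str, int, int]] = field(default_factory=list)
    retained: int = 0

    def add_stage(self, name: str, sites_in: int, excluded: int) -> None:
        if excluded < 0 or excluded > sites_in:
            raise ValueError(f"stage {name}: excluded {excluded} of {sites_in}")
        self.stages.append((name, sites_in, excluded))

    @property
    def total_in(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def total_excluded(self) -> int:
        return sum(e for _, _, e in self.stages)

    def check_conservation(self) -> None:
        """Raise unless counts chain and conserve across stages."""
        for (name_a, in_a, ex_a), (name_b, in_b, _) in zip(self.stages, self.stages[1:]):
            if in_a - ex_a != in_b:
                raise ValueError(
                    f"ledger broken between {name_a} and {name_b}: "
                    f"{in_a} - {ex_a} != {in_b}"
                )
        if self.stages and self.total_in != self.retained + self.total_excluded:
            raise ValueError(
                f"ledger not conserved: {self.total_in} != "
                f"{self.retained} + {self.total_excluded}"
            )


def ledger_report(ledger: FilterLedger) -> str:
    """Text table of the cascade accounting; refuses a broken ledger."""
    ledger.check_conservation()
    lines = [f"{'stage':<24}{'sites_in':>12}{'excluded':>12}{'retained':>12}"]
    for name, sites_in, excluded in ledger.stages:
        lines.append(f"{name:<24}{sites_in:>12}{excluded:>12}{sites_in - excluded:>12}")
    lines.append(
        f"{'total':<24}{ledger.total_in:>12}{ledger.total_excluded:>12}{ledger.retained:>12}"
    )
    return "\n".join(lines)


def ledger_table(ledger: FilterLedger):
    import pandas as pd

    ledger.check_conservation()
    rows = [
        {"stage": n, "sites_in": i, "excluded": e, "retained": i - e}
        for n, i, e in ledger.stages
    ]
    rows.append(
        {
            "stage": "total",
            "sites_in": ledger.total_in,
            "excluded": ledger.total_excluded,
            "retained": ledger.retained,
        }
    )
    return pd.DataFrame(rows, columns=["stage", "sites_in", "excluded", "retained"])


def build_high_confidence_set(
    records: Iterable[SiteRecord],
    thresholds: Optional[HardFilterThresholds] = None,
) -> Set[SiteKey]:
    """High-confidence (chrom, pos, ref, alt) keys from the combined
    high-coverage call set.

    Retains biallelic SNPs (ref and alt both single bases) that pass
    the hard filters with QUAL > 30 and combined DP > 30.
    """
    if thresholds is None:
        thresholds = HardFilterThresholds(qual_min=30.0, depth_min=30.0)
    keys: Set[SiteKey] = set()
    for rec in records:
        if len(rec.alts) != 1 or not rec.is_snp():
            continue
        ok, _ = hard_filter(rec, thresholds)
        if ok:
            keys.add(rec.key)
    return keys


def minor_allele_carriers(record: SiteRecord) -> Tuple[int, int]:
    """Carrier counts (individuals with >=1 copy) of the (ref, alt) alleles
    at a biallelic site, and which is minor.

    Returns (minor carriers, other carriers); at an exact frequency tie
    the smaller carrier count is reported first.
    """
    dosages = record.dosages()
    called = dosages[dosages >= 0]
    alt_copies = int(called.sum())
    ref_copies = int(2 * len(called) - alt_copies)
    alt_carriers = int(np.count_nonzero(called > 0))
    ref_carriers = int(np.count_nonzero(called < 2))
    if alt_copies < ref_copies:
        return alt_carriers, ref_carriers
    if ref_copies < alt_copies:
        return ref_carriers, alt_carriers
    lo, hi = sorted((alt_carriers, ref_carriers))
    return lo, hi


def cascade_filter(
    records: Iterable[SiteRecord],
    hc: Set[SiteKey],
    n_samples: int,
    min_carriers: int = 5,
    qual_min: float = 4.0,
    thresholds: Optional[HardFilterThresholds] = None,
    stage_keys: Optional[Dict[str, List[SiteKey]]] = None,
) -> Tuple[List[SiteRecord], FilterLedger]:
    """Apply the low-coverage filter cascade; return retained records
    and the per-stage ledger.

    Stage order: non-SNP alleles, hard filters (QUAL > ``qual_min``,
    no depth filter), then the four exclusion rules.  Each excluded
    site is charged to its first failing stage.  ``stage_keys``, when
    given a dict, is filled with the excluded site keys per stage (for
    auditing).  Rules 2 and 3 are identity/carrier tests defined for
    biallelic sites; multiallelic sites pass through to rule 4.
    """
    if thresholds is None:
        thresholds = HardFilterThresholds(qual_min=qual_min, depth_min=None)
    else:
        thresholds = HardFilterThresholds(
            **{**thresholds.__dict__, "qual_min": qual_min, "depth_min": None}
        )
    counts = {name: 0 for name in CASCADE_STAGES}
    retained: List[SiteRecord] = []
    total = 0

    def _charge(stage: str, rec: SiteRecord) -> None:
        counts[stage] += 1
        if stage_keys is not None:
            key = (rec.chrom, rec.pos, rec.ref, rec.alts[0] if len(rec.alts) == 1 else ",".join(rec.alts))
            stage_keys.setdefault(stage, []).append(key)

    for rec in records:
        total += 1
        if len(rec.genotypes) != n_samples:
            raise ValueError(
                f"record at {rec.chrom}:{rec.pos} has {len(rec.genotypes)} "
                f"genotypes, expected {n_samples}"
            )
        if not rec.is_snp():
            _charge("non_snp", rec)
            continue
        ok, _ = hard_filter(rec, thresholds)
        if not ok:
            _charge("hard_filter", rec)
            continue
        if rec.n_called() < n_samples:
            _charge("not_called_in_all", rec)
            continue
        biallelic = len(rec.alts) == 1
        if biallelic and rec.key not in hc:
            _charge("not_in_high_confidence", rec)
            continue
        if biallelic:
            minor, other = minor_allele_carriers(rec)
            dosages = rec.dosages()
            called = dosages[dosages >= 0]
            tied = int(called.sum()) * 2 == 2 * len(called)  # alt copies == ref copies
            if tied:
                if minor < min_carriers or other < min_carriers:
                    _charge("minor_carriers", rec)
                    continue
            elif minor < min_carriers:
                _charge("minor_carriers", rec)
                continue
        if not biallelic:
            _charge("multiallelic", rec)
            continue
        retained.append(rec)

    ledger = FilterLedger()
    sites_in = total
    for name in CASCADE_STAGES:
        ledger.add_stage(name, sites_in, counts[name])
        sites_in -= counts[name]
    ledger.retained = len(retained)
    ledger.check_conservation()
    return retained, ledger
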