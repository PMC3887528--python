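"""Synthetic two-population SNP data with realistic statistical structure.

The generator emulates the features the pipeline's analyses assume:

* **Allele frequencies** drawn from the neutral site-frequency spectrum
  over a founder panel (P(derived count = i) proportional to 1/i).
* **Population divergence** via the Balding-Nichols model: each
  population's site frequency is Beta(p(1-t)/t, (1-p)(1-t)/t) around
  the ancestral frequency p, so the expected F_ST equals t.  Because
  descendants copy from a finite per-population founder panel of size
  n_f, panel sampling adds drift variance (1-t)p(1-p)/n_f; the Beta
  parameter is therefore calibrated to t' = (t*n_f - 1)/(n_f - 1) so
  the realized divergence matches the requested ``theta_fst``
  (requires theta_fst >= 1/n_f; theta_fst = 0 means the populations
  share one panel and are undifferentiated).
* **Linkage disequilibrium** from a founder-mosaic (copying) model:
  each haplotype copies founder segments with a per-bp switch
  probability, so r² decays with distance at scale ~1/switch_rate.
* **Inversions**: recombination (mosaic switching) is suppressed inside
  an inversion only for heterokaryotypous individuals — those carrying
  one standard and one inverted arrangement — emulating the lack of
  crossing over in heterokaryotypes.  A centromeric interval suppresses
  switching in everyone.
* **Site annotations** (QUAL, QD, MQ, FS, HaplotypeScore, MQRankSum,
  ReadPosRankSum, DP) drawn from configurable passing ranges, with
  optional engineered fractions of sites constructed to fail each hard
  filter and each cascade exclusion rule, with a truth table recording
  the stage each engineered site must be charged to.

All randomness flows from a single mandatory seed, split into named
substreams (founders, populations, annotations, depth) in a fixed
order, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .vcf_io import (
    MISSING,
    GenotypeMatrix,
    RegionSet,
    SiteRecord,
    write_populations,
    write_regions,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


@dataclass
class InversionSpec:
    """One polymorphic inversion: interval, recombination suppression
    factor applied to heterokaryotypes (0 = full suppression), and the
    frequency of the inverted arrangement among chromosome copies."""

    name: str
    start: int
    end: int
    suppression: float = 0.0
    inverted_freq: float = 0.5


@dataclass
class EngineeredFractions:
    """Fractions of sites constructed to fail one specific filter stage."""

    qd: float = 0.0
    mq: float = 0.0
    fs: float = 0.0
    haplotype_score: float = 0.0
    mq_rank_sum: float = 0.0
    read_pos_rank_sum: float = 0.0
    qual_low: float = 0.0
    missing_call: float = 0.0
    not_in_hc: float = 0.0
    low_carriers: float = 0.0
    multiallelic: float = 0.0

    def total(self) -> float:
        return sum(asdict(self).values())


@dataclass
class SimulationConfig:
    """All generator parameters.  Defaults mirror the study design:
    a high-density SNP set (one SNP per ~250 bp) on one chromosome arm,
    20 + 4 diploids in two diverged populations (theta ~ 0.057), LD
    decaying on a sub-kilobase scale, one polymorphic inversion with
    fully suppressed heterokaryotype recombination, and a centromeric
    low-recombination zone."""

    seed: int
    chrom: str = "2R"
    chrom_length: int = 1_000_000
    n_sites: int = 4000
    n_founders: int = 24
    switch_rate: float = 1e-3
    theta_fst: float = 0.057
    n_per_pop: Dict[str, int] = field(default_factory=lambda: {"TZ": 20, "CM": 4})
    inversions: List[InversionSpec] = field(
        default_factory=lambda: [InversionSpec("2Rc", 250_000, 500_000, 0.0, 0.5)]
    )
    centromere: Optional[Tuple[int, int, float]] = (900_000, 1_000_000, 0.1)
    missing_rate: float = 0.0
    engineered: Optional[EngineeredFractions] = None
    annotation_law: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "QUAL": (100.0, 1000.0),
            "QD": (5.0, 35.0),
            "MQ": (45.0, 60.0),
            "FS": (0.0, 30.0),
            "HaplotypeScore": (0.0, 10.0),
            "MQRankSum": (-7.5, 7.5),
            "ReadPosRankSum": (-7.5, 7.5),
            "DP": (100.0, 900.0),
        }
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; no implicit entropy")
        if self.n_sites > self.chrom_length:
            raise ValueError("n_sites exceeds chrom_length")
        if not (0.0 <= self.switch_rate):
            raise ValueError("switch_rate must be non-negative")
        if not (0.0 <= self.theta_fst < 1.0) and self.theta_fst != 1.0:
            raise ValueError("theta_fst must lie in [0, 1]")
        if self.theta_fst > 0 and self.theta_fst * self.n_founders <= 1:
            raise ValueError(
                "theta_fst must be 0 or > 1/n_founders: with a founder panel "
                f"of {self.n_founders}, panel drift alone contributes "
                f"{1 / self.n_founders:.3f} to the realized divergence"
            )
        for inv in self.inversions:
            if not (0 <= inv.start < inv.end <= self.chrom_length):
                raise ValueError(f"inversion {inv.name} outside chromosome")
            if not (0.0 <= inv.suppression <= 1.0 and 0.0 <= inv.inverted_freq <= 1.0):
                raise ValueError(f"inversion {inv.name}: rates must lie in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")

    # -- deterministic substreams, in documented order -------------------
    def stream(self, which: str) -> np.random.Generator:
        order = ("founders", "populations", "annotations", "depth")
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order.index(which)])

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "inversions" in raw:
            raw["inversions"] = [InversionSpec(**iv) for iv in raw["inversions"]]
        if raw.get("centromere") is not None:
            raw["centromere"] = tuple(raw["centromere"])
        if raw.get("engineered") is not None:
            raw["engineered"] = EngineeredFractions(**raw["engineered"])
        if "annotation_law" in raw:
            raw["annotation_law"] = {k: tuple(v) for k, v in raw["annotation_law"].items()}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def region_set(self) -> RegionSet:
        rs = RegionSet()
        for inv in self.inversions:
            rs.add(inv.name, self.chrom, inv.start, inv.end)
        if self.centromere is not None:
            rs.add("centromere", self.chrom, int(self.centromere[0]), int(self.centromere[1]))
        return rs


@dataclass
class FounderPanel:
    positions: np.ndarray  # 0-based, sorted, unique
    haplotypes: np.ndarray  # (n_sites, n_founders) bool: derived allele carried
    ancestral_freq: np.ndarray  # derived-allele frequency among founders


def neutral_sfs_counts(n_founders: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts i in 1..n_founders-1 with P(i) proportional to 1/i."""
    counts = np.arange(1, n_founders)
    weights = 1.0 / counts
    return rng.choice(counts, size=n_sites, p=weights / weights.sum())


def simulate_founders(config: SimulationConfig) -> FounderPanel:
    """Founder haplotypes with neutral-SFS derived-allele frequencies and
    uniformly placed positions."""
    if config.n_founders < 2:
        raise ValueError("need at least two founders")
    rng = config.stream("founders")
    positions = np.sort(
        rng.choice(config.chrom_length, size=config.n_sites, replace=False)
    ).astype(np.int64)
    counts = neutral_sfs_counts(config.n_founders, config.n_sites, rng)
    hap = np.zeros((config.n_sites, config.n_founders), dtype=bool)
    for s in range(config.n_sites):
        carriers = rng.choice(config.n_founders, size=counts[s], replace=False)
        hap[s, carriers] = True
    return FounderPanel(
        positions=positions,
        haplotypes=hap,
        ancestral_freq=counts / config.n_founders,
    )


def balding_nichols_frequencies(
    p: np.ndarray, theta: float, n_founders: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population site frequencies under Balding-Nichols, with the
    concentration calibrated for founder-panel drift (see module docs)."""
    tp = (theta * n_founders - 1.0) / (n_founders - 1.0)
    if tp < 0:
        raise ValueError("theta_fst below the panel-drift floor 1/n_founders")
    if tp == 0:
        return p.astype(float).copy()
    if tp >= 1:
        return (rng.random(len(p)) < p).astype(float)
    return rng.beta(p * (1 - tp) / tp, (1 - p) * (1 - tp) / tp)


def _integrated_rate(
    chrom_length: int,
    suppressed: Sequence[Tuple[int, int, float]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative effective length E(x) = integral of the local switch
    factor over [0, x), as (breakpoints, cumulative) for interpolation.
    Overlapping suppressed intervals combine multiplicatively."""
    points = {0, chrom_length}
    for s, e, _ in suppressed:
        points.update((s, e))
    pts = np.array(sorted(points), dtype=np.int64)
    factors = np.ones(len(pts) - 1)
    for i in range(len(pts) - 1):
        mid = (pts[i] + pts[i + 1]) / 2.0
        for s, e, f in suppressed:
            if s <= mid < e:
                factors[i] *= f
    cum = np.concatenate([[0.0], np.cumsum(factors * np.diff(pts))])
    return pts.astype(float), cum


def _mosaic_haplotype(
    panel: np.ndarray, p_switch: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One descendant haplotype copying founder segments.

    ``p_switch[k]`` is the probability of switching to a fresh uniform
    founder in the gap before site k (p_switch[0] = 1: the initial
    founder is always drawn)."""
    n_sites, n_founders = panel.shape
    switch = rng.random(n_sites) < p_switch
    seg = np.cumsum(switch) - 1  # first site has seg 0
    founders = rng.integers(0, n_founders, size=seg[-1] + 1)
    return panel[np.arange(n_sites), founders[seg]]


def assign_karyotypes(
    config: SimulationConfig, samples: Sequence[str], rng: np.random.Generator
) -> Dict[str, Dict[str, Tuple[int, int]]]:
    """Per-sample arrangement pair (0 = standard, 1 = inverted) for each
    inversion."""
    out: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for s in samples:
        out[s] = {}
        for inv in config.inversions:
            k1 = int(rng.random() < inv.inverted_freq)
            k2 = int(rng.random() < inv.inverted_freq)
            out[s][inv.name] = (k1, k2)
    return out


def simulate_population(
    founders: FounderPanel,
    config: SimulationConfig,
    population_freq_shift: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[GenotypeMatrix, Dict]:
    """Diploid genotypes for all configured populations, plus truth tables.

    Each haplotype is a founder mosaic over its population's panel with
    per-bp switch probability switch_rate x suppression(pos, karyotype).
    ``population_freq_shift`` optionally supplies precomputed
    per-population site frequencies; by default they are drawn from the
    calibrated Balding-Nichols model (theta_fst = 0 shares the
    ancestral panel across populations)."""
    rng = config.stream("populations")
    n_sites = config.n_sites
    nf = config.n_founders
    samples: List[str] = []
    populations: Dict[str, str] = {}
    for pop, n in config.n_per_pop.items():
        for i in range(n):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            populations[name] = pop

    karyotypes = assign_karyotypes(config, samples, rng)

    # per-karyotype-class integrated switch profiles
    inv_names = [iv.name for iv in config.inversions]
    profile_cache: Dict[Tuple[int, ...], Tuple[np.ndarray, np.ndarray]] = {}

    def gap_probs(het_flags: Tuple[int, ...]) -> np.ndarray:
        if het_flags not in profile_cache:
            suppressed = []
            for flag, inv in zip(het_flags, config.inversions):
                if flag:
                    suppressed.append((inv.start, inv.end, inv.suppression))
            if config.centromere is not None:
                cs, ce, cf = config.centromere
                suppressed.append((int(cs), int(ce), float(cf)))
            pts, cum = _integrated_rate(config.chrom_length, suppressed)
            profile_cache[het_flags] = (pts, cum)
        pts, cum = profile_cache[het_flags]
        eff = np.interp(founders.positions.astype(float), pts, cum)
        gaps = np.diff(eff, prepend=eff[0])
        p = 1.0 - np.exp(-config.switch_rate * gaps)
        p[0] = 1.0
        return p

    truth_freqs: Dict[str, np.ndarray] = {}
    dosage_cols: List[np.ndarray] = []
    for pop in config.n_per_pop:
        if population_freq_shift is not None and pop in population_freq_shift:
            pop_freq = np.asarray(population_freq_shift[pop], dtype=float)
            panel = rng.random((n_sites, nf)) < pop_freq[:, None]
        elif config.theta_fst == 0:
            pop_freq = founders.ancestral_freq.copy()
            panel = founders.haplotypes
        else:
            pop_freq = balding_nichols_frequencies(
                founders.ancestral_freq, config.theta_fst, nf, rng
            )
            panel = rng.random((n_sites, nf)) < pop_freq[:, None]
        truth_freqs[pop] = pop_freq
        for s in samples:
            if populations[s] != pop:
                continue
            het = tuple(
                int(karyotypes[s][nm][0] != karyotypes[s][nm][1]) for nm in inv_names
            )
            p_gap = gap_probs(het)
            h1 = _mosaic_haplotype(panel, p_gap, rng)
            h2 = _mosaic_haplotype(panel, p_gap, rng)
            dosage_cols.append(h1.astype(np.int8) + h2.astype(np.int8))

    dosages = np.column_stack(dosage_cols)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    ann_rng = config.stream("annotations")  # alleles share the annotation stream
    refs = _BASES[ann_rng.integers(0, 4, size=n_sites)]
    alt_offsets = ann_rng.integers(1, 4, size=n_sites)
    alts = _BASES[(np.searchsorted(_BASES, refs) + alt_offsets) % 4]

    sites = [
        (config.chrom, int(pos) + 1, str(r), str(a))
        for pos, r, a in zip(founders.positions, refs, alts)
    ]
    matrix = GenotypeMatrix(
        sites=sites, dosages=dosages, samples=samples, populations=populations
    )
    truth = {
        "ancestral_freq": founders.ancestral_freq,
        "population_freqs": truth_freqs,
        "karyotypes": karyotypes,
        "positions": founders.positions,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# VCF emission with annotations and engineered filter failures
# ---------------------------------------------------------------------------

def _round_f32(x: float, ndigits: int = 1) -> float:
    """Quantize to one decimal at VCF single precision so values
    round-trip exactly through write_vcf/read_vcf."""
    return float(np.float32(round(float(x), ndigits)))


def _draw_annotations(
    law: Dict[str, Tuple[float, float]], rng: np.random.Generator
) -> Dict[str, float]:
    ann: Dict[str, float] = {}
    for tag, (lo, hi) in law.items():
        val = rng.uniform(lo, hi)
        ann[tag] = float(int(round(val))) if tag == "DP" else _round_f32(val)
    if "DP" in ann:
        ann["DP"] = int(ann["DP"])
    return ann


def matrix_to_records(
    matrix: GenotypeMatrix,
    annotations: Optional[List[Dict[str, float]]] = None,
) -> List[SiteRecord]:
    records = []
    for i, (chrom, pos, ref, alt) in enumerate(matrix.sites):
        genotypes: List[Tuple[Optional[int], Optional[int]]] = []
        for d in matrix.dosages[i]:
            if d == MISSING:
                genotypes.append((None, None))
            else:
                genotypes.append((0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1))
        records.append(
            SiteRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                genotypes=genotypes,
                annotations=dict(annotations[i]) if annotations is not None else {},
            )
        )
    return records


_ENGINEER_ORDER = (
    "qd",
    "mq",
    "fs",
    "haplotype_score",
    "mq_rank_sum",
    "read_pos_rank_sum",
    "qual_low",
    "missing_call",
    "not_in_hc",
    "low_carriers",
    "multiallelic",
)

#: Stage of the cascade each engineered failure mode is charged to.
ENGINEER_STAGE = {
    "qd": "hard_filter",
    "mq": "hard_filter",
    "fs": "hard_filter",
    "haplotype_score": "hard_filter",
    "mq_rank_sum": "hard_filter",
    "read_pos_rank_sum": "hard_filter",
    "qual_low": "hard_filter",
    "missing_call": "not_called_in_all",
    "not_in_hc": "not_in_high_confidence",
    "low_carriers": "minor_carriers",
    "multiallelic": "multiallelic",
}

_FAIL_RANGES = {
    "qd": ("QD", 0.0, 1.9),
    "mq": ("MQ", 0.0, 39.0),
    "fs": ("FS", 60.5, 120.0),
    "haplotype_score": ("HaplotypeScore", 13.5, 25.0),
    "mq_rank_sum": ("MQRankSum", -20.0, -13.0),
    "read_pos_rank_sum": ("ReadPosRankSum", -15.0, -8.5),
    "qual_low": ("QUAL", 0.5, 3.9),
}


def _enforce_carriers(
    record: SiteRecord, min_carriers: int, rng: np.random.Generator
) -> None:
    """Adjust genotypes in place so both alleles reach the carrier floor."""
    from .filtering import minor_allele_carriers

    for _ in range(4 * len(record.genotypes)):
        minor, other = minor_allele_carriers(record)
        if minor >= min_carriers and other >= min_carriers:
            return
        dosages = record.dosages()
        called = dosages[dosages >= 0]
        alt_minor = int(called.sum()) <= len(called)
        target = 0 if alt_minor else 2  # convert one major homozygote to het
        candidates = np.flatnonzero(dosages == target)
        if len(candidates) == 0:
            raise ValueError("cannot enforce carrier floor: too few samples")
        record.genotypes[int(rng.choice(candidates))] = (0, 1)


def emit_vcf(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    out_dir: str,
    min_carriers: int = 5,
    hc_samples: int = 3,
) -> Dict:
    """Write the simulated call set to disk: low-coverage VCF,
    high-confidence VCF, population TSV and region BED.

    With ``config.engineered`` set, disjoint site subsets are modified
    to fail each hard filter / cascade rule; every other site is
    guaranteed to pass the whole cascade (carrier floors enforced, no
    missing calls).  Returns a manifest with file paths and, when
    engineering is on, the per-site truth stage.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = config.stream("annotations")
    rng.integers(0, 4, size=matrix.n_sites)  # skip the allele draws
    rng.integers(1, 4, size=matrix.n_sites)
    n_sites = matrix.n_sites
    annotations = [_draw_annotations(config.annotation_law, rng) for _ in range(n_sites)]
    records = matrix_to_records(matrix, annotations)

    truth_stage: Dict[Tuple[str, int], str] = {}
    hc_excluded: set = set()
    if config.engineered is not None:
        fr = config.engineered
        order = rng.permutation(n_sites)
        cursor = 0
        for mode in _ENGINEER_ORDER:
            frac = getattr(fr, mode)
            k = int(round(frac * n_sites))
            chosen = order[cursor : cursor + k]
            cursor += k
            for idx in chosen:
                rec = records[idx]
                truth_stage[(rec.chrom, rec.pos)] = ENGINEER_STAGE[mode]
                if mode in _FAIL_RANGES:
                    tag, lo, hi = _FAIL_RANGES[mode]
                    rec.annotations[tag] = _round_f32(rng.uniform(lo, hi))
                elif mode == "missing_call":
                    victim = int(rng.integers(0, len(rec.genotypes)))
                    rec.genotypes[victim] = (None, None)
                elif mode == "not_in_hc":
                    hc_excluded.add(idx)
                elif mode == "low_carriers":
                    k_carriers = int(rng.integers(1, min_carriers))
                    rec.genotypes[:] = [(0, 0)] * len(rec.genotypes)
                    for v in rng.choice(len(rec.genotypes), size=k_carriers, replace=False):
                        rec.genotypes[int(v)] = (0, 1)
                elif mode == "multiallelic":
                    second = next(b for b in "ACGT" if b not in (rec.ref, rec.alts[0]))
                    rec.alts = (rec.alts[0], second)
                    rec.genotypes[0] = (1, 2)
        # everything unengineered must sail through the cascade
        engineered_idx = set(int(i) for i in order[:cursor])
        for idx, rec in enumerate(records):
            if idx in engineered_idx:
                continue
            _enforce_carriers(rec, min_carriers, rng)
            truth_stage[(rec.chrom, rec.pos)] = "retained"

    contigs = {config.chrom: config.chrom_length}
    low_path = os.path.join(out_dir, "low_coverage.vcf")
    write_vcf(low_path, records, matrix.samples, contigs)

    # high-confidence companion call set: same sites (biallelic form),
    # passing annotations with QUAL > 30 and combined DP > 30
    hc_names = [f"HC_{i + 1:02d}" for i in range(hc_samples)]
    hc_records = []
    for idx, (chrom, pos, ref, alt) in enumerate(matrix.sites):
        if idx in hc_excluded:
            continue
        row = matrix.dosages[idx]
        freq = max(0.05, min(0.95, float(row[row >= 0].mean()) / 2.0 if (row >= 0).any() else 0.5))
        genos = []
        for _ in hc_names:
            d = int(rng.binomial(2, freq))
            genos.append((0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1))
        ann = _draw_annotations(config.annotation_law, rng)
        ann["QUAL"] = _round_f32(rng.uniform(100, 1000))
        ann["DP"] = int(rng.integers(60, 400))
        hc_records.append(
            SiteRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,), genotypes=genos, annotations=ann)
        )
    hc_path = os.path.join(out_dir, "high_confidence.vcf")
    write_vcf(hc_path, hc_records, hc_names, contigs)

    pops_path = os.path.join(out_dir, "populations.tsv")
    write_populations(pops_path, matrix.populations)
    regions_path = os.path.join(out_dir, "regions.bed")
    write_regions(regions_path, config.region_set())

    return {
        "low_vcf": low_path,
        "hc_vcf": hc_path,
        "populations": pops_path,
        "regions": regions_path,
        "truth_stage": truth_stage,
        "n_sites": n_sites,
    }


def simulate_depth(
    chrom_length: int,
    mean_depth: float,
    rng: np.random.Generator,
    centromere: Optional[Tuple[int, int]] = None,
    zero_fraction: float = 0.02,
    overdispersion: float = 5.0,
) -> np.ndarray:
    """Combined per-base depth with gamma-Poisson noise, a linear dip
    toward the centromere, and dropout runs of zero coverage."""
    x = np.arange(chrom_length, dtype=float)
    mean = np.full(chrom_length, float(mean_depth))
    if centromere is not None:
        s, e = centromere
        inside = (x >= s) & (x < e)
        ramp = 1.0 - 0.7 * (x[inside] - s) / max(1, e - s)
        mean[inside] *= ramp
    lam = rng.gamma(overdispersion, mean / overdispersion)
    depth = rng.poisson(lam)
    n_zero_runs = max(1, int(zero_fraction * chrom_length / 500))
    starts = rng.integers(0, chrom_length, size=n_zero_runs)
    lengths = rng.integers(100, 900, size=n_zero_runs)
    for s0, ln in zip(starts, lengths):
        depth[s0 : s0 + ln] = 0
    return depth.astype(np.int64)
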