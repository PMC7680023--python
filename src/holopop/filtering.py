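"""Four-step variant filter cascade plus one-SNP-per-contig thinning.

Step 1: recode genotypes with depth < 5 to missing, then keep sites with
QUAL > 30, biallelic SNPs only (no indels), minor allele count >= 3, and
drop individuals with > 50% missing data.
Step 2: drop individuals with > 85% missing data.
Step 3: keep sites with <= 75% missing data, minor allele frequency
>= 0.05, and mean depth across included individuals >= 10.
Step 4: drop sites out of Hardy-Weinberg equilibrium (exact-test
p < 0.01) in more than half of the populations.

Every step is recorded in a :class:`FilterReport` with in/out counts and
removed identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "FilterParams",
    "FilterReport",
    "recode_low_depth",
    "filter_sites_basic",
    "filter_individuals",
    "filter_sites_secondary",
    "hwe_exact_test",
    "hwe_filter_by_pop",
    "thin_one_snp_per_contig",
    "run_cascade",
]


@dataclass
class FilterParams:
    """Cascade thresholds. Defaults follow the published filter settings."""

    ind_missing_1: float = 0.50
    mac_min: int = 3
    qual_min: float = 30.0
    depth_min_genotype: int = 5
    biallelic_only: bool = True
    drop_indels: bool = True
    ind_missing_2: float = 0.85
    site_missing_max: float = 0.75
    maf_min: float = 0.05
    mean_depth_min: float = 10.0
    hwe_p_cutoff: float = 0.01
    hwe_pop_fraction: float = 0.5
    # literal_mac=True excludes (rather than keeps) sites with mac >= mac_min,
    # the verbatim wording of the source protocol; default is the
    # conventional keep-threshold reading.
    literal_mac: bool = False

    def __post_init__(self):
        for name in ("ind_missing_1", "ind_missing_2", "site_missing_max",
                     "maf_min", "hwe_p_cutoff", "hwe_pop_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0, 1]")
        if self.mac_min < 0 or self.depth_min_genotype < 0:
            raise DataError("counts must be non-negative")


@dataclass
class StepRecord:
    name: str
    sites_in: int
    sites_out: int
    individuals_in: int
    individuals_out: int
    removed_sites: list[str] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    steps: list[StepRecord] = field(default_factory=list)

    def add(self, rec: StepRecord) -> None:
        if self.steps:
            prev = self.steps[-1]
            if rec.sites_in != prev.sites_out or rec.individuals_in != prev.individuals_out:
                raise DataError("filter report steps are not contiguous")
        if rec.sites_out > rec.sites_in or rec.individuals_out > rec.individuals_in:
            raise DataError("filter step increased counts")
        self.steps.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "sites_in": s.sites_in,
                    "sites_out": s.sites_out,
                    "individuals_in": s.individuals_in,
                    "individuals_out": s.individuals_out,
                    "n_sites_removed": s.sites_in - s.sites_out,
                    "n_individuals_removed": s.individuals_in - s.individuals_out,
                }
                for s in self.steps
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def recode_low_depth(gm: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set calls with per-genotype depth below ``min_depth`` to missing."""
    if min_depth <= 0:
        return gm
    if gm.depth is None:
        raise DataError(
            "no depth data in matrix; set depth_min_genotype=0 to disable recoding"
        )
    out = gm.take_loci(np.arange(gm.n_loci))  # copy
    out.calls = np.where(gm.depth < min_depth, MISSING, gm.calls).astype(np.int8)
    return out


def _site_mac_maf(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    alt, n_genotyped = gm.alt_counts()
    total = 2 * n_genotyped
    ref = total - alt
    mac = np.minimum(alt, ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, mac / np.maximum(total, 1), 0.0)
    return mac, maf


def filter_sites_basic(gm: GenotypeMatrix, params: FilterParams) -> GenotypeMatrix:
    """QUAL > qual_min (strict), biallelic SNPs only, mac >= mac_min."""
    keep = np.ones(gm.n_loci, dtype=bool)
    if gm.site_qual is not None and params.qual_min > 0:
        keep &= gm.site_qual > params.qual_min
    if params.biallelic_only:
        keep &= ~gm.multiallelic
    if params.drop_indels:
        is_snp = np.array(
            [len(str(r)) == 1 and len(str(a)) == 1 for r, a in zip(gm.ref, gm.alt)]
        )
        keep &= is_snp
    if params.mac_min > 0:
        mac, _ = _site_mac_maf(gm)
        if params.literal_mac:
            keep &= mac < params.mac_min
        else:
            keep &= mac >= params.mac_min
    return gm.take_loci(keep)


def filter_individuals(gm: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop samples whose missing fraction strictly exceeds the threshold."""
    if gm.n_loci == 0:
        return gm
    frac = gm.missing_mask().mean(axis=1)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise DataError("individual filter would remove every sample")
    return gm.take_samples(np.flatnonzero(keep))


def filter_sites_secondary(gm: GenotypeMatrix, params: FilterParams) -> GenotypeMatrix:
    """Site missingness <= max, MAF >= min (inclusive), mean depth >= min."""
    keep = np.ones(gm.n_loci, dtype=bool)
    miss_frac = gm.missing_mask().mean(axis=0)
    keep &= miss_frac <= params.site_missing_max
    if params.maf_min > 0:
        _, maf = _site_mac_maf(gm)
        keep &= maf >= params.maf_min
    if params.mean_depth_min > 0:
        if gm.depth is None:
            raise DataError("no depth data; set mean_depth_min=0 to disable")
        keep &= gm.depth.mean(axis=0) >= params.mean_depth_min
    return gm.take_loci(keep)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (Wigginton-Cutler-Abecasis convention).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise DataError("at least one genotyped individual required")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # enumerate het counts with the parity of the rare-allele count
    het_values = list(range(rare % 2, rare + 1, 2))
    logprob = {}
    for h in het_values:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logprob[h] = lp
    probs = {h: math.exp(lp) for h, lp in logprob.items()}
    z = sum(probs.values())
    p_obs = probs[n_het] / z
    p = sum(pv for pv in probs.values() if pv / z <= p_obs * (1 + 1e-12)) / z
    return min(p, 1.0)


def hwe_filter_by_pop(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    p_cutoff: float = 0.01,
    pop_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Drop sites out of HWE (p < cutoff) in more than ``pop_fraction`` of
    populations; populations with < 2 genotyped individuals at a site are
    skipped for that site."""
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    keep = np.ones(gm.n_loci, dtype=bool)
    calls = gm.calls
    for l in range(gm.n_loci):
        n_viol = n_tested = 0
        for pop in pops:
            sub = calls[labels == pop, l]
            sub = sub[sub != MISSING]
            if len(sub) < 2:
                continue
            n_tested += 1
            counts = (
                int((sub == 0).sum()),
                int((sub == 1).sum()),
                int((sub == 2).sum()),
            )
            if hwe_exact_test(*counts) < p_cutoff:
                n_viol += 1
        if n_tested and n_viol / n_tested > pop_fraction:
            keep[l] = False
    return gm.take_loci(keep)


def thin_one_snp_per_contig(gm: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Retain exactly one uniformly random SNP per contig (seeded)."""
    rng = np.random.default_rng(seed)
    chosen = []
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(gm.contigs):
        groups.setdefault(c, []).append(i)
    for contig in sorted(groups):
        idx = groups[contig]
        chosen.append(idx[int(rng.integers(len(idx)))])
    return gm.take_loci(np.sort(chosen))


def run_cascade(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    params: FilterParams | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full four-step cascade in order; returns matrix + report."""
    params = params or FilterParams()
    report = FilterReport()

    def record(name, before, after):
        removed_s = sorted(set(before.locus_ids) - set(after.locus_ids))
        removed_i = sorted(set(before.samples) - set(after.samples))
        report.add(
            StepRecord(
                name=name,
                sites_in=before.n_loci,
                sites_out=after.n_loci,
                individuals_in=before.n_samples,
                individuals_out=after.n_samples,
                removed_sites=removed_s,
                removed_individuals=removed_i,
            )
        )

    stage = recode_low_depth(gm, params.depth_min_genotype) if params.depth_min_genotype else gm
    record("1a_recode_low_depth", gm, stage)
    nxt = filter_sites_basic(stage, params)
    record("1b_sites_basic", stage, nxt)
    stage = nxt
    nxt = filter_individuals(stage, params.ind_missing_1)
    record("1c_individuals_50", stage, nxt)
    stage = nxt
    nxt = filter_individuals(stage, params.ind_missing_2)
    record("2_individuals_85", stage, nxt)
    stage = nxt
    nxt = filter_sites_secondary(stage, params)
    record("3_sites_secondary", stage, nxt)
    stage = nxt
    nxt = hwe_filter_by_pop(stage, pm, params.hwe_p_cutoff, params.hwe_pop_fraction)
    record("4_hwe_by_pop", stage, nxt)
    return nxt, report
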