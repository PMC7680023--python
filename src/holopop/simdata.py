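"""Synthetic holobiont dataset generator with known ground truth.

Emulates a two-origin x two-state sampling design (default populations
VA-B, VA-W, RI-B, RI-W x 10 diploid individuals): neutral loci drift
independently per population under the Balding-Nichols model, outlier loci
diverge at the origin level, one clone pair is planted, genotypes carry
negative-binomial read depths and MCAR missingness. The fixture bundle also
fabricates contigs, BLAST hit tables and GO annotations consistent with the
compartment-assignment rules, so the whole pipeline is testable offline.

The symbiont compartment is emitted as diploid genotype calls even though
the algal symbionts are biologically haploid; this mirrors default
diploid-caller treatment of the real data and is a deliberate
simplification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ModelError
from .formats import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_pod",
    "write_fixture_bundle",
    "default_pop_labels",
]

_BASES = np.array(list("ACGT"))


def default_pop_labels(n_pops: int) -> list[str]:
    if n_pops == 4:
        return ["VA-B", "VA-W", "RI-B", "RI-W"]
    if n_pops == 2:
        return ["VA-B", "RI-B"]
    return [f"P{i + 1}-B" for i in range(n_pops)]


@dataclass
class SimConfig:
    """Parameters of one simulated compartment.

    ``fst_neutral``/``fst_outlier`` are Balding-Nichols F parameters; with
    ``origin_effect`` the outlier differentiation is applied between origins
    (label prefix before ``-``) rather than between individual populations.
    """

    n_pops: int = 4
    n_ind_per_pop: int = 10
    n_neutral_loci: int = 1000
    n_outlier_loci: int = 50
    fst_neutral: float = 0.02
    fst_outlier: float = 0.40
    origin_effect: bool = True
    missing_rate: float = 0.05
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    clone_pairs: int = 1
    clone_error_rate: float = 0.0
    loci_per_contig: float = 3.0
    symbiont_in_brown_only: bool = True
    seed: int = 0
    pop_labels: list[str] | None = None
    # "mirrored": origin frequencies placed at anc +/- sqrt(F anc(1-anc)),
    # guaranteeing per-locus divergence with expected between-origin Fst = F;
    # "balding_nichols": independent per-origin draws (per-locus divergence
    # then varies widely and many planted outliers carry no signal).
    outlier_mode: str = "mirrored"

    def resolved_labels(self) -> list[str]:
        labels = self.pop_labels or default_pop_labels(self.n_pops)
        if len(labels) != self.n_pops:
            raise ConfigurationError(
                f"{len(labels)} labels given for n_pops={self.n_pops}"
            )
        return labels

    def validate(self) -> None:
        for name in ("missing_rate", "clone_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("fst_neutral", "fst_outlier"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1)")
        if (
            self.fst_neutral > 0
            and self.fst_outlier > 0
            and self.n_outlier_loci > 0
            and self.fst_outlier <= self.fst_neutral
        ):
            raise ConfigurationError("fst_outlier must exceed fst_neutral")
        labels = self.resolved_labels()
        origins = {lab.split("-")[0] for lab in labels}
        if self.origin_effect and self.n_outlier_loci > 0 and len(origins) < 2:
            raise ConfigurationError(
                "origin_effect requires populations from at least two origins"
            )
        if self.n_pops < 1 or self.n_ind_per_pop < 1:
            raise ConfigurationError("need at least one population and individual")
        if self.outlier_mode not in ("mirrored", "balding_nichols"):
            raise ConfigurationError(f"unknown outlier_mode {self.outlier_mode!r}")


@dataclass
class TruthTable:
    """Per-locus generating truth plus planted clone pairs."""

    loci: pd.DataFrame  # locus_id, contig_id, position, is_outlier, ancestral_freq, freq_<pop>
    clone_pairs: list[tuple[str, str]] = field(default_factory=list)

    def write_tsv(self, path) -> None:
        df = self.loci.copy()
        df["clone_pairs"] = ""
        if len(df) and self.clone_pairs:
            df.loc[df.index[0], "clone_pairs"] = ";".join(
                f"{a}|{b}" for a, b in self.clone_pairs
            )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        pairs: list[tuple[str, str]] = []
        if "clone_pairs" in df.columns:
            raw = df["clone_pairs"].dropna()
            for cell in raw:
                if isinstance(cell, str) and cell:
                    pairs.extend(tuple(p.split("|")) for p in cell.split(";"))
            df = df.drop(columns=["clone_pairs"])
        return cls(df, pairs)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float, size) -> np.ndarray:
    """Population frequencies around ancestral p at differentiation F."""
    if fst <= 0.0:
        return np.broadcast_to(p, size).copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)


def _assign_contigs(rng: np.random.Generator, n_loci: int, mean_loci: float, prefix: str):
    """Group consecutive loci into contigs of ~mean_loci SNPs each."""
    contigs, positions = [], []
    idx = 0
    cid = 0
    while idx < n_loci:
        size = 1 + rng.poisson(max(mean_loci - 1.0, 0.0))
        size = min(size, n_loci - idx)
        name = f"{prefix}{cid:05d}"
        for k in range(size):
            contigs.append(name)
            positions.append(101 + 37 * k)
        idx += size
        cid += 1
    return np.array(contigs, dtype=object), np.array(positions, dtype=np.int64)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate one compartment: genotypes, depths, missingness, clones.

    Neutral loci: ancestral frequency ~ U(0.05, 0.95), per-population
    frequency from Balding-Nichols at ``fst_neutral``. Outlier loci: one
    Balding-Nichols draw at ``fst_outlier`` per origin (shared by the
    populations of that origin). Genotypes ~ Binomial(2, pop frequency).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.resolved_labels()
    origins = [lab.split("-")[0] for lab in labels]
    n_ind = cfg.n_ind_per_pop
    n_total_loci = cfg.n_neutral_loci + cfg.n_outlier_loci

    anc = rng.uniform(0.05, 0.95, size=n_total_loci)
    pop_freq = np.empty((cfg.n_pops, n_total_loci))
    nn = cfg.n_neutral_loci
    pop_freq[:, :nn] = _balding_nichols(
        rng, anc[:nn], cfg.fst_neutral, (cfg.n_pops, nn)
    )
    if cfg.n_outlier_loci:
        if cfg.origin_effect:
            uniq = list(dict.fromkeys(origins))
            if cfg.outlier_mode == "mirrored" and cfg.fst_outlier > 0:
                # deterministic divergence: anc +/- sqrt(F anc(1-anc));
                # for two origins the expected between-origin Fst is F
                delta = np.sqrt(cfg.fst_outlier * anc[nn:] * (1 - anc[nn:]))
                # translate the pair inward when a boundary would clip it,
                # so the full 2*delta gap survives at every locus
                center = np.clip(anc[nn:], 0.01 + delta, 0.99 - delta)
                signs = np.ones((len(uniq), cfg.n_outlier_loci))
                signs[1::2] = -1.0
                flip = rng.random(cfg.n_outlier_loci) < 0.5
                signs[:, flip] *= -1.0
                origin_freq = {
                    o: np.clip(center + signs[k] * delta, 0.01, 0.99)
                    for k, o in enumerate(uniq)
                }
            else:
                origin_freq = {
                    o: _balding_nichols(
                        rng, anc[nn:], cfg.fst_outlier, (cfg.n_outlier_loci,)
                    )
                    for o in uniq
                }
            for j, o in enumerate(origins):
                pop_freq[j, nn:] = origin_freq[o]
        else:
            pop_freq[:, nn:] = _balding_nichols(
                rng, anc[nn:], cfg.fst_outlier, (cfg.n_pops, cfg.n_outlier_loci)
            )

    samples: list[str] = []
    rows = []
    for j, lab in enumerate(labels):
        g = rng.binomial(2, pop_freq[j], size=(n_ind, n_total_loci)).astype(np.int8)
        rows.append(g)
        samples.extend(f"{lab}_{i + 1:02d}" for i in range(n_ind))
    calls = np.vstack(rows)
    pop_of_sample = np.repeat(np.arange(cfg.n_pops), n_ind)

    # clones: extra samples duplicating a donor, per-allele flip errors
    clone_pairs: list[tuple[str, str]] = []
    for k in range(cfg.clone_pairs):
        pop_j = int(rng.integers(cfg.n_pops))
        donor_idx = int(rng.integers(n_ind)) + pop_j * n_ind
        donor = samples[donor_idx]
        g = calls[donor_idx].astype(np.int16)
        a1 = (g >= 1).astype(np.int16)
        a2 = (g == 2).astype(np.int16)
        if cfg.clone_error_rate > 0:
            flip1 = rng.random(n_total_loci) < cfg.clone_error_rate
            flip2 = rng.random(n_total_loci) < cfg.clone_error_rate
            a1 = np.where(flip1, 1 - a1, a1)
            a2 = np.where(flip2, 1 - a2, a2)
        clone_name = f"{donor}_clone"
        samples.append(clone_name)
        calls = np.vstack([calls, (a1 + a2).astype(np.int8)])
        pop_of_sample = np.append(pop_of_sample, pop_j)
        clone_pairs.append((donor, clone_name))

    n_samples = calls.shape[0]
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
    depth = rng.negative_binomial(
        cfg.depth_dispersion, p_nb, size=(n_samples, n_total_loci)
    ).astype(np.int32)
    if cfg.missing_rate > 0:
        miss = rng.random((n_samples, n_total_loci)) < cfg.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    contigs, positions = _assign_contigs(
        rng, n_total_loci, cfg.loci_per_contig, prefix="contig"
    )
    ref = _BASES[rng.integers(0, 4, n_total_loci)].astype(object)
    shift = rng.integers(1, 4, n_total_loci)
    alt = _BASES[
        (np.char.find("ACGT", ref.astype(str)) + shift) % 4
    ].astype(object)
    qual = np.round(rng.uniform(50.0, 900.0, n_total_loci), 2)

    gm = GenotypeMatrix(
        samples=samples,
        contigs=contigs,
        positions=positions,
        ref=ref,
        alt=alt,
        calls=calls,
        depth=depth,
        site_qual=qual,
    )
    truth = pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "contig_id": contigs,
            "position": positions,
            "is_outlier": np.arange(n_total_loci) >= nn,
            "ancestral_freq": anc,
        }
    )
    for j, lab in enumerate(labels):
        truth[f"freq_{lab}"] = pop_freq[j]
    return gm, TruthTable(truth, clone_pairs)


def simulate_pod(
    omega: np.ndarray,
    pi_dist,
    sample_sizes: dict[str, int],
    n_loci: int,
    seed: int,
) -> GenotypeMatrix:
    """Pseudo-observed data from a fitted null model.

    Per locus: ancestral frequency pi from ``pi_dist`` (an array resampled
    with replacement, or a callable ``f(rng, size)``), population frequency
    vector ~ N(pi * 1, pi(1-pi) * omega) truncated to [0, 1], then
    per-individual genotypes ~ Binomial(2, frequency) at the observed
    sample sizes.
    """
    omega = np.asarray(omega, dtype=float)
    n_pops = len(sample_sizes)
    if omega.shape != (n_pops, n_pops):
        raise ModelError(
            f"omega shape {omega.shape} does not match {n_pops} populations"
        )
    eigvals = np.linalg.eigvalsh((omega + omega.T) / 2.0)
    if eigvals.min() < -1e-8:
        raise ModelError("omega is not positive semi-definite")
    rng = np.random.default_rng(seed)
    if callable(pi_dist):
        pi = np.asarray(pi_dist(rng, n_loci), dtype=float)
    else:
        pool = np.asarray(pi_dist, dtype=float)
        pi = rng.choice(pool, size=n_loci, replace=True)
    pi = np.clip(pi, 1e-6, 1 - 1e-6)
    chol = np.linalg.cholesky(omega + 1e-10 * np.eye(n_pops))
    z = rng.standard_normal((n_loci, n_pops))
    freqs = pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * (z @ chol.T)
    freqs = np.clip(freqs, 0.0, 1.0)

    samples: list[str] = []
    rows = []
    for j, (pop, n) in enumerate(sample_sizes.items()):
        if n <= 0:
            raise ModelError(f"sample size for {pop} must be positive")
        g = rng.binomial(2, freqs[:, j], size=(n, n_loci)).astype(np.int8)
        rows.append(g)
        samples.extend(f"POD_{pop}_{i + 1:02d}" for i in range(n))
    calls = np.vstack(rows)
    return GenotypeMatrix(
        samples=samples,
        contigs=np.array([f"pod{l:06d}" for l in range(n_loci)], dtype=object),
        positions=np.full(n_loci, 101, dtype=np.int64),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["T"] * n_loci, dtype=object),
        calls=calls,
    )


def pod_population_map(sample_sizes: dict[str, int]) -> PopulationMap:
    """Population map matching :func:`simulate_pod` sample naming."""
    records = {}
    for pop, n in sample_sizes.items():
        origin, _, state = pop.partition("-")
        for i in range(n):
            records[f"POD_{pop}_{i + 1:02d}"] = (origin, state or "B")
    return PopulationMap.from_records(records)


# ---------------------------------------------------------------------------
# fixture bundle


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _population_map_for(gm: GenotypeMatrix, labels: list[str]) -> PopulationMap:
    records = {}
    for s in gm.samples:
        base = s[:-6] if s.endswith("_clone") else s
        lab = base.rsplit("_", 1)[0]
        origin, _, state = lab.partition("-")
        records[s] = (origin, state)
    return PopulationMap.from_records(records)


def write_fixture_bundle(cfg: SimConfig, outdir) -> dict:
    """Emit a full synthetic bundle: VCF, population map, contig FASTA,
    BLAST hit tables, GO annotation, truth TSV and a checksum manifest.

    The VCF contains host loci for every sample plus symbiont loci that are
    missing in white (aposymbiotic) individuals when
    ``symbiont_in_brown_only`` is set. Contig labels in the truth are
    backed by BLAST hit rows engineered to satisfy (or fail) the
    compartment-assignment rules, alongside planted rRNA and too-short
    contigs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 104729)

    host_gm, host_truth = simulate_genotypes(cfg)
    host_gm = GenotypeMatrix(
        samples=host_gm.samples,
        contigs=np.array([c.replace("contig", "hostctg") for c in host_gm.contigs], dtype=object),
        positions=host_gm.positions,
        ref=host_gm.ref,
        alt=host_gm.alt,
        calls=host_gm.calls,
        depth=host_gm.depth,
        site_qual=host_gm.site_qual,
    )
    host_truth.loci["contig_id"] = [
        c.replace("contig", "hostctg") for c in host_truth.loci["contig_id"]
    ]
    host_truth.loci["locus_id"] = host_gm.locus_ids
    host_truth.loci["compartment"] = "host"

    labels = cfg.resolved_labels()
    brown = [lab for lab in labels if lab.endswith("-B")] or labels[:1]
    origins = list(dict.fromkeys(lab.split("-")[0] for lab in brown))
    sym_cfg = SimConfig(
        n_pops=len(brown),
        n_ind_per_pop=cfg.n_ind_per_pop,
        n_neutral_loci=max(cfg.n_neutral_loci // 10, 10),
        n_outlier_loci=max(cfg.n_outlier_loci // 10, 2),
        fst_neutral=min(max(cfg.fst_neutral * 4, 0.05), 0.3),
        fst_outlier=cfg.fst_outlier,
        origin_effect=len(origins) > 1,
        missing_rate=cfg.missing_rate,
        mean_depth=cfg.mean_depth,
        depth_dispersion=cfg.depth_dispersion,
        clone_pairs=0,
        loci_per_contig=cfg.loci_per_contig,
        seed=cfg.seed + 7919,
        pop_labels=brown,
    )
    sym_gm, sym_truth = simulate_genotypes(sym_cfg)
    sym_contigs = np.array(
        [c.replace("contig", "symctg") for c in sym_gm.contigs], dtype=object
    )
    sym_truth.loci["contig_id"] = [
        c.replace("contig", "symctg") for c in sym_truth.loci["contig_id"]
    ]
    sym_truth.loci["compartment"] = "symbiont"

    # embed symbiont loci in the holobiont sample frame
    n_sym_loci = sym_gm.n_loci
    sym_calls = np.full((host_gm.n_samples, n_sym_loci), MISSING, dtype=np.int8)
    sym_depth = np.zeros((host_gm.n_samples, n_sym_loci), dtype=np.int32)
    host_index = {s: i for i, s in enumerate(host_gm.samples)}
    for i, s in enumerate(sym_gm.samples):
        if s in host_index:
            sym_calls[host_index[s]] = sym_gm.calls[i]
            sym_depth[host_index[s]] = sym_gm.depth[i]
    if not cfg.symbiont_in_brown_only:
        # give white samples symbiont genotypes drawn from their origin pop
        for s, i in host_index.items():
            if (sym_calls[i] == MISSING).all():
                base = s[:-6] if s.endswith("_clone") else s
                origin = base.split("-")[0]
                donor_pop = next((b for b in brown if b.startswith(origin)), brown[0])
                freqs = sym_truth.loci[f"freq_{donor_pop}"].to_numpy()
                sym_calls[i] = rng.binomial(2, freqs).astype(np.int8)
                sym_depth[i] = rng.negative_binomial(
                    cfg.depth_dispersion,
                    cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth),
                    n_sym_loci,
                ).astype(np.int32)

    sym_truth.loci["locus_id"] = [
        f"{c}_{p}" for c, p in zip(sym_contigs, sym_truth.loci["position"])
    ]

    combined = GenotypeMatrix(
        samples=host_gm.samples,
        contigs=np.concatenate([host_gm.contigs, sym_contigs]),
        positions=np.concatenate([host_gm.positions, sym_gm.positions]),
        ref=np.concatenate([host_gm.ref, sym_gm.ref]),
        alt=np.concatenate([host_gm.alt, sym_gm.alt]),
        calls=np.hstack([host_gm.calls, sym_calls]),
        depth=np.hstack([host_gm.depth, sym_depth]),
        site_qual=np.concatenate([host_gm.site_qual, sym_gm.site_qual]),
    )

    pm = _population_map_for(host_gm, labels)

    # contigs: real host/sym contigs plus planted rRNA / short / unassigned
    contig_rows = []  # (name, length, true_label)
    for name in dict.fromkeys(host_gm.contigs):
        contig_rows.append((name, int(rng.integers(600, 2000)), "host"))
    for name in dict.fromkeys(sym_contigs):
        contig_rows.append((name, int(rng.integers(600, 2000)), "symbiont"))
    for k in range(3):
        contig_rows.append((f"rrnactg{k:03d}", int(rng.integers(600, 1200)), "rRNA_removed"))
    for k in range(3):
        contig_rows.append((f"shortctg{k:03d}", int(rng.integers(100, 500)), "too_short"))
    for k in range(3):
        contig_rows.append((f"noisectg{k:03d}", int(rng.integers(600, 1500)), "unassigned"))
    for k in range(2):
        contig_rows.append((f"ambigctg{k:03d}", int(rng.integers(600, 1500)), "ambiguous_removed"))

    fasta_path = outdir / "contigs.fasta"
    with open(fasta_path, "w") as fh:
        for name, length, _ in contig_rows:
            fh.write(f">{name}\n{_random_seq(rng, length)}\n")

    # BLAST hits consistent with labels
    hit_tables: dict[str, list[tuple]] = {
        db: [] for db in ("dirty_coral", "dirty_sym", "clean_coral", "clean_sym")
    }
    rrna_hits: list[tuple] = []
    for name, length, label in contig_rows:
        if label == "host":
            hit_tables["dirty_coral"].append(
                (name, f"cnidarian{rng.integers(100)}", round(rng.uniform(70, 99), 2),
                 int(rng.integers(150, min(length, 800))), 1e-30)
            )
        elif label == "symbiont":
            hit_tables["clean_sym"].append(
                (name, f"symculture{rng.integers(100)}", round(rng.uniform(70, 99), 2),
                 int(rng.integers(150, min(length, 800))), 1e-30)
            )
        elif label == "ambiguous_removed":
            hit_tables["dirty_coral"].append(
                (name, f"cnidarian{rng.integers(100)}", 85.0, 200, 1e-20)
            )
            hit_tables["clean_sym"].append(
                (name, f"symculture{rng.integers(100)}", 85.0, 200, 1e-20)
            )
        elif label == "rRNA_removed":
            rrna_hits.append(
                (name, f"LSU{rng.integers(50)}", 95.0,
                 max(100, int(np.ceil(0.80 * length))), 1e-50)
            )
        elif label == "unassigned":
            # sub-threshold hit only: short overlap
            hit_tables["dirty_coral"].append(
                (name, f"cnidarian{rng.integers(100)}", 90.0, 80, 1e-5)
            )
    blast_paths = {}
    for db, rows in hit_tables.items():
        p = outdir / f"blast_{db}.tsv"
        pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "pident", "length", "evalue"]
        ).to_csv(p, sep="\t", index=False, header=False)
        blast_paths[db] = p
    for db, rows in (("rRNA_LSU", rrna_hits), ("rRNA_SSU", [])):
        p = outdir / f"blast_{db}.tsv"
        pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "pident", "length", "evalue"]
        ).to_csv(p, sep="\t", index=False, header=False)
        blast_paths[db] = p

    # GO annotation: every real contig gets 1-4 GO terms from a pool of 40
    go_pool = [f"GO:{n:07d}" for n in rng.choice(2_000_000, size=40, replace=False)]
    ann_rows = []
    for name, _, label in contig_rows:
        if label in ("host", "symbiont"):
            terms = rng.choice(go_pool, size=int(rng.integers(1, 5)), replace=False)
            ann_rows.append((name, ";".join(sorted(terms))))
    go_path = outdir / "annotation.tsv"
    pd.DataFrame(ann_rows, columns=["contig", "go_terms"]).to_csv(
        go_path, sep="\t", index=False, header=False
    )

    vcf_path = outdir / "holobiont.vcf"
    write_vcf(combined, vcf_path)
    pm_path = outdir / "popmap.csv"
    pm.write_csv(pm_path)
    truth = TruthTable(
        pd.concat([host_truth.loci, sym_truth.loci], ignore_index=True),
        host_truth.clone_pairs,
    )
    truth_path = outdir / "truth.tsv"
    truth.write_tsv(truth_path)
    contig_truth_path = outdir / "contig_truth.tsv"
    pd.DataFrame(contig_rows, columns=["contig", "length", "true_label"]).to_csv(
        contig_truth_path, sep="\t", index=False
    )

    files = {
        "vcf": vcf_path,
        "popmap": pm_path,
        "truth": truth_path,
        "contig_truth": contig_truth_path,
        "fasta": fasta_path,
        "annotation": go_path,
        **{f"blast_{db}": p for db, p in blast_paths.items()},
    }
    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "files": {
            key: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for key, p in files.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
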