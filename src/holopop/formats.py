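"""Readers and writers for VCF, genepop, population maps and report tables.

The two central containers of the pipeline live here:

``GenotypeMatrix``
    samples x loci diploid alt-allele counts in {0, 1, 2} with ``-1`` for
    missing, plus optional per-genotype depth and per-site quality.

``PopulationMap``
    sample -> (origin, state); the population label is ``origin-state``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataError

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "read_vcf",
    "write_vcf",
    "write_genepop",
    "read_genepop",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n_samples`` individuals at ``n_loci`` sites.

    ``calls`` counts copies of the (first) ALT allele; ``-1`` means missing.
    Positions are 1-based as in VCF. ``multiallelic`` flags records that
    carried more than one ALT allele in the source VCF; such sites are kept
    on read and removed by the biallelic filter.
    """

    samples: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    depth: np.ndarray | None = None
    site_qual: np.ndarray | None = None
    multiallelic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.contigs)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.contigs)} loci"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise DataError("depth shape does not match calls shape")
        if self.site_qual is not None:
            self.site_qual = np.asarray(self.site_qual, dtype=float)
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_loci, dtype=bool)
        else:
            self.multiallelic = np.asarray(self.multiallelic, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.contigs)

    @property
    def locus_ids(self) -> np.ndarray:
        """``contig_position`` identifiers, the pipeline-wide locus key."""
        return np.array(
            [f"{c}_{p}" for c, p in zip(self.contigs, self.positions)], dtype=object
        )

    def take_loci(self, index) -> "GenotypeMatrix":
        """Subset loci by a boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            contigs=self.contigs[index],
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            site_qual=None if self.site_qual is None else self.site_qual[index],
            multiallelic=self.multiallelic[index],
        )

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset samples by names, boolean mask, or integer indices."""
        which = list(which)
        if which and isinstance(which[0], str):
            pos = {s: i for i, s in enumerate(self.samples)}
            missing = [s for s in which if s not in pos]
            if missing:
                raise DataError(f"samples not in matrix: {missing}")
            idx = np.array([pos[s] for s in which], dtype=int)
        else:
            idx = np.asarray(which)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            calls=self.calls[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def equals(self, other: "GenotypeMatrix", calls_only: bool = False) -> bool:
        same = (
            self.samples == other.samples
            and np.array_equal(self.contigs, other.contigs)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.calls, other.calls)
        )
        if calls_only or not same:
            return same
        return np.array_equal(self.ref, other.ref) and np.array_equal(
            self.alt, other.alt
        )

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def alt_counts(self) -> np.ndarray:
        """Per-locus (alt allele count, genotyped sample count)."""
        valid = self.calls != MISSING
        alt = np.where(valid, self.calls, 0).sum(axis=0)
        return alt, valid.sum(axis=0)


@dataclass
class PopulationMap:
    """sample -> (origin, state) assignments; population = ``origin-state``."""

    table: pd.DataFrame  # index: sample; columns: origin, state

    @classmethod
    def from_records(cls, records: dict[str, tuple[str, str]]) -> "PopulationMap":
        df = pd.DataFrame.from_dict(records, orient="index", columns=["origin", "state"])
        df.index.name = "sample"
        return cls(df)

    @classmethod
    def read_csv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, dtype=str)
        required = {"sample", "origin", "state"}
        if not required.issubset(df.columns):
            raise DataError(f"population map must have columns {sorted(required)}")
        return cls(df.set_index("sample")[["origin", "state"]])

    def write_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    def population_of(self, sample: str) -> str:
        if sample not in self.table.index:
            raise DataError(f"sample {sample!r} absent from population map")
        row = self.table.loc[sample]
        return f"{row['origin']}-{row['state']}"

    def labels_for(self, samples) -> np.ndarray:
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise DataError(f"samples absent from population map: {missing}")
        sub = self.table.loc[list(samples)]
        return (sub["origin"] + "-" + sub["state"]).to_numpy(dtype=object)

    def populations(self, samples=None) -> list[str]:
        """Population labels in order of first appearance."""
        labels = (
            self.labels_for(samples)
            if samples is not None
            else (self.table["origin"] + "-" + self.table["state"]).to_numpy()
        )
        seen: dict[str, None] = {}
        for lab in labels:
            seen.setdefault(lab, None)
        return list(seen)

    def origins_for(self, samples) -> np.ndarray:
        return self.table.loc[list(samples), "origin"].to_numpy(dtype=object)

    def restrict(self, populations) -> "PopulationMap":
        labels = self.table["origin"] + "-" + self.table["state"]
        return PopulationMap(self.table[labels.isin(set(populations))])

    def with_samples(self, samples: dict[str, tuple[str, str]]) -> "PopulationMap":
        extra = pd.DataFrame.from_dict(samples, orient="index", columns=["origin", "state"])
        extra.index.name = "sample"
        return PopulationMap(pd.concat([self.table, extra]))


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT required, DP used if present) into a matrix.

    Half-missing diploid calls (``./0``) are treated as fully missing.
    Multiallelic records are retained but flagged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    contigs, positions, refs, alts, quals, multi = [], [], [], [], [], []
    call_rows, depth_rows = [], []
    has_depth = False
    for i, var in enumerate(vcf):
        gts = var.genotypes
        if gts is None:
            raise DataError(f"record {i + 1} ({var.CHROM}:{var.POS}) lacks GT")
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) < 2 or any(a < 0 for a in alleles):
                row[j] = MISSING
            else:
                row[j] = sum(1 for a in alleles if a == 1)
        call_rows.append(row)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depth_rows.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
        else:
            depth_rows.append(np.zeros(len(samples), dtype=np.int32))
        contigs.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        multi.append(len(var.ALT) > 1)
    if not contigs:
        raise DataError(f"no variant records in {path}")
    return GenotypeMatrix(
        samples=samples,
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=np.vstack(call_rows).T,
        depth=np.vstack(depth_rows).T if has_depth else None,
        site_qual=np.array(quals, dtype=float),
        multiallelic=np.array(multi, dtype=bool),
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT:DP genotype fields."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
    for contig in dict.fromkeys(gm.contigs):
        buf.write(f"##contig=<ID={contig}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
        + "\n"
    )
    qual = gm.site_qual if gm.site_qual is not None else np.full(gm.n_loci, np.nan)
    depth = gm.depth
    for l in range(gm.n_loci):
        q = "." if np.isnan(qual[l]) else f"{qual[l]:g}"
        fields = [
            str(gm.contigs[l]),
            str(gm.positions[l]),
            ".",
            str(gm.ref[l]),
            str(gm.alt[l]),
            q,
            ".",
            ".",
            "GT:DP",
        ]
        col = gm.calls[:, l]
        dcol = depth[:, l] if depth is not None else np.zeros(gm.n_samples, dtype=int)
        fields.extend(f"{_GT_CODE[int(c)]}:{int(d)}" for c, d in zip(col, dcol))
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# genepop

_GENEPOP_CODE = {0: "001001", 1: "001002", 2: "002002", MISSING: "000000"}


def write_genepop(gm: GenotypeMatrix, pm: PopulationMap, path, title: str = "holopop export") -> None:
    """Write a genepop 4.x file: 3-digit allele codes, allele 1=REF, 2=ALT."""
    labels = pm.labels_for(gm.samples)  # raises on unmapped sample
    pops = pm.populations(gm.samples)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for lid in gm.locus_ids:
            fh.write(lid + "\n")
        for pop in pops:
            fh.write("Pop\n")
            for i, sample in enumerate(gm.samples):
                if labels[i] != pop:
                    continue
                codes = " ".join(_GENEPOP_CODE[int(c)] for c in gm.calls[i])
                fh.write(f"{sample} ,  {codes}\n")


_CODE_TO_CALL = {v: k for k, v in _GENEPOP_CODE.items()}


def read_genepop(path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a genepop file written by :func:`write_genepop`.

    Returns the matrix and the per-sample population labels (one per row,
    in file order). Only the 3-digit two-allele dialect is supported.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise DataError("genepop file too short")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].split(","):
            if name.strip():
                loci.append(name.strip())
        i += 1
    samples, rows, pop_labels = [], [], []
    pop_idx = -1
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        if not ln.strip():
            continue
        if "," not in ln:
            raise DataError(f"malformed genepop row: {ln!r}")
        name, genos = ln.split(",", 1)
        codes = genos.split()
        if len(codes) != len(loci):
            raise DataError(
                f"sample {name.strip()!r} has {len(codes)} genotypes, expected {len(loci)}"
            )
        row = []
        for code in codes:
            if code not in _CODE_TO_CALL:
                raise DataError(f"unsupported genepop code {code!r}")
            row.append(_CODE_TO_CALL[code])
        samples.append(name.strip())
        rows.append(row)
        pop_labels.append(f"pop{pop_idx}")
    contigs, positions = [], []
    for lid in loci:
        contig, _, pos = lid.rpartition("_")
        contigs.append(contig or lid)
        positions.append(int(pos) if pos.isdigit() else 0)
    return (
        GenotypeMatrix(
            samples=samples,
            contigs=np.array(contigs, dtype=object),
            positions=np.array(positions),
            ref=np.array(["A"] * len(loci), dtype=object),
            alt=np.array(["T"] * len(loci), dtype=object),
            calls=np.array(rows, dtype=np.int8),
        ),
        pop_labels,
    )
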