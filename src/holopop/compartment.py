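"""Classify reference contigs as host, symbiont, removed, or unassigned.

Rules, applied in order per contig:

1. rRNA filter: drop if any LSU/SSU hit covers >= 78% of the contig over
   at least 100 bp.
2. Length filter: drop contigs of 500 bp or less (strictly greater than
   500 bp are kept).
3. Compartment assignment from four BLAST databases (dirty/clean coral,
   dirty/clean symbiont): a qualifying hit has alignment length > 100 bp
   and identity >= 60%. A contig qualifying for both a coral and a
   symbiont database (in any combination, including the clean-database
   conflict removals) is dropped as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .formats import GenotypeMatrix

CORAL_DBS = frozenset({"dirty_coral", "clean_coral"})
SYM_DBS = frozenset({"dirty_sym", "clean_sym"})
RRNA_DBS = frozenset({"rRNA_LSU", "rRNA_SSU"})
KNOWN_DBS = CORAL_DBS | SYM_DBS | RRNA_DBS

LABELS = (
    "host",
    "symbiont",
    "ambiguous_removed",
    "rRNA_removed",
    "too_short",
    "unassigned",
)

__all__ = [
    "BlastHit",
    "read_blast_table",
    "filter_rrna",
    "filter_length",
    "assign_contig",
    "assign_all",
    "split_vcf_by_compartment",
]


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    pct_identity: float
    align_length: int
    database: str
    evalue: float = 0.0

    def __post_init__(self):
        if self.database not in KNOWN_DBS:
            raise DataError(f"unknown database tag {self.database!r}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise DataError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.align_length < 0:
            raise DataError("negative alignment length")


def read_blast_table(path, database: str) -> list[BlastHit]:
    """Read an outfmt-6-style table (qseqid sseqid pident length evalue)."""
    if database not in KNOWN_DBS:
        raise DataError(f"unknown database tag {database!r}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3, 4],
            names=["qseqid", "sseqid", "pident", "length", "evalue"],
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        BlastHit(
            query=str(r.qseqid),
            subject=str(r.sseqid),
            pct_identity=float(r.pident),
            align_length=int(r.length),
            database=database,
            evalue=float(r.evalue),
        )
        for r in df.itertuples()
    ]


def filter_rrna(
    contig_length: int,
    hits: list[BlastHit],
    min_align: int = 100,
    min_coverage: float = 0.78,
) -> bool:
    """True iff the contig is rRNA contamination and must be removed."""
    if contig_length <= 0:
        raise DataError("contig length must be positive")
    for h in hits:
        if h.database not in RRNA_DBS:
            continue
        if h.align_length >= min_align and h.align_length / contig_length >= min_coverage:
            return True
    return False


def filter_length(contig_length: int, min_length: int = 500) -> bool:
    """True iff the contig passes the length filter (> min_length, strict)."""
    if contig_length <= 0:
        raise DataError("contig length must be positive")
    return contig_length > min_length


def _qualifies(hit: BlastHit, min_overlap: int, min_identity: float, strict_overlap: bool) -> bool:
    long_enough = (
        hit.align_length > min_overlap if strict_overlap else hit.align_length >= min_overlap
    )
    return long_enough and hit.pct_identity >= min_identity


def assign_contig(
    hits: list[BlastHit],
    min_overlap: int = 100,
    min_identity: float = 60.0,
    strict_overlap: bool = True,
) -> tuple[str, str]:
    """Assign one contig (already past rRNA/length filters) to a compartment.

    Returns ``(label, reason)``. Order of ``hits`` never matters.
    """
    coral_q = sym_q = clean_coral_q = clean_sym_q = False
    for h in hits:
        if h.database in RRNA_DBS:
            continue
        if h.database not in KNOWN_DBS:
            raise DataError(f"unknown database tag {h.database!r}")
        if not _qualifies(h, min_overlap, min_identity, strict_overlap):
            continue
        if h.database in CORAL_DBS:
            coral_q = True
            clean_coral_q = clean_coral_q or h.database == "clean_coral"
        else:
            sym_q = True
            clean_sym_q = clean_sym_q or h.database == "clean_sym"
    if coral_q and sym_q:
        if clean_sym_q and not clean_coral_q:
            return "ambiguous_removed", "host candidate with qualifying clean_sym hit"
        if clean_coral_q and not clean_sym_q:
            return "ambiguous_removed", "symbiont candidate with qualifying clean_coral hit"
        return "ambiguous_removed", "qualifies as both coral and symbiont"
    if coral_q:
        return "host", "qualifying coral hit, no symbiont conflict"
    if sym_q:
        return "symbiont", "qualifying symbiont hit, no coral conflict"
    return "unassigned", "no qualifying hit"


def assign_all(
    contig_lengths: dict[str, int],
    hits: list[BlastHit],
    min_length: int = 500,
    min_overlap: int = 100,
    min_identity: float = 60.0,
) -> pd.DataFrame:
    """Classify every contig; returns a frame (contig, label, reason).

    Each contig gets exactly one label; the labels partition the set.
    """
    by_contig: dict[str, list[BlastHit]] = {c: [] for c in contig_lengths}
    for h in hits:
        by_contig.setdefault(h.query, []).append(h)
    rows = []
    for contig, length in contig_lengths.items():
        chits = by_contig.get(contig, [])
        if filter_rrna(length, chits):
            rows.append((contig, "rRNA_removed", "rRNA database hit >=78% over >=100 bp"))
        elif not filter_length(length, min_length):
            rows.append((contig, "too_short", f"length {length} <= {min_length} bp"))
        else:
            label, reason = assign_contig(
                chits, min_overlap=min_overlap, min_identity=min_identity
            )
            rows.append((contig, label, reason))
    return pd.DataFrame(rows, columns=["contig", "label", "reason"])


def write_assignment(assign: pd.DataFrame, path) -> None:
    assign.to_csv(path, sep="\t", index=False)


def read_assignment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    if not {"contig", "label"}.issubset(df.columns):
        raise DataError("assignment table needs columns: contig, label")
    return df


def split_vcf_by_compartment(
    gm: GenotypeMatrix, assign: pd.DataFrame
) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, int]]:
    """Partition variants into host and symbiont matrices by contig label.

    Variants on removed/unassigned contigs are dropped; the returned counts
    dict records how many variants fell in each label class. Every variant
    CHROM must be present in the assignment.
    """
    label_of = dict(zip(assign["contig"], assign["label"]))
    unknown = sorted({c for c in gm.contigs if c not in label_of})
    if unknown:
        raise DataError(
            f"{len(unknown)} VCF contigs absent from assignment, e.g. {unknown[:5]}"
        )
    labels = np.array([label_of[c] for c in gm.contigs], dtype=object)
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    host = gm.take_loci(labels == "host")
    sym = gm.take_loci(labels == "symbiont")
    return host, sym, counts
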