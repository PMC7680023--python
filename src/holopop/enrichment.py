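"""Fisher's-exact GO enrichment of outlier-bearing genes.

Each gene (contig) in the universe gets a binary outlier indicator; per GO
term a 2x2 table (in-term x outlier-bearing) is tested one-sided for
enrichment. Benjamini-Hochberg adjustment is the default; GO-graph
ancestor propagation is deliberately not performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .exceptions import DataError

_GO_RE = re.compile(r"^GO:\d{7}$")

__all__ = ["GoAnnotation", "fisher_enrichment", "benjamini_hochberg"]


@dataclass
class GoAnnotation:
    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for gene, terms in self.gene_terms.items():
            bad = [t for t in terms if not _GO_RE.match(t)]
            if bad:
                raise DataError(f"invalid GO ids for {gene!r}: {bad[:3]}")

    @classmethod
    def read_tsv(cls, path) -> "GoAnnotation":
        """Read `contig<TAB>GO:NNNNNNN;GO:...` rows (no header)."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln.strip():
                    continue
                gene, _, terms = ln.partition("\t")
                termset = {t.strip() for t in terms.split(";") if t.strip()}
                mapping.setdefault(gene, set()).update(termset)
        return cls(mapping)

    def genes_for_term(self, term: str, universe: set[str]) -> set[str]:
        return {g for g in universe if term in self.gene_terms.get(g, ())}

    def terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.gene_terms.values():
            out |= terms
        return out


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone in the raw p)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def fisher_enrichment(
    outlier_genes: set[str],
    universe: set[str],
    annot: GoAnnotation,
    alpha: float = 0.05,
    correction: str = "BH",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each GO term among outlier genes.

    Returns a frame with per-term counts, the ``k/K`` fraction of
    outlier-bearing over annotated genes, raw p, and (optionally)
    BH-adjusted p with a significance flag at ``alpha``. Terms annotating
    no universe gene are skipped.
    """
    if correction not in ("none", "BH"):
        raise DataError(f"unknown correction {correction!r}")
    if not outlier_genes <= universe:
        raise DataError("outlier_genes must be a subset of the universe")
    n_univ = len(universe)
    n_out = len(outlier_genes)
    rows = []
    for term in sorted(annot.terms()):
        in_term = annot.genes_for_term(term, universe)
        K = len(in_term)
        if K == 0:
            continue
        k = len(in_term & outlier_genes)
        table = [[k, K - k], [n_out - k, (n_univ - K) - (n_out - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "namespace": annot.term_namespaces.get(term, ""),
                "n_outlier_in_term": k,
                "n_in_term": K,
                "n_outlier": n_out,
                "n_universe": n_univ,
                "fraction": f"{k}/{K}",
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if correction == "BH":
        df["p_adj"] = benjamini_hochberg(list(df["p"]))
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = df["p"]
        df["significant"] = df["p"] < alpha
    return df.sort_values("p", kind="stable").reset_index(drop=True)
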