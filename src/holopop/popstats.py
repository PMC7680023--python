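"""AMOVA-style F-statistics, permutation tests and diversity measures.

The differentiation estimator is the Weir-Cockerham variance-component
Fst: per-locus among-population (a), among-individual (b) and
within-individual (c) components, combined across loci as a ratio of sums
Fst = sum(a) / sum(a + b + c). Permutation tests shuffle individuals among
populations (sizes preserved) and use the standard add-one p-value
p = (1 + #{perm >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "global_fst",
    "permutation_test",
    "pairwise_fst",
    "heterozygosity",
    "DifferentiationResult",
    "DiversityResult",
]


def _group_matrix(labels: np.ndarray, pops: list[str]) -> np.ndarray:
    return np.stack([(labels == p).astype(np.float64) for p in pops])


def _wc_components(n, s_alt, s_het):
    """Per-locus Weir-Cockerham components from per-pop summaries.

    All inputs have shape (..., r, L): genotyped counts, alt-allele sums
    (in allele copies), heterozygote counts. Returns (a, b, c), each
    (..., L); loci without >= 2 populations of >= 2 average individuals
    contribute zeros.
    """
    present = n > 0
    r = present.sum(axis=-2)
    N = n.sum(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = N / r
        p = np.where(present, s_alt / np.maximum(2 * n, 1), 0.0)
        nc = (N - (n**2).sum(axis=-2) / np.maximum(N, 1)) / np.maximum(r - 1, 1)
        pbar = s_alt.sum(axis=-2) / np.maximum(2 * N, 1)
        s2 = (n * (p - pbar[..., None, :]) ** 2 * present).sum(axis=-2) / (
            np.maximum(r - 1, 1) * nbar
        )
        hbar = s_het.sum(axis=-2) / np.maximum(N, 1)
        inner = pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / np.maximum(r, 1) * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = (r >= 2) & (nbar > 1.0) & (nc > 0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    return a, b, c


def _pop_summaries(calls: np.ndarray, group: np.ndarray):
    """Group sums: genotyped counts, alt sums, het counts; group is
    (..., r, n_samples), calls is (n_samples, L)."""
    valid = (calls != MISSING).astype(np.float64)
    alt = np.where(calls != MISSING, calls, 0).astype(np.float64)
    het = ((calls == 1)).astype(np.float64)
    n = group @ valid
    s_alt = group @ alt
    s_het = group @ het
    return n, s_alt, s_het


def _fst_from_summaries(n, s_alt, s_het):
    a, b, c = _wc_components(n, s_alt, s_het)
    num = a.sum(axis=-1)
    den = (a + b + c).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan)


def global_fst(gm: GenotypeMatrix, pm: PopulationMap) -> float:
    """Multi-locus Weir-Cockerham Fst (ratio of summed components).

    Returns NaN when every locus is monomorphic (undefined denominator).
    May be slightly negative for undifferentiated data.
    """
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    if len(pops) < 2:
        raise DataError("need at least two populations")
    group = _group_matrix(labels, pops)
    n, s_alt, s_het = _pop_summaries(gm.calls, group)
    return float(_fst_from_summaries(n, s_alt, s_het))


def permutation_test(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int = 0,
    chunk: int = 250,
) -> tuple[float, float]:
    """Permute individuals among populations; returns (observed Fst, p).

    p = (1 + #{permuted Fst >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    group = _group_matrix(labels, pops)
    n, s_alt, s_het = _pop_summaries(gm.calls, group)
    obs = float(_fst_from_summaries(n, s_alt, s_het))
    if np.isnan(obs):
        return obs, np.nan
    rng = np.random.default_rng(seed)
    n_samples = gm.n_samples
    count_ge = 0
    valid = (gm.calls != MISSING).astype(np.float64)
    alt = np.where(gm.calls != MISSING, gm.calls, 0).astype(np.float64)
    het = (gm.calls == 1).astype(np.float64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(n_samples) for _ in range(m)])
        pg = group[:, perms]                       # (r, m, n)
        pg = np.swapaxes(pg, 0, 1)                 # (m, r, n)
        flat = pg.reshape(m * len(pops), n_samples)
        pn = (flat @ valid).reshape(m, len(pops), -1)
        ps_alt = (flat @ alt).reshape(m, len(pops), -1)
        ps_het = (flat @ het).reshape(m, len(pops), -1)
        fsts = _fst_from_summaries(pn, ps_alt, ps_het)
        count_ge += int(np.sum(fsts >= obs - 1e-12))
        done += m
    p = (1 + count_ge) / (n_perm + 1)
    return obs, float(p)


@dataclass
class DifferentiationResult:
    locus_set: str
    fst_global: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write_tsv(self, path) -> None:
        df = self.pairwise.copy()
        df.to_csv(path, sep="\t", index=False)


def pairwise_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int = 0,
    locus_set: str = "all",
) -> DifferentiationResult:
    """Global and per-pair Fst with permutation p-values.

    Pairs where either population has < 2 individuals are skipped.
    """
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    g_fst, g_p = permutation_test(gm, pm, n_perm=n_perm, seed=seed)
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pa, pb = pops[i], pops[j]
            mask = (labels == pa) | (labels == pb)
            if (labels == pa).sum() < 2 or (labels == pb).sum() < 2:
                continue
            sub = gm.take_samples(np.flatnonzero(mask))
            fst, p = permutation_test(sub, pm, n_perm=n_perm, seed=seed + 17 * (i * len(pops) + j))
            rows.append(
                {
                    "pop_a": pa,
                    "pop_b": pb,
                    "fst": fst,
                    "p_value": p,
                    "significant": bool(p < 0.05) if not np.isnan(p) else False,
                }
            )
    return DifferentiationResult(
        locus_set=locus_set,
        fst_global=g_fst,
        p_value=g_p,
        n_permutations=n_perm,
        pairwise=pd.DataFrame(rows),
    )


@dataclass
class DiversityResult:
    table: pd.DataFrame  # population, Ho, Hs, n_loci

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def heterozygosity(gm: GenotypeMatrix, pm: PopulationMap) -> DiversityResult:
    """Per-population observed (Ho) and unbiased expected (Hs)
    heterozygosity, averaged over loci.

    Per locus: Ho = het / genotyped; Hs uses Nei's small-sample
    correction Hs = n/(n-1) * (1 - sum p^2 - Ho/(2n)) with n the number of
    genotyped individuals. Loci with < 2 genotyped individuals in a
    population are skipped for that population.
    """
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    rows = []
    for pop in pops:
        sub = gm.calls[labels == pop]
        valid = sub != MISSING
        n = valid.sum(axis=0).astype(float)
        ok = n >= 2
        het = ((sub == 1) & valid).sum(axis=0)
        alt = np.where(valid, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
            p = alt / np.maximum(2 * n, 1)
            sum_p2 = p**2 + (1 - p) ** 2
            hs = (n / np.maximum(n - 1, 1)) * (1 - sum_p2 - ho / np.maximum(2 * n, 1))
        rows.append(
            {
                "population": pop,
                "Ho": float(np.nanmean(np.where(ok, ho, np.nan))) if ok.any() else np.nan,
                "Hs": float(np.nanmean(np.where(ok, hs, np.nan))) if ok.any() else np.nan,
                "n_loci": int(ok.sum()),
            }
        )
    return DiversityResult(pd.DataFrame(rows))
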