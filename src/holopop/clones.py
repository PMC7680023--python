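"""Multilocus clone identification via allelic-difference distances.

Distances between two individuals over their shared non-missing loci:

- ``hamming``: total allelic differences, sum |a_i - a_j| counting allele
  copies (hom-ref vs het = 1, hom-ref vs hom-alt = 2);
- ``prevosti``: hamming divided by twice the shared-locus count;
- ``manhattan``: sum of absolute genotype-code differences.

Clones are flagged from the normalized pairwise distance (fraction of the
maximum possible allelic differences) against a declared threshold, and
the complete-linkage dendrogram is exported as newick for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .exceptions import DataError
from .formats import MISSING, GenotypeMatrix

METRICS = ("hamming", "prevosti", "manhattan")

__all__ = [
    "DistanceMatrix",
    "allelic_distance",
    "detect_clones",
    "metric_concordance",
    "CloneReport",
]


@dataclass
class DistanceMatrix:
    samples: list[str]
    metric: str
    values: np.ndarray           # raw distances
    shared_loci: np.ndarray      # pairwise shared non-missing locus counts

    def normalized(self) -> np.ndarray:
        """Distance as a fraction of the maximum possible allelic
        differences over the shared loci of each pair."""
        if self.metric == "prevosti":
            return self.values
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.values / (2.0 * self.shared_loci)


def allelic_distance(gm: GenotypeMatrix, metric: str = "hamming") -> DistanceMatrix:
    """Pairwise distance over shared non-missing loci."""
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}; choose from {METRICS}")
    if gm.n_samples < 2:
        raise DataError("need at least two samples")
    calls = gm.calls.astype(np.float64)
    valid = gm.calls != MISSING
    callsv = np.where(valid, calls, 0.0)
    n = gm.n_samples
    shared = valid.astype(np.float64) @ valid.T.astype(np.float64)
    pair_zero = shared == 0
    np.fill_diagonal(pair_zero, False)
    if pair_zero.any():
        i, j = np.argwhere(pair_zero)[0]
        raise DataError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no genotyped loci"
        )
    # |a_i - a_j| summed over shared loci; identical for hamming and
    # manhattan on alt-count codes, kept as separate metrics for the
    # robustness-check surface.
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(callsv[i] - callsv)          # (n, L)
        both = valid[i] & valid                    # (n, L)
        dist[i] = (diff * both).sum(axis=1)
    if metric == "prevosti":
        values = dist / (2.0 * shared)
        np.fill_diagonal(values, 0.0)
    else:
        values = dist
    return DistanceMatrix(list(gm.samples), metric, values, shared.astype(np.int64))


@dataclass
class CloneReport:
    metric: str
    threshold: float
    pairs: list[tuple[str, str, float]]  # (sample_a, sample_b, normalized distance)
    removed: list[str]
    retained: dict[str, str] = field(default_factory=dict)  # group rep -> kept member
    newick: str = ""

    @property
    def flagged_sets(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["sample_a", "sample_b", "normalized_distance"]
        )


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def detect_clones(
    dm: DistanceMatrix,
    threshold: float = 0.05,
    seed: int = 0,
) -> CloneReport:
    """Flag clone pairs below a normalized-distance threshold.

    Complete-linkage agglomerative clustering groups ramets; in each clone
    group one member is retained (seeded random choice, mirroring the
    study's random removal) and the rest are listed for removal.
    """
    if threshold <= 0:
        raise DataError("threshold must be positive")
    norm = dm.normalized()
    n = len(dm.samples)
    condensed = norm[np.triu_indices(n, k=1)]
    link = hierarchy.linkage(condensed, method="complete")
    newick = _to_newick(hierarchy.to_tree(link), dm.samples) + ";"
    groups = hierarchy.fcluster(link, t=threshold, criterion="distance")
    rng = np.random.default_rng(seed)
    pairs, removed, retained = [], [], {}
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if len(members) < 2:
            continue
        for ii, i in enumerate(members):
            for j in members[ii + 1:]:
                if norm[i, j] < threshold:
                    pairs.append((dm.samples[i], dm.samples[j], float(norm[i, j])))
        keep = members[int(rng.integers(len(members)))]
        retained[dm.samples[members[0]]] = dm.samples[keep]
        removed.extend(dm.samples[i] for i in members if i != keep)
    return CloneReport(
        metric=dm.metric,
        threshold=threshold,
        pairs=sorted(pairs),
        removed=sorted(removed),
        retained=retained,
        newick=newick,
    )


def metric_concordance(
    gm: GenotypeMatrix, threshold: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Run clone detection under all three metrics and compare flagged sets.

    Returns one row per metric with the flagged pairs, plus a
    ``concordant`` flag (same pair set under every metric) and the pairs
    that are not shared by all metrics.
    """
    reports = {m: detect_clones(allelic_distance(gm, m), threshold, seed) for m in METRICS}
    sets = {m: r.flagged_sets for m, r in reports.items()}
    common = set.intersection(*sets.values()) if sets else set()
    union = set.union(*sets.values()) if sets else set()
    concordant = all(s == common for s in sets.values())
    rows = []
    for m, r in reports.items():
        rows.append(
            {
                "metric": m,
                "n_pairs": len(r.flagged_sets),
                "pairs": ";".join(
                    "|".join(sorted(p)) for p in sorted(r.flagged_sets, key=sorted)
                ),
                "concordant": concordant,
                "discordant_pairs": ";".join(
                    "|".join(sorted(p)) for p in sorted(union - common, key=sorted)
                ),
            }
        )
    return pd.DataFrame(rows)
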