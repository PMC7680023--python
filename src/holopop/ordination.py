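"""Genotype PCA with mean imputation of missing calls."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = ["PCAResult", "pca", "plot_pca"]


@dataclass
class PCAResult:
    samples: list[str]
    coordinates: np.ndarray   # (n_samples, n_components)
    eigenvalues: np.ndarray   # descending, non-negative
    pct_variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=self.samples,
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.index.name = "sample"
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pca(gm: GenotypeMatrix, scaling: str = "center") -> PCAResult:
    """PCA of the genotype matrix.

    Missing calls are imputed with the per-locus mean; columns are centered
    and, with ``scaling='center_scale'``, divided by sqrt(p(1-p)) of the
    imputed allele frequency. Deterministic up to component sign.
    """
    if scaling not in ("center", "center_scale"):
        raise DataError(f"unknown scaling {scaling!r}")
    if gm.n_samples < 2 or gm.n_loci < 1:
        raise DataError("need >= 2 samples and >= 1 locus")
    X = gm.calls.astype(float)
    X[X == MISSING] = np.nan
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} all-missing loci")
        X = X[:, ~all_missing]
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - col_mean
    if scaling == "center_scale":
        p = col_mean / 2.0
        sd = np.sqrt(p * (1 - p))
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    n = Xc.shape[0]
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    coords = u * s
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return PCAResult(
        samples=list(gm.samples),
        coordinates=coords,
        eigenvalues=eig,
        pct_variance=pct,
    )


def plot_pca(res: PCAResult, pm: PopulationMap, path, components=(0, 1)) -> None:
    """PC scatter colored by population, axis labels carrying % variance."""
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "holopop"  # deterministic ids
    import matplotlib.pyplot as plt

    labels = pm.labels_for(res.samples)  # raises naming any unmapped sample
    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in pm.populations(res.samples):
        mask = labels == pop
        ax.scatter(
            res.coordinates[mask, i],
            res.coordinates[mask, j],
            label=pop,
            alpha=0.8,
        )
    ax.set_xlabel(f"PC{i + 1} ({res.pct_variance[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({res.pct_variance[j]:.1f}%)")
    ax.legend(frameon=False)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    if str(path).endswith(".svg"):
        fig.savefig(path, metadata={"Date": None})  # byte-reproducible
    else:
        fig.savefig(path)
    plt.close(fig)
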