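"""Covariance-corrected differentiation scan with simulated-null FDR.

Per locus, population allele frequencies are standardized against their
cross-population mean pi: z_j = (p_j - pi) / sqrt(pi (1 - pi)). The scaled
covariance Omega of these residuals captures shared drift; the per-locus
score XtX = z' Omega^-1 z is an Fst analog corrected for that shared
structure. Significance is calibrated with pseudo-observed data (POD):
loci simulated from the fitted null, scored the same way, and the
empirical (1 - fdr) quantile of their scores used as the outlier
threshold (default fdr = 0.5%).

This is a method-of-moments implementation of the statistic (not the
original MCMC machinery): same mathematical target, deterministic and
fast enough for desk-scale calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ModelError
from .formats import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "CovarianceModel",
    "OutlierScores",
    "estimate_omega",
    "xtx",
    "pod_threshold_from_scores",
    "pod_calibrate",
    "classify",
]


@dataclass
class CovarianceModel:
    omega: np.ndarray
    pop_labels: list[str]
    n_loci_used: int
    pi_hat: np.ndarray  # per-usable-locus mean frequencies
    sample_sizes: dict[str, int] = field(default_factory=dict)
    trim_fraction: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "omega": self.omega.tolist(),
                    "pop_labels": self.pop_labels,
                    "n_loci_used": self.n_loci_used,
                    "sample_sizes": self.sample_sizes,
                },
                fh,
                indent=2,
            )


@dataclass
class OutlierScores:
    locus_ids: np.ndarray
    xtx: np.ndarray
    flagged: np.ndarray            # loci where the score is degenerate (pi in {0,1})
    pod_threshold: float | None = None
    is_outlier: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"locus_id": self.locus_ids, "xtx": self.xtx})
        if self.is_outlier is not None:
            df["class"] = np.where(self.is_outlier, "high_outlier", "neutral")
        df["degenerate"] = self.flagged
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pop_freqs(gm: GenotypeMatrix, pm: PopulationMap):
    """Per-population sample allele frequencies, (r, L), plus genotyped
    counts; populations with no data at a locus get NaN frequency."""
    labels = pm.labels_for(gm.samples)
    pops = pm.populations(gm.samples)
    if len(pops) < 2:
        raise DataError("need at least two populations")
    freqs = np.empty((len(pops), gm.n_loci))
    counts = np.empty((len(pops), gm.n_loci))
    for j, pop in enumerate(pops):
        sub = gm.calls[labels == pop]
        valid = sub != MISSING
        n = valid.sum(axis=0)
        alt = np.where(valid, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[j] = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        counts[j] = n
    return pops, freqs, counts


def _standardize(freqs: np.ndarray):
    """Residuals z = (p - pi)/sqrt(pi(1-pi)); returns (z, pi, usable mask).

    NaN population frequencies (no data) contribute zero residual.
    Loci with pi in {0, 1} are unusable (zero denominator).
    """
    pi = np.nanmean(freqs, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(pi * (1 - pi))
        z = (freqs - pi) / denom
    z = np.where(np.isnan(z), 0.0, z)
    usable = (pi > 0) & (pi < 1) & ~np.isnan(pi)
    return z, pi, usable


def estimate_omega(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    ridge: float = 1e-6,
    trim_fraction: float = 0.025,
) -> CovarianceModel:
    """Estimate the scaled covariance of population allele frequencies.

    Omega = (1/L) sum_l z_l z_l' over usable loci, with a small ridge on
    the diagonal. Loci monomorphic across all populations are skipped.

    With ``trim_fraction > 0`` a second pass drops the top-scoring
    fraction of loci (by the quadratic form under the first-pass Omega)
    before refitting, so strongly differentiated loci do not contaminate
    the null covariance. Set ``trim_fraction=0`` for the plain one-pass
    estimator. The same setting must be used when scoring pseudo-observed
    data, which :func:`pod_calibrate` does automatically.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise DataError("trim_fraction must be in [0, 0.5)")
    pops, freqs, counts = _pop_freqs(gm, pm)
    z, pi, usable = _standardize(freqs)
    if usable.sum() < 2:
        raise ModelError("fewer than 2 usable (polymorphic) loci")

    def fit(mask):
        zu = z[:, mask]
        return (zu @ zu.T) / zu.shape[1] + ridge * np.eye(len(pops))

    omega = fit(usable)
    if trim_fraction > 0 and usable.sum() >= 40:
        scores = np.einsum("jl,jk,kl->l", z, np.linalg.inv(omega), z)
        cut = np.quantile(scores[usable], 1.0 - trim_fraction)
        trimmed = usable & (scores <= cut)
        if trimmed.sum() >= 2:
            omega = fit(trimmed)
    labels = pm.labels_for(gm.samples)
    sizes = {p: int((labels == p).sum()) for p in pops}
    return CovarianceModel(
        omega=omega,
        pop_labels=list(pops),
        n_loci_used=int(usable.sum()),
        pi_hat=pi[usable],
        sample_sizes=sizes,
        trim_fraction=trim_fraction,
    )


def xtx(gm: GenotypeMatrix, pm: PopulationMap, model: CovarianceModel) -> OutlierScores:
    """Per-locus XtX = z' Omega^-1 z; degenerate loci scored 0 and flagged."""
    pops, freqs, _ = _pop_freqs(gm, pm)
    if pops != model.pop_labels:
        raise DataError(
            f"population mismatch: data {pops} vs model {model.pop_labels}"
        )
    z, pi, usable = _standardize(freqs)
    try:
        omega_inv = np.linalg.inv(model.omega)
    except np.linalg.LinAlgError as exc:
        raise ModelError("omega is singular even after ridge") from exc
    scores = np.einsum("jl,jk,kl->l", z, omega_inv, z)
    scores = np.where(usable, scores, 0.0)
    return OutlierScores(
        locus_ids=gm.locus_ids,
        xtx=scores,
        flagged=~usable,
    )


def pod_threshold_from_scores(pod_scores: np.ndarray, fdr: float) -> float:
    """Empirical (1 - fdr) quantile of POD scores, linear interpolation."""
    if not 0 < fdr <= 1:
        raise DataError("fdr must be in (0, 1]")
    return float(np.quantile(np.asarray(pod_scores, dtype=float), 1.0 - fdr, method="linear"))


def pod_calibrate(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    model: CovarianceModel,
    n_pod_loci: int = 10_000,
    fdr: float = 0.005,
    seed: int = 0,
    refit_omega: bool = True,
) -> tuple[float, np.ndarray]:
    """Simulate POD from the fitted model and return the score threshold.

    The POD matrix is scored exactly like the observed data (Omega
    re-estimated on the POD itself by default, mirroring the analysis of
    the real data); the threshold is the empirical (1 - fdr) quantile
    (linear interpolation) of the POD scores. Returns
    (threshold, pod_scores).
    """
    from .simdata import pod_population_map, simulate_pod

    if not 0 < fdr <= 1:
        raise DataError("fdr must be in (0, 1]")
    pod = simulate_pod(
        omega=model.omega,
        pi_dist=model.pi_hat,
        sample_sizes=model.sample_sizes,
        n_loci=n_pod_loci,
        seed=seed,
    )
    pod_pm = pod_population_map(model.sample_sizes)
    pod_model = estimate_omega(
        pod, pod_pm, trim_fraction=model.trim_fraction
    ) if refit_omega else CovarianceModel(
        omega=model.omega,
        pop_labels=pod_pm.populations(pod.samples),
        n_loci_used=model.n_loci_used,
        pi_hat=model.pi_hat,
        sample_sizes=model.sample_sizes,
    )
    pod_scores = xtx(pod, pod_pm, pod_model)
    usable = ~pod_scores.flagged
    threshold = pod_threshold_from_scores(pod_scores.xtx[usable], fdr)
    return threshold, pod_scores.xtx[usable]


def classify(scores: OutlierScores, threshold: float) -> OutlierScores:
    """Strict exceedance: XtX > threshold => high_outlier."""
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    return OutlierScores(
        locus_ids=scores.locus_ids,
        xtx=scores.xtx,
        flagged=scores.flagged,
        pod_threshold=threshold,
        is_outlier=scores.xtx > threshold,
    )
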