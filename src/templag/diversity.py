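"""Alpha-diversity indices and Bray-Curtis beta-diversity with PCoA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from templag.io_profiles import AbundanceTable, ValidationError

__all__ = [
    "DiversityProfile",
    "OrdinationResult",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
]


@dataclass
class DiversityProfile:
    """Per-sample alpha diversity: observed species, Shannon (nats),
    Simpson (1 - sum p^2) and Pielou's evenness."""

    table: pd.DataFrame  # samples x (observed, shannon, simpson, pielou)

    def __post_init__(self) -> None:
        t = self.table
        if (t["observed"] < 1).any():
            raise ValidationError("non-empty samples must have observed >= 1")
        if ((t["pielou"] < 0) | (t["pielou"] > 1 + 1e-12)).any():
            raise ValidationError("pielou outside [0, 1]")


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes (PCo1, PCo2, ...)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValidationError("eigenvalues must be non-increasing")
        centers = self.coordinates.to_numpy().mean(axis=0)
        if np.any(np.abs(centers) > 1e-8):
            raise ValidationError("coordinates must be column-centered")


def alpha_diversity(table: AbundanceTable) -> DiversityProfile:
    """Observed species, Shannon, Simpson and Pielou per sample.

    Abundances are renormalized to sum to one over the retained
    features before computing the indices. Pielou is H / ln(observed),
    defined as 0 for single-species samples.
    """
    values = table.data.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = table.data.columns[totals <= 0].tolist()
        raise ValidationError(f"all-zero samples: {bad}")
    p = values / totals
    observed = (values > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (p**2).sum(axis=0)
    log_obs = np.log(observed.astype(float))
    pielou = np.where(observed > 1, shannon / np.where(log_obs > 0, log_obs, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "observed": observed,
            "shannon": shannon,
            "simpson": simpson,
            "pielou": np.clip(pielou, 0.0, 1.0),
        },
        index=table.data.columns,
    )
    return DiversityProfile(out)


def bray_curtis(table: AbundanceTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples.

    d(a, b) = sum |a_i - b_i| / sum (a_i + b_i); 0 on the diagonal and
    in [0, 1] for non-negative data.
    """
    values = table.data.to_numpy(dtype=float).T  # samples x features
    if (values < 0).any():
        raise ValidationError("negative abundances")
    totals = values.sum(axis=1)
    if (totals == 0).sum() >= 2:
        raise ValidationError("Bray-Curtis undefined between all-zero samples")
    # |a-b| summed pairwise; vectorized over sample pairs
    n = values.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(values[i] - values[i + 1 :]).sum(axis=1)
        denom = totals[i] + totals[i + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, diff / denom, 0.0)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    ids = table.data.columns
    return pd.DataFrame(dist, index=ids, columns=ids)


def pcoa(distance_matrix: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Classical metric MDS of a square distance matrix.

    Double-centers the Gower matrix -0.5 * D^2 and eigendecomposes it.
    Axes are ordered by eigenvalue; negative eigenvalues are retained
    in the report but excluded from the coordinates. Axis signs are
    fixed by forcing each axis's largest-magnitude loading positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValidationError("distances must be non-negative")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    n_pos = int((eigvals > 1e-10).sum())
    k = min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        lead = np.argmax(np.abs(coords[:, j]))
        if coords[lead, j] < 0:
            coords[:, j] = -coords[:, j]
    index = (
        distance_matrix.index
        if isinstance(distance_matrix, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    labels = [f"PCo{j + 1}" for j in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=labels),
        eigenvalues=eigvals,
    )
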