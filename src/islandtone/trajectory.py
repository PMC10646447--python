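"""Phenotypic trajectory analysis for mainland-island divergence.

Each taxon's divergence is the vector from the mainland multivariate
centroid to the island centroid in wavelength space.  Vector length measures
the magnitude of divergence; pairwise angles / vector correlations measure
whether taxa diverged in similar directions (convergence).  Significance is
assessed by permuting mainland/island labels within each taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "fit_trajectories",
    "angle_and_correlation",
    "disparity",
    "permutation_pairwise",
    "pca_scores",
    "PCAResult",
]


@dataclass
class TrajectorySet:
    """Per-taxon mainland and island specimen matrices (specimens x wavelengths)."""

    data: dict[str, tuple[np.ndarray, np.ndarray]]  # taxon -> (mainland, island)
    band: str = "FULL"

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("empty trajectory set")
        ncol = None
        for taxon, (mainland, island) in self.data.items():
            mainland = np.atleast_2d(np.asarray(mainland, dtype=float))
            island = np.atleast_2d(np.asarray(island, dtype=float))
            if mainland.shape[0] < 2 or island.shape[0] < 2:
                raise ValueError(f"taxon {taxon!r}: need >= 2 specimens per group")
            if mainland.shape[1] != island.shape[1]:
                raise ValueError(f"taxon {taxon!r}: wavelength columns differ between groups")
            if ncol is None:
                ncol = mainland.shape[1]
            elif mainland.shape[1] != ncol:
                raise ValueError("taxa have different numbers of wavelength columns")
            self.data[taxon] = (mainland, island)

    @property
    def taxa(self) -> list[str]:
        return list(self.data)


def _vector(mainland: np.ndarray, island: np.ndarray) -> np.ndarray:
    return island.mean(axis=0) - mainland.mean(axis=0)


def fit_trajectories(ts: TrajectorySet) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Centroid-difference vector and Euclidean length per taxon."""
    vectors = {t: _vector(m, i) for t, (m, i) in ts.data.items()}
    table = pd.DataFrame(
        {
            "taxon": list(vectors),
            "length": [float(np.linalg.norm(v)) for v in vectors.values()],
        }
    )
    return vectors, table


def angle_and_correlation(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Angle in degrees and vector correlation (cosine) between two trajectories."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("angle undefined for a zero-length trajectory")
    corr = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(corr))), corr


def disparity(matrices: Mapping[str, np.ndarray]) -> float:
    """Mean squared distance of taxon centroids from their pooled centroid.

    Lower disparity among island taxa than mainland taxa indicates
    convergence sensu stricto.
    """
    if len(matrices) < 2:
        raise ValueError("disparity needs >= 2 taxa")
    centroids = np.vstack([np.atleast_2d(m).mean(axis=0) for m in matrices.values()])
    pooled = centroids.mean(axis=0)
    return float(np.mean(np.sum((centroids - pooled) ** 2, axis=1)))


def disparity_by_side(ts: TrajectorySet, side: str) -> float:
    idx = {"mainland": 0, "island": 1}[side]
    return disparity({t: g[idx] for t, g in ts.data.items()})


def _null_vectors(
    mainland: np.ndarray, island: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Centroid-difference vectors under within-taxon label permutation.

    Builds an (n_perm, n_specimens) weight matrix with +1/n_island on the
    permuted island positions and -1/n_mainland elsewhere, so all null
    vectors come from one matmul.  The observed arrangement is excluded from
    sampling; the p-value's +1 already accounts for it.
    """
    stacked = np.vstack([mainland, island])
    n = stacked.shape[0]
    n_isl = island.shape[0]
    observed = frozenset(range(n - n_isl, n))
    weights = np.full((n_perm, n), -1.0 / (n - n_isl))
    for b in range(n_perm):
        while True:
            pick = rng.permutation(n)[:n_isl]
            if frozenset(pick) != observed:
                break
        weights[b, pick] = 1.0 / n_isl
    return weights @ stacked


def permutation_pairwise(
    ts: TrajectorySet,
    n_perm: int = 999,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Permutation tests for trajectory lengths and pairwise orientations.

    The null permutes mainland/island labels within each taxon.  p-values use
    the count formula (#{null >= observed} + 1) / (n_perm + 1), counting the
    observed arrangement as one realisation.  Length differences are tested
    two-sided on |L_i - L_j|; orientations one-sided toward convergence
    (smaller angle than null).

    Returns ``{"lengths": per-taxon table, "pairs": per-pair table}``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    vectors, lengths = fit_trajectories(ts)
    taxa = ts.taxa
    obs_len = {t: float(np.linalg.norm(vectors[t])) for t in taxa}

    null_vecs = {
        t: _null_vectors(ts.data[t][0], ts.data[t][1], n_perm, rng) for t in taxa
    }
    null_len = {t: np.linalg.norm(null_vecs[t], axis=1) for t in taxa}

    p_len = {
        t: (np.count_nonzero(null_len[t] >= obs_len[t]) + 1) / (n_perm + 1)
        for t in taxa
    }
    lengths["p_length"] = [p_len[t] for t in taxa]

    rows = []
    for ta, tb in combinations(taxa, 2):
        angle, corr = angle_and_correlation(vectors[ta], vectors[tb])
        d_len = abs(obs_len[ta] - obs_len[tb])

        va, vb = null_vecs[ta], null_vecs[tb]
        dots = np.einsum("ij,ij->i", va, vb)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_null = dots / (null_len[ta] * null_len[tb])
        cos_null = np.clip(np.nan_to_num(cos_null, nan=0.0), -1.0, 1.0)
        ang_null = np.degrees(np.arccos(cos_null))
        d_len_null = np.abs(null_len[ta] - null_len[tb])

        p_angle = (np.count_nonzero(ang_null <= angle) + 1) / (n_perm + 1)
        p_dlen = (np.count_nonzero(d_len_null >= d_len) + 1) / (n_perm + 1)
        rows.append(
            {
                "taxon_a": ta,
                "taxon_b": tb,
                "angle_deg": angle,
                "correlation": corr,
                "length_diff": d_len,
                "p_angle": p_angle,
                "p_length_diff": p_dlen,
            }
        )
    return {"lengths": lengths, "pairs": pd.DataFrame(rows)}


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (n_wavelengths, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_scores(X: np.ndarray, n_components: int | None = None) -> PCAResult:
    """Covariance-based PCA of specimen spectra.

    Loadings are returned so sign conventions are auditable (in this system
    PC1 is achromatic brightness, PC2 contrasts short vs long wavelengths;
    signs themselves are arbitrary).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("degenerate input: zero variance everywhere")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    if n_components is None:
        n_components = len(s)
    return PCAResult(
        scores=(u * s)[:, :n_components],
        loadings=vt.T[:, :n_components],
        explained_variance_ratio=var / var.sum(),
        mean=mean,
    )
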