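"""Principal-component QC of spectral collections and automatic outlier flags.

Spectral samples that differ grossly from the rest of a measurement session
(a mis-aimed shot, a dry-leaf control, a saturated trace) separate from the
canopy cluster in the space of the first two principal components.  The
outlier rule flags a sample when its PC1 or PC2 score lies more than
``threshold_sd`` standard deviations from the per-axis mean score.

PCA here is the plain mean-centered variety: wavelength columns are
centered but *not* scaled to unit variance, since all columns share
reflectance units and scaling would inflate noisy low-signal bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpectralCollection
from .errors import DegenerateDataError, InsufficientSamplesError, UsageError

__all__ = ["PcaResult", "OutlierReport", "pca", "detect_outliers", "remove_samples"]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a spectral PCA.

    ``scores`` is samples x components, ``loadings`` wavelengths x
    components (orthonormal columns), and ``explained_variance_fraction``
    uses the total variance of the full decomposition as denominator, so
    the retained fractions sum to at most 1.
    """

    sample_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class OutlierReport:
    """Per-sample PC1/PC2 scores, z-magnitudes, and the outlier flag."""

    table: pd.DataFrame  # columns pc1_score, pc2_score, z1, z2, outlier_flag
    threshold_sd: float

    @property
    def outliers(self) -> list[str]:
        return self.table.index[self.table["outlier_flag"]].tolist()


def pca(collection: SpectralCollection, n_components: int | None = None) -> PcaResult:
    """Mean-centered PCA of the samples x wavelengths matrix via SVD.

    Sign convention: each loading vector is flipped so its largest-magnitude
    element is positive, which makes the decomposition deterministic.
    """
    if collection.n_samples < 3:
        raise InsufficientSamplesError(
            f"PCA needs at least 3 samples, got {collection.n_samples}"
        )
    if collection.n_wavelengths < 2:
        raise InsufficientSamplesError(
            f"PCA needs at least 2 wavelengths, got {collection.n_wavelengths}"
        )
    X = np.asarray(collection.values, dtype=float)
    centered = X - X.mean(axis=0)
    total_var = float((centered**2).sum())
    if total_var == 0.0:
        raise DegenerateDataError("spectral matrix has zero total variance")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    max_rank = int((s > s[0] * 1e-12).sum())
    k = max_rank if n_components is None else min(int(n_components), len(s))
    if k < 1:
        raise UsageError("n_components must be a positive integer")
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = (s**2 / (s**2).sum())[:k]
    # deterministic sign: largest-|loading| element positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(list(collection.sample_ids), scores, loadings, explained)


def detect_outliers(pca_result: PcaResult, threshold_sd: float = 3.0) -> OutlierReport:
    """Flag samples far from the score-space mean on PC1 or PC2.

    For axis k in {1, 2}: ``z_k = |score_k - mean(score_k)| / sd(score_k)``
    with the unbiased (n-1) standard deviation; a sample is flagged when
    either z exceeds ``threshold_sd``.  A zero-variance axis contributes
    z = 0, so identical samples are never flagged.
    """
    if threshold_sd <= 0:
        raise UsageError(f"threshold_sd must be positive, got {threshold_sd}")
    if pca_result.n_components < 2:
        raise UsageError("outlier detection needs at least 2 components")
    z = np.zeros((len(pca_result.sample_ids), 2))
    for axis in range(2):
        sc = pca_result.scores[:, axis]
        sd = sc.std(ddof=1)
        if sd > 0:
            z[:, axis] = np.abs(sc - sc.mean()) / sd
    flags = (z > threshold_sd).any(axis=1)
    table = pd.DataFrame(
        {
            "pc1_score": pca_result.scores[:, 0],
            "pc2_score": pca_result.scores[:, 1],
            "z1": z[:, 0],
            "z2": z[:, 1],
            "outlier_flag": flags,
        },
        index=pca_result.sample_ids,
    )
    table.index.name = "sample_id"
    return OutlierReport(table, float(threshold_sd))


def remove_samples(collection: SpectralCollection, sample_ids) -> SpectralCollection:
    """Drop the named samples from a collection (see also the method form)."""
    return collection.remove_samples(sample_ids)
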