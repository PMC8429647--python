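"""PCA-based tumor/margin discrimination.

The pooled, preprocessed spectra are decomposed by mean-centered (unscaled)
PCA.  Classification uses the PC1 score with the sign convention that the
margin class has the larger mean score; discrimination strength is the ROC
AUC of a threshold sweep on PC1, which equals the Mann-Whitney pair
statistic P(score_margin > score_tumor) + 1/2 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve, roc_auc_score

from .assignments import assign_band
from .core import MARGIN, TUMOR, Modality, SpectralDataset
from .errors import DegeneracyError, LabelError, SizeError

__all__ = [
    "PCAResult",
    "GroupSummary",
    "RocResult",
    "LoadingFeature",
    "fit_pca",
    "summarize_groups",
    "roc_auc",
    "extract_loading_features",
]


@dataclass
class PCAResult:
    """Scores, unit-norm loadings and explained-variance fractions.

    Sign convention: PC1 is oriented so the mean margin score is >= the mean
    tumor score (when both labels are present); remaining components are
    oriented so their largest-magnitude loading element is positive.
    """

    scores: np.ndarray          # (n_spectra, k)
    loadings: np.ndarray        # (k, n_wavenumbers), orthonormal rows
    explained_var: np.ndarray   # (k,) fractions, non-increasing
    mean_spectrum: np.ndarray
    wavenumbers: np.ndarray
    labels: np.ndarray

    @property
    def pc1_scores(self) -> np.ndarray:
        return self.scores[:, 0]


@dataclass
class GroupSummary:
    """Per-class mean and SD (n-1) of the PC1 score."""

    mean_tumor: float
    sd_tumor: float
    mean_margin: float
    sd_margin: float
    sd_ratio: float | None  # SD(margin)/SD(tumor); None when SD(tumor)==0

    def to_dict(self) -> dict:
        return {
            "mean_tumor": self.mean_tumor,
            "sd_tumor": self.sd_tumor,
            "mean_margin": self.mean_margin,
            "sd_margin": self.sd_margin,
            "sd_ratio": self.sd_ratio,
        }


@dataclass
class RocResult:
    """ROC threshold sweep with the margin class treated as positive."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class LoadingFeature:
    """A local extremum of a loading vector, with band assignment."""

    wavenumber: float
    sign: str               # "positive" | "negative"
    magnitude: float
    assignment: str
    description: str = ""


def fit_pca(ds: SpectralDataset, k: int = 10) -> PCAResult:
    """Mean-centered, unscaled PCA of the pooled dataset.

    Deterministic (full SVD) and sign-fixed: see :class:`PCAResult`.
    """
    n, p = ds.intensities.shape
    if not (n > k >= 1):
        raise SizeError(f"need n_spectra > k >= 1 (got n={n}, k={k})")
    X = ds.intensities
    total_var = float(np.var(X, axis=0).sum())
    scale = float(np.mean(np.abs(X))) or 1.0
    if total_var <= (1e-12 * scale) ** 2 * p:
        raise DegeneracyError("dataset has (near-)zero total variance")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    labels = ds.labels
    # orient each component: largest-|loading| element positive
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, imax] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    # PC1 overridden by the group-mean convention when both classes present
    t_mask = labels == TUMOR
    m_mask = labels == MARGIN
    if t_mask.any() and m_mask.any():
        if scores[m_mask, 0].mean() < scores[t_mask, 0].mean():
            loadings[0] = -loadings[0]
            scores[:, 0] = -scores[:, 0]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_var=pca.explained_variance_ratio_.copy(),
        mean_spectrum=pca.mean_.copy(),
        wavenumbers=ds.axis.values.copy(),
        labels=labels.copy(),
    )


def summarize_groups(p: PCAResult, labels: np.ndarray | None = None) -> GroupSummary:
    """Per-class mean/SD of PC1 scores and the margin/tumor SD ratio."""
    labels = p.labels if labels is None else np.asarray(labels)
    s = p.pc1_scores
    t = s[labels == TUMOR]
    m = s[labels == MARGIN]
    if t.size < 2 or m.size < 2:
        raise SizeError("each class needs at least 2 spectra")
    sd_t = float(np.std(t, ddof=1))
    sd_m = float(np.std(m, ddof=1))
    return GroupSummary(
        mean_tumor=float(t.mean()),
        sd_tumor=sd_t,
        mean_margin=float(m.mean()),
        sd_margin=sd_m,
        sd_ratio=(sd_m / sd_t) if sd_t > 0 else None,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC sweep on a score vector, margin positive.

    The AUC equals the Mann-Whitney statistic
    P(score_margin > score_tumor) + 1/2 P(tie); no orientation flip is
    applied, so values below 0.5 are reported as such.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == MARGIN
    if y.all() or not y.any():
        raise LabelError("both tumor and margin labels are required")
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(roc_auc_score(y, scores)),
    )


def extract_loading_features(
    p: PCAResult,
    component: int = 1,
    min_prominence: float = 0.02,
    modality: Modality | str = Modality.FTIR,
) -> list[LoadingFeature]:
    """Local extrema of a loading vector, split by sign and assigned.

    ``component`` is 1-based.  Prominence is measured on the loading (and its
    negation for negative features) with :func:`scipy.signal.find_peaks`.
    """
    if not (1 <= component <= p.loadings.shape[0]):
        raise SizeError(f"component {component} not in 1..{p.loadings.shape[0]}")
    v = p.loadings[component - 1]
    feats: list[LoadingFeature] = []
    for sign, vec in (("positive", v), ("negative", -v)):
        peaks, props = find_peaks(vec, prominence=min_prominence)
        for idx, prom in zip(peaks, props["prominences"]):
            if vec[idx] <= 0:
                continue  # extremum on the wrong side of zero
            wn = float(p.wavenumbers[idx])
            cls, desc = assign_band(wn, modality)
            feats.append(
                LoadingFeature(
                    wavenumber=wn,
                    sign=sign,
                    magnitude=float(abs(v[idx])),
                    assignment=cls,
                    description=desc,
                )
            )
    feats.sort(key=lambda f: f.wavenumber)
    return feats
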