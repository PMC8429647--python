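"""Lipid-domain quantification and filtering.

The discriminating step of the workflow: each (preprocessed, area-normalized)
spectrum is scored by the locally-baselined trapezoidal integral of the
ester carbonyl band around 1746 cm^-1.  Spectra above a fixed threshold are
lipid-rich (adipose domains of the healthy margin) and are removed before
the second-pass PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BandDefinition, ESTER_BAND, SpectralDataset, Spectrum
from .errors import RangeError, SizeError

__all__ = [
    "BandIntegralStats",
    "LipidFilterConfig",
    "band_integral",
    "band_integrals",
    "distribution_stats",
    "filter_lipid_rich",
]


@dataclass
class BandIntegralStats:
    """Summary of a band-integral distribution (normalized-intensity x cm^-1)."""

    n: int
    mean: float
    median: float
    max: float
    min: float
    mode_center: float
    skewness: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "max": self.max,
            "min": self.min,
            "mode_center": self.mode_center,
            "skewness": self.skewness,
        }


@dataclass
class LipidFilterConfig:
    """Band, threshold and baseline options for lipid-rich filtering.

    The default threshold (0.014 in post-area-normalization integral units)
    is the FT-IR cutoff; pass ``threshold`` explicitly for other
    calibrations.
    """

    band: BandDefinition = field(default_factory=lambda: ESTER_BAND)
    threshold: float = 0.014
    local_baseline: bool = True

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def band_integral(
    s: Spectrum, band: BandDefinition = ESTER_BAND, local_baseline: bool = True
) -> float:
    """Trapezoidal integral of one band window, optionally locally baselined.

    With ``local_baseline`` the trapezoid under the straight line joining the
    window's endpoint intensities is subtracted, so the value may be negative
    for noise-only windows.
    """
    return float(
        _band_integrals_matrix(
            s.axis.values, s.intensity[None, :], band, local_baseline
        )[0]
    )


def band_integrals(
    ds: SpectralDataset, band: BandDefinition = ESTER_BAND, local_baseline: bool = True
) -> np.ndarray:
    """Vectorized :func:`band_integral` over a whole dataset."""
    return _band_integrals_matrix(ds.axis.values, ds.intensities, band, local_baseline)


def _band_integrals_matrix(
    x: np.ndarray, y: np.ndarray, band: BandDefinition, local_baseline: bool
) -> np.ndarray:
    lo, hi = band.window
    if lo < x[0] or hi > x[-1]:
        raise RangeError(
            f"band window [{lo}, {hi}] outside axis [{x[0]}, {x[-1]}]"
        )
    mask = (x >= lo) & (x <= hi)
    xw = x[mask]
    yw = y[:, mask]
    area = np.trapezoid(yw, xw, axis=1)
    if local_baseline:
        # trapezoid under the chord joining the window endpoints
        area -= 0.5 * (yw[:, 0] + yw[:, -1]) * (xw[-1] - xw[0])
    return area


def distribution_stats(values: np.ndarray, bins: int = 50) -> BandIntegralStats:
    """Summary statistics + histogram of a vector of band integrals.

    ``mode_center`` is the center of the most populated histogram bin;
    skewness is the adjusted Fisher-Pearson sample skewness.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise SizeError("need at least 2 values")
    counts, edges = np.histogram(values, bins=bins, range=(values.min(), values.max()))
    imax = int(np.argmax(counts))
    return BandIntegralStats(
        n=int(values.size),
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        max=float(np.max(values)),
        min=float(np.min(values)),
        mode_center=float(0.5 * (edges[imax] + edges[imax + 1])),
        skewness=float(stats.skew(values, bias=False)),
        bin_edges=edges,
        counts=counts,
    )


def filter_lipid_rich(
    ds: SpectralDataset, cfg: LipidFilterConfig | None = None
) -> tuple[SpectralDataset, float, np.ndarray]:
    """Remove spectra whose ester-band integral exceeds the threshold.

    Returns ``(reduced, retained_fraction, removed_mask)`` where
    ``retained_fraction`` is computed over the whole dataset and the mask is
    aligned with the input order (True = removed).  Emptying a tissue class
    raises a warning, not an error.
    """
    if cfg is None:
        cfg = LipidFilterConfig()
    integrals = band_integrals(ds, cfg.band, cfg.local_baseline)
    removed = integrals > cfg.threshold
    retained_fraction = float(np.mean(~removed))
    labels = ds.labels
    for cls in [c for c in pd.unique(labels) if c is not None]:
        cls_mask = labels == cls
        if cls_mask.any() and removed[cls_mask].all():
            warnings.warn(
                f"lipid filter removed every spectrum of class {cls!r}",
                stacklevel=2,
            )
    return ds.select(~removed), retained_fraction, removed


def per_class_filter_report(
    ds: SpectralDataset, cfg: LipidFilterConfig | None = None, bins: int = 50
) -> dict:
    """Per-class integral statistics before/after filtering, for run reports."""
    if cfg is None:
        cfg = LipidFilterConfig()
    integrals = band_integrals(ds, cfg.band, cfg.local_baseline)
    removed = integrals > cfg.threshold
    labels = ds.labels
    report: dict = {
        "threshold": cfg.threshold,
        "band": {"name": cfg.band.name, "window": list(cfg.band.window)},
        "retained_fraction": float(np.mean(~removed)),
        "classes": {},
    }
    for cls in [c for c in pd.unique(labels) if c is not None]:
        m = labels == cls
        entry = {
            "n_before": int(m.sum()),
            "n_removed": int(removed[m].sum()),
            "stats_before": distribution_stats(integrals[m], bins).to_dict(),
        }
        kept = m & ~removed
        if kept.sum() >= 2:
            entry["stats_after"] = distribution_stats(integrals[kept], bins).to_dict()
        report["classes"][str(cls)] = entry
    return report
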