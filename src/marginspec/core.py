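"""Core data model: wavenumber axes, spectra, labeled spectral datasets.

The containers here are deliberately thin wrappers over numpy arrays and a
pandas metadata frame.  All wavenumber axes are stored ascending (descending
input is reversed on construction) and every window specification throughout
the package is a closed interval in cm^-1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RangeError, SizeError

__all__ = [
    "Modality",
    "WavenumberAxis",
    "Spectrum",
    "SpectralDataset",
    "BandDefinition",
    "TUMOR",
    "MARGIN",
]

#: canonical tissue-class labels
TUMOR = "tumor"
MARGIN = "margin"

#: metadata columns recognised by the I/O layer
META_COLUMNS = ("patient_id", "tissue", "map_id", "px_row", "px_col")


class Modality(str, enum.Enum):
    """Vibrational spectroscopy modality."""

    FTIR = "ftir"
    RAMAN = "raman"

    @classmethod
    def coerce(cls, value: "Modality | str") -> "Modality":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotone ascending wavenumber axis in cm^-1.

    Parameters
    ----------
    values:
        Wavenumber positions.  Descending input is reversed; the companion
        intensity vector must then be reversed by the caller (the I/O layer
        does this automatically).
    """

    values: np.ndarray

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise SizeError("axis needs at least two wavenumber points")
        diffs = np.diff(arr)
        if np.all(diffs < 0):
            arr = arr[::-1]
            diffs = -diffs
        if not np.all(diffs > 0):
            raise RangeError("wavenumber axis must be strictly monotone")
        if not np.all(arr > 0):
            raise RangeError("wavenumbers must be positive")
        object.__setattr__(self, "values", arr)
        self.values.flags.writeable = False

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))

    @property
    def resolution(self) -> float:
        """Nominal spacing (median step), cm^-1."""
        return float(np.median(np.diff(self.values)))

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of points in the closed interval [lo, hi]."""
        if lo >= hi:
            raise RangeError(f"empty window [{lo}, {hi}]")
        return (self.values >= lo) & (self.values <= hi)

    def index_of(self, wavenumber: float) -> int:
        """Index of the axis point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass
class Spectrum:
    """A single vibrational spectrum with acquisition metadata."""

    axis: WavenumberAxis
    intensity: np.ndarray
    modality: Modality = Modality.FTIR
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.modality = Modality.coerce(self.modality)
        if self.intensity.shape != (len(self.axis),):
            raise SizeError(
                f"intensity length {self.intensity.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, intensity, self.modality, dict(self.meta))

    @property
    def label(self) -> str | None:
        return self.meta.get("tissue")


class SpectralDataset:
    """Ordered collection of spectra sharing one axis and modality.

    Stored internally as an ``(n_spectra, n_points)`` intensity matrix plus a
    pandas metadata frame — the natural layout for pooled chemometric
    analysis.
    """

    def __init__(
        self,
        axis: WavenumberAxis,
        intensities: np.ndarray,
        modality: Modality | str,
        meta: pd.DataFrame | None = None,
    ):
        self.axis = axis
        self.intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        self.modality = Modality.coerce(modality)
        if self.intensities.shape[1] != len(axis):
            raise SizeError(
                f"intensity matrix has {self.intensities.shape[1]} columns, "
                f"axis has {len(axis)} points"
            )
        n = self.intensities.shape[0]
        if meta is None:
            meta = pd.DataFrame(index=range(n))
        if len(meta) != n:
            raise SizeError("metadata length does not match spectrum count")
        self.meta = meta.reset_index(drop=True)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(
            self.axis,
            self.intensities[i].copy(),
            self.modality,
            self.meta.iloc[i].to_dict(),
        )

    def __iter__(self) -> Iterable[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    @property
    def labels(self) -> np.ndarray:
        if "tissue" not in self.meta.columns:
            return np.array([None] * len(self), dtype=object)
        return self.meta["tissue"].to_numpy()

    def class_counts(self) -> dict:
        labels = [l for l in self.labels if l is not None]
        uniq, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    # -- construction helpers ----------------------------------------------
    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectralDataset":
        if not spectra:
            raise SizeError("need at least one spectrum")
        axis = spectra[0].axis
        modality = spectra[0].modality
        for s in spectra[1:]:
            if s.axis != axis:
                raise RangeError("all spectra must share one axis")
            if s.modality != modality:
                raise ValueError("all spectra must share one modality")
        intensities = np.vstack([s.intensity for s in spectra])
        meta = pd.DataFrame([s.meta for s in spectra])
        return cls(axis, intensities, modality, meta)

    def select(self, mask: np.ndarray) -> "SpectralDataset":
        """Subset by boolean mask or integer index array, preserving order."""
        mask = np.asarray(mask)
        return SpectralDataset(
            self.axis,
            self.intensities[mask],
            self.modality,
            self.meta.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.meta.iloc[mask].reset_index(drop=True),
        )

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.axis, intensities, self.modality, self.meta.copy())

    def concat(self, other: "SpectralDataset") -> "SpectralDataset":
        if other.axis != self.axis or other.modality != self.modality:
            raise RangeError("datasets must share axis and modality")
        return SpectralDataset(
            self.axis,
            np.vstack([self.intensities, other.intensities]),
            self.modality,
            pd.concat([self.meta, other.meta], ignore_index=True),
        )


@dataclass(frozen=True)
class BandDefinition:
    """A named integration band: center and closed window, in cm^-1."""

    name: str
    center: float
    window: tuple[float, float]
    assignment: str = "mixed"

    def __post_init__(self):
        lo, hi = self.window
        if not (lo < self.center < hi):
            raise RangeError(
                f"band window [{lo}, {hi}] must strictly bracket center {self.center}"
            )


#: the ester carbonyl band used for lipid-domain filtering
ESTER_BAND = BandDefinition(
    name="ester C=O", center=1746.0, window=(1710.0, 1790.0), assignment="lipid"
)


def crop(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Restrict a dataset to axis points in the closed interval [lo, hi]."""
    mask = ds.axis.window_mask(lo, hi)
    if not mask.any():
        raise RangeError(f"window [{lo}, {hi}] does not overlap the axis")
    new_axis = WavenumberAxis(ds.axis.values[mask])
    return SpectralDataset(new_axis, ds.intensities[:, mask], ds.modality, ds.meta.copy())


def crop_spectrum(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Single-spectrum version of :func:`crop`."""
    mask = s.axis.window_mask(lo, hi)
    if not mask.any():
        raise RangeError(f"window [{lo}, {hi}] does not overlap the axis")
    return Spectrum(
        WavenumberAxis(s.axis.values[mask]), s.intensity[mask], s.modality, dict(s.meta)
    )
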