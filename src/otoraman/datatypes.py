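"""Core containers for Raman spectra.

A :class:`Spectrum` is one site's measurement: a strictly ascending
wavenumber axis (cm^-1) with an intensity vector in detector counts.
A :class:`SpectralDataset` stacks spectra that share one common axis,
together with specimen/site identifiers and gross pathology labels; it is
the unit every downstream stage (despiking, screening, PCA, PLS-DA)
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

#: Gross (otoscopic) pathology labels carried by measured spectra.
GROSS_LABELS = ("cholesteatoma", "myringosclerosis")

#: The three analysis classes produced by the mineralization screen.
CLASS_LABELS = (
    "cholesteatoma",
    "mineralized_myringosclerosis",
    "nonmineralized_myringosclerosis",
)


@dataclass
class Spectrum:
    """One measured Raman spectrum with site metadata.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly ascending Raman shift axis in cm^-1.
    intensities : ndarray
        Detector counts per channel, same length as ``wavenumbers``.
    specimen_id, site_id : str
        Identifiers of the tissue specimen and the measured site.
    gross_label : str, optional
        Gross pathology assigned at excision, one of :data:`GROSS_LABELS`.
    meta : dict
        Free-form provenance flags (e.g. ``axis_reversed`` set by readers).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    specimen_id: str = ""
    site_id: str = ""
    gross_label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly ascending")
        if not np.all(np.isfinite(self.intensities)):
            bad = int(np.flatnonzero(~np.isfinite(self.intensities))[0])
            raise ValueError(f"non-finite intensity at channel {bad}")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.wavenumbers.copy(),
            self.intensities.copy(),
            self.specimen_id,
            self.site_id,
            self.gross_label,
            dict(self.meta),
        )


@dataclass
class SpectralDataset:
    """Spectra on a common wavenumber axis with per-site metadata.

    ``meta`` holds one row per spectrum (same order as the rows of
    ``intensities``) with at least ``site_id``, ``specimen_id`` and
    ``gross_label`` columns; synthetic datasets additionally carry
    ``true_label`` and generator provenance columns.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (n_spectra, n_channels)")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError("channel count mismatch between axis and intensities")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata rows must match spectrum count")
        if "site_id" not in self.meta.columns:
            raise ValueError("metadata must contain a site_id column")
        if self.meta["site_id"].duplicated().any():
            dup = self.meta.loc[self.meta["site_id"].duplicated(), "site_id"].iloc[0]
            raise ValueError(f"duplicate site_id {dup!r}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def site_ids(self) -> np.ndarray:
        return self.meta["site_id"].to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            self.wavenumbers,
            self.intensities[i],
            specimen_id=str(row.get("specimen_id", "")),
            site_id=str(row["site_id"]),
            gross_label=row.get("gross_label"),
        )

    def __iter__(self) -> Iterator[Spectrum]:
        return (self.spectrum(i) for i in range(self.n_spectra))

    def __len__(self) -> int:
        return self.n_spectra

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset by boolean mask or integer indices."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectralDataset(
            self.wavenumbers,
            self.intensities[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavenumbers.copy(), self.intensities.copy(), self.meta.copy()
        )
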