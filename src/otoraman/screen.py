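"""Mineralization screen on the apatite phosphate nu1 band.

Myringosclerosis tissue is spatially heterogeneous: some sites carry
calcium phosphate plaques, others are grossly uninvolved. The screen
partitions myringosclerosis spectra into mineralized vs non-mineralized
by detecting the 960 cm^-1 nu1(PO4) peak inside a 20 cm^-1 search band.

Detection statistic: the height of the tallest in-band local maximum
above a linear chord spanning the band endpoints, divided by a robust
noise scale estimated from a flanking signal-free window. The ratio is
invariant to multiplying the spectrum by a positive constant, so the
decision is scale-free despite the uncorrected autofluorescence
background. Cholesteatoma spectra pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import SpectralDataset, Spectrum

_MAD_SCALE = 1.4826

#: Flanking window (cm^-1) assumed free of Raman bands, used for the
#: noise estimate. Above the amide-I region on the default axis.
DEFAULT_NOISE_WINDOW = (1750.0, 1800.0)


@dataclass
class PeakCall:
    """A detected in-band peak."""

    center: float
    height_above_local_baseline: float
    prominence: float
    snr: float
    in_band: bool = True


@dataclass
class ClassAssignment:
    """Final analysis class of one site, with detection evidence if screened."""

    site_id: str
    assigned_class: str
    evidence: Optional[PeakCall] = None


def noise_sigma(spectrum: Spectrum, window: tuple[float, float] = DEFAULT_NOISE_WINDOW) -> float:
    """Robust per-channel noise from first differences in a signal-free window.

    Differencing removes the slowly varying autofluorescence slope; the
    MAD of the differences divided by sqrt(2) estimates the channel noise.
    The estimate is floored at the Poisson shot-noise limit of the
    window's median counts — a photon-counting channel is never quieter
    than sqrt(counts), so an idealized noise-free signal still faces a
    physically meaningful detection threshold.
    """
    lo, hi = window
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 4:
        raise ValueError("noise window covers fewer than 4 channels")
    y = spectrum.intensities[mask]
    d = np.diff(y)
    empirical = _MAD_SCALE * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    shot_floor = float(np.sqrt(max(np.median(y), 0.0)))
    return max(empirical, shot_floor)


def find_band_peak(
    spectrum: Spectrum,
    band_center: float = 960.0,
    band_width: float = 20.0,
    snr_threshold: float = 5.0,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
) -> Optional[PeakCall]:
    """Detect the tallest significant local maximum inside a search band.

    Peak height (prominence) is measured against the linear chord between
    the band endpoints; the call is made when height / noise exceeds
    ``snr_threshold``. Equal maxima are resolved toward ``band_center``.
    Returns ``None`` when nothing in the band clears the threshold.
    """
    x, y = spectrum.wavenumbers, spectrum.intensities
    lo, hi = band_center - band_width / 2.0, band_center + band_width / 2.0
    if lo < x[0] or hi > x[-1]:
        raise ValueError(
            f"search band [{lo}, {hi}] cm^-1 extends outside the axis "
            f"[{x[0]}, {x[-1]}] cm^-1"
        )
    idx = np.flatnonzero((x >= lo) & (x <= hi))
    if idx.size < 3:
        raise ValueError("search band covers fewer than 3 channels")
    xb, yb = x[idx], y[idx]
    # Chord endpoints are averaged over up to 3 channels each: a single
    # noisy endpoint channel would shift the whole chord and with it
    # every in-band residual, dominating the false-call rate.
    k = min(3, max(1, yb.size // 4))
    y_lo, y_hi = float(yb[:k].mean()), float(yb[-k:].mean())
    x_lo, x_hi = float(xb[:k].mean()), float(xb[-k:].mean())
    chord = y_lo + (xb - x_lo) * (y_hi - y_lo) / (x_hi - x_lo)
    resid = yb - chord
    # The phosphate band spans several channels while the shot noise is
    # per-channel white: a short moving average over the chord residual
    # acts as a crude matched filter, cutting the noise on the prominence
    # estimate by sqrt(width) and attenuating residual 1-2 channel
    # cosmic-ray stubs rather than real bands.
    width = min(3, resid.size)
    kernel = np.ones(width) / width
    resid = np.convolve(resid, kernel, mode="same")

    interior = np.arange(1, resid.size - 1)
    is_max = (resid[interior] >= resid[interior - 1]) & (resid[interior] >= resid[interior + 1])
    cands = interior[is_max & (resid[interior] > 0)]
    if cands.size == 0:
        return None
    heights = resid[cands]
    best_h = heights.max()
    ties = cands[np.isclose(heights, best_h, rtol=0.0, atol=1e-12 * max(best_h, 1.0))]
    best = ties[np.argmin(np.abs(xb[ties] - band_center))]

    sigma = noise_sigma(spectrum, noise_window) / np.sqrt(width)
    height = float(resid[best])
    snr = height / sigma if sigma > 0 else np.inf
    if snr <= snr_threshold:
        return None
    return PeakCall(
        center=float(xb[best]),
        height_above_local_baseline=height,
        prominence=height,
        snr=float(snr),
    )


def screen_dataset(
    dataset: SpectralDataset,
    band_center: float = 960.0,
    band_width: float = 20.0,
    snr_threshold: float = 5.0,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
) -> list[ClassAssignment]:
    """Assign every site its analysis class.

    Cholesteatoma gross labels pass through unchanged (never re-screened);
    myringosclerosis sites become ``mineralized_myringosclerosis`` iff the
    phosphate-band peak is detected, else ``nonmineralized_myringosclerosis``.
    Spectra without a gross label raise.
    """
    assignments = []
    for s in dataset:
        label = s.gross_label
        if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
            raise ValueError(f"site {s.site_id!r} has no gross label")
        if label == "cholesteatoma":
            assignments.append(ClassAssignment(s.site_id, "cholesteatoma"))
            continue
        if label != "myringosclerosis":
            raise ValueError(f"site {s.site_id!r}: unknown gross label {label!r}")
        call = find_band_peak(s, band_center, band_width, snr_threshold, noise_window)
        assigned = (
            "mineralized_myringosclerosis" if call is not None
            else "nonmineralized_myringosclerosis"
        )
        assignments.append(ClassAssignment(s.site_id, assigned, evidence=call))
    return assignments


def assignments_frame(assignments: list[ClassAssignment]) -> pd.DataFrame:
    """Tabular view of screen output (site_id, assigned_class, peak_center, snr)."""
    return pd.DataFrame(
        {
            "site_id": [a.site_id for a in assignments],
            "assigned_class": [a.assigned_class for a in assignments],
            "peak_center": [a.evidence.center if a.evidence else np.nan for a in assignments],
            "snr": [a.evidence.snr if a.evidence else np.nan for a in assignments],
        }
    )


def assigned_labels(assignments: list[ClassAssignment], dataset: SpectralDataset) -> np.ndarray:
    """Assigned class per dataset row, aligned to dataset order."""
    by_site = {a.site_id: a.assigned_class for a in assignments}
    return np.asarray([by_site[str(s)] for s in dataset.site_ids])
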