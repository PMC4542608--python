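"""Cosmic-ray despiking — the only preprocessing applied before analysis.

Cosmic-ray events hit single CCD channels (occasionally two adjacent
ones) and produce narrow, very tall excursions unrelated to the Raman
signal. They are removed with a Hampel filter: a channel whose robust
z-score against the windowed median/MAD exceeds a threshold is replaced
by its local median; everything else is left bit-unchanged. No baseline
or autofluorescence correction is performed anywhere in this package —
the broad background is deliberately carried into the multivariate
analysis.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import SpectralDataset, Spectrum

_MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian noise


class DespikeQualityError(ValueError):
    """Raised when despiking would alter an implausible fraction of channels."""


def hampel_filter(
    y: np.ndarray, window: int = 7, threshold: float = 8.0
) -> tuple[np.ndarray, list[int]]:
    """Hampel filter on a 1-D signal.

    Parameters
    ----------
    window : odd int >= 3
        Total window length in channels.
    threshold : float
        Robust z-score above which a channel counts as a spike.

    Returns the cleaned signal and the sorted list of replaced channels.
    """
    y = np.asarray(y, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > y.size:
        raise ValueError(f"window {window} longer than spectrum ({y.size} channels)")
    half = window // 2
    padded = np.pad(y, half, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(win, axis=1)
    mad = np.median(np.abs(win - med[:, None]), axis=1)
    dev = np.abs(y - med)
    # The handful of samples in a window make the local MAD an erratic
    # scale estimate (it is tiny by chance often enough to flag ordinary
    # shot noise), so floor it with the spectrum-wide robust residual
    # scale. Both scales are medians, hence immune to the spikes sought.
    sigma = _MAD_SCALE * np.maximum(mad, np.median(dev))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, dev / np.where(sigma > 0, sigma, 1.0), np.where(dev > 0, np.inf, 0.0))
    spikes = np.flatnonzero(z > threshold)
    cleaned = y.copy()
    cleaned[spikes] = med[spikes]
    return cleaned, spikes.tolist()


def _hampel_to_convergence(
    y: np.ndarray, window: int, threshold: float, max_passes: int = 10
) -> tuple[np.ndarray, list[int]]:
    """Iterate the Hampel filter until a pass replaces nothing.

    A converged output is a fixed point, which makes despiking exactly
    idempotent; broad two-channel cosmic events also fall in one extra
    pass once their taller neighbor is gone.
    """
    cleaned = np.asarray(y, dtype=float)
    all_spikes: set[int] = set()
    for _ in range(max_passes):
        cleaned, spikes = hampel_filter(cleaned, window, threshold)
        if not spikes:
            break
        all_spikes.update(spikes)
    return cleaned, sorted(all_spikes)


def despike(
    spectrum: Spectrum,
    window: int = 7,
    threshold: float = 8.0,
    max_fraction: float = 0.02,
) -> tuple[Spectrum, list[int]]:
    """Despike one spectrum; returns the cleaned spectrum and spike channels.

    Raises :class:`DespikeQualityError` if more than ``max_fraction`` of
    channels would be replaced — a spectrum that anomalous should be
    inspected, not silently rewritten.
    """
    cleaned, spikes = _hampel_to_convergence(spectrum.intensities, window, threshold)
    if len(spikes) > max_fraction * len(spectrum):
        raise DespikeQualityError(
            f"site {spectrum.site_id!r}: despiking flagged {len(spikes)} of "
            f"{len(spectrum)} channels (> {max_fraction:.0%} cap)"
        )
    out = spectrum.copy()
    out.intensities = cleaned
    out.meta["despiked_channels"] = spikes
    return out, spikes


class HampelDespiker(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the Hampel filter row-wise.

    Stateless (``fit`` only validates); after ``transform`` the channels
    replaced in each row are available as ``spike_channels_``.
    """

    def __init__(self, window: int = 7, threshold: float = 8.0, max_fraction: float = 0.02):
        self.window = window
        self.threshold = threshold
        self.max_fraction = max_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_spectra, n_channels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        self.spike_channels_ = []
        for i, row in enumerate(X):
            cleaned, spikes = _hampel_to_convergence(row, self.window, self.threshold)
            if len(spikes) > self.max_fraction * row.size:
                raise DespikeQualityError(
                    f"row {i}: {len(spikes)} channels flagged "
                    f"(> {self.max_fraction:.0%} cap)"
                )
            out[i] = cleaned
            self.spike_channels_.append(spikes)
        return out


def despike_dataset(
    dataset: SpectralDataset,
    window: int = 7,
    threshold: float = 8.0,
    max_fraction: float = 0.02,
) -> tuple[SpectralDataset, dict[str, list[int]]]:
    """Despike every spectrum in a dataset; map site_id -> replaced channels."""
    filt = HampelDespiker(window, threshold, max_fraction)
    cleaned = filt.fit(dataset.intensities).transform(dataset.intensities)
    out = dataset.copy()
    out.intensities = cleaned
    report = {
        str(site): ch for site, ch in zip(dataset.site_ids, filt.spike_channels_) if ch
    }
    return out, report
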