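"""Forward model for labelled synthetic middle-ear Raman spectra.

Generates spectra for the three analysis phenotypes — cholesteatoma
(keratin/collagen protein bands at 956/1005/1032/1128/1447/1654/1680
cm^-1), mineralized myringosclerosis (apatite phosphate nu1 at 960 cm^-1,
the substitution-dependent nu3 mode near 1044 cm^-1, the 948 cm^-1 nu1
shoulder and 748 cm^-1), and non-mineralized myringosclerosis (weak
protein bands plus optional faint 960/1048 traces) — over a broad
autofluorescence baseline, with specimen-level amplitude heterogeneity,
Poisson shot noise on total counts, and sparse cosmic-ray spikes.

Lattice substitution of the apatite is a single scalar ``d`` in [0, 1]:

* fwhm(960)      = f0 * (1 + kappa * d)  (band broadening)
* amplitude(1044) = a_1044 * d            (nu3 grows with substitution)
* amplitude(948)  = a_948 * (1 - d)       (shoulder resolved only near d=0)

Specimen heterogeneity has two components, both log-normal and both with
a between-specimen sd exceeding the within-specimen (per-site) sd:

* a band-amplitude factor (``specimen_effect_sd`` / ``site_effect_sd``)
  scaling the Raman bands relative to the autofluorescence baseline —
  this is what makes the two protein-band phenotypes genuinely
  confusable; and
* an overall intensity multiplier (``intensity_specimen_sd`` /
  ``intensity_site_sd``) scaling the whole spectrum, baseline included,
  as collection efficiency and illumination vary.

So a noise-free spectrum is ``(baseline + g * bands) * m`` with band
factor ``g`` and intensity multiplier ``m``, both recorded per spectrum
in the dataset metadata.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import CLASS_LABELS, SpectralDataset, Spectrum

_MINERALIZED = "mineralized_myringosclerosis"


@dataclass
class BandSpec:
    """One Raman band: ``center``/``fwhm`` in cm^-1, peak ``amplitude`` in counts."""

    center: float
    amplitude: float
    fwhm: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} cm^-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} cm^-1: amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Evaluate the band on ``axis`` with unit-amplitude peak scaling."""
        if self.shape == "lorentzian":
            gamma = self.fwhm / 2.0
            return self.amplitude * gamma**2 / ((axis - self.center) ** 2 + gamma**2)
        return self.amplitude * np.exp(
            -4.0 * np.log(2.0) * (axis - self.center) ** 2 / self.fwhm**2
        )


@dataclass
class PhenotypeModel:
    """Spectral model of one phenotype: bands over an autofluorescence baseline.

    ``baseline_coefficients`` are polynomial coefficients in the normalized
    axis coordinate xi in [0, 1] (ascending powers), scaled by
    ``baseline_scale`` counts. ``substitution_degree`` applies only to the
    mineralized phenotype (see module docstring).
    """

    label: str
    bands: list[BandSpec]
    baseline_coefficients: Sequence[float] = (1.0,)
    baseline_scale: float = 0.0
    substitution_degree: Optional[float] = None
    substitution_broadening: float = 0.8
    gross_label: str = ""

    def __post_init__(self) -> None:
        if self.substitution_degree is not None and not (
            0.0 <= self.substitution_degree <= 1.0
        ):
            raise ValueError("substitution_degree must lie in [0, 1]")
        if not self.gross_label:
            self.gross_label = (
                "cholesteatoma" if self.label == "cholesteatoma" else "myringosclerosis"
            )

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        xi = (axis - axis[0]) / max(axis[-1] - axis[0], 1e-300)
        b = self.baseline_scale * np.polynomial.polynomial.polyval(
            xi, np.asarray(self.baseline_coefficients, dtype=float)
        )
        if np.any(b < 0):
            raise ValueError(
                f"phenotype {self.label!r}: baseline is negative on the axis"
            )
        return b


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the structure of an ex-vivo specimen-scanning study:
    several specimens per phenotype, replicate sites per specimen,
    inter-specimen amplitude heterogeneity larger than intra-specimen,
    shot-noise-limited counts, and occasional cosmic-ray spikes.
    """

    axis_start: float = 600.0
    axis_end: float = 1800.0
    axis_step: float = 2.0
    phenotypes: list[PhenotypeModel] = field(default_factory=lambda: default_phenotypes())
    n_specimens_per_class: int = 8
    n_sites_per_specimen: int = 10
    specimen_effect_sd: float = 0.35
    site_effect_sd: float = 0.12
    intensity_specimen_sd: float = 0.15
    intensity_site_sd: float = 0.05
    shot_noise: bool = True
    spike_rate: float = 1.0
    spike_amplitude_range: tuple[float, float] = (500.0, 3000.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_start >= self.axis_end:
            raise ValueError("axis_start must be < axis_end")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.n_specimens_per_class < 1 or self.n_sites_per_specimen < 1:
            raise ValueError("specimen and site counts must be >= 1")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_end - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


def _load_band_tables() -> dict:
    text = (
        importlib.resources.files("otoraman").joinpath("band_tables.yaml").read_text()
    )
    return yaml.safe_load(text)


def default_phenotypes() -> list[PhenotypeModel]:
    """The shipped v1 band tables as :class:`PhenotypeModel` objects."""
    tables = _load_band_tables()
    models = []
    for label in CLASS_LABELS:
        entry = tables["phenotypes"][label]
        models.append(
            PhenotypeModel(
                label=label,
                bands=[BandSpec(**b) for b in entry["bands"]],
                baseline_coefficients=entry["baseline_coefficients"],
                baseline_scale=entry["baseline_scale"],
                substitution_degree=entry.get("substitution_degree"),
                substitution_broadening=entry.get("substitution_broadening", 0.8),
                gross_label=entry["gross_label"],
            )
        )
    return models


def _effective_bands(model: PhenotypeModel) -> list[BandSpec]:
    """Apply the substitution mapping to the apatite phosphate bands."""
    d = model.substitution_degree
    if d is None:
        return list(model.bands)
    out = []
    for band in model.bands:
        b = dataclasses.replace(band)
        if abs(band.center - 960.0) <= 1.0:
            b.fwhm = band.fwhm * (1.0 + model.substitution_broadening * d)
        elif abs(band.center - 1044.0) <= 1.0:
            b.amplitude = band.amplitude * d
        elif abs(band.center - 948.0) <= 1.0:
            b.amplitude = band.amplitude * (1.0 - d)
        out.append(b)
    return out


def _render_parts(model: PhenotypeModel, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and summed band profiles of a phenotype on ``axis``."""
    axis = np.asarray(axis, dtype=float)
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly ascending")
    for band in model.bands:
        if not (axis[0] <= band.center <= axis[-1]):
            raise ValueError(
                f"band at {band.center} cm^-1 lies outside the axis "
                f"[{axis[0]}, {axis[-1]}] cm^-1"
            )
    baseline = (
        np.asarray(model.baseline(axis), dtype=float)
        if model.baseline_scale
        else np.zeros_like(axis)
    )
    bands = np.zeros_like(axis)
    for band in _effective_bands(model):
        bands = bands + band.profile(axis)
    return baseline, bands


def render_clean_spectrum(model: PhenotypeModel, axis: np.ndarray) -> Spectrum:
    """Noise-free spectrum of a phenotype: baseline plus band profiles.

    Raises if any band center falls outside the axis (naming the band).
    """
    baseline, bands = _render_parts(model, axis)
    return Spectrum(
        np.asarray(axis, dtype=float),
        baseline + bands,
        gross_label=model.gross_label or None,
    )


def generate_dataset(config: SimulationConfig) -> SpectralDataset:
    """Draw a full labelled synthetic cohort.

    Per phenotype: ``n_specimens_per_class`` specimens ×
    ``n_sites_per_specimen`` sites, each site one spectrum. Identical
    ``rng_seed`` yields a bit-identical dataset. Per-spectrum metadata
    records the ground-truth phenotype (``true_label``), the applied
    amplitude multiplier, and planted cosmic-ray spike channels.
    """
    rng = np.random.default_rng(config.rng_seed)
    axis = config.axis
    parts = {m.label: _render_parts(m, axis) for m in config.phenotypes}

    rows = []
    intensities = []
    for model in config.phenotypes:
        short = "".join(w[0] for w in model.label.split("_")) or model.label[:3]
        baseline, bands = parts[model.label]
        for s in range(config.n_specimens_per_class):
            specimen_id = f"{short}{s:02d}"
            g_spec = float(rng.lognormal(0.0, config.specimen_effect_sd))
            m_spec = float(rng.lognormal(0.0, config.intensity_specimen_sd))
            for k in range(config.n_sites_per_specimen):
                g_site = float(rng.lognormal(0.0, config.site_effect_sd))
                m_site = float(rng.lognormal(0.0, config.intensity_site_sd))
                g = g_spec * g_site
                mult = m_spec * m_site
                y = (baseline + g * bands) * mult
                if config.shot_noise:
                    y = rng.poisson(y).astype(float)
                n_spikes = int(rng.poisson(config.spike_rate))
                spike_channels: list[int] = []
                for _ in range(n_spikes):
                    ch = int(rng.integers(0, axis.size))
                    width = int(rng.integers(1, 3))
                    amp = float(rng.uniform(*config.spike_amplitude_range))
                    if config.shot_noise:
                        amp = float(round(amp))
                    y[ch] += amp
                    spike_channels.append(ch)
                    if width == 2 and ch + 1 < axis.size:
                        y[ch + 1] += 0.6 * amp if not config.shot_noise else round(0.6 * amp)
                        spike_channels.append(ch + 1)
                rows.append(
                    {
                        "site_id": f"{specimen_id}-s{k:02d}",
                        "specimen_id": specimen_id,
                        "gross_label": model.gross_label,
                        "true_label": model.label,
                        "band_multiplier": g,
                        "amplitude_multiplier": mult,
                        "n_spikes": n_spikes,
                        "spike_channels": ";".join(map(str, sorted(set(spike_channels)))),
                    }
                )
                intensities.append(y)

    return SpectralDataset(axis, np.asarray(intensities), pd.DataFrame(rows))


def write_dataset(dataset: SpectralDataset, outdir: str | Path,
                  config: Optional[SimulationConfig] = None) -> Path:
    """Write a dataset as per-site two-column CSVs + manifest TSV (+ config YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for i in range(dataset.n_spectra):
        row = dataset.meta.iloc[i]
        fname = f"{row['site_id']}.csv"
        pd.DataFrame(
            {"wavenumber_cm-1": dataset.wavenumbers, "intensity": dataset.intensities[i]}
        ).to_csv(outdir / fname, index=False)
        entry = {
            "file": fname,
            "specimen_id": row.get("specimen_id", ""),
            "site_id": row["site_id"],
            "gross_label": row.get("gross_label", ""),
        }
        if "true_label" in dataset.meta.columns:
            entry["true_label"] = row["true_label"]
        manifest_rows.append(entry)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    if config is not None:
        (outdir / "config.yaml").write_text(yaml.safe_dump(config_to_dict(config)))
    return outdir


def config_to_dict(config: SimulationConfig) -> dict:
    """YAML-serializable form of a simulation config (band tables inlined)."""
    d = dataclasses.asdict(config)
    d["spike_amplitude_range"] = list(config.spike_amplitude_range)
    return d
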