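"""Forward-model tests: band rendering, substitution mapping, cohort
generation, determinism and noise structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from otoraman import (
    BandSpec,
    PhenotypeModel,
    SimulationConfig,
    generate_dataset,
    load_dataset,
    render_clean_spectrum,
    write_dataset,
)
from otoraman.synthetic import _render_parts


def local_maxima(axis, y):
    i = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    return axis[i]


def band_height_above_baseline(model, axis, center):
    baseline, bands = _render_parts(model, axis)
    return bands[int(np.argmin(np.abs(axis - center)))]


class TestRenderCleanSpectrum:
    def test_substituted_apatite_shows_960_and_1044_peaks(self, phenotypes, axis):
        model = dataclasses.replace(
            phenotypes["mineralized_myringosclerosis"], substitution_degree=0.8
        )
        s = render_clean_spectrum(model, axis)
        peaks = local_maxima(axis, s.intensities)
        assert np.any(np.abs(peaks - 960.0) <= 2.0)
        assert np.any(np.abs(peaks - 1044.0) <= 2.0)

    def test_pure_apatite_limit_resolves_948_doublet_without_1044(self, phenotypes, axis):
        model = dataclasses.replace(
            phenotypes["mineralized_myringosclerosis"], substitution_degree=0.0
        )
        s = render_clean_spectrum(model, axis)
        peaks = local_maxima(axis, s.intensities)
        assert not np.any(np.abs(peaks - 1044.0) <= 10.0)
        assert np.any(np.abs(peaks - 948.0) <= 2.0)
        # 960 band keeps its configured pure-apatite width: half-max points
        baseline, bands = _render_parts(model, axis)
        f0 = next(b.fwhm for b in model.bands if b.center == 960.0)
        band960 = [b for b in model.bands if b.center == 960.0][0]
        profile = band960.profile(axis)
        above = axis[profile >= band960.amplitude / 2.0]
        assert above[-1] - above[0] == pytest.approx(f0, abs=2 * (axis[1] - axis[0]))

    def test_substitution_monotonically_raises_1044_to_960_ratio(self, phenotypes, axis):
        base = phenotypes["mineralized_myringosclerosis"]
        ratios = []
        for d in [0.0, 0.25, 0.5, 0.75, 1.0]:
            model = dataclasses.replace(base, substitution_degree=d)
            h1044 = band_height_above_baseline(model, axis, 1044.0)
            h960 = band_height_above_baseline(model, axis, 960.0)
            ratios.append(h1044 / h960)
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] < 0.05 < ratios[-1]

    def test_empty_band_list_and_zero_baseline_renders_zeros(self, axis):
        model = PhenotypeModel(label="blank", bands=[], baseline_scale=0.0)
        s = render_clean_spectrum(model, axis)
        assert np.all(s.intensities == 0.0)

    def test_band_outside_axis_raises_naming_the_band(self, axis):
        model = PhenotypeModel(
            label="bad", bands=[BandSpec(center=2500.0, amplitude=1.0, fwhm=10.0)]
        )
        with pytest.raises(ValueError, match="2500"):
            render_clean_spectrum(model, axis)

    def test_clean_spectra_are_nonnegative(self, phenotypes, axis):
        for model in phenotypes.values():
            assert np.all(render_clean_spectrum(model, axis).intensities >= 0.0)


class TestGenerateDataset:
    def test_identical_seeds_give_bit_identical_datasets(self):
        cfg = SimulationConfig(n_specimens_per_class=2, n_sites_per_specimen=3, rng_seed=7)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_different_seeds_give_different_noise(self):
        base = dict(n_specimens_per_class=2, n_sites_per_specimen=3)
        a = generate_dataset(SimulationConfig(rng_seed=7, **base))
        b = generate_dataset(SimulationConfig(rng_seed=8, **base))
        assert not np.array_equal(a.intensities, b.intensities)

    def test_noiseless_limit_is_scaled_clean_spectrum(self, clean_dataset, phenotypes):
        axis = clean_dataset.wavenumbers
        parts = {lbl: _render_parts(m, axis) for lbl, m in phenotypes.items()}
        for i in range(clean_dataset.n_spectra):
            row = clean_dataset.meta.iloc[i]
            baseline, bands = parts[row["true_label"]]
            expected = (baseline + row["band_multiplier"] * bands) * row[
                "amplitude_multiplier"
            ]
            np.testing.assert_allclose(clean_dataset.intensities[i], expected, rtol=1e-12)

    def test_shot_noise_yields_nonnegative_integer_counts(self, small_dataset):
        y = small_dataset.intensities
        assert np.all(y >= 0)
        assert np.all(y == np.round(y))

    def test_planted_spike_count_matches_poisson_rate(self):
        cfg = SimulationConfig(
            n_specimens_per_class=5, n_sites_per_specimen=10, spike_rate=2.0, rng_seed=21
        )
        ds = generate_dataset(cfg)
        mean_spikes = ds.meta["n_spikes"].mean()
        # 150 spectra at rate 2: sample mean within the +/-3 SE band
        assert 1.5 <= mean_spikes <= 2.5

    def test_expected_cohort_shape(self, small_dataset):
        assert small_dataset.n_spectra == 3 * 4 * 5
        counts = small_dataset.meta["true_label"].value_counts()
        assert set(counts) == {20}
        assert small_dataset.meta["site_id"].is_unique

    def test_within_class_distances_smaller_than_between(self, clean_dataset):
        y = clean_dataset.intensities
        lab = clean_dataset.meta["true_label"].to_numpy()
        chol = y[lab == "cholesteatoma"]
        mine = y[lab == "mineralized_myringosclerosis"]

        def mean_pairwise(a, b):
            return np.mean(
                [np.linalg.norm(x - z) for x in a for z in b if not np.array_equal(x, z)]
            )

        within = 0.5 * (mean_pairwise(chol, chol) + mean_pairwise(mine, mine))
        between = mean_pairwise(chol, mine)
        assert within < between


def test_dataset_round_trips_through_csv_and_manifest(tmp_path, clean_dataset):
    outdir = write_dataset(clean_dataset, tmp_path / "cohort")
    loaded = load_dataset(outdir / "manifest.tsv")
    assert loaded.n_spectra == clean_dataset.n_spectra
    np.testing.assert_allclose(loaded.wavenumbers, clean_dataset.wavenumbers)
    np.testing.assert_allclose(
        loaded.intensities, clean_dataset.intensities, rtol=1e-10
    )
    assert list(loaded.meta["true_label"]) == list(clean_dataset.meta["true_label"])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(axis_start=1800, axis_end=600)
    with pytest.raises(ValueError):
        SimulationConfig(axis_step=0)
    with pytest.raises(ValueError):
        SimulationConfig(spike_rate=-1.0)
    with pytest.raises(ValueError):
        PhenotypeModel(label="x", bands=[], substitution_degree=1.5)
    with pytest.raises(ValueError):
        BandSpec(center=960.0, amplitude=1.0, fwhm=0.0)
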