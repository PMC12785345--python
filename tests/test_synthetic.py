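import dataclasses

import numpy as np
import pytest

from nirauth import preprocess, synthetic
from nirauth.synthetic import (ADULTERANT_CLASSES, GENUINE_CLASS,
                               EndmemberSpec, SimulationConfig, SpectraSet,
                               WavenumberGrid, evaluate_endmember, generate,
                               make_endmembers, read_csv, write_csv)


class TestWavenumberGrid:
    def test_default_matches_instrument_convention(self):
        g = WavenumberGrid.default()
        assert g.n_points == 1557
        assert g.values[0] == 10_000.0
        assert g.values[-1] == 4_000.0
        assert np.allclose(np.diff(g.values), -6000.0 / 1556)

    def test_rejects_increasing_or_nonuniform(self):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([4000.0, 5000.0, 6000.0]))
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([6000.0, 5000.0, 4500.0]))

    def test_normalized_range(self):
        g = WavenumberGrid.default(n_points=11)
        nt = g.normalized()
        assert nt[0] == 1.0 and nt[-1] == 0.0


class TestEndmembers:
    def test_six_specs_with_first_overtone_band(self):
        specs = make_endmembers(0)
        assert [s.class_name for s in specs] == list(synthetic.ALL_CLASSES)
        for spec in specs:
            assert any(6600 <= c <= 7075 for c, _w, _a in spec.bands)

    def test_deterministic(self):
        assert make_endmembers(5) == make_endmembers(5)
        assert make_endmembers(5) != make_endmembers(6)

    def test_similarity_groups(self):
        groups = {s.class_name: s.similarity_group for s in make_endmembers(1)}
        assert groups["DL"] == groups["DKM"] == "dendrobium"
        assert groups["bamboo"] == groups["corn"] == "non-dendrobium"

    def test_spectra_nonnegative(self, small_grid):
        for spec in make_endmembers(3):
            assert np.all(evaluate_endmember(spec, small_grid) >= 0)

    def test_pairwise_distinguishable(self):
        # minimum separation needed for the default noise level
        grid = WavenumberGrid.default()
        cfg = SimulationConfig()
        floor = 10 * cfg.noise_sd * np.sqrt(grid.n_points)
        spectra = [evaluate_endmember(s, grid) for s in make_endmembers(0)]
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                assert np.linalg.norm(spectra[i] - spectra[j]) > floor


class TestEvaluateEndmember:
    def test_gaussian_peak_value(self):
        grid = WavenumberGrid.default()
        spec = EndmemberSpec("DKM", ((5100.0, 50.0, 1.0),), "dendrobium")
        y = evaluate_endmember(spec, grid)
        nearest = np.argmin(np.abs(grid.values - 5100.0))
        offset = abs(grid.values[nearest] - 5100.0)
        assert offset < grid.spacing
        assert y[nearest] == pytest.approx(np.exp(-offset**2 / (2 * 50.0**2)))
        assert y.max() == y[nearest]

    def test_zero_amplitude_gives_zero_vector(self, small_grid):
        spec = EndmemberSpec("DKM", ((5100.0, 50.0, 0.0),), "dendrobium")
        assert np.all(evaluate_endmember(spec, small_grid) == 0.0)

    def test_linearity_in_bands(self, small_grid):
        half = EndmemberSpec("DKM", ((5100.0, 50.0, 0.5), (5100.0, 50.0, 0.5)),
                             "dendrobium")
        full = EndmemberSpec("DKM", ((5100.0, 50.0, 1.0),), "dendrobium")
        np.testing.assert_allclose(evaluate_endmember(half, small_grid),
                                   evaluate_endmember(full, small_grid),
                                   rtol=0, atol=1e-300)

    def test_empty_band_list_rejected(self, small_grid):
        spec = EndmemberSpec("DKM", (), "dendrobium")
        with pytest.raises(ValueError, match="no bands"):
            evaluate_endmember(spec, small_grid)


class TestGenerate:
    def test_default_shape(self, dataset42):
        assert dataset42.absorbance.shape == (275, 1557)
        assert dataset42.n_samples == 275

    def test_composition(self, dataset42):
        assert int(dataset42.is_genuine.sum()) == 50
        assert int((dataset42.fraction == 1.0).sum()) == 25
        # 6 pure-class groups, 20 mixture cells
        pure_labels = set(dataset42.label[dataset42.is_pure])
        assert pure_labels == set(synthetic.ALL_CLASSES)
        mix = ~dataset42.is_pure
        cells = set(zip(dataset42.label[mix], dataset42.fraction[mix]))
        assert len(cells) == 20

    def test_deterministic(self, dataset42):
        again = generate(SimulationConfig(seed=42))
        np.testing.assert_array_equal(again.absorbance, dataset42.absorbance)
        assert list(again.label) == list(dataset42.label)

    def test_seed_changes_data(self, dataset42):
        other = generate(SimulationConfig(seed=43))
        assert not np.array_equal(other.absorbance, dataset42.absorbance)

    def test_mixing_identity_without_distortions(self):
        cfg = SimulationConfig(seed=7).noiseless()
        ds = generate(cfg)
        grid = cfg.grid
        pure = {s.class_name: evaluate_endmember(s, grid)
                for s in make_endmembers(cfg.seed)}
        for adulterant in ADULTERANT_CLASSES:
            for f in (0.2, 0.4, 0.6, 0.8):
                row = np.flatnonzero((ds.label == adulterant)
                                     & (ds.fraction == f))[0]
                expected = (1 - f) * pure[GENUINE_CLASS] + f * pure[adulterant]
                np.testing.assert_allclose(ds.absorbance[row], expected,
                                           rtol=0, atol=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimulationConfig(adulteration_fractions=(0.2, 1.0))

    def test_separability_after_snv(self, dataset42):
        # genuine within-class spread < gap to any pure-adulterant centroid
        X = preprocess.snv(dataset42.absorbance)
        genuine = X[dataset42.is_genuine]
        centroid = genuine.mean(axis=0)
        within = np.linalg.norm(genuine - centroid, axis=1).mean()
        gaps = []
        for name in ADULTERANT_CLASSES:
            rows = X[(dataset42.label == name) & (dataset42.fraction == 1.0)]
            gaps.append(np.linalg.norm(rows.mean(axis=0) - centroid))
        assert within < min(gaps)


class TestCsvRoundTrip:
    def test_round_trip(self, dataset42, tmp_path):
        path = tmp_path / "spectra.csv"
        write_csv(dataset42, path)
        back = read_csv(path)
        assert list(back.label) == list(dataset42.label)
        np.testing.assert_array_equal(back.batch, dataset42.batch)
        np.testing.assert_allclose(back.fraction, dataset42.fraction, atol=0)
        np.testing.assert_allclose(back.absorbance, dataset42.absorbance,
                                   rtol=0, atol=1e-10)
        np.testing.assert_allclose(back.grid.values, dataset42.grid.values)

    def test_single_sample(self, dataset42, tmp_path):
        path = tmp_path / "one.csv"
        write_csv(dataset42.subset([0]), path)
        assert read_csv(path).n_samples == 1

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_csv(path)

    def test_ragged_row_reports_index(self, dataset42, tmp_path):
        path = tmp_path / "bad.csv"
        write_csv(dataset42.subset([0, 1]), path)
        lines = path.read_text().splitlines()
        lines[2] = ",".join(lines[2].split(",")[:-3])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            read_csv(path)

    def test_non_monotone_header_rejected(self, dataset42, tmp_path):
        path = tmp_path / "bad.csv"
        write_csv(dataset42.subset([0]), path)
        lines = path.read_text().splitlines()
        cols = lines[0].split(",")
        cols[5], cols[6] = cols[6], cols[5]
        path.write_text("\n".join([",".join(cols)] + lines[1:]) + "\n")
        with pytest.raises(ValueError, match="column"):
            read_csv(path)


class TestSpectraSet:
    def test_length_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            SpectraSet(small_grid, np.zeros((2, small_grid.n_points)),
                       np.array(["a"]), np.zeros(2), np.zeros(2, int),
                       np.array(["s1", "s2"]))

    def test_non_finite_rejected(self, small_grid):
        X = np.zeros((1, small_grid.n_points))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SpectraSet(small_grid, X, np.array(["a"]), np.zeros(1),
                       np.zeros(1, int), np.array(["s"]))

    def test_pair_series_contents(self, dataset42):
        series = dataset42.pair_series("corn")
        assert set(series.label) == {"DKM", "corn"}
        assert series.n_samples == 95

    def test_config_sample_count(self):
        assert SimulationConfig().n_samples == 275
        assert dataclasses.replace(SimulationConfig(),
                                   mixture_replicates=2).n_samples == 115
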