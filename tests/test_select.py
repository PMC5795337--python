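"""PCA fit, loading-peak picking, and emission-line assignment."""

import numpy as np
import pytest
from dataclasses import replace

from libsid.core import EmissionLine, builtin_line_table
from libsid.select import (
    PCAModel,
    SelectionConfig,
    assign_lines,
    pca_fit,
    pick_loading_peaks,
    select_variables,
)
from libsid.presets import mini_sim_config
from libsid.preprocess import WTConfig, preprocess_set
from libsid.simulate import simulate_dataset


class TestPCAFit:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=50)
        gains = rng.uniform(0.5, 2.0, 12)
        X = gains[:, None] * base[None, :]
        model = pca_fit(X, 3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 40))
        model = pca_fit(X, 5)
        np.testing.assert_allclose(model.loadings @ model.loadings.T, np.eye(5), atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        """Explained variances equal the covariance eigenvalues (independent
        oracle: numpy.linalg.eigh on the sample covariance)."""
        X = rng.normal(size=(10, 50))
        model = pca_fit(X, 9)
        cov = np.cov(X, rowvar=False, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ratios = eigvals[:9] / eigvals.sum()
        np.testing.assert_allclose(model.explained_variance_ratio, ratios, atol=1e-10)

    def test_full_rank_ratios_sum_to_one_and_reconstruction(self, rng):
        X = rng.normal(size=(8, 30))
        model = pca_fit(X, 7)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)
        Xc = X - model.mean_spectrum
        recon = model.scores(X) @ model.loadings
        np.testing.assert_allclose(recon, Xc, atol=1e-6 * np.abs(Xc).max())

    def test_degenerate_data_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_fit(np.ones((5, 10)), 2)
        with pytest.raises(ValueError, match="n_components"):
            pca_fit(np.random.default_rng(0).normal(size=(3, 10)), 5)


def _model_from_loadings(loadings):
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    return PCAModel(
        mean_spectrum=np.zeros(loadings.shape[1]),
        loadings=loadings,
        explained_variance_ratio=np.full(loadings.shape[0], 1.0 / loadings.shape[0]),
    )


class TestPickLoadingPeaks:
    def setup_method(self):
        self.grid = np.linspace(0.0, 19.9, 200)  # step 0.1 nm

    def test_single_spike(self):
        loading = np.zeros(200)
        loading[77] = 1.0
        got = pick_loading_peaks(_model_from_loadings(loading), self.grid, SelectionConfig(n_pcs=1))
        assert [v.index for v in got] == [77]

    def test_negative_spike_found_by_magnitude(self):
        loading = np.zeros(200)
        loading[50] = -1.0
        got = pick_loading_peaks(_model_from_loadings(loading), self.grid, SelectionConfig(n_pcs=1))
        assert [v.index for v in got] == [50]
        assert got[0].loading == -1.0

    def test_dedupe_keeps_stronger(self):
        loading = np.zeros(200)
        loading[100] = 1.0
        loading[101] = 0.6  # 0.1 nm away, window 0.3 nm
        got = pick_loading_peaks(_model_from_loadings(loading), self.grid, SelectionConfig(n_pcs=1))
        assert [v.index for v in got] == [100]

    def test_flat_loading_empty(self):
        got = pick_loading_peaks(_model_from_loadings(np.zeros(200)), self.grid, SelectionConfig(n_pcs=1))
        assert got == []

    def test_below_prominence_excluded(self):
        rng = np.random.default_rng(0)
        loading = rng.normal(0.0, 1.0, 200) * 0.5
        loading[120] = 30.0  # ~> 4 sd; background bumps are not
        cfg = SelectionConfig(n_pcs=1, peak_prominence=10.0)
        got = pick_loading_peaks(_model_from_loadings(loading), self.grid, cfg)
        assert [v.index for v in got] == [120]


class TestAssignLines:
    def _cand(self, wl):
        from libsid.select import SelectedVariable

        return SelectedVariable(index=0, wavelength_nm=wl, pc=1, loading=1.0)

    def test_nearest_within_tolerance(self):
        res = assign_lines([self._cand(279.50)], builtin_line_table(), 0.5)
        assert res.variables[0].species == "Mg II"

    def test_unassigned_when_far(self):
        res = assign_lines([self._cand(500.00)], builtin_line_table(), 0.5)
        assert res.variables[0].species == "unassigned"

    def test_equidistant_tie_flags_ambiguous(self):
        lines = [EmissionLine(300.0, "A I"), EmissionLine(300.4, "B I")]
        res = assign_lines([self._cand(300.2)], lines, 0.5)
        assert res.variables[0].species == "A I"
        assert res.variables[0].ambiguous

    def test_empty_line_table_errors(self):
        with pytest.raises(ValueError):
            assign_lines([self._cand(300.0)], [], 0.5)


@pytest.fixture(scope="module")
def calibration():
    sim = replace(mini_sim_config(seed=3), samples_per_variety=2, outlier_fraction=0.0)
    data = simulate_dataset(sim)
    return preprocess_set(data, WTConfig())


class TestSelectVariables:
    def test_recovers_planted_lines(self, calibration):
        res = select_variables(calibration, SelectionConfig(dedupe_window_nm=0.6))
        matched = res.matched_lines(builtin_line_table(), 0.5)
        assert len(matched) == 20
        assert res.species_set() >= {"C I", "Mg II", "Fe I", "Na I"}

    def test_invariant_to_shot_order(self, calibration):
        cfg = SelectionConfig(dedupe_window_nm=0.6)
        a = select_variables(calibration, cfg)
        perm = np.random.default_rng(0).permutation(calibration.n_shots)
        b = select_variables(calibration.subset(perm), cfg)
        assert a.indices().tolist() == b.indices().tolist()

    def test_invariant_to_intensity_doubling(self, calibration):
        cfg = SelectionConfig(dedupe_window_nm=0.6)
        a = select_variables(calibration, cfg)
        b = select_variables(calibration.with_intensities(2.0 * calibration.intensities), cfg)
        assert a.indices().tolist() == b.indices().tolist()

    def test_no_signal_yields_near_empty_selection(self, rng):
        from libsid.core import ShotMeta, SpectrumSet

        grid = np.linspace(246.53, 880.26, 2048)
        X = 1.0 + rng.normal(0.0, 0.01, (24, 2048))
        meta = [ShotMeta(1 + i % 4, f"V{1 + i % 4}S01", f"T{i}") for i in range(24)]
        res = select_variables(SpectrumSet(grid, X, meta), SelectionConfig())
        assert len(res.variables) <= 3

    def test_max_variables_cap(self, calibration):
        res = select_variables(calibration, SelectionConfig(dedupe_window_nm=0.6, max_variables=5))
        assert len(res.variables) == 5
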