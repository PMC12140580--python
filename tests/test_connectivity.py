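"""Wavelet decomposition, windowing, coherence estimation, thresholding."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from dynmod.connectivity import (
    TimeSeriesPanel,
    WindowSpec,
    band_coherence,
    build_multilayer,
    coherence_null_threshold,
    enforce_uniform_sparsity,
    modwt_band_coefficients,
    node_strength,
    scale_passband,
    window_slices,
    _coherence_matrix,
)
from dynmod.connectivity import modwt_decompose
from dynmod.synthetic import CohortConfig, generate_modular_timeseries


class TestMODWT:
    def test_constant_series_has_zero_detail(self):
        w = modwt_band_coefficients(np.full(64, 3.7), scale=1)
        assert np.allclose(w, 0.0)

    def test_scale1_passband_at_tr2(self):
        lo, hi = scale_passband(1, tr=2.0)
        assert hi == pytest.approx(0.25)
        assert lo == pytest.approx(0.125)

    def test_energy_preservation(self, rng):
        """Detail energies across scales plus the final smooth equal the
        total energy of the input (orthonormal MODWT pyramid)."""
        x = rng.standard_normal(1024)
        details, smooth = modwt_decompose(x, level=5)
        energy = sum(float(d @ d) for d in details) + float(smooth @ smooth)
        assert energy == pytest.approx(float(x @ x), rel=1e-6)

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            modwt_band_coefficients(np.ones(3), scale=2)

    def test_rowwise_matches_per_row(self, rng):
        x = rng.standard_normal((4, 128))
        full = modwt_band_coefficients(x, scale=1)
        for i in range(4):
            assert np.allclose(full[i], modwt_band_coefficients(x[i], scale=1))


class TestWindows:
    @pytest.mark.parametrize(
        "T,length,step,expected",
        [(180, 32, 16, 10), (64, 32, 16, 3), (32, 32, 16, 1), (96, 32, 16, 5)],
    )
    def test_window_count(self, T, length, step, expected):
        slices = window_slices(T, WindowSpec(length, step))
        assert len(slices) == expected
        assert slices[0].start == 0
        assert all(s.stop - s.start == length for s in slices)
        assert slices[-1].stop <= T

    def test_default_spec_covers_study_geometry(self):
        slices = window_slices(180, WindowSpec())
        assert (slices[0].start, slices[0].stop) == (0, 32)
        assert (slices[-1].start, slices[-1].stop) == (144, 176)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            window_slices(31, WindowSpec())

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(length=16, step=17)


class TestBandCoherence:
    BAND = (0.125, 0.25)

    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(32)
        assert band_coherence(x, x, self.BAND, 2.0) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(32), rng.standard_normal(32)
        assert band_coherence(x, y, self.BAND, 2.0) == band_coherence(y, x, self.BAND, 2.0)

    def test_circular_delay_preserves_magnitude(self):
        """Magnitude-squared coherence ignores phase: a circularly delayed
        copy of an in-band sinusoid keeps coherence near 1."""
        t = np.arange(32)
        # 0.375 cycles/sample = 0.1875 Hz at tr = 2 s: inside the scale-1 band;
        # weak broadband noise keeps off-tone band bins nondegenerate
        x = np.sin(2 * np.pi * 0.375 * t)
        x = x + 0.05 * np.random.default_rng(8).standard_normal(32)
        y = np.roll(x, 2)
        assert band_coherence(x, y, self.BAND, 2.0) > 0.9

    def test_degenerate_window_errors(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            band_coherence(np.zeros(32), rng.standard_normal(32), self.BAND, 2.0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal(32), rng.standard_normal(32)
            c = band_coherence(x, y, self.BAND, 2.0)
            assert 0.0 <= c <= 1.0

    def test_white_noise_bias_matches_monte_carlo_oracle(self, rng):
        """The Welch coherence of independent noise has a known positive
        small-sample bias; an independent scipy-based Monte-Carlo oracle
        must agree with the implementation's mean within ±0.02."""
        n = 3000
        ours = np.empty(n)
        oracle = np.empty(n)
        for i in range(n):
            x, y = rng.standard_normal(32), rng.standard_normal(32)
            ours[i] = band_coherence(x, y, self.BAND, 2.0)
            f, cxy = sp_signal.coherence(x, y, fs=0.5, window="hann",
                                         nperseg=16, noverlap=8)
            m = (f >= self.BAND[0]) & (f <= self.BAND[1])
            oracle[i] = cxy[m].mean()
        assert abs(ours.mean() - oracle.mean()) < 0.02

    def test_vectorized_matrix_matches_pairwise_scipy(self, rng):
        """The all-pairs coherence path must agree with scipy's pairwise
        estimator to floating-point accuracy."""
        w = rng.standard_normal((5, 32))
        C = _coherence_matrix(w, self.BAND, 2.0)
        for i in range(5):
            for j in range(i + 1, 5):
                assert C[i, j] == pytest.approx(
                    band_coherence(w[i], w[j], self.BAND, 2.0), abs=1e-10
                )
        assert np.allclose(np.diag(C), 0.0)


class TestNullThreshold:
    def test_threshold_in_unit_interval(self, small_config):
        panel, _ = generate_modular_timeseries(small_config, 0)
        thr = coherence_null_threshold(panel, n_iter=300, seed=0)
        assert 0.0 <= thr <= 1.0

    def test_percentile_definition(self, small_config):
        """A fresh draw of null coherences falls below the 95th-percentile
        threshold about 95% of the time."""
        panel, _ = generate_modular_timeseries(small_config, 1)
        thr = coherence_null_threshold(panel, n_iter=2000, seed=0)
        rng = np.random.default_rng(99)
        fresh = coherence_null_threshold(panel, n_iter=2000, percentile=50.0, seed=rng)
        # cheap proxy: the median of a fresh null draw sits well below the
        # 95th percentile of the first
        assert fresh < thr

    def test_small_null_errors(self, small_config):
        panel, _ = generate_modular_timeseries(small_config, 0)
        with pytest.raises(ValueError, match="null too small"):
            coherence_null_threshold(panel, n_iter=50)

    @staticmethod
    def _survival(coupling: float, n_seeds: int = 5) -> float:
        surviving = total = 0
        for seed in range(n_seeds):
            cfg = CohortConfig(
                n_subjects=2, n_regions=8, n_volumes=96, n_modules_planted=2,
                subgroup_sizes={"FF": 2, "SS": 0, "SF": 0},
                coupling_strength_by_profile={"FF": coupling, "SS": 0.3, "SF": 0.5},
                cohesion_rate_by_profile={"FF": 0.0, "SS": 0, "SF": 0},
                disjoint_rate_by_profile={"FF": 0.0, "SS": 0, "SF": 0},
                coupling_jitter=0.0, seed=seed)
            panel, truth = generate_modular_timeseries(cfg, 0)
            thr = coherence_null_threshold(panel, n_iter=500, seed=seed)
            net = build_multilayer(panel, threshold=thr)
            same = truth.partitions[0]
            i, j = np.flatnonzero(same == same[0])[:2]
            surviving += int(np.sum(net.layers[:, i, j] > 0))
            total += net.n_layers
        return surviving / total

    def test_strong_pair_survives_thresholding(self):
        """A near-deterministically coupled planted pair keeps
        supra-threshold coherence in essentially every window; at weaker
        coupling the survival rate is governed by the population band
        coherence ρ² against the null threshold, so it falls off but
        stays well above chance and ordered in ρ."""
        assert self._survival(0.95) >= 0.99
        s_med = self._survival(0.8)
        assert 0.6 <= s_med < 1.0
        assert self._survival(0.95) > s_med


class TestBuildMultilayer:
    def test_maximal_threshold_gives_empty_layers(self, small_config):
        panel, _ = generate_modular_timeseries(small_config, 0)
        net = build_multilayer(panel, threshold=1.0)
        assert net.sparsity == 1.0
        assert np.all(net.layers == 0)

    def test_zero_threshold_keeps_everything(self, small_config):
        panel, _ = generate_modular_timeseries(small_config, 0)
        net = build_multilayer(panel, threshold=0.0)
        assert net.sparsity == pytest.approx(0.0)

    def test_planted_modules_have_stronger_within_edges(self, small_config):
        panel, truth = generate_modular_timeseries(small_config, 0)
        net = build_multilayer(panel)
        for l in range(net.n_layers):
            labels = truth.partitions[l]
            same = labels[:, None] == labels[None, :]
            off = ~np.eye(net.n_regions, dtype=bool)
            within = net.layers[l][same & off].mean()
            between = net.layers[l][~same].mean()
            assert within > between

    def test_region_permutation_equivariance(self, small_config):
        panel, _ = generate_modular_timeseries(small_config, 0)
        perm = np.random.default_rng(3).permutation(panel.n_regions)
        net = build_multilayer(panel)
        panel_p = TimeSeriesPanel(data=panel.data[perm], tr=panel.tr)
        net_p = build_multilayer(panel_p)
        assert np.allclose(net_p.layers, net.layers[:, perm][:, :, perm], atol=1e-10)


class TestNodeStrength:
    def test_empty_network_is_zero(self, make_net):
        net = make_net(density=0.5)
        net.layers[:] = 0
        per_region, scalar = node_strength(net)
        assert np.all(per_region == 0) and scalar == 0

    def test_complete_graph_closed_form(self):
        from dynmod.connectivity import MultilayerNetwork
        n = 7
        layers = np.ones((3, n, n)) - np.eye(n)
        net = MultilayerNetwork(layers=layers, window=WindowSpec(4, 4), band=(0.1, 0.2))
        per_region, scalar = node_strength(net)
        assert np.allclose(per_region, n - 1)
        assert scalar == pytest.approx(n - 1)

    def test_matches_row_sum_oracle(self, make_net):
        net = make_net(n_layers=3, n_regions=10)
        per_region, scalar = node_strength(net)
        oracle = np.mean([[net.layers[l][i].sum() for i in range(10)]
                          for l in range(3)], axis=0)
        assert np.allclose(per_region, oracle)
        assert scalar == pytest.approx(oracle.mean())


class TestUniformSparsity:
    def test_density_one_is_identity(self, make_net):
        net = make_net(n_layers=2, n_regions=8, density=0.6)
        out = enforce_uniform_sparsity(net, 1.0)
        assert np.allclose(out.layers, net.layers)

    def test_realized_density_near_target(self, make_net):
        net = make_net(n_layers=2, n_regions=12, density=1.0)
        out = enforce_uniform_sparsity(net, 0.15)
        n_pairs = 12 * 11 // 2
        target = int(np.ceil(0.15 * n_pairs))
        for l in range(2):
            kept = np.count_nonzero(np.triu(out.layers[l], 1))
            assert abs(kept - target) <= 1

    def test_thresholding_monotone_in_strength(self, make_net):
        """Raising the retained density never decreases any node strength."""
        net = make_net(n_layers=2, n_regions=10, density=1.0)
        s_low, _ = node_strength(enforce_uniform_sparsity(net, 0.2))
        s_high, _ = node_strength(enforce_uniform_sparsity(net, 0.6))
        assert np.all(s_high >= s_low - 1e-12)


class TestPanelValidation:
    def test_rows_renormalized(self, rng):
        data = 5 + 3 * rng.standard_normal((4, 64))
        panel = TimeSeriesPanel(data=data, tr=2.0)
        assert np.allclose(panel.data.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(panel.data.std(axis=1), 1, atol=1e-8)

    def test_constant_row_rejected(self):
        data = np.vstack([np.ones(64), np.arange(64.0)])
        with pytest.raises(ValueError, match="zero variance"):
            TimeSeriesPanel(data=data, tr=2.0)

    def test_nan_rejected(self, rng):
        data = rng.standard_normal((3, 64))
        data[1, 5] = np.nan
        with pytest.raises(ValueError, match="missing"):
            TimeSeriesPanel(data=data, tr=2.0)
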