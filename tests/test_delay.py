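import numpy as np
import pytest
from scipy import stats

from grnlag.delay import (
    DelayCorrelationMatrix,
    WindowConfig,
    build_delay_matrix,
    default_window_config,
    plot_delay_heatmap,
    required_cells,
    segment_bounds,
)
from grnlag.synthetic import SyntheticConfig, simulate_dataset


def naive_delay_matrix(tf_row, target_row, cfg):
    """Independent oracle: per-entry Pearson via scipy on explicit slices."""
    M = np.zeros((cfg.p, cfg.q))
    for k in range(1, cfg.p + 1):
        for l in range(1, cfg.q + 1):
            (a, b), (c, d) = segment_bounds(k, l, cfg)
            x = tf_row[a - 1 : b]
            y = target_row[c - 1 : d]
            if np.std(x) == 0 or np.std(y) == 0:
                M[k - 1, l - 1] = 0.0
            else:
                M[k - 1, l - 1] = stats.pearsonr(x, y).statistic
    return M


class TestSegmentBounds:
    def test_printed_index_arithmetic(self):
        cfg = WindowConfig(p=4, q=4, m=2, n=2, w=3)
        tf, tgt = segment_bounds(2, 2, cfg)
        assert tf == (3, 5)
        assert tgt == (5, 7)

    def test_zero_offset_case(self):
        cfg = WindowConfig(p=2, q=2, m=1, n=1, w=5)
        tf, tgt = segment_bounds(1, 1, cfg)
        assert tf == (1, 5) and tgt == (1, 5)

    def test_last_segment_reaches_published_cell_count(self):
        cfg = WindowConfig(p=64, q=64, m=5, n=5, w=441)
        _, tgt = segment_bounds(64, 64, cfg)
        assert tgt[1] == 1071

    def test_out_of_range_indices(self):
        cfg = WindowConfig(p=2, q=2, m=1, n=1, w=3)
        with pytest.raises(ValueError):
            segment_bounds(3, 1, cfg)
        with pytest.raises(ValueError):
            segment_bounds(1, 0, cfg)

    def test_segment_lengths_always_w(self, rng):
        for _ in range(20):
            cfg = WindowConfig(
                p=int(rng.integers(1, 6)), q=int(rng.integers(1, 6)),
                m=int(rng.integers(1, 4)), n=int(rng.integers(1, 4)),
                w=int(rng.integers(3, 10)),
            )
            k = int(rng.integers(1, cfg.p + 1))
            l = int(rng.integers(1, cfg.q + 1))
            (a, b), (c, d) = segment_bounds(k, l, cfg)
            assert b - a + 1 == cfg.w and d - c + 1 == cfg.w
            assert c - a == (l - 1) * cfg.n  # target lags the TF


class TestRequiredCells:
    def test_published_configuration(self):
        assert required_cells(WindowConfig(p=64, q=64, m=5, n=5, w=441)) == 1071

    def test_single_window(self):
        assert required_cells(WindowConfig(p=1, q=1, m=1, n=1, w=7)) == 7

    def test_equals_max_segment_end_over_all_indices(self, rng):
        for _ in range(20):
            cfg = WindowConfig(
                p=int(rng.integers(1, 6)), q=int(rng.integers(1, 6)),
                m=int(rng.integers(1, 5)), n=int(rng.integers(1, 5)),
                w=int(rng.integers(3, 12)),
            )
            ends = [
                segment_bounds(k, l, cfg)[1][1]
                for k in range(1, cfg.p + 1)
                for l in range(1, cfg.q + 1)
            ]
            assert required_cells(cfg) == max(ends)


class TestDefaultWindowConfig:
    def test_published_cell_count_recovers_published_width(self):
        cfg = default_window_config(1071)
        assert (cfg.p, cfg.q, cfg.m, cfg.n, cfg.w) == (64, 64, 5, 5, 441)

    def test_boundary_feasibility(self):
        p = q = 4
        m = n = 2
        T = (p - 1) * m + (q - 1) * n + 3
        cfg = default_window_config(T, p=p, q=q, m=m, n=n)
        assert cfg.w == 3

    @pytest.mark.parametrize("T", [25, 100, 240, 600, 1071, 2000])
    def test_emitted_configs_fit_trajectory(self, T):
        cfg = default_window_config(T)
        assert required_cells(cfg) <= T

    def test_too_small_trajectory_raises(self):
        with pytest.raises(ValueError):
            default_window_config(2)


class TestBuildDelayMatrix:
    def test_identical_rows_give_unit_zero_lag_column(self, rng):
        row = rng.random(40)
        cfg = WindowConfig(p=4, q=4, m=3, n=3, w=10)
        M = build_delay_matrix(row, row, cfg)
        np.testing.assert_allclose(M.values[:, 0], 1.0, atol=1e-12)

    def test_constant_target_yields_zero_matrix(self, rng):
        cfg = WindowConfig(p=3, q=3, m=2, n=2, w=5)
        M = build_delay_matrix(rng.random(required_cells(cfg)), np.full(required_cells(cfg), 2.0), cfg)
        np.testing.assert_array_equal(M.values, 0.0)

    def test_matches_naive_double_loop(self, rng):
        cfg = WindowConfig(p=8, q=8, m=2, n=2, w=11)
        T = required_cells(cfg)
        for _ in range(5):
            tf = rng.standard_normal(T)
            tgt = rng.standard_normal(T)
            M = build_delay_matrix(tf, tgt, cfg)
            np.testing.assert_allclose(M.values, naive_delay_matrix(tf, tgt, cfg), atol=1e-10)

    def test_short_trajectory_raises_with_requirement(self):
        cfg = WindowConfig(p=4, q=4, m=2, n=2, w=10)
        with pytest.raises(ValueError, match=str(required_cells(cfg))):
            build_delay_matrix(np.ones(5), np.ones(5), cfg)

    def test_affine_invariance_of_full_rows(self, rng):
        cfg = WindowConfig(p=5, q=4, m=2, n=3, w=8)
        T = required_cells(cfg)
        tf = rng.standard_normal(T)
        tgt = rng.standard_normal(T)
        base = build_delay_matrix(tf, tgt, cfg).values
        shifted = build_delay_matrix(2.5 * tf + 7.0, 0.3 * tgt - 4.0, cfg).values
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_swapping_rows_is_not_a_transpose(self):
        """The delay is one-sided, so M(i,j) and M(j,i) differ in general."""
        cfg = WindowConfig(p=4, q=4, m=2, n=2, w=8)
        T = required_cells(cfg)
        t = np.arange(T, dtype=float)
        tf = np.sin(2 * np.pi * t / 20)
        tgt = np.roll(tf, 6)  # target lags the TF by 6 cells
        M_fwd = build_delay_matrix(tf, tgt, cfg).values
        M_rev = build_delay_matrix(tgt, tf, cfg).values
        assert not np.allclose(M_fwd, M_rev.T, atol=1e-3)

    def test_entries_clamped_to_unit_interval(self, rng):
        cfg = WindowConfig(p=6, q=6, m=1, n=1, w=3)
        M = build_delay_matrix(rng.random(required_cells(cfg)), rng.random(required_cells(cfg)), cfg)
        assert M.values.min() >= -1.0 and M.values.max() <= 1.0


class TestLagRecovery:
    @pytest.mark.parametrize("tau,n_step", [(4, 2), (8, 2), (6, 3), (12, 3), (10, 5)])
    def test_noiseless_planted_lag_argmax(self, tau, n_step):
        """With zero noise, the strongest mean correlation sits at delay
        column 1 + tau/n (1-based), i.e. offset tau/n with 0-based columns."""
        cfg = SyntheticConfig(
            n_genes=8, n_cells=200, n_tfs=2, n_edges=2,
            lag_range=(tau, tau), noise_sd=0.0, seed=11,
        )
        expr, net = simulate_dataset(cfg)
        wcfg = WindowConfig(p=8, q=10, m=n_step, n=n_step, w=100)
        index = {g: i for i, g in enumerate(expr.gene_ids)}
        for (tf, tgt), lag in net.lags.items():
            assert lag == tau
            M = build_delay_matrix(expr.values[index[tf]], expr.values[index[tgt]], wcfg)
            col_means = M.values.mean(axis=0)
            assert int(np.argmax(col_means)) == tau // n_step


class TestHeatmap:
    def test_writes_image_file(self, tmp_path, rng):
        cfg = WindowConfig(p=4, q=4, m=2, n=2, w=5)
        T = required_cells(cfg)
        M = build_delay_matrix(rng.random(T), rng.random(T), cfg)
        out = tmp_path / "pair.png"
        plot_delay_heatmap(M, str(out))
        assert out.stat().st_size > 0

    def test_invalid_entries_rejected_by_type(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            DelayCorrelationMatrix("a", "b", np.array([[0.0, 2.0], [0.0, 0.0]]))
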