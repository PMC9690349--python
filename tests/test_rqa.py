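import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermorqa.io_sensors import ValidationError
from thermorqa.rqa import (
    DegenerateSeriesError,
    EmbeddingConfig,
    LineDistributions,
    RecurrencePlot,
    RQAConfig,
    compute_metrics,
    embed,
    extract_lines,
    recurrence_plot,
    rqa_pipeline,
)
from _reference import reference_embed, reference_rqa

HYP = settings(derandomize=True, max_examples=30, deadline=None)


def make_rp(matrix, r_frac=0.1):
    m = np.asarray(matrix, dtype=bool)
    return RecurrencePlot(matrix=m, radius=1.0, mean_distance=10.0, radius_fraction=r_frac)


class TestEmbed:
    def test_worked_example_dimension_three(self):
        s = [10, 11, 21, 32, 41, 35, 40, 19]
        em = embed(np.array(s, float), EmbeddingConfig(3, 1))
        assert em.shape == (6, 3)
        assert em[0].tolist() == [10, 11, 21]
        assert em[2].tolist() == [21, 32, 41]
        assert em[5].tolist() == [35, 40, 19]

    def test_dimension_one_is_identity(self, rng):
        x = rng.normal(size=17)
        em = embed(x, EmbeddingConfig(1, 3))
        assert em.shape == (17, 1)
        assert np.array_equal(em[:, 0], x)

    def test_too_short_error_states_minimum(self):
        with pytest.raises(ValidationError, match="minimum length is 7"):
            embed(np.arange(6, dtype=float), EmbeddingConfig(4, 2))

    @HYP
    @given(n=st.integers(5, 60), p=st.integers(1, 4), lag=st.integers(1, 4))
    def test_vector_count_matches_sliding_window_enumeration(self, n, p, lag):
        if n < (p - 1) * lag + 1:
            return
        x = np.sin(np.arange(n, dtype=float))
        em = embed(x, EmbeddingConfig(p, lag))
        ref = reference_embed(list(x), p, lag)
        assert em.shape[0] == len(ref)
        assert [tuple(row) for row in em] == ref


class TestRecurrencePlot:
    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError, match="zero mean distance"):
            recurrence_plot(embed(np.full(30, 35.0)), RQAConfig())

    def test_two_points_no_offdiagonal_recurrence(self):
        em = np.array([[0.0], [3.0]])
        rp = recurrence_plot(em, RQAConfig(radius_fraction=0.1, border=0))
        assert rp.mean_distance == 3.0
        assert rp.matrix.tolist() == [[True, False], [False, True]]

    def test_matrix_matches_all_pairs_scan(self, rng):
        x = rng.normal(size=50)
        rp = recurrence_plot(embed(x), RQAConfig())
        ref = reference_rqa(x, p=2, lag=1)
        assert rp.matrix.tolist() == ref["matrix"]
        assert rp.mean_distance == pytest.approx(ref["mean_distance"], rel=1e-12)

    def test_tiled_path_equals_direct_path(self, rng, monkeypatch):
        import thermorqa.rqa as rqa_mod
        x = rng.normal(size=300)
        em = embed(x)
        direct = recurrence_plot(em, RQAConfig())
        monkeypatch.setattr(rqa_mod, "_TILE_THRESHOLD", 100)
        monkeypatch.setattr(rqa_mod, "_TILE_ROWS", 64)
        tiled = recurrence_plot(em, RQAConfig())
        assert np.array_equal(direct.matrix, tiled.matrix)
        assert direct.radius == pytest.approx(tiled.radius, rel=1e-12)

    @HYP
    @given(seed=st.integers(0, 1000))
    def test_symmetric_with_unit_diagonal(self, seed):
        x = np.random.default_rng(seed).normal(size=40)
        rp = recurrence_plot(embed(x), RQAConfig())
        assert np.array_equal(rp.matrix, rp.matrix.T)
        assert rp.matrix.diagonal().all()

    @HYP
    @given(seed=st.integers(0, 500), c_exp=st.integers(-3, 6))
    def test_scale_invariance_of_radius_rule(self, seed, c_exp):
        x = np.random.default_rng(seed).normal(size=45)
        c = 2.0 ** c_exp
        a = recurrence_plot(embed(x), RQAConfig())
        b = recurrence_plot(embed(c * x), RQAConfig())
        assert np.array_equal(a.matrix, b.matrix)

    @HYP
    @given(seed=st.integers(0, 500), lo=st.floats(0.02, 0.3), hi=st.floats(0.02, 0.3))
    def test_rec_monotone_in_radius_fraction(self, seed, lo, hi):
        if lo > hi:
            lo, hi = hi, lo
        x = np.random.default_rng(seed).normal(size=45)
        em = embed(x)
        cfg_lo, cfg_hi = RQAConfig(radius_fraction=lo), RQAConfig(radius_fraction=hi)
        m_lo = compute_metrics(*(lambda rp: (rp, extract_lines(rp, cfg_lo)))(recurrence_plot(em, cfg_lo)), cfg_lo)
        m_hi = compute_metrics(*(lambda rp: (rp, extract_lines(rp, cfg_hi)))(recurrence_plot(em, cfg_hi)), cfg_hi)
        assert m_hi.REC >= m_lo.REC


class TestExtractLines:
    def test_single_offdiagonal_run_counted_with_mirror(self):
        n = 12
        m = np.eye(n, dtype=bool)
        for i in range(3, 8):  # diagonal k=2 run of length 5, clear of the border
            m[i, i + 2] = m[i + 2, i] = True
        ld = extract_lines(make_rp(m), RQAConfig(border=2))
        assert ld.diagonal_hist == {5: 2}
        assert ld.lmax == 5

    def test_isolated_recurrences_have_no_lines(self):
        # points spaced two apart: no adjacency along columns or diagonals
        n = 10
        idx = np.indices((n, n))
        m = (idx[0] % 2 == 0) & (idx[1] % 2 == 0)
        ld = extract_lines(make_rp(m), RQAConfig(border=0))
        assert ld.diagonal_hist == {} and ld.vertical_hist == {}
        assert ld.lmax == 0

    def test_border_cells_ignored(self):
        n = 8
        m = np.ones((n, n), dtype=bool)
        ld0 = extract_lines(make_rp(m), RQAConfig(border=0))
        ld2 = extract_lines(make_rp(m), RQAConfig(border=2))
        assert max(ld0.diagonal_hist) == n - 1
        # only the 4x4 interior survives; its longest off-LOI diagonal has 3 cells
        assert max(ld2.diagonal_hist) == (n - 2 * 2) - 1
        assert ld2.n_recurrent_offdiag == 4 * 4 - 4

    def test_random_matrix_matches_runlength_scanner(self, rng):
        x = rng.normal(size=42)
        rp = recurrence_plot(embed(x), RQAConfig())
        ld = extract_lines(rp, RQAConfig())
        ref = reference_rqa(x)
        assert dict(ld.diagonal_hist) == ref["diagonal_hist"]
        assert dict(ld.vertical_hist) == ref["vertical_hist"]
        assert ld.lmax == ref["lmax"]
        assert ld.n_recurrent_offdiag == ref["n_offdiag"]


class TestMetrics:
    def test_equal_line_lengths_give_zero_entropy(self):
        ld = LineDistributions(diagonal_hist={4: 6}, vertical_hist={3: 2}, lmax=4,
                               n_recurrent_offdiag=40, n_loi_in_vertical_runs=0,
                               diag_counts=np.zeros(9, dtype=np.int64))
        m = compute_metrics(make_rp(np.eye(10, dtype=bool)), ld)
        assert m.ENT == 0.0

    def test_div_is_inverse_lmax(self):
        ld = LineDistributions(diagonal_hist={200: 2, 5: 4}, vertical_hist={},
                               lmax=200, n_recurrent_offdiag=500,
                               n_loi_in_vertical_runs=0,
                               diag_counts=np.zeros(299, dtype=np.int64))
        with pytest.warns(UserWarning):
            m = compute_metrics(make_rp(np.eye(300, dtype=bool)), ld)
        assert m.DIV == pytest.approx(0.005)
        assert m.DIV * m.Lmax == pytest.approx(1.0)

    def test_fully_lined_matrix_has_det_one(self):
        # two parallel full diagonals: every off-diagonal recurrence in a run
        n, b = 14, 2
        m = np.eye(n, dtype=bool)
        for i in range(n - 3):
            m[i, i + 3] = m[i + 3, i] = True
        cfg = RQAConfig(border=b)
        ld = extract_lines(make_rp(m), cfg)
        metrics = compute_metrics(make_rp(m), ld, cfg)
        assert metrics.DET == pytest.approx(1.0)

    def test_trend_zero_for_constant_diagonal_density(self):
        n = 30
        m = np.ones((n, n), dtype=bool)  # every diagonal fully recurrent
        cfg = RQAConfig(border=0)
        ld = extract_lines(make_rp(m), cfg)
        metrics = compute_metrics(make_rp(m), ld, cfg)
        assert abs(metrics.TRE) < 1e-12

    def test_no_recurrences_yields_missing_with_warning(self):
        m = np.eye(20, dtype=bool)
        cfg = RQAConfig()
        with pytest.warns(UserWarning, match="DET/LAM undefined"):
            metrics = compute_metrics(make_rp(m), extract_lines(make_rp(m), cfg), cfg)
        assert math.isnan(metrics.DET) and math.isnan(metrics.LAM)

    def test_lam_equal_on_rows_and_columns(self, rng):
        x = rng.normal(size=60)
        cfg = RQAConfig()
        rp = recurrence_plot(embed(x), cfg)
        transposed = RecurrencePlot(matrix=rp.matrix.T.copy(), radius=rp.radius,
                                    mean_distance=rp.mean_distance,
                                    radius_fraction=rp.radius_fraction)
        m1 = compute_metrics(rp, extract_lines(rp, cfg), cfg)
        m2 = compute_metrics(transposed, extract_lines(transposed, cfg), cfg)
        assert m1.LAM == m2.LAM
        for key, v1 in m1.as_dict().items():
            v2 = m2.as_dict()[key]
            assert v1 == v2 or (math.isnan(v1) and math.isnan(v2)), key


class TestPipeline:
    def test_full_oracle_agreement_on_simulated_series(self, rng):
        x = np.cumsum(rng.normal(size=60))
        metrics = rqa_pipeline(x)
        ref = reference_rqa(x)["metrics"]
        for name, val in ref.items():
            got = getattr(metrics, name)
            assert got == pytest.approx(val, rel=1e-9, nan_ok=True), name

    def test_periodic_signal_more_deterministic_than_noise(self):
        t = np.arange(1440, dtype=float)
        g = np.random.default_rng(2024)
        sine = np.sin(2 * np.pi * t / 240) + 0.05 * g.normal(size=t.size)
        noise = np.random.default_rng(2024).normal(size=t.size)
        m_sine = rqa_pipeline(sine)
        m_noise = rqa_pipeline(noise)
        assert m_sine.DET > 0.5
        assert m_sine.DET > m_sine.REC
        assert m_noise.DET < m_sine.DET

    def test_deterministic_bitwise(self, rng):
        x = rng.normal(size=200)
        a, b = rqa_pipeline(x), rqa_pipeline(x)
        assert a.as_dict() == b.as_dict()

    def test_worked_series_runs_without_error(self):
        s = np.array([10, 11, 21, 32, 41, 35, 40, 19], float)
        with pytest.warns(UserWarning):
            m = rqa_pipeline(s, EmbeddingConfig(3, 1))
        assert m.n_vectors == 6
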