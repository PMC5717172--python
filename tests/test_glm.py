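"""Prewhitening, least squares, best-LR mapping, sub-session splitting."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lrspectrum.glm import (estimate_ar1, fit_glm, map_best_lr, prewhiten,
                            split_subsessions, subsession_segments)
from lrspectrum.regressors import RegressorBank
from lrspectrum.simulate import (RegionSpec, make_region_layout,
                                 synthesize_bold)


class TestPrewhiten:
    def test_white_noise_transform_near_identity(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(400), rng.standard_normal(400)])
        y = rng.standard_normal(400)
        yw, Xw, phi = prewhiten(y, X)
        assert abs(phi) < 0.1
        assert np.corrcoef(yw, y)[0, 1] > 0.98

    def test_whitening_removes_ar1_autocorrelation(self):
        rng = np.random.default_rng(1)
        n, phi_true = 2000, 0.4
        eps = rng.standard_normal(n)
        y = np.empty(n)
        y[0] = eps[0]
        for t in range(1, n):
            y[t] = phi_true * y[t - 1] + eps[t]
        X = np.ones((n, 1))
        yw, Xw, phi = prewhiten(y, X)
        assert abs(phi - phi_true) < 0.08
        resid = yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]
        assert abs(estimate_ar1(resid)) < 0.08

    def test_matches_dense_gls_oracle(self):
        # whitened OLS must equal closed-form GLS with the AR(1) covariance
        rng = np.random.default_rng(2)
        n, phi = 50, 0.6
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        yw, Xw, _ = prewhiten(y, X, phi=phi)
        beta_white = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        ij = np.arange(n)
        Sigma = phi ** np.abs(ij[:, None] - ij[None, :]) / (1 - phi ** 2)
        Si = np.linalg.inv(Sigma)
        beta_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        np.testing.assert_allclose(beta_white, beta_gls, rtol=1e-8)

    def test_extreme_ar1_clipped_with_warning(self):
        ramp = np.linspace(0, 1, 1000)   # near-unit-root smooth series
        with pytest.warns(UserWarning, match="clipped"):
            phi = estimate_ar1(ramp)
        assert abs(phi) <= 0.97


class TestFitGLM:
    def test_recovers_single_column(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        res = fit_glm(X[:, 2], X)
        np.testing.assert_allclose(res.betas, [0, 0, 1, 0], atol=1e-10)
        assert res.RSS == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_target_gives_zero_betas(self):
        n = 64
        X = np.column_stack([np.ones(n), np.sin(2 * np.pi * np.arange(n) / 8)])
        y = np.cos(2 * np.pi * np.arange(n) * 3 / n)   # orthogonal harmonics
        res = fit_glm(y, X)
        np.testing.assert_allclose(res.betas, 0.0, atol=1e-10)
        assert res.RSS == pytest.approx(float(y @ y))

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        res = fit_glm(y, X)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.betas, beta_oracle, rtol=1e-10)
        assert res.residuals @ X == pytest.approx(np.zeros(3), abs=1e-9)

    def test_rank_deficiency_drops_column(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        X = np.column_stack([X, X[:, 0]])   # duplicate
        with pytest.warns(UserWarning, match="rank deficient"):
            res = fit_glm(rng.standard_normal(30), X)
        assert res.k == 3
        assert len(res.betas) == 4

    def test_needs_more_volumes_than_columns(self):
        with pytest.raises(ValueError):
            fit_glm(np.zeros(3), np.eye(3))

    def test_adding_true_regressor_never_increases_rss(self, demo_design,
                                                       demo_bank30):
        rng = np.random.default_rng(6)
        y = (demo_bank30.X_value[:, 11]
             + 0.5 * rng.standard_normal(demo_design.n_volumes))
        rss_base = fit_glm(y, demo_design.values).RSS
        rss_full = fit_glm(y, np.column_stack(
            [demo_design.values, demo_bank30.X_value[:, [11]]])).RSS
        assert rss_full <= rss_base


class TestMapBestLR:
    def test_noiseless_voxel_recovered(self, demo_design, demo_bank30):
        # the unit-amplitude fit at the true rank is exact; the argmax can
        # land on an immediate neighbor because the PE co-regressor lets a
        # neighbor's partial beta exceed 1 by a hair (suppressor effect)
        y = demo_bank30.X_value[:, 11]   # rank 12
        m = map_best_lr(y, demo_design, demo_bank30, whiten=False)
        assert abs(int(m.best_rank[0]) - 12) <= 1
        assert m.all_betas[0, 11] == pytest.approx(1.0, abs=1e-8)
        assert m.best_beta[0] == pytest.approx(1.0, abs=0.01)

    def test_tie_broken_toward_lower_rank(self, demo_design, demo_bank30):
        # a bank with duplicated columns produces exactly tying betas
        Xv = demo_bank30.X_value.copy()
        Xv[:, 6] = Xv[:, 2]
        Xp = demo_bank30.X_pe.copy()
        Xp[:, 6] = Xp[:, 2]
        bank = RegressorBank(alphas=demo_bank30.alphas, X_value=Xv, X_pe=Xp,
                             TR=demo_bank30.TR)
        y = Xv[:, 2] + 0.1 * demo_design.values[:, 0]
        m = map_best_lr(y, demo_design, bank, whiten=False)
        assert m.best_rank[0] == 3

    def test_pure_noise_spreads_over_many_ranks(self, demo_design,
                                                demo_bank30):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((300, demo_design.n_volumes))
        m = map_best_lr(Y, demo_design, demo_bank30, whiten=False)
        counts = np.bincount(m.best_rank, minlength=31)[1:]
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert entropy > 3.0

    def test_invariant_to_voxel_order(self, demo_design, demo_bank30):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((20, demo_design.n_volumes))
        Y[:, :] += demo_bank30.X_value[:, 5]
        m1 = map_best_lr(Y, demo_design, demo_bank30)
        m2 = map_best_lr(Y[::-1], demo_design, demo_bank30)
        np.testing.assert_array_equal(m1.best_rank, m2.best_rank[::-1])

    def test_abs_criterion_flag(self, demo_design, demo_bank30):
        y = -demo_bank30.X_value[:, 20]
        m_abs = map_best_lr(y, demo_design, demo_bank30, whiten=False,
                            criterion="abs")
        assert abs(int(m_abs.best_rank[0]) - 21) <= 2
        assert m_abs.all_betas[0, 20] == pytest.approx(-1.0, abs=1e-8)
        # the signed criterion would never pick a strongly negative beta
        m_signed = map_best_lr(y, demo_design, demo_bank30, whiten=False)
        assert m_signed.all_betas[0, m_signed.best_rank[0] - 1] > -0.9


class TestRecovery:
    @pytest.fixture(scope="class")
    @staticmethod
    def region(demo_bank30):
        layout = make_region_layout(
            [RegionSpec("regionA", shape=(5, 10, 4), gradient_slope=2.5,
                        intercept_rank=4.0, rank_jitter_sd=3.0)], seed=13)
        return layout

    def test_rank_recovery_at_default_snr(self, region, demo_design,
                                          demo_bank30):
        ds = synthesize_bold(region, demo_bank30, value_r2=0.08, seed=14)
        m = map_best_lr(ds.Y, demo_design, demo_bank30)
        err = np.mean(np.abs(m.best_rank - region.gen_lr_rank))
        rho = spearmanr(m.best_rank, region.gen_lr_rank).statistic
        assert err < 5.0
        assert rho > 0.6

    def test_recovery_error_monotone_in_snr(self, region, demo_design,
                                            demo_bank30):
        errs = []
        for r2 in (0.02, 0.08, 0.3):
            ds = synthesize_bold(region, demo_bank30, value_r2=r2, seed=15)
            m = map_best_lr(ds.Y, demo_design, demo_bank30)
            errs.append(np.mean(np.abs(m.best_rank - region.gen_lr_rank)))
        assert errs[0] > errs[1] > errs[2]


class TestSubsessionSplit:
    def test_boundary_volume_arithmetic(self, demo_session):
        segs = subsession_segments(demo_session)
        first = segs[demo_session.schedule.subsession_label[0]]
        last_out = demo_session.outcome_onset[first["trials"]].max()
        v_containing = int(np.floor(last_out / demo_session.TR))
        assert first["volumes"].stop == v_containing + 3   # +2 extra volumes

    def test_segments_disjoint_and_cover_scan(self, demo_session):
        segs = subsession_segments(demo_session)
        sls = [s["volumes"] for s in segs.values()]
        stops = sorted((sl.start, sl.stop) for sl in sls)
        assert stops[0][0] == 0
        assert stops[0][1] == stops[1][0]
        assert stops[1][1] == demo_session.n_volumes

    def test_split_is_deterministic_and_matches_slices(self, demo_session):
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((4, demo_session.n_volumes))
        a = split_subsessions(Y, demo_session)
        b = split_subsessions(Y, demo_session)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
        assert a["stable"].shape[1] + a["volatile"].shape[1] \
            == demo_session.n_volumes

    def test_short_segment_rejected(self, demo_session):
        Y = np.zeros((1, demo_session.n_volumes))
        with pytest.raises(ValueError, match="too short"):
            split_subsessions(Y, demo_session, min_volumes=10 ** 6)
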