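"""SVD compression, AIC, and group Bayesian model selection."""

import numpy as np
import pytest

from lrspectrum.evidence import (aic_score, component_regressors,
                                 evidence_map, exceedance_probability,
                                 rfx_bms, svd_components)
from lrspectrum.glm import GLMResult, fit_glm
from lrspectrum.regressors import build_design_matrix
from lrspectrum.simulate import (RegionSpec, make_nuisance,
                                 make_region_layout, synthesize_bold)
from lrspectrum.value import LR_GRID_FULL, compute_value_traces


class TestSVD:
    def test_rank_one_matrix(self):
        M = np.outer(np.sin(np.linspace(0, 6, 50)), np.linspace(1, 2, 9))
        M = M - M.mean(axis=0)
        res = svd_components(M, m=1)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((40, 8))
        Mc = M - M.mean(axis=0)
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        np.testing.assert_allclose(U @ np.diag(s) @ Vt, Mc, atol=1e-10)

    def test_rejects_m_beyond_rank(self):
        M = np.outer(np.arange(20.0), np.ones(5))
        with pytest.raises(ValueError, match="rank"):
            svd_components(M, m=3)

    def test_value_traces_compress_to_three_components(self, demo_session):
        tr = compute_value_traces(demo_session, LR_GRID_FULL)
        res = svd_components(tr.p_chosen, m=3)
        assert res.top_fraction > 0.98
        # components orthonormal
        G = res.components.T @ res.components
        np.testing.assert_allclose(G, np.eye(3), atol=1e-10)

    def test_variance_fractions_sum_to_one_nonincreasing(self, demo_session):
        tr = compute_value_traces(demo_session, LR_GRID_FULL)
        res = svd_components(tr.p_chosen, m=3)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)


class TestAIC:
    def test_equal_rss_delta_is_twice_k_difference(self):
        a = GLMResult(betas=np.zeros(3), RSS=10.0, n=100, k=3,
                      residuals=np.zeros(100))
        b = GLMResult(betas=np.zeros(4), RSS=10.0, n=100, k=4,
                      residuals=np.zeros(100))
        assert aic_score(b) - aic_score(a) == pytest.approx(2.0)

    def test_hand_computation(self):
        res = GLMResult(betas=np.zeros(2), RSS=5.0, n=10, k=2,
                        residuals=np.zeros(10))
        assert aic_score(res) == pytest.approx(10 * np.log(0.5) + 6)

    def test_zero_rss_floored_with_warning(self):
        res = GLMResult(betas=np.zeros(2), RSS=0.0, n=10, k=2,
                        residuals=np.zeros(10))
        with pytest.warns(UserWarning, match="floored"):
            val = aic_score(res)
        assert np.isfinite(val)

    def test_noise_columns_increase_aic_in_expectation(self):
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(100):
            X = np.column_stack([np.ones(60), rng.standard_normal((60, 2))])
            y = X[:, 1] + rng.standard_normal(60)
            X_extra = np.column_stack([X, rng.standard_normal((60, 3))])
            deltas.append(aic_score(fit_glm(y, X_extra))
                          - aic_score(fit_glm(y, X)))
        assert np.mean(deltas) > 0


class TestRFXBMS:
    def test_symmetric_evidence_gives_half(self):
        lme = np.zeros((17, 2))
        res = rfx_bms(lme)
        np.testing.assert_allclose(res.EP, 0.5, atol=1e-10)
        np.testing.assert_allclose(res.PXP, 0.5, atol=1e-10)

    def test_consistent_evidence_gives_high_pxp(self):
        lme = np.column_stack([np.zeros(17), np.full(17, 3.0)])
        res = rfx_bms(lme)
        assert res.PXP[1] > 0.95
        assert res.EP[1] > res.EP[0]

    def test_pxp_identity_and_normalization(self):
        rng = np.random.default_rng(2)
        lme = rng.normal(0, 2, size=(17, 2))
        res = rfx_bms(lme)
        assert res.EP.sum() == pytest.approx(1.0)
        assert res.PXP.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(
            res.PXP, res.EP * (1 - res.BOR) + res.BOR / 2, atol=1e-12)
        assert 0.0 <= res.BOR <= 1.0

    @pytest.mark.parametrize("a", [(1.0, 1.0), (3.0, 1.5), (7.2, 2.3),
                                   (0.7, 1.9), (12.0, 11.0)])
    def test_analytic_ep_matches_dirichlet_sampling(self, a):
        # oracle: 10^6 Monte-Carlo draws from the Dirichlet marginal
        rng = np.random.default_rng(3)
        samples = rng.beta(a[0], a[1], size=1_000_000)
        mc = np.mean(samples > 0.5)
        ep = exceedance_probability(np.array(a))
        assert ep[0] == pytest.approx(mc, abs=0.005)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rfx_bms(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            rfx_bms(np.array([[0.0, np.inf], [0.0, 1.0]]))


class TestEvidenceMap:
    @staticmethod
    def _group(n_sub, n_vox, signal, seed):
        subs = []
        for s in range(n_sub):
            from lrspectrum.task import AgentParams, make_schedule, \
                simulate_agent
            sched = make_schedule("stable_first", 60, seed=seed + s)
            sess = simulate_agent(sched, AgentParams(), seed=seed + 100 + s)
            tr30 = compute_value_traces(sess)
            from lrspectrum.regressors import build_regressor_bank
            bank = build_regressor_bank(sess, tr30)
            lay = make_region_layout(
                [RegionSpec("r", shape=(n_vox, 1, 1), gradient_slope=0.0,
                            intercept_rank=10.0, rank_jitter_sd=8.0,
                            is_null=not signal)], seed=seed + 200 + s)
            nuis = make_nuisance(sess.n_volumes, seed=seed + 300 + s)
            ds = synthesize_bold(lay, bank, nuisance=nuis,
                                 value_r2=0.08, seed=seed + 400 + s)
            design = build_design_matrix(sess, nuisance=nuis)
            tr99 = compute_value_traces(sess, LR_GRID_FULL)
            svd = svd_components(tr99.p_chosen, m=3)
            comps = component_regressors(svd, sess, sess.TR)
            subs.append(dict(Y=ds.Y, base=design, components=comps))
        return subs

    def test_signal_voxels_get_high_pxp(self):
        subs = self._group(n_sub=8, n_vox=30, signal=True, seed=10)
        ev = evidence_map(subs)
        assert np.median(ev["pxp"]) > 0.9
        assert np.all((ev["pxp"] >= 0) & (ev["pxp"] <= 1))

    def test_null_voxels_rarely_cross_threshold(self):
        # under H0 the AIC penalty favors the base model consistently,
        # so the learning-rate model's PXP stays low
        subs = self._group(n_sub=8, n_vox=60, signal=False, seed=20)
        ev = evidence_map(subs)
        assert np.mean(ev["pxp"] > 0.95) < 0.02
        assert np.median(ev["pxp"]) < 0.5

    def test_invariant_to_affine_voxel_rescaling(self):
        subs = self._group(n_sub=4, n_vox=5, signal=True, seed=30)
        ev1 = evidence_map(subs)
        for sub in subs:
            sub["Y"] = 3.7 * sub["Y"] - 11.0
        ev2 = evidence_map(subs)
        np.testing.assert_allclose(ev1["pxp"], ev2["pxp"], atol=1e-6)
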