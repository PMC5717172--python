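"""Synthetic BOLD generator: layouts, noise, regimes, shared components."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from lrspectrum.connectivity import residualize
from lrspectrum.simulate import (RegionSpec, inject_shared_bins,
                                 make_region_layout, subsession_masks,
                                 synthesize_bold)


def lag1(x):
    x = x - x.mean()
    return (x[1:] @ x[:-1]) / (x @ x)


class TestLayout:
    def test_flat_layout_constant_rank(self):
        lay = make_region_layout([RegionSpec("r", shape=(3, 4, 2),
                                             gradient_slope=0.0,
                                             intercept_rank=12.0)], seed=0)
        assert np.all(lay.gen_lr_rank == 12)

    def test_noiseless_gradient_monotone_in_y(self):
        lay = make_region_layout([RegionSpec("r", shape=(3, 10, 2),
                                             gradient_slope=2.0,
                                             intercept_rank=3.0)], seed=0)
        rho = spearmanr(lay.gen_lr_rank, lay.coords[:, 1]).statistic
        assert rho == pytest.approx(1.0)

    def test_jitter_degrades_but_keeps_gradient(self):
        rhos = []
        for seed in range(20):
            lay = make_region_layout([RegionSpec("r", shape=(3, 10, 2),
                                                 gradient_slope=2.0,
                                                 intercept_rank=3.0,
                                                 rank_jitter_sd=3.0)],
                                     seed=seed)
            rhos.append(spearmanr(lay.gen_lr_rank,
                                  lay.coords[:, 1]).statistic)
        assert 0.2 < np.mean(rhos) < 0.999

    def test_ranks_clipped_to_grid(self):
        lay = make_region_layout([RegionSpec("r", shape=(2, 10, 2),
                                             gradient_slope=8.0,
                                             intercept_rank=-5.0)], seed=0)
        assert lay.gen_lr_rank.min() >= 1
        assert lay.gen_lr_rank.max() <= 30

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            make_region_layout([RegionSpec("r", shape=(0, 4, 2))], seed=0)


class TestSynthesizeBold:
    @pytest.fixture(scope="class")
    @staticmethod
    def flat_layout():
        return make_region_layout([RegionSpec("r", shape=(5, 5, 4),
                                              gradient_slope=0.0,
                                              intercept_rank=7.0)], seed=1)

    def test_no_signal_white_noise(self, flat_layout, demo_bank30):
        null = make_region_layout([RegionSpec("n", shape=(5, 5, 4),
                                              is_null=True)], seed=2)
        ds = synthesize_bold(null, demo_bank30, nuisance_amp=0.0,
                             ar1_phi=0.0, seed=3)
        phis = [lag1(y) for y in ds.Y]
        assert abs(np.mean(phis)) < 0.05

    def test_ar1_noise_autocorrelation(self, demo_bank30):
        null = make_region_layout([RegionSpec("n", shape=(10, 5, 4),
                                              is_null=True)], seed=4)
        ds = synthesize_bold(null, demo_bank30, nuisance_amp=0.0,
                             ar1_phi=0.3, seed=5)
        phis = [lag1(y) for y in ds.Y]
        assert np.mean(phis) == pytest.approx(0.3, abs=0.03)

    def test_noiseless_voxel_proportional_to_regressor(self, demo_bank30):
        lay = make_region_layout([RegionSpec("r", shape=(1, 1, 1),
                                             gradient_slope=0.0,
                                             intercept_rank=7.0)], seed=6)
        # amplitudes are calibrated to a target R^2, so "noiseless" means
        # value_r2 -> 1 rather than noise_sd -> 0
        ds = synthesize_bold(lay, demo_bank30, value_r2=1 - 1e-9,
                             nuisance_amp=0.0, pe_r2=0.0, ar1_phi=0.0, seed=7)
        r = np.corrcoef(ds.Y[0], demo_bank30.X_value[:, 6])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-4)

    def test_variance_decomposition(self, flat_layout, demo_bank30):
        ds = synthesize_bold(flat_layout, demo_bank30, value_r2=0.08,
                             pe_r2=0.0, nuisance_amp=0.0, noise_sd=1.0,
                             ar1_phi=0.3, seed=8)
        noise_var = 1.0 / (1.0 - 0.3 ** 2)
        expect = noise_var * (1.0 + 0.08 / 0.92)
        assert np.mean(ds.Y.var(axis=1)) == pytest.approx(expect, rel=0.1)

    def test_target_r2_calibration(self, flat_layout, demo_bank30):
        ds = synthesize_bold(flat_layout, demo_bank30, value_r2=0.08,
                             pe_r2=0.0, seed=9)
        x = demo_bank30.X_value[:, 6]
        r2 = np.array([np.corrcoef(y, x)[0, 1] ** 2 for y in ds.Y])
        assert np.mean(r2) == pytest.approx(0.08, abs=0.03)

    def test_shift_mode_changes_ranks_only_at_boundary(self, flat_layout,
                                                       demo_session,
                                                       demo_bank30):
        ds = synthesize_bold(flat_layout, demo_bank30, session=demo_session,
                             regime_mode="shift", shift_delta=5, seed=10)
        assert np.all(ds.truth["gen_rank_volatile"]
                      == ds.truth["gen_rank_stable"] + 5)
        ds_gain = synthesize_bold(flat_layout, demo_bank30,
                                  session=demo_session, regime_mode="gain",
                                  seed=10)
        np.testing.assert_array_equal(ds_gain.truth["gen_rank_volatile"],
                                      ds_gain.truth["gen_rank_stable"])

    def test_invalid_mode_and_missing_session(self, flat_layout, demo_bank30):
        with pytest.raises(ValueError, match="regime_mode"):
            synthesize_bold(flat_layout, demo_bank30, regime_mode="bogus")
        with pytest.raises(ValueError, match="session"):
            synthesize_bold(flat_layout, demo_bank30, regime_mode="shift")

    def test_reproducible_from_seed(self, flat_layout, demo_bank30):
        a = synthesize_bold(flat_layout, demo_bank30, seed=11)
        b = synthesize_bold(flat_layout, demo_bank30, seed=11)
        np.testing.assert_array_equal(a.Y, b.Y)


class TestSharedBins:
    def test_component_survives_residualization(self, demo_session,
                                                demo_design, demo_bank30):
        specs = [RegionSpec("regionA", shape=(2, 5, 3), gradient_slope=2.5,
                            intercept_rank=4.0, origin=(0, 0, 0)),
                 RegionSpec("regionB", shape=(2, 5, 3), gradient_slope=2.5,
                            intercept_rank=4.0, origin=(20, 0, 0))]
        lay = make_region_layout(specs, seed=12)
        ds = synthesize_bold(lay, demo_bank30, session=demo_session,
                             noise_sd=0.2, nuisance_amp=0.0, seed=13)
        masks = subsession_masks(demo_session, demo_session.n_volumes)
        inject_shared_bins(ds, demo_design, demo_bank30,
                           ("regionA", "regionB"), strength=1.0,
                           segment_masks=masks, seed=14)
        lat = ds.truth["shared_bins"][("regionA", "regionB")]["latent"]
        resid = residualize(ds.Y, demo_design, demo_bank30,
                            segment_masks=masks)
        # recovered amplitude of the injected series per voxel ~ strength
        amps = []
        for v in lay.region("regionA"):
            c = lat[lay.gen_lr_rank[v] - 1]
            amps.append((resid[v] @ c) / (c @ c))
        assert np.mean(amps) == pytest.approx(1.0, abs=0.1)
        # i.e. >= 90% of the component's variance survives
        assert np.mean(amps) ** 2 >= 0.81
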