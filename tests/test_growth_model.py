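import numpy as np
import pytest

from paleoresil.calibration import C14Date, bin_dates, sample_uncal
from paleoresil.growth_model import (
    GrowthModelParams,
    MCMCConfig,
    bin_members,
    diagnostics,
    fit_mcmc,
    growth_density,
    log_likelihood,
    split_region,
)


class TestGrowthDensity:
    def test_uniform_limit_r_zero(self):
        gp = GrowthModelParams(r=0.0, a=5000, b=1000)
        t = np.array([1000.0, 2500.0, 5000.0])
        assert np.allclose(growth_density(t, gp), 1 / 4000)

    def test_closed_form_ratio(self):
        gp = GrowthModelParams(r=0.001, a=5000, b=1000)
        ratio = growth_density(1000, gp) / growth_density(5000, gp)
        assert ratio == pytest.approx(np.exp(4.0), rel=1e-12)

    @pytest.mark.parametrize("r", [0.002, -0.001, 0.0])
    def test_normalization(self, r):
        gp = GrowthModelParams(r=r, a=5000, b=1000)
        grid = np.arange(5000, 999, -1.0)
        # midpoint-corrected Riemann sum on the 1-yr grid
        total = growth_density(grid, gp).sum() - 0.5 * (growth_density(5000, gp) + growth_density(1000, gp))
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_continuity_at_zero(self):
        grid = np.arange(5000, 999, -1.0)
        uniform = growth_density(grid, GrowthModelParams(r=0.0, a=5000, b=1000))
        for r in (1e-8, -1e-8):
            near = growth_density(grid, GrowthModelParams(r=r, a=5000, b=1000))
            assert np.max(np.abs(near - uniform)) < 1e-6

    def test_zero_outside_bounds(self):
        gp = GrowthModelParams(r=0.001, a=5000, b=1000)
        assert growth_density(900, gp) == 0.0
        assert growth_density(5100, gp) == 0.0


class TestLogLikelihood:
    def test_near_delta_limit(self, identity_curve):
        # a tight measurement approximates a point observation at t0
        gp = GrowthModelParams(r=0.0015, a=5000, b=1000)
        d = C14Date("L", "S", 3000.0, 1.0)
        ll = log_likelihood([[d]], gp, identity_curve)
        assert ll == pytest.approx(np.log(growth_density(3000, gp)), abs=1e-3)

    def test_additivity_over_bins(self, identity_curve):
        gp = GrowthModelParams(r=0.001, a=5000, b=1000)
        d1 = C14Date("L1", "S1", 2000.0, 25.0)
        d2 = C14Date("L2", "S2", 3500.0, 35.0)
        assert log_likelihood([[d1], [d2]], gp, identity_curve) == pytest.approx(
            log_likelihood([[d1]], gp, identity_curve) + log_likelihood([[d2]], gp, identity_curve)
        )

    def test_order_invariance(self, identity_curve):
        gp = GrowthModelParams(r=0.001, a=5000, b=1000)
        bins = [[C14Date(f"L{i}", f"S{i}", c, 30.0)] for i, c in enumerate((1500.0, 2800.0, 4100.0))]
        assert log_likelihood(bins, gp, identity_curve) == pytest.approx(
            log_likelihood(bins[::-1], gp, identity_curve)
        )

    def test_matches_brute_force_oracle(self, noisy_curve):
        # independent double loop over grid years and dates
        gp = GrowthModelParams(r=0.002, a=4000, b=2000)
        dates = [C14Date("L1", "S1", 2500.0, 30.0), C14Date("L2", "S2", 3100.0, 45.0), C14Date("L3", "S3", 3900.0, 25.0)]
        expected = 0.0
        for d in dates:
            total = 0.0
            for t in range(2000, 4001):
                f = gp.r * np.exp(gp.r * (gp.a - t)) / np.expm1(gp.r * (gp.a - gp.b))
                sd = np.sqrt(d.error**2 + float(noisy_curve.sigma_at(t)) ** 2)
                mu = float(noisy_curve.c14_at(t))
                total += f * np.exp(-0.5 * ((d.cra - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
            expected += np.log(total)
        got = log_likelihood([[d] for d in dates], gp, noisy_curve)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_marginal_is_minus_inf(self, identity_curve):
        gp = GrowthModelParams(r=0.001, a=5000, b=4000)
        far = C14Date("L", "S", 1000.0, 10.0)  # mass entirely outside [4000, 5000]
        with pytest.warns(UserWarning, match="zero marginal"):
            assert log_likelihood([[far]], gp, identity_curve) == -np.inf


def _simulate_bins(curve, r, a, b, n, seed, lab_error=30.0):
    rng = np.random.default_rng(seed)
    grid = np.arange(a, b - 1, -1.0)
    p = growth_density(grid, GrowthModelParams(r=r, a=a, b=b))
    p = p / p.sum()
    years = rng.choice(grid, size=n, p=p)
    dates = [
        sample_uncal(t, curve, lab_error, rng, lab_id=f"L{i}", site_id=f"S{i}")
        for i, t in enumerate(years)
    ]
    return bin_members(dates, bin_dates(dates))


class TestFitMcmc:
    def test_seed_determinism(self, identity_curve):
        binned = _simulate_bins(identity_curve, 0.001, 4000, 2000, 40, seed=1)
        cfg = MCMCConfig(n_chains=2, n_iter=400, burn_in=100, seed=9)
        p1 = fit_mcmc(binned, (4000, 2000), identity_curve, cfg)
        p2 = fit_mcmc(binned, (4000, 2000), identity_curve, cfg)
        assert np.array_equal(p1.draws, p2.draws)

    def test_draw_count_shape(self, identity_curve):
        binned = _simulate_bins(identity_curve, 0.001, 4000, 2000, 30, seed=2)
        cfg = MCMCConfig(n_chains=3, n_iter=500, burn_in=100, thin=2, seed=4)
        p = fit_mcmc(binned, (4000, 2000), identity_curve, cfg)
        assert p.draws.shape == (3, (500 - 100) // 2)

    def test_too_few_bins_rejected(self, identity_curve):
        binned = _simulate_bins(identity_curve, 0.001, 4000, 2000, 3, seed=3)
        with pytest.raises(ValueError, match="at least 5 bins"):
            fit_mcmc(binned, (4000, 2000), identity_curve, MCMCConfig(n_iter=100, burn_in=10))

    def test_posterior_concentrates_with_sample_size(self, identity_curve):
        # posterior sd of r shrinks when the dataset doubles
        cfg = MCMCConfig(n_chains=2, n_iter=1500, burn_in=400, seed=12)
        sds = []
        for n in (60, 240):
            binned = _simulate_bins(identity_curve, 0.0015, 5000, 1500, n, seed=7)
            sds.append(fit_mcmc(binned, (5000, 1500), identity_curve, cfg).summary()["sd"])
        assert sds[1] < sds[0]


class TestDiagnostics:
    def test_identical_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=4000)
        rep = diagnostics(np.vstack([chain, chain]))
        assert rep.rhat == pytest.approx(1.0, abs=0.01)

    def test_iid_chains_ess_near_total(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(3, 2000))
        rep = diagnostics(draws)
        assert abs(rep.ess - draws.size) / draws.size < 0.2

    def test_disjoint_chains_large_rhat(self):
        rng = np.random.default_rng(2)
        draws = np.vstack([rng.normal(0, 0.1, 1000), rng.normal(5, 0.1, 1000)])
        assert diagnostics(draws).rhat > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            diagnostics(np.zeros((1, 100)))


class TestSplitRegion:
    def _binned_with_modes(self):
        # one single-date bin per mode; identity curve puts the mode at the CRA
        bins = [[C14Date(f"L{i}", f"S{i}", c, 20.0)] for i, c in enumerate((7000.0, 6000.0, 5000.0, 3000.0))]
        return bins, [7000.0, 6000.0, 5000.0, 3000.0]

    def test_no_breakpoints_identity(self):
        binned, modes = self._binned_with_modes()
        segments = split_region(binned, (8000, 2000), [], modes=modes)
        assert segments == [(binned, (8000.0, 2000.0))]

    def test_partition_bounds(self):
        binned, modes = self._binned_with_modes()
        (old_seg, old_b), (young_seg, young_b) = split_region(binned, (8000, 2000), [5000], modes=modes)
        assert old_b == (8000, 5000) and young_b == (5000, 2000)
        assert len(old_seg) == 3 and len(young_seg) == 1

    def test_mode_on_breakpoint_goes_older(self):
        binned, modes = self._binned_with_modes()
        (old_seg, _), _ = split_region(binned, (8000, 2000), [5000], modes=modes)
        assert binned[2] in old_seg  # mode exactly 5000

    def test_breakpoint_outside_bounds_rejected(self):
        binned, modes = self._binned_with_modes()
        with pytest.raises(ValueError, match="outside region bounds"):
            split_region(binned, (8000, 2000), [9000], modes=modes)

    def test_modes_from_curve(self, identity_curve):
        binned, _ = self._binned_with_modes()
        segments = split_region(binned, (8000, 2000), [5500], curve=identity_curve)
        assert [len(s) for s, _ in segments] == [2, 2]
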