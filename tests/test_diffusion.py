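import math

import numpy as np
import pytest

from planksim import diffusion as dg
from planksim.errors import DomainError


class TestCarbonContent:
    def test_12um_non_diatom(self):
        assert dg.carbon_content(12.0, "non_diatom") == pytest.approx(
            129.2, rel=2e-3)

    def test_127um_diatom(self):
        assert dg.carbon_content(127.0, "diatom") == pytest.approx(
            2.24e4, rel=5e-3)

    def test_monotone(self):
        for d in (0.6, 3.0, 40.0):
            assert dg.carbon_content(2 * d) > dg.carbon_content(d)

    def test_domain(self):
        with pytest.raises(DomainError):
            dg.carbon_content(-1.0)


class TestMuMaxEnvelope:
    def test_peak_near_7um(self):
        d = np.linspace(0.5, 14.9, 2000)
        mu = np.array([dg.mu_max_envelope(x) for x in d])
        assert d[np.argmax(mu)] == pytest.approx(0.789 / (2 * 0.0555),
                                                 abs=0.02)

    def test_small_cell(self):
        assert dg.mu_max_envelope(0.6) == pytest.approx(0.758, abs=1e-3)

    def test_branch_switch_at_15(self):
        assert dg.mu_max_envelope(15.0) == pytest.approx(
            9.29 * 15 ** (-0.533) * math.log(2), rel=1e-12)
        assert dg.mu_max_envelope(15.0) == pytest.approx(1.521, abs=1e-3)

    def test_negative_region_clamped(self):
        with pytest.warns(RuntimeWarning):
            assert dg.mu_max_envelope(14.995) == 0.0


class TestNCOfMu:
    def test_intercept(self):
        assert dg.nc_of_mu(0.0) == 0.0389

    def test_unit_rate(self):
        assert dg.nc_of_mu(1.0) == pytest.approx(0.1151)

    def test_linearity(self):
        a, b = 0.3, 1.7
        assert dg.nc_of_mu(a) + dg.nc_of_mu(b) == pytest.approx(
            dg.nc_of_mu(a + b) + 0.0389, rel=1e-12)


class TestVelocities:
    def test_swimming_small(self):
        assert dg.swimming_velocity(0.6) == pytest.approx(7.43, abs=0.01)

    def test_swimming_12um(self):
        assert dg.swimming_velocity(12.0) == pytest.approx(16.2, abs=0.05)

    def test_dialects(self):
        for d in (0.6, 5.0, 100.0):
            assert dg.swimming_velocity(d, "as_printed") == pytest.approx(
                1e4 * dg.swimming_velocity(d, "bracket_only"), rel=1e-12)

    def test_sinking_below_8um(self):
        assert dg.sinking_velocity(5.0) == 0.0

    def test_sinking_at_8um(self):
        assert dg.sinking_velocity(8.0) == pytest.approx(1.23, abs=0.01)

    def test_sinking_127um(self):
        assert dg.sinking_velocity(127.0) == pytest.approx(20.6, abs=0.05)


class TestPecletSherwood:
    def test_no_motion(self):
        assert dg.peclet(10.0, 0.0, 1500.0) == 0.0
        assert dg.sherwood(0.0) == 1.0

    def test_large_diatom(self):
        pe = dg.peclet(127.0, 20.6, 1500.0)
        assert pe == pytest.approx(1.74, abs=0.01)
        assert dg.sherwood(pe) == pytest.approx(1.325, abs=2e-3)

    def test_perfect_cube(self):
        # 1 + 2*13 = 27 is a perfect cube: Sh = 0.5*(1 + 3) exactly
        assert dg.sherwood(13.0) == pytest.approx(2.0, rel=1e-12)

    def test_linearity(self):
        assert dg.peclet(4.0, 6.0, 1500.0) == pytest.approx(
            2 * dg.peclet(2.0, 6.0, 1500.0), rel=1e-12)

    def test_sherwood_at_least_one(self):
        pe = np.linspace(0, 100, 50)
        assert all(dg.sherwood(p) >= 1.0 for p in pe)


class TestFluxes:
    def test_zero_concentration(self):
        ctx = dg.TransportContext(s_inf=0.0)
        assert dg.diffusive_flux(5.0, ctx) == 0.0

    def test_127um_1nm(self, ctx_n_1nm):
        # 2*pi*127*1500*1.4e-8*86400
        assert dg.diffusive_flux(127.0, ctx_n_1nm) == pytest.approx(
            1.45e3, rel=5e-3)

    def test_linearity_in_d(self, ctx_n_1nm):
        assert dg.diffusive_flux(20.0, ctx_n_1nm) == pytest.approx(
            2 * dg.diffusive_flux(10.0, ctx_n_1nm), rel=1e-12)

    def test_volume_specific_ratio_1_vs_100(self, ctx_n_1nm):
        ratio = (dg.volume_specific_flux(1.0, ctx_n_1nm)
                 / dg.volume_specific_flux(100.0, ctx_n_1nm))
        assert ratio == pytest.approx(1e4, rel=1e-12)

    def test_volume_specific_identity(self, ctx_n_1nm):
        for d in (0.6, 12.0, 127.0):
            direct = dg.volume_specific_flux(d, ctx_n_1nm)
            closed = (3 * ctx_n_1nm.D * ctx_n_1nm.s_inf_per_um3
                      * 86400.0 / (d / 2) ** 2)
            assert direct == pytest.approx(closed, rel=1e-12)

    def test_quadrupling_on_halving(self, ctx_n_1nm):
        assert dg.volume_specific_flux(5.0, ctx_n_1nm) == pytest.approx(
            4 * dg.volume_specific_flux(10.0, ctx_n_1nm), rel=1e-12)


class TestAvailableFlux:
    def test_stationary_cell(self, ctx_n_1nm):
        # small diatoms neither sink nor swim: Sh = 1
        assert dg.available_flux(5.0, "diatom", ctx_n_1nm) == pytest.approx(
            0.9 * dg.diffusive_flux(5.0, ctx_n_1nm), rel=1e-12)

    def test_large_diatom(self, ctx_n_1nm):
        assert dg.available_flux(127.0, "diatom", ctx_n_1nm) == pytest.approx(
            1.73e3, rel=5e-3)

    def test_full_capture(self):
        ctx = dg.TransportContext(s_inf=1.0, capture_eff=1.0)
        assert dg.available_flux(5.0, "diatom", ctx) == pytest.approx(
            dg.diffusive_flux(5.0, ctx), rel=1e-12)

    def test_at_least_90pct_of_diffusive(self, ctx_n_1nm):
        for d in (0.6, 8.0, 50.0, 127.0):
            for group in ("non_diatom", "diatom"):
                assert dg.available_flux(d, group, ctx_n_1nm) >= \
                    0.9 * dg.diffusive_flux(d, ctx_n_1nm) - 1e-12


def quadratic_root_oracle(sol: dg.GrowthSolution, np_ratio_divisor=1.0):
    """Closed-form positive root of mu*Q(mu) = assim."""
    c_fg = 1000.0 * sol.phenotype.c_pg / np_ratio_divisor
    a, b, c = 0.0762 * c_fg, 0.0389 * c_fg, sol.assim
    return (-b + math.sqrt(b * b + 4 * a * c)) / (2 * a)


class TestSolveMu:
    def test_small_non_diatom_1nm(self, ctx_n_1nm):
        sol = dg.solve_mu(0.6, "non_diatom", ctx_n_1nm)
        assert sol.mu == pytest.approx(0.632, abs=2e-3)
        assert sol.converged and sol.iterations <= 25

    def test_large_diatom_1nm(self, ctx_n_1nm):
        sol = dg.solve_mu(127.0, "diatom", ctx_n_1nm)
        assert sol.mu == pytest.approx(2.0e-3, rel=0.05)

    def test_saturation_limit(self):
        ctx = dg.TransportContext(s_inf=1e6)
        sol = dg.solve_mu(0.6, "non_diatom", ctx)
        assert sol.mu == pytest.approx(sol.phenotype.mu_max, rel=0.02)

    def test_zero_concentration(self):
        sol = dg.solve_mu(3.0, "non_diatom", dg.TransportContext(s_inf=0.0))
        assert sol.mu == 0.0 and sol.converged

    def test_quadratic_oracle_200_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            d = float(10 ** rng.uniform(math.log10(0.6), math.log10(130)))
            group = str(rng.choice(["non_diatom", "diatom"]))
            s = float(10 ** rng.uniform(0.0, math.log10(2e4)))
            sol = dg.solve_mu(d, group, dg.TransportContext(s_inf=s))
            assert abs(sol.mu - quadratic_root_oracle(sol)) < 1e-6

    def test_mu_never_exceeds_mu_max(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            d = float(10 ** rng.uniform(math.log10(0.6), math.log10(130)))
            s = float(10 ** rng.uniform(0.0, 5.0))
            sol = dg.solve_mu(d, "non_diatom", dg.TransportContext(s_inf=s))
            assert sol.mu <= sol.phenotype.mu_max * (1 + 1e-9)

    def test_vmax_identity(self, ctx_n_1nm):
        sol = dg.solve_mu(3.0, "non_diatom", ctx_n_1nm)
        ph = sol.phenotype
        assert ph.v_max_fg == pytest.approx(
            1000.0 * ph.nc_max * ph.c_pg * ph.mu_max, rel=1e-14)

    def test_assim_bounded(self, ctx_n_1nm):
        sol = dg.solve_mu(10.0, "non_diatom", ctx_n_1nm)
        assert sol.assim <= min(sol.a_f, sol.phenotype.v_max_fg)


class TestDivisionRateSpectra:
    def test_between_bounds_at_3nm(self):
        # realized spectra sit between the inverse-square diffusion floor
        # and the size envelope
        ctx = dg.TransportContext(s_inf=3.0)
        diam = np.logspace(math.log10(0.6), math.log10(130.0), 30)
        for d in diam:
            sol = dg.solve_mu(float(d), "non_diatom", ctx)
            assert sol.mu <= sol.phenotype.mu_max * (1 + 1e-9)
            # pure-diffusion rate with quota fixed at the realized value
            pure = sol.a_f / sol.q
            assert sol.mu <= pure * (1 + 1e-9)

    def test_pure_diffusion_inverse_square(self, ctx_n_1nm):
        # with Sh = 1 and quota per volume fixed, mu_diffusion ~ 1/d^2
        def mu_diff(d):
            vol = math.pi / 6 * d**3
            return dg.diffusive_flux(d, ctx_n_1nm) / vol  # quota ~ volume

        assert mu_diff(1.0) / mu_diff(10.0) == pytest.approx(100.0, rel=1e-12)


class TestChemostat:
    def test_t_suecica_point(self):
        sols = dg.chemostat_prediction(12.0, 1.19, [5.6])
        assert sols[0].mu == pytest.approx(0.64, abs=0.01)

    def test_zero(self):
        sols = dg.chemostat_prediction(12.0, 1.19, [0.0])
        assert sols[0].mu == 0.0

    def test_monotone(self):
        s_grid = [0.7, 1.4, 2.8, 5.6]
        mus = [s.mu for s in dg.chemostat_prediction(12.0, 1.19, s_grid)]
        assert all(b > a for a, b in zip(mus, mus[1:]))

    def test_phosphorus_quadratic_oracle(self):
        sol = dg.chemostat_prediction(12.0, 1.19, [5.6])[0]
        root = quadratic_root_oracle(sol, np_ratio_divisor=14.0 * 16.0)
        assert abs(sol.mu - root) < 1e-6
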