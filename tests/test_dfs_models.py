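"""Landscape models: rates, rupture-force statistics, unit bridges."""

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.stats import kstest

import mechanofak as mf
from mechanofak.dfs_models import OutOfRegimeError, ValidationError

from _oracles import langevin_escape_rate

KT = 1.380649e-2 * 300.0


class TestStiffnessConversion:
    @pytest.mark.parametrize(
        "kjmol,expected",
        [(250.0, 415.13), (0.0, 0.0), (1.0, 1.66054)],
    )
    def test_values(self, kjmol, expected):
        assert mf.stiffness_from_kjmol(kjmol) == pytest.approx(expected, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            mf.stiffness_from_kjmol(-1.0)


class TestIntrinsicRate:
    def test_unstable_unconstrained_fit_exceeds_one_hertz(self, s7_params):
        """The thermally unstable parameter set opens spontaneously >1/s."""
        assert mf.intrinsic_rate(s7_params, "bsk") >= 1.0

    def test_constrained_fit_is_thermally_stable(self, fig4a_params):
        """The headline fit satisfies the k0 <= 1e-3 1/s stability bound."""
        for kind in ("bsk", "hs"):
            assert mf.intrinsic_rate(fig4a_params, kind) <= 1e-3

    def test_arrhenius_limit(self):
        rates = [
            mf.intrinsic_rate(mf.LandscapeParams(dG, 0.86, 6.6e6), "bsk")
            for dG in (20.0, 60.0, 120.0, 240.0)
        ]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < 1e-90

    def test_strictly_decreasing_in_deltaG_increasing_in_D(self):
        for kind in ("bsk", "hs"):
            k_dG = [
                mf.intrinsic_rate(mf.LandscapeParams(dG, 0.5, 1e6), kind)
                for dG in np.linspace(6, 40, 12)
            ]
            assert all(a > b for a, b in zip(k_dG, k_dG[1:]))
            k_D = [
                mf.intrinsic_rate(mf.LandscapeParams(15, 0.5, D), kind)
                for D in np.geomspace(1e4, 1e9, 10)
            ]
            assert all(a < b for a, b in zip(k_D, k_D[1:]))

    def test_proportional_to_diffusivity(self):
        k1 = mf.intrinsic_rate(mf.LandscapeParams(12, 0.4, 1e6), "bsk")
        k2 = mf.intrinsic_rate(mf.LandscapeParams(12, 0.4, 3e6), "bsk")
        assert k2 / k1 == pytest.approx(3.0, rel=1e-12)

    def test_against_langevin_first_passage(self):
        """Kramers high-barrier rate vs brute-force Euler-Maruyama escapes."""
        params = mf.LandscapeParams(5.0, 0.5, 1e6)
        analytic = mf.intrinsic_rate(params, "hs")  # linear-cubic default
        oracle = langevin_escape_rate(5.0, 0.5, 1e6, "linear-cubic",
                                      n_walkers=10000, seed=42)
        assert analytic == pytest.approx(oracle, rel=0.15)

    @pytest.mark.parametrize("bad", [dict(deltaG=-1), dict(x_b=0), dict(D=np.nan)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(deltaG=10.0, x_b=0.5, D=1e6)
        kw.update(bad)
        with pytest.raises(ValidationError):
            mf.LandscapeParams(**kw)


class TestForceDependentRate:
    @pytest.mark.parametrize("kind", ["bell", "hs", "bsk"])
    def test_zero_force_equals_intrinsic(self, fig4a_params, kind):
        assert mf.force_dependent_rate(fig4a_params, kind, 0.0) == mf.intrinsic_rate(
            fig4a_params, kind
        )

    def test_bell_e_fold_at_thermal_force(self, fig4a_params):
        """At F = kT/x_b the Bell rate is exactly e times k0."""
        F = fig4a_params.kT / fig4a_params.x_b
        k0 = mf.intrinsic_rate(fig4a_params, "bell")
        assert mf.force_dependent_rate(fig4a_params, "bell", F) == pytest.approx(
            k0 * np.e, rel=1e-12
        )

    @pytest.mark.parametrize("kind", ["hs", "bsk"])
    def test_bell_limit_at_small_force(self, fig4a_params, kind):
        """Curved-landscape rates reduce to Bell for F*x_b << kT."""
        k0 = mf.intrinsic_rate(fig4a_params, kind)
        for F in np.linspace(0.05, 0.1 * KT / fig4a_params.x_b, 5):
            bell = k0 * np.exp(F * fig4a_params.x_b / KT)
            assert mf.force_dependent_rate(fig4a_params, kind, F) == pytest.approx(
                bell, rel=0.05
            )

    @pytest.mark.parametrize("kind", ["hs", "bsk"])
    def test_monotone_while_barrier_stands(self, fig4a_params, kind):
        """Rate grows with force throughout the high-barrier-valid region."""
        Fc = mf.barrier_vanishing_force(fig4a_params, kind)
        # residual barrier >= 1 kT: dG*(1 - F/Fc)^(1/nu) >= 1
        nu = 0.5 if kind == "bsk" else 2.0 / 3.0
        F_hi = Fc * (1.0 - (1.0 / fig4a_params.deltaG) ** nu)
        k = mf.force_dependent_rate(fig4a_params, kind, np.linspace(0, F_hi, 200))
        assert np.all(np.diff(k) > 0)

    def test_beyond_critical_force_raises(self, fig4a_params):
        Fc = mf.barrier_vanishing_force(fig4a_params, "bsk")
        with pytest.raises(OutOfRegimeError):
            mf.force_dependent_rate(fig4a_params, "bsk", 1.01 * Fc)
        with pytest.raises(ValidationError):
            mf.force_dependent_rate(fig4a_params, "bsk", -1.0)


class TestRuptureForceDistribution:
    @pytest.mark.parametrize("velocity", [6e-3, 0.1, 1.0])
    def test_normalization_with_survival_deficit(self, fig4a_params, velocity):
        """Density mass plus the surviving fraction accounts for all runs."""
        dist = mf.rupture_force_distribution(
            fig4a_params, "bsk", mf.PullingProtocol.from_kjmol(250.0, velocity)
        )
        total = simpson(dist.density, x=dist.force) + dist.survival_deficit
        assert total == pytest.approx(1.0, abs=1e-6)
        assert np.all(dist.density >= 0)

    def test_mode_increases_with_velocity(self, fig4a_params):
        modes = []
        for v in (6e-3, 1.0):
            dist = mf.rupture_force_distribution(
                fig4a_params, "bsk", mf.PullingProtocol.from_kjmol(250.0, v)
            )
            modes.append(dist.force[np.argmax(dist.density)])
        assert modes[1] > modes[0]

    def test_zero_velocity_rejected(self, fig4a_params):
        with pytest.raises(ValidationError):
            mf.rupture_force_distribution(
                fig4a_params, "bsk", mf.PullingProtocol(415.13, 0.0)
            )

    def test_sampler_histogram_matches_density(self, fig4a_params):
        """Kolmogorov-Smirnov check of 1e4 inverse-transform draws."""
        proto = mf.PullingProtocol.from_kjmol(250.0, 0.05)
        spec = mf.ProtocolSpec(
            velocities=[0.05], runs_per_velocity=[10000], seed=71
        )
        draws = mf.sample_rupture_forces(fig4a_params, "bsk", spec)
        forces = draws.frame["rupture_force_pN"].to_numpy()
        dist = mf.rupture_force_distribution(fig4a_params, "bsk", proto)
        from scipy.integrate import cumulative_simpson

        cdf_grid = cumulative_simpson(dist.density, x=dist.force, initial=0.0)
        cdf_grid /= cdf_grid[-1]  # conditional CDF

        ks = kstest(forces, lambda x: np.interp(x, dist.force, cdf_grid))
        assert ks.pvalue > 0.01


class TestMeanRuptureForce:
    def test_mean_curve_inside_reported_force_band(
        self, fig4a_params, paper_velocities
    ):
        """Across the simulated velocity span the predicted mean rupture
        force stays in the 150-450 pN window of the pulling campaign."""
        means = [
            mf.mean_rupture_force(
                fig4a_params, "bsk", mf.PullingProtocol.from_kjmol(250.0, v)
            )[0]
            for v in paper_velocities
        ]
        assert min(means) >= 150.0
        assert max(means) <= 450.0

    def test_doubling_velocity_never_decreases_mean(self, fig4a_params):
        for v in (0.01, 0.04, 0.16, 0.5):
            m1, _ = mf.mean_rupture_force(
                fig4a_params, "bsk", mf.PullingProtocol.from_kjmol(250.0, v)
            )
            m2, _ = mf.mean_rupture_force(
                fig4a_params, "bsk", mf.PullingProtocol.from_kjmol(250.0, 2 * v)
            )
            assert m2 >= m1

    @pytest.mark.parametrize("deltaG", [10.0, 20.0, 28.5])
    @pytest.mark.parametrize("velocity", [6e-3, 0.1, 1.0])
    def test_quadrature_moments_match_monte_carlo(self, deltaG, velocity):
        """Analytic mean/sd vs 1e4 seeded first-passage draws (2 SE)."""
        params = mf.LandscapeParams(deltaG, 0.86, 6.6e6)
        proto = mf.PullingProtocol.from_kjmol(250.0, velocity)
        mean, sd = mf.mean_rupture_force(params, "bsk", proto)
        n = 10000
        spec = mf.ProtocolSpec(
            velocities=[velocity], runs_per_velocity=[n], seed=5
        )
        draws = mf.sample_rupture_forces(params, "bsk", spec)
        f = draws.frame["rupture_force_pN"].to_numpy()
        se_mean = f.std(ddof=1) / np.sqrt(n)
        assert mean == pytest.approx(f.mean(), abs=2 * se_mean)
        # sd of the sample sd, normal approximation
        se_sd = f.std(ddof=1) / np.sqrt(2 * (n - 1))
        assert sd == pytest.approx(f.std(ddof=1), abs=2 * se_sd)


class TestHypothesisProperties:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        deltaG=st.floats(6.0, 50.0),
        x_b=st.floats(0.15, 1.8),
        logD=st.floats(5.0, 8.5),
        f1=st.floats(0.0, 20.0),
        f2=st.floats(0.0, 20.0),
    )
    def test_bell_rate_is_exactly_exponential(self, deltaG, x_b, logD, f1, f2):
        """k(F1+F2)*k0 == k(F1)*k(F2) characterizes the Bell form."""
        p = mf.LandscapeParams(deltaG, x_b, 10.0**logD)
        k0 = mf.intrinsic_rate(p, "bell")
        lhs = mf.force_dependent_rate(p, "bell", f1 + f2) * k0
        rhs = mf.force_dependent_rate(p, "bell", f1) * mf.force_dependent_rate(
            p, "bell", f2
        )
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        deltaG=st.floats(8.0, 45.0),
        x_b=st.floats(0.2, 1.5),
        frac=st.floats(0.01, 0.5),
    )
    def test_curved_rates_bounded_below_by_intrinsic(self, deltaG, x_b, frac):
        """k(F) >= k0 anywhere below the barrier-vanishing force."""
        p = mf.LandscapeParams(deltaG, x_b, 1e6)
        for kind in ("hs", "bsk"):
            F = frac * mf.barrier_vanishing_force(p, kind)
            assert mf.force_dependent_rate(p, kind, F) >= mf.intrinsic_rate(p, kind)
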