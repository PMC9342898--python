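"""Activation-scheme simulation, eigen-rate structure, mechanism signatures."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from myovi.equilibrium_titration import complex_concentration
from myovi.kinetic_model import (
    KineticScheme,
    ProbeModel,
    eigen_rates,
    predict_kobs_curve,
    simulate_scheme,
)
from myovi.transient_fit import FluorescenceTrace, fit_single_exponential


def default_scheme(**kw):
    base = dict(k_on=1.65, k_off=3.2, k_unfold=2.2, k_dimer=0.0)
    base.update(kw)
    return KineticScheme(**base)


class TestEigenRates:
    def test_sum_and_product_identities(self):
        # trace and determinant of the linearized 2x2 system
        for conc in (0.5, 2.5, 10.0, 40.0):
            s = default_scheme()
            fast, slow = eigen_rates(s, conc)
            assert fast >= slow > 0
            total = s.k_on * conc + s.k_off + s.k_unfold
            prod = s.k_on * conc * s.k_unfold
            assert fast + slow == pytest.approx(total, rel=1e-12)
            assert fast * slow == pytest.approx(prod, rel=1e-12)

    def test_matches_rate_matrix_eigenvalues(self):
        # independent oracle: numpy eigendecomposition of the 2x2 matrix
        s = default_scheme()
        for conc in (10.0, 20.0):
            M = np.array(
                [
                    [-s.k_on * conc, s.k_off],
                    [s.k_on * conc, -(s.k_off + s.k_unfold)],
                ]
            )
            lam = np.sort(np.abs(np.linalg.eigvals(M)))
            fast, slow = eigen_rates(s, conc)
            assert slow == pytest.approx(lam[0], rel=1e-10)
            assert fast == pytest.approx(lam[1], rel=1e-10)

    def test_reference_values(self):
        # quadratic roots of x^2 - 21.9 x + 36.3 and x^2 - 38.4 x + 72.6
        fast, slow = eigen_rates(default_scheme(), 10.0)
        assert fast == pytest.approx(20.0934, abs=1e-3)
        assert slow == pytest.approx(1.8066, abs=1e-3)
        _, slow20 = eigen_rates(default_scheme(), 20.0)
        assert slow20 == pytest.approx(1.9942, abs=1e-3)

    def test_binding_only_limit(self):
        s = default_scheme(k_unfold=0.0)
        fast, slow = eigen_rates(s, 10.0)
        assert slow == 0.0
        assert fast == pytest.approx(s.k_on * 10.0 + s.k_off, rel=1e-12)

    def test_saturation_limit(self):
        s = default_scheme()
        _, slow = eigen_rates(s, 1e6)
        assert slow == pytest.approx(s.k_unfold, rel=1e-4)

    def test_monotone_in_concentration(self):
        s = default_scheme()
        grid = np.linspace(0.5, 50, 40)
        pairs = [eigen_rates(s, p) for p in grid]
        fast = np.array([a for a, _ in pairs])
        slow = np.array([b for _, b in pairs])
        assert np.all(np.diff(fast) > 0)
        assert np.all(np.diff(slow) > 0)
        assert np.all(slow < s.k_unfold)

    def test_zero_partner_rejected(self):
        with pytest.raises(ValueError):
            eigen_rates(default_scheme(), 0.0)


class TestSimulation:
    @pytest.mark.parametrize(
        "scheme,partner",
        [
            (default_scheme(), 10.0),
            (default_scheme(k_dimer=10.0), 10.0),
            (
                KineticScheme(
                    mechanism="conformational_selection",
                    k_open=0.22,
                    k_close=2.2,
                    k_dimer=10.0,
                ),
                10.0,
            ),
        ],
    )
    def test_mass_conservation(self, scheme, partner):
        t = np.linspace(0, 5, 400)
        st = simulate_scheme(scheme, 1.0, partner, t)
        tail = st.F + st.U + st.FP + st.UP + 2 * st.D2
        part = st.P + st.FP + st.UP + 2 * st.D2
        assert np.max(np.abs(tail - 1.0)) < 1e-6
        assert np.max(np.abs(part - partner) / partner) < 1e-6
        assert (st[["F", "U", "P", "FP", "UP", "D2"]] >= 0).all().all()

    def test_irreversible_sink_absorbs_tail(self):
        st = simulate_scheme(default_scheme(), 1.0, 10.0, np.linspace(0, 50, 200))
        assert st.F.iloc[-1] == pytest.approx(0.0, abs=1e-6)
        assert st.UP.iloc[-1] == pytest.approx(1.0, abs=1e-6)

    def test_binding_equilibrium_depleted_partner(self):
        # with unfolding off, FP equilibrates to the exact mass-action value
        s = default_scheme(k_unfold=0.0)
        st = simulate_scheme(s, 1.0, 10.0, np.linspace(0, 30, 100))
        exact = complex_concentration(1.0, 10.0, s.Kd)
        assert st.FP.iloc[-1] == pytest.approx(exact, rel=1e-5)
        # pseudo-first-order approximation [P]/([P]+Kd) holds to ~2%
        assert st.FP.iloc[-1] == pytest.approx(10.0 / (10.0 + s.Kd), rel=0.02)

    def test_no_partner_no_reaction(self):
        st = simulate_scheme(default_scheme(), 1.0, 0.0, np.linspace(0, 10, 50))
        assert np.allclose(st.F, 1.0, atol=1e-9)
        assert np.allclose(st[["FP", "UP", "D2"]], 0.0, atol=1e-9)

    def test_ode_rates_match_eigen_rates(self):
        # pseudo-first-order ODE trace is a two-exponential relaxation
        s = default_scheme()
        partner, tail = 50.0, 0.01
        fast, slow = eigen_rates(s, partner)
        t = np.linspace(0, 5 / slow, 4000)
        st = simulate_scheme(s, tail, partner, t)

        def two_exp(tt, c1, c2, l1, l2):
            return c1 * np.exp(-l1 * tt) + c2 * np.exp(-l2 * tt)

        popt, _ = curve_fit(
            two_exp, t, st.F.to_numpy(), p0=[tail, 0.0, fast * 1.2, slow * 0.8]
        )
        fitted = np.sort(np.abs(popt[2:]))
        assert fitted[1] == pytest.approx(fast, rel=1e-4)
        assert fitted[0] == pytest.approx(slow, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            KineticScheme(k_on=-1.0)
        with pytest.raises(ValueError):
            simulate_scheme(default_scheme(), 1.0, 10.0, [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            simulate_scheme(default_scheme(), -1.0, 10.0, [0.0, 1.0])


class TestDimerization:
    def test_dimer_signal_concentration_independent(self):
        # with dimerization far from rate-limiting and saturating partner
        # (the slow relaxation approaches k_unfold only for [P] >> Kd),
        # the tail-tail FRET rise fits a single exponential within 15% of
        # k_unfold over a 4-fold partner range
        scheme = KineticScheme(k_on=1.65, k_off=3.2, k_unfold=2.2, k_dimer=1000.0)
        probe = ProbeModel(probe="tail_tail_fret")
        t = np.arange(0.002, 4.0, 0.002)
        rates = []
        for partner in (20.0, 40.0, 80.0):
            st = simulate_scheme(scheme, 1.0, partner, t)
            trace = FluorescenceTrace(t, probe.signal(st), partner_conc=partner)
            fit = fit_single_exponential(trace, direction="rise")
            rates.append(fit.k_obs)
        rates = np.array(rates)
        assert np.all(np.abs(rates / scheme.k_unfold - 1) < 0.15)
        # and the spread across a 4-fold [P] range is far below the
        # 3-fold change the binding phase would show
        assert rates.max() / rates.min() < 1.15


class TestMechanismDiscrimination:
    def test_induced_fit_linear_total_rate(self):
        s = default_scheme()
        grid = np.array([5.0, 10.0, 15.0, 20.0])
        pred = predict_kobs_curve(s, grid)
        total = pred.k_fast + pred.k_slow
        slope = np.polyfit(grid, total, 1)[0]
        assert slope == pytest.approx(s.k_on, rel=1e-12)
        assert np.all(np.diff(pred.k_fast) > 0)
        assert np.all(pred.k_slow < s.k_unfold)

    def test_conformational_selection_decreasing_slow_phase(self):
        s = KineticScheme(
            mechanism="conformational_selection", k_open=2.2, k_close=22.0
        )
        grid = np.array([1.0, 5.0, 20.0, 100.0, 1e5])
        pred = predict_kobs_curve(s, grid)
        assert np.all(np.diff(pred.k_slow) < 0)
        assert pred.k_slow.iloc[-1] == pytest.approx(2.2, rel=1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            predict_kobs_curve(default_scheme(), [])
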