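"""Forward model: characteristic roots, modal series, load intensity, fields."""

import numpy as np
import pytest
from scipy.special import j1, jn_zeros

from porelax.constitutive import (
    ConstitutiveError,
    EngineeringConstants,
    TransportParameters,
    stiffness_from_engineering,
)
from porelax.forward import (
    RampProtocol,
    _expansion_amplitudes,
    characteristic_roots,
    load_intensity,
    radial_fields,
    step_response,
)

from conftest import random_engineering_constants


def reference_C(phi=0.5):
    args = {0.5: (8.49, 19.19, 0.75, 0.24), 0.7: (5.61, 11.97, 0.82, 0.24)}[phi]
    return stiffness_from_engineering(EngineeringConstants(*args))


class TestCharacteristicRoots:
    def test_beta_zero_gives_j0_zeros(self):
        roots = characteristic_roots(0.0, 20)
        assert roots.alpha == pytest.approx(jn_zeros(0, 20), abs=1e-12)
        assert roots.alpha[:3] == pytest.approx([2.40483, 5.52008, 8.65373], abs=1e-5)

    def test_reference_beta_first_root(self):
        C = reference_C(0.5)
        assert C.beta == pytest.approx(0.20424, abs=1e-5)
        roots = characteristic_roots(C.beta, 5)
        assert roots.alpha[0] == pytest.approx(2.31515, abs=2e-4)
        assert roots.alpha[0] < 2.40483

    @pytest.mark.parametrize("beta", [0.0, 0.13, 0.2042, 0.5, 0.9])
    def test_residual_below_1e12(self, beta):
        roots = characteristic_roots(beta, 40)
        assert np.max(np.abs(roots.residual())) < 1e-12
        assert np.all(np.diff(roots.alpha) > 0)

    def test_roots_decrease_with_beta(self):
        a_lo = characteristic_roots(0.1, 10).alpha
        a_hi = characteristic_roots(0.4, 10).alpha
        assert np.all(a_hi < a_lo)

    @pytest.mark.parametrize("beta", [-0.1, 1.0, 1.5])
    def test_invalid_beta_raises(self, beta):
        with pytest.raises(ConstitutiveError):
            characteristic_roots(beta, 5)


class TestStepResponse:
    def test_reference_moduli(self):
        C = reference_C(0.5)
        sol = step_response(C, characteristic_roots(C.beta, 20), tg=40.62)
        assert sol.E3_eq == pytest.approx(19.19, abs=5e-3)
        assert sol.M0 == pytest.approx(24.957, abs=5e-3)
        assert sol.M0 - sol.E3_eq == pytest.approx(5.767, abs=5e-3)
        assert np.all(np.diff(sol.tau) < 0)

    def test_amplitudes_match_eigenfunction_expansion(self, rng):
        """Residue closed form vs independent Sturm-Liouville expansion."""
        for ec in random_engineering_constants(rng, 10):
            C = stiffness_from_engineering(ec)
            roots = characteristic_roots(C.beta, 20)
            sol = step_response(C, roots, tg=10.0)
            c_hat = _expansion_amplitudes(roots.alpha, ec.nu31)
            B_expand = (2 * C.C13 - C.C11 - C.C12) * c_hat * j1(roots.alpha)
            assert sol.B == pytest.approx(B_expand, rel=1e-9)

    def test_sum_rule_converges_to_isochoric_gap(self):
        """sum(B_n) -> M0 - E3; boundary-layer convergence is ~1/N."""
        C = reference_C(0.5)
        gap = C.instantaneous_modulus - C.equilibrium_modulus
        errs = []
        for n in (20, 100, 2000):
            sol = step_response(C, characteristic_roots(C.beta, n), tg=40.62)
            errs.append(abs(sol.B.sum() - gap) / gap)
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-3

    def test_isotropic_step_ratio_closed_form(self):
        for nu in (0.0, 0.2, 0.45):
            C = stiffness_from_engineering(EngineeringConstants(10.0, 10.0, nu, nu))
            assert C.instantaneous_modulus / C.equilibrium_modulus == pytest.approx(
                3.0 / (2.0 * (1.0 + nu)), abs=1e-6
            )

    def test_mismatched_roots_raise(self):
        C = reference_C(0.5)
        roots = characteristic_roots(0.5, 20)
        with pytest.raises(ValueError, match="beta"):
            step_response(C, roots, tg=40.62)


class TestLoadIntensity:
    def make_sol(self, phi=0.5, n_roots=20):
        C = reference_C(phi)
        tg = {0.5: 40.62, 0.7: 17.58}[phi]
        return C, step_response(C, characteristic_roots(C.beta, n_roots), tg)

    def test_equilibrium_value(self):
        C, sol = self.make_sol()
        prot = RampProtocol(0.01, 0.1, hold_time=50 * sol.tg)
        P = load_intensity(sol, prot, np.array([prot.duration]))
        assert P.stress[0] / 0.1 == pytest.approx(19.19, rel=1e-3)

    def test_step_instantaneous_value(self):
        C, sol = self.make_sol(n_roots=2000)
        prot = RampProtocol.step(0.1, 100.0)
        P = load_intensity(sol, prot, np.array([1e-6 * sol.tg]))
        assert P.stress[0] == pytest.approx(C.instantaneous_modulus * 0.1, rel=1e-3)

    def test_finite_ramp_peak_below_step_bound(self):
        C, sol = self.make_sol()
        step_peak = C.instantaneous_modulus * 0.1
        for rate in (0.0025, 0.01, 0.03, 0.3):
            prot = RampProtocol(rate, 0.1, 100.0)
            t = np.linspace(0.0, prot.duration, 4000)
            P = load_intensity(sol, prot, t)
            assert P.stress.max() < step_peak

    def test_continuous_at_ramp_end_and_decreasing_after(self):
        _, sol = self.make_sol()
        prot = RampProtocol(0.01, 0.1, 100.0)
        t0 = prot.ramp_time
        t = np.array([t0 - 1e-9, t0, t0 + 1e-9])
        P = load_intensity(sol, prot, t)
        assert np.ptp(P.stress) < 1e-8
        hold = np.linspace(t0, prot.duration, 2000)
        Ph = load_intensity(sol, prot, hold)
        assert np.all(np.diff(Ph.stress) < 0)

    def test_time_rescaling_property(self):
        """P depends on time only through t/t_g when the ramp is too."""
        C = reference_C(0.5)
        for scale in (0.1, 10.0):
            sol1 = step_response(C, characteristic_roots(C.beta, 20), tg=40.62)
            sol2 = step_response(C, characteristic_roots(C.beta, 20), tg=40.62 * scale)
            prot1 = RampProtocol(0.01, 0.1, 100.0)
            prot2 = RampProtocol(0.01 / scale, 0.1, 100.0 * scale)
            t = np.linspace(0.0, prot1.duration, 500)
            P1 = load_intensity(sol1, prot1, t).stress
            P2 = load_intensity(sol2, prot2, t * scale).stress
            assert P2 == pytest.approx(P1, rel=1e-12)

    def test_truncation_stability_roots_21_to_40(self):
        """Default 20-root series is converged once the fast modes die out.

        Modes beyond 20 have relaxation times below t_g/4000; they only
        matter within a fraction of a second of the ramp-end kink.  Away
        from it, and in particular for the final value, doubling the root
        count changes nothing.
        """
        C = reference_C(0.5)
        tg = 40.62
        sol20 = step_response(C, characteristic_roots(C.beta, 20), tg)
        sol40 = step_response(C, characteristic_roots(C.beta, 40), tg)
        for rate in (0.0025, 0.01, 0.03):
            prot = RampProtocol(rate, 0.1, 100.0)
            t = np.linspace(prot.ramp_time + 0.5, prot.duration, 2000)
            P20 = load_intensity(sol20, prot, t).stress
            P40 = load_intensity(sol40, prot, t).stress
            assert np.max(np.abs(P40 - P20)) / np.max(np.abs(P40)) < 1e-6
            assert abs(P40[-1] - P20[-1]) < 1e-9  # final value unchanged

    def test_empty_time_grid_raises(self):
        _, sol = self.make_sol()
        with pytest.raises(ValueError, match="empty"):
            load_intensity(sol, RampProtocol(0.01, 0.1, 100.0), np.array([]))


class TestRadialFields:
    C = reference_C(0.5)
    tp = TransportParameters(tg=40.62, a=1e-3)

    def test_equilibrium_displacement(self):
        prot = RampProtocol(0.01, 0.1, 100.0)
        f = radial_fields(self.C, self.tp, prot, np.linspace(0, 1, 11),
                          np.array([50.0 * 40.62]))
        assert f.u_r[0, -1] == pytest.approx(-0.24 * 0.1, rel=1e-6)
        assert f.u_r[0] == pytest.approx(-0.24 * 0.1 * f.r_over_a, abs=1e-8)

    def test_drained_boundary_pressure_zero(self):
        prot = RampProtocol(0.01, 0.1, 100.0)
        t = np.linspace(0.0, prot.duration, 50)
        f = radial_fields(self.C, self.tp, prot, np.linspace(0, 1, 21), t)
        assert np.max(np.abs(f.p[:, -1])) == 0.0
        assert np.all(np.isfinite(f.u_r)) and np.all(np.isfinite(f.w_r))
        assert np.max(np.abs(f.u_r[:, 0])) == 0.0  # axis pinned

    def test_step_instantaneous_isochoric_displacement(self):
        """Interior displacement just after a step is the isochoric profile.

        The drained boundary develops a layer of thickness ~sqrt(t/t_g), so
        x = 1 is excluded at this early time.
        """
        prot = RampProtocol.step(0.1, 100.0)
        x = np.linspace(0, 0.9, 9)
        f = radial_fields(self.C, self.tp, prot, x, np.array([1e-4 * 40.62]),
                          n_roots=400)
        assert f.u_r[0] == pytest.approx(-0.1 * x / 2, abs=2e-4)

    def test_radius_outside_unit_interval_raises(self):
        with pytest.raises(ValueError, match="r_grid"):
            radial_fields(self.C, self.tp, RampProtocol(0.01, 0.1, 10.0),
                          np.array([0.0, 1.2]), np.array([1.0]))
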