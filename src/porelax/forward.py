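"""Analytic ramp-and-hold relaxation of a long poroelastic cylinder in tension.

A long transversely isotropic biphasic cylinder (length/radius ~ 10) is
stretched axially at constant rate to a total strain ``eps0`` and held.
With ``eps_zz = eps(t)`` uniform and all other fields functions of radius
only, the mixture equations collapse to a single radial consolidation
problem for the solid displacement ``u(r, t)``::

    du/dt = (k C11) d/dr[(1/r) d(r u)/dr] - deps/dt * r / 2,   0 <= r <= a
    u(0, t) = 0
    C11 du/dr + C12 u/a = -C13 eps(t)   at r = a   (traction-free, drained)

The lateral surface is free-draining (p(a, t) = 0); fluid is drawn in from
the bath as the cylinder extends, and the measured load intensity (the
cross-section-averaged axial total stress)

    P(t) = (2/a**2) * int_0^a sigma_zz^t r dr

relaxes from an isochoric peak toward the drained equilibrium ``E3 eps0``.

The homogeneous modes are ``J1(alpha_n r/a)`` with the characteristic
equation ``alpha J0(alpha) = beta J1(alpha)``, ``beta = 1 - C12/C11``.  The
step response per unit strain is the relaxation function

    G(t) = E3 + sum_n B_n exp(-alpha_n**2 t / t_g),
    B_n  = 2 K / (alpha_n**2 + beta**2 - 2 beta),
    K    = (C11 + C12 - 2 C13)**2 / (2 C11)

(obtained by Laplace-transform residues; ``sum_n B_n = M0 - E3`` exactly).
Ramp loading follows by Duhamel superposition, evaluated termwise in closed
form.  All modal relaxation times are ``t_g / alpha_n**2`` with
``t_g = a**2/(k C11)`` the gel diffusion time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1, jn_zeros

from .constitutive import (
    ConstitutiveError,
    StiffnessMatrix,
    TransportParameters,
)

__all__ = [
    "RampProtocol",
    "BesselRootSet",
    "SeriesSolution",
    "RadialFields",
    "RelaxationTrace",
    "characteristic_roots",
    "step_response",
    "load_intensity",
    "radial_fields",
]

DEFAULT_N_ROOTS = 20


@dataclass(frozen=True)
class RampProtocol:
    """Ramp-and-hold axial strain history.

    ``eps(t) = strain_rate * t`` for ``t <= ramp_time``, then constant at
    ``total_strain``.  A step protocol is represented by
    ``strain_rate = inf`` (``ramp_time = 0``) and evaluated analytically,
    not as a small-``t0`` ramp.
    """

    strain_rate: float  # 1/s; may be math.inf for a step
    total_strain: float
    hold_time: float

    def __post_init__(self) -> None:
        if not self.total_strain > 0:
            raise ValueError(f"total_strain must be positive, got {self.total_strain}")
        if not self.strain_rate > 0:
            raise ValueError(f"strain_rate must be positive, got {self.strain_rate}")
        if self.hold_time < 0:
            raise ValueError(f"hold_time must be non-negative, got {self.hold_time}")

    @classmethod
    def step(cls, total_strain: float, hold_time: float) -> "RampProtocol":
        return cls(strain_rate=math.inf, total_strain=total_strain, hold_time=hold_time)

    @property
    def is_step(self) -> bool:
        return math.isinf(self.strain_rate)

    @property
    def ramp_time(self) -> float:
        """``t0 = eps0 / strain_rate`` (0 for a step)."""
        return 0.0 if self.is_step else self.total_strain / self.strain_rate

    @property
    def duration(self) -> float:
        return self.ramp_time + self.hold_time

    def strain(self, t: np.ndarray | float) -> np.ndarray:
        """Applied axial strain at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if self.is_step:
            return np.where(t >= 0, self.total_strain, 0.0)
        return np.clip(t * self.strain_rate, 0.0, self.total_strain)

    def strain_rate_at(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.is_step:
            return np.zeros_like(t)
        return np.where((t >= 0) & (t <= self.ramp_time), self.strain_rate, 0.0)


@dataclass(frozen=True)
class BesselRootSet:
    """Ordered positive roots of ``alpha J0(alpha) - beta J1(alpha) = 0``."""

    alpha: np.ndarray
    beta: float

    @property
    def count(self) -> int:
        return len(self.alpha)

    def residual(self) -> np.ndarray:
        """Characteristic-equation residual at each root."""
        a = self.alpha
        return a * j0(a) - self.beta * j1(a)


@dataclass(frozen=True)
class SeriesSolution:
    """Modal decomposition of the step relaxation function ``G(t)``.

    ``G(t)/eps0 = E3_eq + sum B_n exp(-t/tau_n)`` with ``tau_n`` strictly
    decreasing and proportional to ``tg``.  ``c_hat`` are the displacement
    mode amplitudes used for radial field reconstruction:
    ``u_step(r,t)/(a eps0) = -nu31 x + sum c_hat_n J1(alpha_n x) exp(-t/tau_n)``.
    """

    E3_eq: float
    M0: float
    B: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    beta: float
    tg: float
    nu31: float
    c_hat: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.B)


@dataclass(frozen=True)
class RelaxationTrace:
    """Uniform or arbitrary-grid load-intensity time series, kPa."""

    time: np.ndarray
    stress: np.ndarray
    protocol: RampProtocol | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        s = np.asarray(self.stress, float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and stress must be 1-D arrays of equal length")
        if len(t) == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("trace contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "stress", s)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class RadialFields:
    """Radial field snapshots on a normalized radius grid.

    Attributes
    ----------
    r_over_a : (nr,) array
    time : (nt,) array, s
    u_r : (nt, nr) array
        Radial displacement divided by the radius ``a`` (dimensionless).
    p : (nt, nr) array
        Pore pressure, kPa (zero on the drained surface ``r = a``).
    w_r : (nt, nr) array
        Relative fluid flux (Darcy velocity) divided by ``a``, 1/s.
        Negative values mean inflow from the bath.
    """

    r_over_a: np.ndarray
    time: np.ndarray
    u_r: np.ndarray
    p: np.ndarray
    w_r: np.ndarray


def characteristic_roots(beta: float, n_roots: int = DEFAULT_N_ROOTS) -> BesselRootSet:
    """First ``n_roots`` positive roots of ``alpha J0(alpha) = beta J1(alpha)``.

    For ``beta in [0, 1)`` exactly one root lies in each interval between
    consecutive zeros of ``J0`` (the n-th root sits just below the n-th zero
    of ``J0``; at ``beta = 0`` the roots are the ``J0`` zeros themselves).
    Roots are bracketed there, solved by Brent's method and polished with a
    Newton step so the characteristic equation holds to better than 1e-12.
    """
    if not 0.0 <= beta < 1.0:
        raise ConstitutiveError(
            f"beta = 1 - C12/C11 must lie in [0, 1), got {beta:.6g}"
        )
    if n_roots < 1:
        raise ValueError(f"n_roots must be >= 1, got {n_roots}")
    z0 = jn_zeros(0, n_roots)
    if beta == 0.0:
        return BesselRootSet(alpha=z0, beta=beta)

    def f(x: float) -> float:
        return x * j0(x) - beta * j1(x)

    def fprime(x: float) -> float:
        # d/dx [x J0 - beta J1] with J0' = -J1, J1' = J0 - J1/x
        return j0(x) - x * j1(x) - beta * (j0(x) - j1(x) / x)

    lo = np.concatenate([[1e-9], z0[:-1]])
    roots = np.empty(n_roots)
    for i, (a, b) in enumerate(zip(lo, z0)):
        r = brentq(f, a + 1e-12, b, xtol=1e-15, rtol=4 * np.finfo(float).eps)
        for _ in range(2):  # Newton polish toward |f| < 1e-12
            fr = f(r)
            if abs(fr) < 1e-14:
                break
            r -= fr / fprime(r)
        roots[i] = r
    return BesselRootSet(alpha=roots, beta=beta)


def _expansion_amplitudes(alpha: np.ndarray, nu31: float) -> np.ndarray:
    """Displacement mode amplitudes from the Sturm-Liouville expansion.

    The isochoric initial state ``u/(a eps0) = -x/2`` relaxes toward the
    drained state ``-nu31 x``; the difference ``(nu31 - 1/2) x`` is expanded
    in the orthogonal (weight x) eigenfunctions ``J1(alpha_n x)``.
    """
    j1a = j1(alpha)
    j0a = j0(alpha)
    # int_0^1 x**2 J1(alpha x) dx = J2(alpha)/alpha
    num = (2.0 * j1a / alpha - j0a) / alpha
    j1p = j0a - j1a / alpha
    norm = 0.5 * (j1p**2 + (1.0 - 1.0 / alpha**2) * j1a**2)
    return (nu31 - 0.5) * num / norm


def step_response(
    C: StiffnessMatrix, roots: BesselRootSet, tg: float
) -> SeriesSolution:
    """Modal series of the relaxation function for a step strain.

    Parameters
    ----------
    C : StiffnessMatrix
    roots : BesselRootSet
        Must have been computed for ``beta = 1 - C12/C11`` of this ``C``.
    tg : float
        Gel diffusion time ``a**2/(k C11)``, s.
    """
    beta = C.beta
    if abs(roots.beta - beta) > 1e-12 * max(1.0, abs(beta)):
        raise ValueError(
            f"root set computed for beta={roots.beta:.12g}, "
            f"stiffness matrix has beta={beta:.12g}"
        )
    if not tg > 0:
        raise ValueError(f"tg must be positive, got {tg}")
    alpha = roots.alpha
    K = (C.C11 + C.C12 - 2.0 * C.C13) ** 2 / (2.0 * C.C11)
    B = 2.0 * K / (alpha**2 + beta**2 - 2.0 * beta)
    tau = tg / alpha**2
    nu31 = C.C13 / (C.C11 + C.C12)
    return SeriesSolution(
        E3_eq=C.equilibrium_modulus,
        M0=C.instantaneous_modulus,
        B=B,
        tau=tau,
        alpha=alpha,
        beta=beta,
        tg=tg,
        nu31=nu31,
        c_hat=_expansion_amplitudes(alpha, nu31),
    )


def _mode_time_factors(
    tau: np.ndarray, protocol: RampProtocol, times: np.ndarray
) -> np.ndarray:
    """Duhamel time factor per mode: ``int_0^t deps/dt(s) exp(-(t-s)/tau) ds``.

    Returns an (nt, n_modes) array (units of strain).  For a step protocol
    this is ``eps0 exp(-t/tau)``.
    """
    tau_b = tau[None, :]
    if protocol.is_step:
        return protocol.total_strain * np.exp(-times[:, None] / tau_b)
    rate, t0 = protocol.strain_rate, protocol.ramp_time
    out = np.empty((len(times), len(tau)))
    on_ramp = times <= t0
    tr = times[on_ramp][:, None]
    out[on_ramp] = rate * tau_b * (1.0 - np.exp(-tr / tau_b))
    th = times[~on_ramp][:, None]
    # exp(-(t-t0)/tau) - exp(-t/tau), factored to avoid overflow for t >> tau
    out[~on_ramp] = rate * tau_b * np.exp(-(th - t0) / tau_b) * (1.0 - np.exp(-t0 / tau_b))
    return out


def load_intensity(
    sol: SeriesSolution, protocol: RampProtocol, times: np.ndarray
) -> RelaxationTrace:
    """Load intensity ``P(t)`` for a ramp-and-hold protocol, kPa.

    Closed-form Duhamel superposition of the step relaxation function::

        P(t) = E3 * eps(t)
             + rate * sum_n B_n tau_n (1 - exp(-t/tau_n))            (ramp)
        P(t) = E3 * eps0
             + rate * sum_n B_n tau_n (exp(-(t-t0)/tau_n) - exp(-t/tau_n))
                                                                      (hold)

    continuous at ``t0`` and monotone decreasing afterwards.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time grid")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    factors = _mode_time_factors(sol.tau, protocol, times)
    P = sol.E3_eq * protocol.strain(times) + factors @ sol.B
    return RelaxationTrace(time=times, stress=P, protocol=protocol)


def radial_fields(
    C: StiffnessMatrix,
    tp: TransportParameters,
    protocol: RampProtocol,
    r_grid: np.ndarray,
    times: np.ndarray,
    n_roots: int = DEFAULT_N_ROOTS,
) -> RadialFields:
    """Reconstruct ``u_r``, pore pressure ``p`` and fluid flux ``w_r``.

    The displacement is the Duhamel superposition of the step mode shapes::

        u(x, t)/a = -nu31 x eps(t) + sum_n c_n J1(alpha_n x) T_n(t)

    with ``T_n`` the per-mode time factor.  The pressure follows from radial
    equilibrium, ``p = C11 (L u - L u|_{x=1})`` with
    ``L u = (1/x) d(x u)/dx``, and the relative fluid flux from Darcy's law,
    ``w_r/a = -(1/(C11 t_g)) dp/dx`` (1/s).
    """
    x = np.asarray(r_grid, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("r_grid must lie in [0, 1] (normalized radius)")
    times = np.asarray(times, dtype=float)
    if tp.tg is None:
        raise ValueError("TransportParameters.tg is required")
    roots = characteristic_roots(C.beta, n_roots)
    sol = step_response(C, roots, tp.tg)

    T = _mode_time_factors(sol.tau, protocol, times)  # (nt, n)
    eps = protocol.strain(times)[:, None]  # (nt, 1)
    J1x = j1(np.outer(sol.alpha, x))  # (n, nr)
    J0x = j0(np.outer(sol.alpha, x))  # (n, nr)
    c = sol.c_hat

    u = -sol.nu31 * eps * x[None, :] + T @ (c[:, None] * J1x)
    # L of mode c J1(alpha x) is c alpha J0(alpha x); L of -nu31 eps x is -2 nu31 eps
    Lmode = c[:, None] * sol.alpha[:, None] * (J0x - j0(sol.alpha)[:, None])
    p = C.C11 * (T @ Lmode)  # uniform parts cancel between x and x=1
    # dp/dx = -C11 sum c alpha**2 J1(alpha x) T  =>  w/a = (1/tg) sum c alpha**2 J1 T
    w = (T @ (c[:, None] * sol.alpha[:, None] ** 2 * J1x)) / tp.tg
    return RadialFields(r_over_a=x, time=times, u_r=u, p=p, w_r=w)
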