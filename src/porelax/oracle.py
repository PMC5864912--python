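"""Independent finite-difference solver of the radial consolidation problem.

Method-of-lines discretization of

    dU/dt = (1/t_g) d/dx[(1/x) d(x U)/dx] - deps/dt * x / 2,  x = r/a in [0,1]

with ``U = u/a``, ``U(0) = 0`` and the Robin (traction-free, drained)
condition ``U'(1) + (C12/C11) U(1) = -(C13/C11) eps(t)``.  The spatial
operator is written in conservative flux form on a uniform grid,
second-order accurate, with a ghost node for the boundary condition.  Time
integration uses stiff BDF with a banded Jacobian sparsity pattern (the
relaxation spectrum spans decades of time constants).

The load intensity is recovered by quadrature of the axial total stress
over the cross-section — an independent route from the analytic series,
used to validate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .constitutive import StiffnessMatrix, TransportParameters
from .forward import RampProtocol, RadialFields, RelaxationTrace

__all__ = ["GridSpec", "solve_radial_consolidation"]

#: a step protocol is integrated as a ramp with t0 = STEP_RAMP_FRACTION * t_g
STEP_RAMP_FRACTION = 1e-4


@dataclass(frozen=True)
class GridSpec:
    """Spatial/temporal resolution of the finite-difference solve."""

    n_nodes: int = 201
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_nodes < 32:
            raise ValueError(f"n_nodes must be >= 32, got {self.n_nodes}")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("integration tolerances must be positive")


def _lu_discrete(U: np.ndarray, x: np.ndarray, h: float, robin_slope: float) -> np.ndarray:
    """Discrete ``L U = (1/x) d(x U)/dx`` (second order).

    ``robin_slope`` is the exact ``U'(1)`` from the boundary condition, used
    at the last node; at ``x = 0``, ``L U -> 2 U'(0)`` by L'Hopital.
    """
    LU = np.empty_like(U)
    xU = x * U
    LU[1:-1] = (xU[2:] - xU[:-2]) / (2.0 * h * x[1:-1])
    # x=0: 2*U'(0), one-sided second order with U(0)=0
    LU[0] = 2.0 * (-1.5 * U[0] + 2.0 * U[1] - 0.5 * U[2]) / h
    LU[-1] = robin_slope + U[-1]  # U'(1) + U(1)/1
    return LU


def solve_radial_consolidation(
    C: StiffnessMatrix,
    tp: TransportParameters,
    protocol: RampProtocol,
    grid: GridSpec = GridSpec(),
    times: np.ndarray | None = None,
) -> tuple[RelaxationTrace, RadialFields]:
    """Solve the consolidation PDE and return load intensity + radial fields.

    A step protocol is approximated by a ramp of duration
    ``1e-4 * t_g`` (the analytic model treats the step exactly; the oracle
    cannot integrate a distributional strain rate).

    Raises
    ------
    RuntimeError
        If the stiff integrator fails to converge.
    """
    if tp.tg is None:
        raise ValueError("TransportParameters.tg is required")
    tg = tp.tg
    if protocol.is_step:
        t0 = STEP_RAMP_FRACTION * tg
        protocol = RampProtocol(
            strain_rate=protocol.total_strain / t0,
            total_strain=protocol.total_strain,
            hold_time=protocol.hold_time,
        )
    if times is None:
        times = np.linspace(0.0, protocol.duration, 512)
    times = np.asarray(times, dtype=float)

    N = grid.n_nodes
    x = np.linspace(0.0, 1.0, N)
    h = x[1] - x[0]
    xh = x[:-1] + h / 2.0  # half nodes
    c12_c11 = C.C12 / C.C11
    c13_c11 = C.C13 / C.C11

    # conservative flux form: (1/h) * [G_{i+1/2} - G_{i-1/2}],
    # G_{i+1/2} = (x_{i+1} U_{i+1} - x_i U_i) / (h * x_{i+1/2})
    def rhs(t: float, U: np.ndarray) -> np.ndarray:
        eps = float(protocol.strain(t))
        rate = float(protocol.strain_rate_at(t))
        dU = np.empty_like(U)
        dU[0] = 0.0  # U(0) = 0 pinned
        xU = x * U
        G = (xU[1:] - xU[:-1]) / (h * xh)
        dU[1:-1] = (G[1:] - G[:-1]) / h
        # ghost node at x = 1 + h via Robin slope
        slope = -c12_c11 * U[-1] - c13_c11 * eps
        Ug = U[-2] + 2.0 * h * slope  # central derivative across x = 1
        Gg = ((1.0 + h) * Ug - 1.0 * U[-1]) / (h * (1.0 + h / 2.0))
        dU[-1] = (Gg - G[-1]) / h
        dU /= tg
        dU[1:] -= rate * x[1:] / 2.0
        return dU

    # tridiagonal sparsity (ghost node couples last row to N-2 as well)
    diags = sparse.lil_matrix((N, N))
    for i in range(1, N - 1):
        diags[i, i - 1 : i + 2] = 1
    diags[N - 1, N - 3 :] = 1
    diags[0, 0] = 1

    res = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        np.zeros(N),
        method="BDF",
        t_eval=times,
        rtol=grid.rtol,
        atol=grid.atol,
        jac_sparsity=diags.tocsr(),
    )
    if not res.success:
        raise RuntimeError(f"stiff integration failed: {res.message}")

    Us = res.y.T  # (nt, N)
    eps_t = protocol.strain(times)
    P = np.empty(len(times))
    p_all = np.empty_like(Us)
    w_all = np.empty_like(Us)
    k_norm = 1.0 / (C.C11 * tg)  # (w_r/a) = -k_norm * dp/dx, 1/s per kPa
    for i, (U, eps) in enumerate(zip(Us, eps_t)):
        slope = -c12_c11 * U[-1] - c13_c11 * eps
        LU = _lu_discrete(U, x, h, slope)
        p = C.C11 * (LU - LU[-1])
        sigma_zz = C.C13 * LU + C.C33 * eps - p
        P[i] = 2.0 * np.trapezoid(sigma_zz * x, x)
        p_all[i] = p
        w_all[i] = -k_norm * np.gradient(p, x)
    trace = RelaxationTrace(time=times, stress=P, protocol=protocol)
    fields = RadialFields(r_over_a=x, time=times, u_r=Us, p=p_all, w_r=w_all)
    return trace, fields
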