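"""Inverse estimation of (E1, nu21, t_g) from a force-relaxation trace.

With the equilibrium modulus ``E3`` fixed from the relaxation tail and
``nu31`` fixed from equilibrium displacement imaging, the remaining three
parameters are estimated by bounded trust-region-reflective least squares
against the ramp-and-hold load intensity.  A staged strategy is the
default: first fit ``(E1, t_g)`` with ``nu21`` held at its starting value,
then refit all three from that point — the two-parameter stage is cheap and
lands close to the joint optimum.

The starting point is data-driven rather than visual: ``E1 = E3/2`` (the
fibre direction is typically about twice as stiff as the transverse plane),
``nu21 = 0.7``, and ``t_g`` from the time for the hold-phase stress to
complete 63% of its peak-to-equilibrium drop (scaled by the square of the
first characteristic root, since the slowest relaxation time is
``t_g / alpha_1**2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, RegressorMixin

from .constitutive import EngineeringConstants, stiffness_from_engineering
from .forward import (
    DEFAULT_N_ROOTS,
    RampProtocol,
    RelaxationTrace,
    characteristic_roots,
    load_intensity,
    step_response,
)
from .preprocess import DEFAULT_NU31, equilibrium_modulus

__all__ = [
    "FitConfig",
    "FitResult",
    "PoroelasticRelaxationFitter",
    "fit_parameters",
    "r_squared",
    "predict_trace",
]

DEFAULT_BOUNDS = {"E1": (0.1, 100.0), "nu21": (0.0, 0.999), "tg": (0.1, 1000.0)}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the staged trust-region fit."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    x0: tuple | None = None  # (E1, nu21, tg); None -> data-driven start
    staged: bool = True
    nu21_init: float = 0.7
    nu31: float = DEFAULT_NU31
    E3: float | None = None  # None -> from the relaxation tail
    n_tail: int = 1000
    n_roots: int = DEFAULT_N_ROOTS
    filter_frame: int | None = None
    filter_order: int = 1
    xtol: float = 1e-10
    ftol: float = 1e-10
    gtol: float = 1e-10

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.x0 is not None:
            for v, name in zip(self.x0, ("E1", "nu21", "tg")):
                lo, hi = self.bounds[name]
                if not lo <= v <= hi:
                    raise ValueError(
                        f"starting point {name}={v} outside bounds ({lo}, {hi})"
                    )


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters and fit diagnostics."""

    E1: float
    nu21: float
    tg: float
    E3: float
    nu31: float
    ssd: float  # sum of squared differences, kPa**2
    r2: float
    n_iter: int
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "E1_kPa": self.E1,
            "nu21": self.nu21,
            "tg_s": self.tg,
            "E3_kPa": self.E3,
            "nu31": self.nu31,
            "ssd_kPa2": self.ssd,
            "r2": self.r2,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def r_squared(model: RelaxationTrace, data: RelaxationTrace) -> float:
    """Coefficient of determination ``1 - SSR/SST`` on identical time grids.

    SST is taken about the data mean; a model worse than the mean yields a
    negative value.  Constant data (SST = 0) has no defined r-squared.
    """
    if len(model) != len(data) or not np.allclose(model.time, data.time):
        raise ValueError("model and data must share the same time grid")
    resid = model.stress - data.stress
    sst = float(np.sum((data.stress - data.stress.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("r-squared undefined for constant data (SST = 0)")
    return 1.0 - float(np.sum(resid**2)) / sst


def predict_trace(
    E1: float,
    nu21: float,
    tg: float,
    E3: float,
    nu31: float,
    protocol: RampProtocol,
    times: np.ndarray,
    n_roots: int = DEFAULT_N_ROOTS,
) -> RelaxationTrace:
    """Forward load-intensity trace for one parameter vector."""
    ec = EngineeringConstants(E1=E1, E3=E3, nu21=nu21, nu31=nu31)
    C = stiffness_from_engineering(ec)
    roots = characteristic_roots(C.beta, n_roots)
    sol = step_response(C, roots, tg)
    return load_intensity(sol, protocol, times)


class PoroelasticRelaxationFitter(RegressorMixin, BaseEstimator):
    """Estimate (E1, nu21, t_g) of a poroelastic scaffold from P(t).

    scikit-learn style estimator: ``fit(t, stress)`` with ``t`` in seconds
    (1-D or column vector) and ``stress`` the measured load intensity in
    kPa; ``predict(t)`` returns the fitted model trace.

    Parameters
    ----------
    protocol : RampProtocol
        The applied strain history (required).
    E3 : float or None
        Equilibrium modulus, kPa.  None: estimated from the mean of the
        last ``n_tail`` samples divided by the total strain.
    nu31 : float
        Fixed axial-radial Poisson's ratio.
    staged : bool
        Two-stage strategy: fit (E1, t_g) at held ``nu21_init`` first.
    bounds : dict
        ``{"E1": (lo, hi), "nu21": (lo, hi), "tg": (lo, hi)}``.
    x0 : tuple or None
        Explicit (E1, nu21, tg) start; None uses the data-driven start.

    Attributes
    ----------
    E1_, nu21_, tg_, E3_, nu31_ : float
        Estimated / fixed parameters.
    r2_, ssd_, n_iter_, converged_ : diagnostics
    result_ : FitResult
    """

    def __init__(
        self,
        protocol: RampProtocol | None = None,
        E3: float | None = None,
        nu31: float = DEFAULT_NU31,
        staged: bool = True,
        bounds: dict | None = None,
        x0: tuple | None = None,
        nu21_init: float = 0.7,
        n_tail: int = 1000,
        n_roots: int = DEFAULT_N_ROOTS,
        filter_frame: int | None = None,
        filter_order: int = 1,
        xtol: float = 1e-10,
        ftol: float = 1e-10,
        gtol: float = 1e-10,
    ):
        self.protocol = protocol
        self.E3 = E3
        self.nu31 = nu31
        self.staged = staged
        self.bounds = bounds
        self.x0 = x0
        self.nu21_init = nu21_init
        self.n_tail = n_tail
        self.n_roots = n_roots
        self.filter_frame = filter_frame
        self.filter_order = filter_order
        self.xtol = xtol
        self.ftol = ftol
        self.gtol = gtol

    # -- internals ---------------------------------------------------------

    def _model(self, times, E1, nu21, tg, E3, nu31):
        """Model stress; invalid (Delta1 <= 0) points are continuously
        penalized so the trust region backs away from the boundary."""
        nu_max = 1.0 - 2.0 * nu31**2 * E1 / E3
        if nu_max <= 1e-6:  # no admissible nu21 at this E1/E3: steep penalty
            return np.full(len(times), 1e6 * (1.0 + (1e-6 - nu_max)))
        penalty = 0.0
        if nu21 >= nu_max - 1e-9:
            penalty = 1e3 * (nu21 - (nu_max - 1e-9))
            nu21 = nu_max - 1e-9
        if nu21 < 0:
            penalty += 1e3 * (-nu21)
            nu21 = 0.0
        trace = predict_trace(
            E1, nu21, tg, E3, nu31, self.protocol_, times, self.n_roots
        )
        stress = trace.stress
        if self.filter_frame is not None:
            stress = savgol_filter(stress, self.filter_frame, self.filter_order,
                                   mode="interp")
        return stress + penalty

    def _initial_tg(self, t, y, E3):
        """63%-drop heuristic: slowest relaxation time is tg/alpha_1**2."""
        t0 = self.protocol_.ramp_time
        hold = t >= t0
        if not hold.any():
            return 10.0
        th, yh = t[hold], y[hold]
        p_eq = E3 * self.protocol_.total_strain
        p_pk = float(yh[0])
        if p_pk <= p_eq:
            return 10.0
        target = p_eq + (p_pk - p_eq) * np.exp(-1.0)
        below = np.nonzero(yh <= target)[0]
        if len(below) == 0:
            return float(th[-1] - t0)  # tail never reached: weak identifiability
        t63 = float(th[below[0]] - t0)
        return max(t63, 1e-3) * 5.4  # alpha_1**2 ~ 5.4 for typical beta

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Fit the relaxation model to a measured trace.

        X : array-like of shape (n,) or (n, 1) — sample times, s
        y : array-like of shape (n,) — load intensity, kPa
        """
        if self.protocol is None:
            raise ValueError("a RampProtocol is required to fit a trace")
        self.protocol_ = self.protocol
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D times or a single column")
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y must have equal length")

        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)

        if self.E3 is not None:
            E3 = float(self.E3)
        else:
            trace = RelaxationTrace(time=t, stress=y, protocol=self.protocol_)
            E3 = equilibrium_modulus(
                trace, self.protocol_.total_strain, min(self.n_tail, len(t))
            )
        nu31 = float(self.nu31)

        if self.x0 is not None:
            E1_0, nu21_0, tg_0 = map(float, self.x0)
        else:
            E1_0 = np.clip(E3 / 2.0, *bounds["E1"])
            nu21_0 = np.clip(self.nu21_init, *bounds["nu21"])
            tg_0 = np.clip(self._initial_tg(t, y, E3), *bounds["tg"])

        ls_kw = dict(
            method="trf", xtol=self.xtol, ftol=self.ftol, gtol=self.gtol,
            x_scale=[max(E1_0, 1.0), 1.0, max(tg_0, 1.0)],
        )
        nfev = 0
        if self.staged:
            def resid2(q):
                return self._model(t, q[0], nu21_0, q[1], E3, nu31) - y

            lo = [bounds["E1"][0], bounds["tg"][0]]
            hi = [bounds["E1"][1], bounds["tg"][1]]
            kw2 = dict(ls_kw)
            kw2["x_scale"] = [max(E1_0, 1.0), max(tg_0, 1.0)]
            stage1 = least_squares(resid2, [E1_0, tg_0], bounds=(lo, hi), **kw2)
            nfev += stage1.nfev
            E1_0, tg_0 = stage1.x

        def resid3(q):
            return self._model(t, q[0], q[1], q[2], E3, nu31) - y

        lo = [bounds["E1"][0], bounds["nu21"][0], bounds["tg"][0]]
        hi = [bounds["E1"][1], bounds["nu21"][1], bounds["tg"][1]]
        res = least_squares(resid3, [E1_0, nu21_0, tg_0], bounds=(lo, hi), **ls_kw)
        nfev += res.nfev

        self.E1_, self.nu21_, self.tg_ = map(float, res.x)
        self.E3_, self.nu31_ = E3, nu31
        self.ssd_ = float(np.sum(res.fun**2))
        model = RelaxationTrace(time=t, stress=self._model(t, *res.x, E3, nu31),
                                protocol=self.protocol_)
        data = RelaxationTrace(time=t, stress=y, protocol=self.protocol_)
        self.r2_ = r_squared(model, data)
        self.n_iter_ = int(nfev)
        self.converged_ = bool(res.success)
        self.result_ = FitResult(
            E1=self.E1_, nu21=self.nu21_, tg=self.tg_, E3=E3, nu31=nu31,
            ssd=self.ssd_, r2=self.r2_, n_iter=self.n_iter_,
            converged=self.converged_, message=str(res.message),
        )
        return self

    def predict(self, X):
        """Model load intensity at times ``X`` for the fitted parameters."""
        if not hasattr(self, "E1_"):
            raise RuntimeError("fitter is not fitted")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return predict_trace(
            self.E1_, self.nu21_, self.tg_, self.E3_, self.nu31_,
            self.protocol_, t, self.n_roots,
        ).stress


def fit_parameters(trace: RelaxationTrace, config: FitConfig | None = None) -> FitResult:
    """Functional wrapper around :class:`PoroelasticRelaxationFitter`."""
    if trace.protocol is None:
        raise ValueError("trace carries no protocol")
    config = config or FitConfig()
    est = PoroelasticRelaxationFitter(
        protocol=trace.protocol,
        E3=config.E3,
        nu31=config.nu31,
        staged=config.staged,
        bounds=config.bounds,
        x0=config.x0,
        nu21_init=config.nu21_init,
        n_tail=config.n_tail,
        n_roots=config.n_roots,
        filter_frame=config.filter_frame,
        filter_order=config.filter_order,
        xtol=config.xtol,
        ftol=config.ftol,
        gtol=config.gtol,
    )
    est.fit(trace.time, trace.stress)
    return est.result_
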