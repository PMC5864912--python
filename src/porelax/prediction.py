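"""Prediction layer: rate sweeps, porosity interpolation, peak-force surface.

Once the scaffold parameters are estimated at a few porosities, the model
predicts relaxation behaviour across loading conditions.  The peak load
always occurs at the end of the ramp (the relaxation kernel is completely
monotone, so the stress rises throughout loading and decays throughout the
hold), which gives the peak in closed form.  The peak/equilibrium ratio is
bounded above by the isochoric step ratio ``M0/E3`` and decreases toward 1
as the rate decreases — slow loading lets the fluid drain during the ramp.

Across porosity the parameters are interpolated componentwise linearly
between the estimated anchor sets (``nu31`` is held fixed), and the peak
surface over (porosity, rate) is summarized by the empirical form

    P_pk(x, y) = m x + n + a exp(b y) + c exp(d y)

with ``x`` the porosity as a fraction and ``y`` the strain rate in %/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .constitutive import ScaffoldParameters
from .forward import (
    DEFAULT_N_ROOTS,
    RampProtocol,
    characteristic_roots,
    load_intensity,
    step_response,
)

__all__ = [
    "PeakSurfaceFit",
    "PeakSurface",
    "peak_load",
    "rate_sweep",
    "interpolate_porosity",
    "fit_peak_surface",
]


def peak_load(
    params: ScaffoldParameters,
    protocol: RampProtocol,
    n_roots: int = DEFAULT_N_ROOTS,
) -> float:
    """Peak load intensity, kPa — analytic, at the end of the ramp.

    For a step protocol the peak is the isochoric limit ``M0 * eps0``.
    """
    C = params.stiffness()
    if protocol.is_step:
        return C.instantaneous_modulus * protocol.total_strain
    roots = characteristic_roots(C.beta, n_roots)
    sol = step_response(C, roots, params.tg)
    trace = load_intensity(sol, protocol, np.array([protocol.ramp_time]))
    return float(trace.stress[0])


def rate_sweep(
    params: ScaffoldParameters,
    rates,
    total_strain: float = 0.1,
    hold_time: float = 100.0,
    include_step: bool = True,
    n_roots: int = DEFAULT_N_ROOTS,
) -> pd.DataFrame:
    """Peak, equilibrium and their ratio for a set of strain rates.

    Returns a DataFrame with columns ``rate_per_s`` (inf for the step row),
    ``peak_kPa``, ``equilibrium_kPa`` and ``ratio``.  The equilibrium value
    ``E3 * eps0`` is rate-independent; the ratio increases strictly with
    rate and tends to ``M0/E3`` for a step.
    """
    rates = [float(r) for r in rates]
    if any(r <= 0 for r in rates):
        raise ValueError("strain rates must be positive")
    eq = params.E3 * total_strain
    rows = []
    for rate in sorted(rates):
        protocol = RampProtocol(rate, total_strain, hold_time)
        pk = peak_load(params, protocol, n_roots)
        rows.append({"rate_per_s": rate, "peak_kPa": pk,
                     "equilibrium_kPa": eq, "ratio": pk / eq})
    if include_step:
        pk = peak_load(params, RampProtocol.step(total_strain, hold_time))
        rows.append({"rate_per_s": np.inf, "peak_kPa": pk,
                     "equilibrium_kPa": eq, "ratio": pk / eq})
    return pd.DataFrame(rows)


def interpolate_porosity(
    anchors: dict[float, ScaffoldParameters],
    porosity: float,
    extrapolate: str = "clamp",
) -> ScaffoldParameters:
    """Componentwise linear interpolation of (E1, E3, nu21, t_g) in porosity.

    ``nu31`` and the radius are held at the anchor values.  Outside the
    anchor hull the behaviour is controlled by ``extrapolate``:
    ``"clamp"`` (default; warn and clamp to the nearest anchor),
    ``"linear"`` (warn and extrapolate), or ``"raise"``.
    """
    if len(anchors) < 2:
        raise ValueError("at least two porosity anchors are required")
    phis = np.array(sorted(anchors))
    lo, hi = phis[0], phis[-1]
    if not lo <= porosity <= hi:
        msg = f"porosity {porosity} outside anchor hull [{lo}, {hi}]"
        if extrapolate == "raise":
            raise ValueError(msg)
        warnings.warn(msg + f" ({extrapolate})", stacklevel=2)
        if extrapolate == "clamp":
            porosity = float(np.clip(porosity, lo, hi))
        elif extrapolate != "linear":
            raise ValueError(f"unknown extrapolate mode {extrapolate!r}")

    sets = [anchors[p] for p in phis]
    nu31 = sets[0].nu31
    radius = sets[0].radius

    def interp(attr):
        return float(np.interp(porosity, phis, [getattr(s, attr) for s in sets])
                     if lo <= porosity <= hi
                     else _lin_extrap(porosity, phis, [getattr(s, attr) for s in sets]))

    return ScaffoldParameters(
        E1=interp("E1"), E3=interp("E3"), nu21=interp("nu21"), nu31=nu31,
        tg=interp("tg"), porosity=porosity, radius=radius,
    )


def _lin_extrap(x, xs, ys):
    """Linear extrapolation from the nearest anchor segment."""
    if x < xs[0]:
        i0, i1 = 0, 1
    else:
        i0, i1 = len(xs) - 2, len(xs) - 1
    slope = (ys[i1] - ys[i0]) / (xs[i1] - xs[i0])
    return ys[i0] + slope * (x - xs[i0])


@dataclass(frozen=True)
class PeakSurfaceFit:
    """Coefficients of ``f(x, y) = m x + n + a exp(b y) + c exp(d y)``."""

    m: float
    n: float
    a: float
    b: float
    c: float
    d: float
    residual: float  # root-mean-square residual, kPa

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (self.m * x + self.n
                + self.a * np.exp(self.b * y) + self.c * np.exp(self.d * y))


def _surface(X, m, n, a, b, c, d):
    x, y = X
    return m * x + n + a * np.exp(b * y) + c * np.exp(d * y)


class PeakSurface(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the peak-force surface.

    scikit-learn style regressor: ``fit(X, y)`` with ``X`` of shape
    (n, 2) — columns (porosity, strain rate) — and ``y`` the peak loads,
    kPa.  The two exponential terms make the form exchange-symmetric in
    (a, b) <-> (c, d); the fitted labelling is fixed by the initial guess
    (one fast, one slow rate constant).

    Attributes
    ----------
    m_, n_, a_, b_, c_, d_ : float
    residual_ : float — RMS residual, kPa
    fit_ : PeakSurfaceFit
    """

    def __init__(self, p0=None, maxfev: int = 20000):
        self.p0 = p0
        self.maxfev = maxfev

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n, 2): (porosity, rate)")
        if len(X) < 6:
            raise ValueError("at least 6 grid points are required (6 coefficients)")
        xs, ys = X[:, 0], X[:, 1]
        if np.unique(xs).size < 2 or np.unique(ys).size < 2:
            raise ValueError("degenerate grid: need >= 2 distinct porosities and rates")
        if self.p0 is not None:
            p0 = list(self.p0)
        else:
            # slope/intercept from the porosity trend, exponentials split
            # into one decaying fast and one nearly flat component
            m0 = np.polyfit(xs, y, 1)[0]
            span = y.max() - y.min()
            p0 = [m0, float(np.mean(y)), span, -2.0, -span / 2.0, 0.01]
        popt, _ = curve_fit((lambda X_, *p: _surface(X_, *p)), (xs, ys), y,
                            p0=p0, maxfev=self.maxfev)
        self.m_, self.n_, self.a_, self.b_, self.c_, self.d_ = map(float, popt)
        resid = _surface((xs, ys), *popt) - y
        self.residual_ = float(np.sqrt(np.mean(resid**2)))
        self.fit_ = PeakSurfaceFit(self.m_, self.n_, self.a_, self.b_,
                                   self.c_, self.d_, self.residual_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return _surface((X[:, 0], X[:, 1]), self.m_, self.n_, self.a_,
                        self.b_, self.c_, self.d_)


def fit_peak_surface(peaks: pd.DataFrame, p0=None) -> PeakSurfaceFit:
    """Fit the surface to a table with columns porosity, rate, peak_kPa.

    Rates are taken in the units the table carries (the study convention is
    %/s with porosity as a fraction); row order is irrelevant.
    """
    required = {"porosity", "rate", "peak_kPa"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peaks table must have columns {sorted(required)}")
    est = PeakSurface(p0=p0)
    est.fit(peaks[["porosity", "rate"]].to_numpy(), peaks["peak_kPa"].to_numpy())
    return est.fit_
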