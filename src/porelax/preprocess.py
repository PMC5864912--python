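"""Signal conditioning of raw bioreactor force traces.

Raw sensor output (volts from a strain-gauge amplifier, or newtons) is
converted to load intensity in kPa, the periodic motor interference is
removed with a Savitzky-Golay filter, and the independently fixed
parameters are extracted: the equilibrium modulus ``E3`` from the tail of
the relaxation, and the axial-radial Poisson's ratio ``nu31`` as a
configuration constant (default 0.24, from image-based displacement
analysis of the equilibrium state).

The filter window is matched to the motor period: with sampling at
``sample_rate`` and ``n_cycles`` motor cycles during the ramp, the frame
length is ``ramp_time * sample_rate / n_cycles`` rounded to the nearest odd
integer (a symmetric window must have odd length).  A degree-1 window
averages exactly one noise period, cancelling it while reproducing the
locally linear ramp and slowly varying relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .forward import RelaxationTrace

__all__ = [
    "CalibrationError",
    "Calibration",
    "RawTrace",
    "DEFAULT_NU31",
    "convert_raw",
    "frame_length",
    "smooth",
    "equilibrium_modulus",
    "SavitzkyGolaySmoother",
]

#: axial-radial Poisson's ratio fixed from equilibrium displacement imaging
DEFAULT_NU31 = 0.24


class CalibrationError(ValueError):
    """Raised when a raw trace cannot be converted to stress."""


@dataclass(frozen=True)
class Calibration:
    """Sensor calibration: ``stress = (signal - offset) * gain / area``.

    gain : N/V (use 1.0 if the signal is already in newtons)
    offset : V
    cross_section_area : m**2
    """

    gain: float
    offset: float
    cross_section_area: float

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise CalibrationError(f"gain must be positive, got {self.gain}")
        if not self.cross_section_area > 0:
            raise CalibrationError(
                f"cross_section_area must be positive, got {self.cross_section_area}"
            )


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled sensor trace with its calibration."""

    time: np.ndarray
    signal: np.ndarray
    calibration: Calibration | None = None
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        s = np.asarray(self.signal, float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("raw trace must be uniformly sampled")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


def convert_raw(raw: RawTrace, protocol=None) -> RelaxationTrace:
    """Convert a sensor trace to load intensity in kPa.

    ``stress_kPa = (signal - offset) * gain / cross_section_area / 1000``.
    """
    if raw.calibration is None:
        raise CalibrationError("raw trace has no calibration sidecar")
    cal = raw.calibration
    stress_pa = (raw.signal - cal.offset) * cal.gain / cal.cross_section_area
    return RelaxationTrace(time=raw.time, stress=stress_pa / 1e3, protocol=protocol)


def frame_length(ramp_time: float, sample_rate: float = 100.0, n_cycles: int = 10) -> int:
    """Savitzky-Golay frame length matched to the motor period.

    ``ramp_time * sample_rate / n_cycles`` rounded to the nearest odd
    integer (ties round up); a symmetric filter window must be odd.  Raises
    if the result would be below 3 (filter inapplicable: fewer than ~1.5
    samples per noise cycle).
    """
    if not (ramp_time > 0 and sample_rate > 0 and n_cycles > 0):
        raise ValueError("ramp_time, sample_rate and n_cycles must be positive")
    raw = ramp_time * sample_rate / n_cycles
    lower = int(np.floor(raw))
    lower = lower if lower % 2 == 1 else lower - 1
    upper = lower + 2
    frame = upper if (upper - raw) <= (raw - lower) else lower
    if frame < 3:
        raise ValueError(
            f"frame length {frame} < 3 (window {raw:.3g} samples); the "
            "periodic-noise filter is inapplicable at this sampling"
        )
    return frame


def smooth(
    trace: RelaxationTrace, frame: int, poly_order: int = 1
) -> RelaxationTrace:
    """Savitzky-Golay smoothing of a stress trace.

    Least-squares local polynomial of degree ``poly_order`` over ``frame``
    samples; output has the same length as the input, with the terminal
    windows handled by polynomial extrapolation so the trace is not
    shortened.  A degree-1 filter reproduces affine signals exactly and
    strongly attenuates any periodic component whose period matches the
    frame.
    """
    if frame % 2 == 0:
        raise ValueError(f"frame must be odd, got {frame}")
    if frame <= poly_order:
        raise ValueError(f"frame ({frame}) must exceed poly_order ({poly_order})")
    if frame > len(trace):
        raise ValueError(
            f"frame ({frame}) exceeds trace length ({len(trace)})"
        )
    sm = savgol_filter(trace.stress, frame, poly_order, mode="interp")
    return replace(trace, stress=sm)


def equilibrium_modulus(
    trace: RelaxationTrace, total_strain: float, n_tail: int = 1000
) -> float:
    """Equilibrium fibre-direction modulus from the relaxation tail, kPa.

    Mean of the last ``n_tail`` stress samples divided by the total strain:
    ``E3 = P(inf)/eps0`` at drained equilibrium.
    """
    if not total_strain > 0:
        raise ValueError(f"total_strain must be positive, got {total_strain}")
    if n_tail < 1:
        raise ValueError(f"n_tail must be >= 1, got {n_tail}")
    if len(trace) < n_tail:
        raise ValueError(
            f"trace has {len(trace)} samples, fewer than n_tail={n_tail}"
        )
    return float(np.mean(trace.stress[-n_tail:]) / total_strain)


class SavitzkyGolaySmoother(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing as a scikit-learn transformer.

    Operates column-wise on 2-D input (samples x traces); a 1-D array is
    treated as a single trace.  ``frame=None`` derives the window from the
    motor period via :func:`frame_length`.

    Parameters
    ----------
    frame : int or None
        Odd window length in samples.
    poly_order : int
        Local polynomial degree (1 reproduces the linear ramp exactly).
    ramp_time, sample_rate, n_cycles :
        Used to derive ``frame`` when it is None.
    """

    def __init__(
        self,
        frame: int | None = None,
        poly_order: int = 1,
        ramp_time: float | None = None,
        sample_rate: float = 100.0,
        n_cycles: int = 10,
    ):
        self.frame = frame
        self.poly_order = poly_order
        self.ramp_time = ramp_time
        self.sample_rate = sample_rate
        self.n_cycles = n_cycles

    def fit(self, X, y=None):
        if self.frame is not None:
            frame = int(self.frame)
            if frame % 2 == 0 or frame < 3:
                raise ValueError(f"frame must be an odd integer >= 3, got {frame}")
        else:
            if self.ramp_time is None:
                raise ValueError("either frame or ramp_time must be given")
            frame = frame_length(self.ramp_time, self.sample_rate, self.n_cycles)
        self.frame_ = frame
        return self

    def transform(self, X):
        if not hasattr(self, "frame_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        if self.frame_ > X.shape[0]:
            raise ValueError(
                f"frame ({self.frame_}) exceeds trace length ({X.shape[0]})"
            )
        return savgol_filter(X, self.frame_, self.poly_order, axis=0, mode="interp")
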