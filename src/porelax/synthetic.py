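"""Synthetic bioreactor traces with the noise structure of the real rig.

The force readout of the stress-relaxation bioreactor carries two noise
components: a periodic interference from the stepper motor that drives the
actuator, and broadband sensor noise from the strain-gauge amplifier.  The
generator superimposes both on the analytic poroelastic response:

    signal(t) = P(t) + A_motor * sin(2 pi f_motor t + phase) + N(0, sigma)

The motor phase is drawn from the seed (not fixed), so downstream recovery
tests cannot be tuned to a particular phase.  Default magnitudes make the
periodic component dominant over the sensor noise (amplitude 5% vs standard
deviation 2% of the equilibrium stress ``E3 * eps0``), reflecting a
low-sensitivity load cell next to a cyclically stepping motor, while
leaving the parameters recoverable after filtering.

Traces are emitted as :class:`~porelax.preprocess.RawTrace` in sensor volts
with a calibration sidecar, exercising the full conversion pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constitutive import ScaffoldParameters
from .fitting import predict_trace
from .forward import RampProtocol
from .preprocess import Calibration, RawTrace

__all__ = [
    "NoiseSpec",
    "REFERENCE_SCAFFOLDS",
    "STUDY_STRAIN_RATES",
    "default_noise",
    "generate_trace",
    "generate_study",
]

#: Reference parameter sets for electrospun fibrin scaffolds at 50% and 70%
#: porosity (estimated from ramp-and-hold tension at 1%/s, 10% strain).
REFERENCE_SCAFFOLDS: dict[float, ScaffoldParameters] = {
    0.5: ScaffoldParameters(E1=8.49, E3=19.19, nu21=0.75, nu31=0.24,
                            tg=40.62, porosity=0.5, radius=1.0e-3),
    0.7: ScaffoldParameters(E1=5.61, E3=11.97, nu21=0.82, nu31=0.24,
                            tg=17.58, porosity=0.7, radius=1.0e-3),
}

#: strain rates of the rate-sweep study, 1/s
STUDY_STRAIN_RATES = (0.0025, 0.005, 0.01, 0.03)

#: nominal sensor calibration of the synthetic rig
_CALIBRATION = Calibration(gain=0.5, offset=0.1, cross_section_area=math.pi * 1.0e-6)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of the synthetic rig.

    motor_amplitude : kPa — amplitude of the sinusoidal motor interference
    motor_frequency : Hz — must be below Nyquist of the sampling
    sensor_sigma : kPa — standard deviation of the Gaussian sensor noise
    seed : int — drives both the motor phase and the Gaussian draws
    """

    motor_amplitude: float
    motor_frequency: float
    sensor_sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.motor_amplitude < 0 or self.sensor_sigma < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.motor_frequency < 0:
            raise ValueError("motor_frequency must be non-negative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseSpec":
        return cls(motor_amplitude=0.0, motor_frequency=1.0, sensor_sigma=0.0, seed=seed)


def default_noise(E3: float, total_strain: float, seed: int) -> NoiseSpec:
    """Default noise: motor 1 Hz at 5% and sensor sigma 2% of ``E3 * eps0``."""
    scale = E3 * total_strain
    return NoiseSpec(
        motor_amplitude=0.05 * scale,
        motor_frequency=1.0,
        sensor_sigma=0.02 * scale,
        seed=seed,
    )


def generate_trace(
    params: ScaffoldParameters,
    protocol: RampProtocol,
    noise: NoiseSpec,
    sample_rate: float = 100.0,
) -> RawTrace:
    """One synthetic raw trace: analytic response + motor + sensor noise.

    Deterministic for a fixed ``noise.seed``.  The stress-domain signal is
    converted to sensor volts through the rig calibration, so the trace
    must pass through :func:`porelax.preprocess.convert_raw` like real data.
    """
    if noise.motor_frequency >= sample_rate / 2.0:
        raise ValueError(
            f"motor_frequency {noise.motor_frequency} Hz is at or above "
            f"Nyquist ({sample_rate / 2.0} Hz)"
        )
    n = int(round(protocol.duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    clean = predict_trace(
        params.E1, params.nu21, params.tg, params.E3, params.nu31, protocol, t
    ).stress
    rng = np.random.default_rng(noise.seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    stress = (
        clean
        + noise.motor_amplitude * np.sin(2.0 * math.pi * noise.motor_frequency * t + phase)
        + rng.normal(0.0, noise.sensor_sigma, size=n)
    )
    cal = _CALIBRATION
    signal = stress * 1e3 * cal.cross_section_area / cal.gain + cal.offset
    return RawTrace(time=t, signal=signal, calibration=cal, sample_rate=sample_rate)


def _subseed(seed: int, index: int) -> int:
    """Counter-scheme sub-seed: independent streams from one global seed."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def generate_study(
    seed: int,
    noiseless: bool = False,
    hold_time: float = 100.0,
    total_strain: float = 0.1,
    sample_rate: float = 100.0,
) -> list[dict]:
    """The full synthetic study: two porosities x four strain rates.

    Returns a list of records, each with keys ``raw`` (RawTrace),
    ``protocol`` (RampProtocol), ``params`` (generating ScaffoldParameters),
    ``noise`` (NoiseSpec) and ``meta`` (self-describing JSON-able dict).
    Each trace gets a distinct sub-seed derived from the global seed by a
    counter scheme, so traces are independent yet reproducible.
    """
    records = []
    index = 0
    for porosity in sorted(REFERENCE_SCAFFOLDS):
        params = REFERENCE_SCAFFOLDS[porosity]
        for rate in STUDY_STRAIN_RATES:
            protocol = RampProtocol(
                strain_rate=rate, total_strain=total_strain, hold_time=hold_time
            )
            sub = _subseed(seed, index)
            if noiseless:
                noise = NoiseSpec.silent(seed=sub)
            else:
                noise = default_noise(params.E3, total_strain, seed=sub)
            raw = generate_trace(params, protocol, noise, sample_rate)
            meta = {
                "porosity": porosity,
                "strain_rate_per_s": rate,
                "total_strain": total_strain,
                "hold_time_s": hold_time,
                "sample_rate_hz": sample_rate,
                "seed": sub,
                "motor_frequency_hz": noise.motor_frequency,
                "motor_amplitude_kPa": noise.motor_amplitude,
                "sensor_sigma_kPa": noise.sensor_sigma,
                "params": params.to_dict(),
            }
            records.append(
                {"raw": raw, "protocol": protocol, "params": params,
                 "noise": noise, "meta": meta}
            )
            index += 1
    return records
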