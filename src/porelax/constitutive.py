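"""Elastic and transport parameters of a transversely isotropic biphasic scaffold.

The solid skeleton of a fibrous-porous scaffold is modelled as a linear
transversely isotropic material: isotropic in the plane normal to the fibre
axis (``x1 x2``), with distinct stiffness along the fibres (``x3``).  Under
axisymmetric loading only four stiffness coefficients enter the plane-strain
problem, here collected in :class:`StiffnessMatrix`.  They are obtained from
the engineering constants (two Young's moduli, two Poisson's ratios) by exact
inversion of the compliance matrix

    S = [[ 1/E1, -nu21/E1, -nu31/E3],
         [-nu21/E1,  1/E1, -nu31/E3],
         [-nu31/E3, -nu31/E3, 1/E3]]

All stresses and moduli are carried in kPa.  The fluid phase enters through
the Darcy permeability ``k`` or, equivalently, the gel diffusion time
``t_g = a**2 / (k * C11)`` — the characteristic time for pore fluid to
diffuse across the cylinder radius ``a``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ConstitutiveError",
    "EngineeringConstants",
    "StiffnessMatrix",
    "TransportParameters",
    "ScaffoldParameters",
    "stiffness_from_engineering",
    "engineering_from_stiffness",
    "gel_time_permeability",
]

#: kPa -> N/m**2
KPA = 1.0e3


class ConstitutiveError(ValueError):
    """A parameter set violates a thermodynamic or algebraic constraint."""


@dataclass(frozen=True)
class EngineeringConstants:
    """Engineering constants of the transversely isotropic solid skeleton.

    Parameters
    ----------
    E1 : float
        In-plane Young's modulus (radial direction), kPa.
    E3 : float
        Fibre-direction Young's modulus, kPa.
    nu21 : float
        In-plane Poisson's ratio ``-eps_phiphi / eps_rr``.
    nu31 : float
        Axial-radial Poisson's ratio ``-eps_rr / eps_zz``.
    """

    E1: float
    E3: float
    nu21: float
    nu31: float

    def __post_init__(self) -> None:
        if not self.E1 > 0:
            raise ConstitutiveError(f"E1 must be positive, got {self.E1}")
        if not self.E3 > 0:
            raise ConstitutiveError(f"E3 must be positive, got {self.E3}")
        if not 1.0 + self.nu21 > 0:
            raise ConstitutiveError(f"1 + nu21 must be positive, got nu21={self.nu21}")
        if not self.delta1 > 0:
            raise ConstitutiveError(
                "Delta1 = 1 - nu21 - 2*nu31**2*E1/E3 must be positive, got "
                f"{self.delta1:.6g} (nu21={self.nu21}, nu31={self.nu31}, "
                f"E1/E3={self.E1 / self.E3:.4g})"
            )
        # positive definiteness of the full compliance
        if np.linalg.eigvalsh(self.compliance()).min() <= 0:
            raise ConstitutiveError(
                "compliance matrix is not positive definite for "
                f"(E1={self.E1}, E3={self.E3}, nu21={self.nu21}, nu31={self.nu31})"
            )

    @property
    def delta1(self) -> float:
        """``1 - nu21 - 2 nu31**2 E1/E3``, positive for a stable material."""
        return 1.0 - self.nu21 - 2.0 * self.nu31**2 * self.E1 / self.E3

    def compliance(self) -> np.ndarray:
        """3x3 compliance in the (rr, phiphi, zz) basis, 1/kPa."""
        s11 = 1.0 / self.E1
        s12 = -self.nu21 / self.E1
        s13 = -self.nu31 / self.E3
        s33 = 1.0 / self.E3
        return np.array([[s11, s12, s13], [s12, s11, s13], [s13, s13, s33]])


@dataclass(frozen=True)
class StiffnessMatrix:
    """Axisymmetric plane-problem stiffness coefficients, kPa.

    The elastic stress is ``sigma^E = C @ (eps_rr, eps_phiphi, eps_zz)`` with

        C = [[C11, C12, C13],
             [C12, C11, C13],
             [C13, C13, C33]]
    """

    C11: float
    C12: float
    C13: float
    C33: float

    def __post_init__(self) -> None:
        if not self.C11 > abs(self.C12):
            raise ConstitutiveError(
                f"C11 > |C12| required, got C11={self.C11}, C12={self.C12}"
            )
        if not self.C11 + self.C12 > 0:
            raise ConstitutiveError(
                f"C11 + C12 must be positive, got {self.C11 + self.C12}"
            )
        if not self.C33 > 0:
            raise ConstitutiveError(f"C33 must be positive, got {self.C33}")
        if not (self.C11 + self.C12) * self.C33 - 2.0 * self.C13**2 > 0:
            raise ConstitutiveError(
                "(C11+C12)*C33 - 2*C13**2 must be positive, got "
                f"{(self.C11 + self.C12) * self.C33 - 2.0 * self.C13**2:.6g}"
            )

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.C11, self.C12, self.C13],
                [self.C12, self.C11, self.C13],
                [self.C13, self.C13, self.C33],
            ]
        )

    @property
    def beta(self) -> float:
        """``1 - C12/C11``, coefficient of the characteristic Bessel equation."""
        return 1.0 - self.C12 / self.C11

    @property
    def equilibrium_modulus(self) -> float:
        """Drained fibre-direction modulus ``E3 = C33 - 2 C13**2/(C11+C12)``."""
        return self.C33 - 2.0 * self.C13**2 / (self.C11 + self.C12)

    @property
    def instantaneous_modulus(self) -> float:
        """Isochoric step modulus ``M0 = C33 - 2 C13 + (C11+C12)/2``.

        At ``t = 0+`` after a step strain no fluid has moved; the mixture
        responds at constant volume with ``u_r = -eps0 r / 2`` and the
        cross-section-averaged axial stress is ``M0 * eps0``.
        """
        return self.C33 - 2.0 * self.C13 + (self.C11 + self.C12) / 2.0


def stiffness_from_engineering(ec: EngineeringConstants) -> StiffnessMatrix:
    """Invert the compliance matrix to obtain the stiffness coefficients.

    The conversion is done by numerical inversion of the 3x3 compliance
    rather than closed-form expressions; the identities
    ``C13/(C11+C12) == nu31`` and ``C33 - 2 C13**2/(C11+C12) == E3`` then
    hold to rounding error by construction.
    """
    C = np.linalg.inv(ec.compliance())
    return StiffnessMatrix(C11=C[0, 0], C12=C[0, 1], C13=C[0, 2], C33=C[2, 2])


def engineering_from_stiffness(C: StiffnessMatrix) -> EngineeringConstants:
    """Inverse map of :func:`stiffness_from_engineering`."""
    M = C.as_matrix()
    if abs(np.linalg.det(M)) < 1e-300:
        raise ConstitutiveError("stiffness matrix is singular")
    S = np.linalg.inv(M)
    E1 = 1.0 / S[0, 0]
    E3 = 1.0 / S[2, 2]
    nu21 = -S[0, 1] / S[0, 0]
    nu31 = -S[0, 2] / S[2, 2]
    return EngineeringConstants(E1=E1, E3=E3, nu21=nu21, nu31=nu31)


@dataclass(frozen=True)
class TransportParameters:
    """Fluid-transport parameters of the scaffold.

    At most two of ``k`` (Darcy permeability, m^4/(N s)), ``tg`` (gel
    diffusion time, s) and ``a`` (specimen radius, m) are independent once
    ``C11`` is known; :func:`gel_time_permeability` completes the third.
    Porosity (fluid volume fraction) drops out of the reduced displacement
    problem and is carried as metadata only.
    """

    k: float | None = None
    tg: float | None = None
    a: float | None = None
    porosity: float | None = None

    def __post_init__(self) -> None:
        for name in ("k", "tg", "a"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConstitutiveError(f"{name} must be positive, got {v}")
        if self.porosity is not None and not 0.0 <= self.porosity < 1.0:
            raise ConstitutiveError(
                f"porosity must lie in [0, 1), got {self.porosity}"
            )


def gel_time_permeability(tp: TransportParameters, C11: float) -> TransportParameters:
    """Complete ``(k, tg, a)`` from any two of them via ``tg = a**2/(k C11)``.

    Parameters
    ----------
    tp : TransportParameters
        Exactly two of ``k``, ``tg``, ``a`` set.
    C11 : float
        Radial stiffness coefficient, kPa (converted to N/m**2 internally).
    """
    given = [name for name in ("k", "tg", "a") if getattr(tp, name) is not None]
    if len(given) != 2:
        raise ConstitutiveError(
            f"exactly two of (k, tg, a) must be given, got {given or 'none'}"
        )
    c11 = C11 * KPA
    if tp.k is None:
        k = tp.a**2 / (tp.tg * c11)
        return replace(tp, k=k)
    if tp.tg is None:
        tg = tp.a**2 / (tp.k * c11)
        return replace(tp, tg=tg)
    a = math.sqrt(tp.tg * tp.k * c11)
    return replace(tp, a=a)


@dataclass(frozen=True)
class ScaffoldParameters:
    """A complete scaffold description: elasticity + transport + geometry.

    JSON round-trips bit-stably through :meth:`to_json` / :meth:`from_json`
    using the keys ``E1_kPa, E3_kPa, nu21, nu31, tg_s, porosity, radius_m``.
    """

    E1: float
    E3: float
    nu21: float
    nu31: float
    tg: float
    porosity: float | None = None
    radius: float = 1.0e-3

    def __post_init__(self) -> None:
        self.engineering()  # validate
        if not self.tg > 0:
            raise ConstitutiveError(f"tg must be positive, got {self.tg}")
        if not self.radius > 0:
            raise ConstitutiveError(f"radius must be positive, got {self.radius}")

    def engineering(self) -> EngineeringConstants:
        return EngineeringConstants(self.E1, self.E3, self.nu21, self.nu31)

    def stiffness(self) -> StiffnessMatrix:
        return stiffness_from_engineering(self.engineering())

    def transport(self) -> TransportParameters:
        """Transport parameters with permeability completed from ``tg``."""
        tp = TransportParameters(tg=self.tg, a=self.radius, porosity=self.porosity)
        return gel_time_permeability(tp, self.stiffness().C11)

    def to_dict(self) -> dict:
        return {
            "E1_kPa": self.E1,
            "E3_kPa": self.E3,
            "nu21": self.nu21,
            "nu31": self.nu31,
            "tg_s": self.tg,
            "porosity": self.porosity,
            "radius_m": self.radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldParameters":
        return cls(
            E1=d["E1_kPa"],
            E3=d["E3_kPa"],
            nu21=d["nu21"],
            nu31=d["nu31"],
            tg=d["tg_s"],
            porosity=d.get("porosity"),
            radius=d.get("radius_m", 1.0e-3),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaffoldParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))
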