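"""Constitutive conversions: compliance inversion, identities, transport."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from porelax.constitutive import (
    ConstitutiveError,
    EngineeringConstants,
    ScaffoldParameters,
    StiffnessMatrix,
    TransportParameters,
    engineering_from_stiffness,
    gel_time_permeability,
    stiffness_from_engineering,
)

from conftest import random_engineering_constants


def closed_form_stiffness(ec):
    """Independent algebraic oracle: corrected closed-form coefficients."""
    r = ec.nu31**2 * ec.E1 / ec.E3
    d1 = 1.0 - ec.nu21 - 2.0 * r
    C11 = ec.E1 * (1.0 - r) / ((1.0 + ec.nu21) * d1)
    C12 = ec.E1 * (ec.nu21 + r) / ((1.0 + ec.nu21) * d1)
    C13 = ec.E1 * ec.nu31 / d1
    C33 = ec.E3 * (1.0 - ec.nu21) / d1
    return C11, C12, C13, C33


class TestStiffnessFromEngineering:
    @pytest.mark.parametrize(
        "ec_args, expected",
        [
            # numeric inversion of the compliance assembled from the two
            # reference scaffolds
            ((8.49, 19.19, 0.75, 0.24), (23.7538, 18.9024, 10.2375, 24.1040)),
            ((5.61, 11.97, 0.82, 0.24), (23.8015, 20.7191, 10.6849, 17.0988)),
        ],
    )
    def test_reference_values(self, ec_args, expected):
        C = stiffness_from_engineering(EngineeringConstants(*ec_args))
        got = (C.C11, C.C12, C.C13, C.C33)
        assert got == pytest.approx(expected, abs=5e-4)

    def test_isotropic_limit(self):
        E, nu = 10.0, 0.3
        C = stiffness_from_engineering(EngineeringConstants(E, E, nu, nu))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        diag = E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
        assert C.C11 == pytest.approx(diag, rel=1e-12)
        assert C.C33 == pytest.approx(diag, rel=1e-12)
        assert C.C12 == pytest.approx(lam, rel=1e-12)
        assert C.C13 == pytest.approx(lam, rel=1e-12)

    def test_agrees_with_closed_form_on_random_sets(self, rng):
        for ec in random_engineering_constants(rng, 25):
            C = stiffness_from_engineering(ec)
            exp = closed_form_stiffness(ec)
            assert (C.C11, C.C12, C.C13, C.C33) == pytest.approx(exp, rel=1e-10)

    def test_algebraic_identities_on_random_sets(self, rng):
        """nu31 and E3 are recoverable from C exactly."""
        for ec in random_engineering_constants(rng, 25):
            C = stiffness_from_engineering(ec)
            assert C.C13 / (C.C11 + C.C12) == pytest.approx(ec.nu31, abs=1e-10)
            assert C.equilibrium_modulus == pytest.approx(ec.E3, rel=1e-10)

    def test_invalid_material_raises_named_error(self):
        with pytest.raises(ConstitutiveError, match="Delta1"):
            EngineeringConstants(E1=10.0, E3=10.0, nu21=0.9, nu31=0.4)
        with pytest.raises(ConstitutiveError, match="E1"):
            EngineeringConstants(E1=-1.0, E3=10.0, nu21=0.3, nu31=0.2)


class TestEngineeringFromStiffness:
    def test_reference_equilibrium_modulus_and_nu31(self):
        C = stiffness_from_engineering(EngineeringConstants(8.49, 19.19, 0.75, 0.24))
        ec = engineering_from_stiffness(C)
        assert ec.E3 == pytest.approx(19.19, abs=5e-3)
        assert ec.nu31 == pytest.approx(0.24, abs=5e-4)

    def test_round_trip_identity(self, rng):
        for ec in random_engineering_constants(rng, 25):
            back = engineering_from_stiffness(stiffness_from_engineering(ec))
            assert back.E1 == pytest.approx(ec.E1, rel=1e-10)
            assert back.E3 == pytest.approx(ec.E3, rel=1e-10)
            assert back.nu21 == pytest.approx(ec.nu21, abs=1e-10)
            assert back.nu31 == pytest.approx(ec.nu31, abs=1e-10)

    def test_stiffness_invariants_enforced(self):
        with pytest.raises(ConstitutiveError):
            StiffnessMatrix(C11=10.0, C12=12.0, C13=5.0, C33=20.0)  # C11 < C12
        with pytest.raises(ConstitutiveError):
            StiffnessMatrix(C11=10.0, C12=8.0, C13=20.0, C33=20.0)  # PD violated


class TestGelTimePermeability:
    C11 = 23.7538  # kPa

    def test_missing_quantity_computed_consistently(self):
        tp = gel_time_permeability(
            TransportParameters(tg=40.62, a=1e-3), C11=self.C11
        )
        # re-substitution: tg * k * C11 == a**2 (C11 in N/m**2)
        assert tp.tg * tp.k * self.C11 * 1e3 == pytest.approx(1e-6, rel=1e-12)
        tp2 = gel_time_permeability(
            TransportParameters(k=tp.k, a=1e-3), C11=self.C11
        )
        assert tp2.tg == pytest.approx(40.62, rel=1e-12)

    def test_radius_squared_scaling(self):
        k = 1e-12
        tg1 = gel_time_permeability(TransportParameters(k=k, a=1e-3), self.C11).tg
        tg2 = gel_time_permeability(TransportParameters(k=k, a=2e-3), self.C11).tg
        assert tg2 == pytest.approx(4.0 * tg1, rel=1e-12)

    def test_high_permeability_limit(self):
        tgs = [
            gel_time_permeability(TransportParameters(k=k, a=1e-3), self.C11).tg
            for k in (1e-12, 1e-9, 1e-6)
        ]
        assert tgs[0] > tgs[1] > tgs[2]
        assert tgs[2] < 1e-3 * tgs[0]

    def test_over_and_under_determined_inputs_raise(self):
        with pytest.raises(ConstitutiveError, match="exactly two"):
            gel_time_permeability(
                TransportParameters(k=1e-12, tg=40.0, a=1e-3), self.C11
            )
        with pytest.raises(ConstitutiveError, match="exactly two"):
            gel_time_permeability(TransportParameters(a=1e-3), self.C11)


class TestScaffoldParameters:
    def test_json_round_trip_bit_stable(self, tmp_path):
        p = ScaffoldParameters(E1=8.49, E3=19.19, nu21=0.75, nu31=0.24,
                               tg=40.62, porosity=0.5, radius=1e-3)
        path = tmp_path / "params.json"
        p.to_json(path)
        first = path.read_bytes()
        back = ScaffoldParameters.from_json(path)
        assert back == p
        back.to_json(path)
        assert path.read_bytes() == first

    def test_transport_consistency(self):
        p = ScaffoldParameters(E1=8.49, E3=19.19, nu21=0.75, nu31=0.24, tg=40.62)
        tp = p.transport()
        assert tp.tg == p.tg
        assert tp.k > 0


@given(
    E1=st.floats(1.0, 30.0),
    E3=st.floats(2.0, 40.0),
    nu21=st.floats(0.0, 0.9),
    nu31=st.floats(0.0, 0.45),
)
def test_positive_definiteness_is_preserved_or_rejected(E1, E3, nu21, nu31):
    """Valid inputs produce a PD stiffness; invalid ones raise."""
    try:
        ec = EngineeringConstants(E1=E1, E3=E3, nu21=nu21, nu31=nu31)
    except ConstitutiveError:
        return
    C = stiffness_from_engineering(ec)
    eigs = np.linalg.eigvalsh(C.as_matrix())
    assert eigs.min() > 0
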