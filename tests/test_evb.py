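"""Diabat, mapping-potential and adiabatic-ground surface behaviour."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from evbkit import (
    DiabaticState,
    EVBTopology,
    adiabatic_ground,
    diabat_energy,
    energy_gap,
    mapping_energy,
)
from evbkit.errors import ConfigurationError, ValidationError
from evbkit.evb import pair_ground

from conftest import marcus_topology


def state(x0=0.0, f=100.0, c=0.0, role="reactant", quartic=0.0):
    return DiabaticState(id="s", role=role, x0=x0, f=f, c=c, quartic=quartic)


@pytest.mark.parametrize(
    "x0,f,c,x,expected",
    [
        (0.0, 100.0, 0.0, 0.0, 0.0),  # parabola minimum
        (0.0, 100.0, 0.0, 1.0, 50.0),  # 0.5 * 100 * 1^2
        (2.0, 80.0, -3.0, 3.0, 37.0),  # 0.5 * 80 * 1 - 3
    ],
)
def test_diabat_energy_hand_values(x0, f, c, x, expected):
    assert diabat_energy(state(x0, f, c), x) == pytest.approx(expected, abs=1e-12)


def test_diabat_quartic_term():
    s = state(1.0, 10.0, 0.0, quartic=2.0)
    assert s.energy(3.0) == pytest.approx(0.5 * 10 * 4 + 2 * 16)
    assert s.derivative(3.0) == pytest.approx(10 * 2 + 4 * 2 * 8)


def test_diabat_validation():
    with pytest.raises(ConfigurationError):
        state(f=0.0)
    with pytest.raises(ConfigurationError):
        state(f=-5.0)
    with pytest.raises(ConfigurationError):
        state(role="banana")


def two_state(alpha2=0.0, h=0.0, c2=0.0, d=1.0, f=100.0):
    return EVBTopology(
        states=(state(0.0, f), state(d, f, c2, role="product")),
        alpha=(0.0, alpha2),
        coupling=((0.0, h), (h, 0.0)),
        temperature=300.0,
    )


class TestMappingEnergy:
    def test_endpoint_identity(self):
        topo = two_state(alpha2=5.0, c2=-2.0)
        xs = np.linspace(-3, 3, 41)
        np.testing.assert_array_equal(
            mapping_energy(topo, (1.0, 0.0), xs), topo.states[0].energy(xs)
        )
        np.testing.assert_allclose(
            mapping_energy(topo, (0.0, 1.0), xs),
            topo.states[1].energy(xs) + 5.0,
            rtol=0,
            atol=1e-12,
        )

    def test_midpoint_average(self):
        # eps1(x) = 10 and eps2(x) + alpha2 = 20 at a chosen point -> 15
        topo = two_state(alpha2=20.0 - 50.0, d=1.0)  # eps2(0)=50, shifted=20
        x = np.sqrt(2 * 10 / 100.0)  # eps1 = 10 there? 0.5*100*x^2 = 10
        e1 = topo.states[0].energy(x)
        e2 = topo.states[1].energy(x) + topo.alpha[1]
        got = mapping_energy(topo, (0.5, 0.5), x)
        assert got == pytest.approx(0.5 * (e1 + e2), abs=1e-12)

    def test_unnormalized_lambda_rejected(self):
        topo = two_state()
        with pytest.raises(ValidationError):
            mapping_energy(topo, (0.7, 0.7), 0.0)
        with pytest.raises(ValidationError):
            mapping_energy(topo, (1.2, -0.2), 0.0)
        with pytest.raises(ValidationError):
            mapping_energy(topo, (1.0, 0.0, 0.0), 0.0)


class TestAdiabaticGround:
    def test_degenerate_uncoupled(self):
        # eps1 = eps2 = 10 shifted, H = 0 -> 10
        topo = two_state(alpha2=0.0, d=0.0, c2=0.0)
        x = np.sqrt(0.2)  # 0.5*100*x^2 = 10
        assert adiabatic_ground(topo, x, active=(0, 1)) == pytest.approx(10.0)

    def test_degenerate_coupled(self):
        topo = two_state(h=3.0, d=0.0)
        x = np.sqrt(0.2)
        assert adiabatic_ground(topo, x, active=(0, 1)) == pytest.approx(7.0)

    def test_asymmetric_closed_form(self):
        # eps1=0, eps2=10, H=2 -> 5 - sqrt(29)
        assert pair_ground(0.0, 10.0, 2.0) == pytest.approx(5 - np.sqrt(29), abs=1e-12)

    def test_pair_formula_matches_eigendecomposition(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            e1, e2 = rng.normal(0, 50, 2)
            h = rng.uniform(0, 30)
            ref = np.linalg.eigvalsh(np.array([[e1, h], [h, e2]]))[0]
            assert pair_ground(e1, e2, h) == pytest.approx(ref, abs=1e-10)

    def test_three_state_full_diagonalization(self):
        topo = EVBTopology(
            states=(
                state(0.0, 100.0),
                state(1.0, 100.0, role="intermediate"),
                state(2.0, 100.0, role="product"),
            ),
            alpha=(0.0, 5.0, -3.0),
            coupling=((0, 4.0, 0), (4.0, 0, 2.0), (0, 2.0, 0)),
            temperature=300.0,
        )
        x = 0.7
        eps = topo.shifted_energies(x)
        Hm = topo.coupling_array + np.diag(eps)
        ref = np.linalg.eigvalsh(Hm)[0]
        assert adiabatic_ground(topo, x, active="all") == pytest.approx(ref, abs=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(
        x=st.floats(-3, 4),
        lam=st.floats(0, 1),
        h=st.floats(0, 20),
        alpha2=st.floats(-30, 30),
    )
    def test_ground_below_mapping(self, x, lam, h, alpha2):
        """The adiabatic ground never exceeds any mapping potential."""
        topo = two_state(alpha2=alpha2, h=h)
        eg = adiabatic_ground(topo, x, active=(0, 1))
        em = mapping_energy(topo, (1 - lam, lam), x)
        assert eg <= em + 1e-10


class TestEnergyGap:
    def test_zero_at_crossing_and_antisymmetry(self):
        topo = two_state(d=1.0)
        x_cross = 0.5  # symmetric diabats cross midway
        assert energy_gap(topo, (0, 1), x_cross) == pytest.approx(0.0, abs=1e-12)
        for x in (-1.0, 0.3, 2.0):
            assert energy_gap(topo, (0, 1), x) == pytest.approx(
                -energy_gap(topo, (1, 0), x)
            )

    def test_reactant_basin_negative(self):
        # f=100 both, centers 0 and 1, alpha=0: gap(0) = 0 - 50 = -50
        topo = two_state(d=1.0)
        assert energy_gap(topo, (0, 1), 0.0) == pytest.approx(-50.0)

    def test_invalid_pair(self):
        topo = two_state()
        with pytest.raises(ValidationError):
            energy_gap(topo, (0, 2), 0.0)
        with pytest.raises(ValidationError):
            energy_gap(topo, (1, 1), 0.0)


def test_gauge_invariance_of_surfaces():
    """Adding a constant to every diabat shifts all energies by it."""
    topo = marcus_topology(dG0=3.0, H=2.0)
    shifted = EVBTopology(
        states=tuple(
            DiabaticState(
                id=s.id, role=s.role, x0=s.x0, f=s.f, c=s.c + 7.5
            )
            for s in topo.states
        ),
        alpha=topo.alpha,
        coupling=topo.coupling,
        temperature=topo.temperature,
    )
    xs = np.linspace(-1, 2, 31)
    np.testing.assert_allclose(
        mapping_energy(shifted, (0.3, 0.7), xs),
        mapping_energy(topo, (0.3, 0.7), xs) + 7.5,
        atol=1e-10,
    )
    np.testing.assert_allclose(
        adiabatic_ground(shifted, xs, active=(0, 1)),
        adiabatic_ground(topo, xs, active=(0, 1)) + 7.5,
        atol=1e-10,
    )
    np.testing.assert_allclose(
        energy_gap(shifted, (0, 1), xs), energy_gap(topo, (0, 1), xs), atol=1e-10
    )


class TestTopologyValidation:
    def test_alpha_zero_reference(self):
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(), state(1.0, role="product")),
                alpha=(1.0, 0.0),
                coupling=((0, 0), (0, 0)),
            )

    def test_coupling_symmetry_and_sign(self):
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(), state(1.0, role="product")),
                alpha=(0.0, 0.0),
                coupling=((0, 1.0), (2.0, 0)),
            )
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(), state(1.0, role="product")),
                alpha=(0.0, 0.0),
                coupling=((0, -1.0), (-1.0, 0)),
            )
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(), state(1.0, role="product")),
                alpha=(0.0, 0.0),
                coupling=((1.0, 0), (0, 1.0)),
            )

    def test_temperature_and_arity(self):
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(),),
                alpha=(0.0,),
                coupling=((0.0,),),
            )
        with pytest.raises(ConfigurationError):
            EVBTopology(
                states=(state(), state(1.0, role="product")),
                alpha=(0.0, 0.0),
                coupling=((0, 0), (0, 0)),
                temperature=-5.0,
            )


def test_topology_config_round_trip(tmp_path):
    from evbkit.io import load_topology, save_topology

    topo = marcus_topology(dG0=-12.25, H=4.125, d=0.85)
    path = tmp_path / "topo.yaml"
    save_topology(topo, path)
    back = load_topology(path)
    assert back == topo
    # the on-disk form is plain nested key-value text
    doc = yaml.safe_load(path.read_text())
    assert doc["alpha"] == [0.0, -12.25]
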