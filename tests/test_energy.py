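"""Energy model: gradients, flat-bottom wells, invariances."""
import numpy as np
import pytest

from quadfold.energy import EnergyModel, ForceConstants
from quadfold.geometry import random_rotation
from quadfold.model import build_extended_model
from quadfold.restraints import DihedralRestraint, DistanceRestraint, RestraintSet


@pytest.fixture(scope="module")
def small_model():
    return build_extended_model([(1, "G"), (2, "A"), (3, "T")])


def test_analytic_gradient_matches_finite_differences(small_model, rng):
    em = EnergyModel(small_model)
    x = small_model.coords + rng.normal(0, 0.05, small_model.coords.shape)
    em.refresh_neighbors(x)
    _, G = em.energy_grad(x)
    h = 1e-6
    for idx in rng.choice(small_model.n_atoms, size=8, replace=False):
        for c in range(3):
            xp = x.copy()
            xp[idx, c] += h
            xm = x.copy()
            xm[idx, c] -= h
            num = (em.energy(xp) - em.energy(xm)) / (2 * h)
            assert abs(num - G[idx, c]) < 1e-4


def test_energy_zero_at_ideal_geometry():
    m = build_extended_model([(1, "G")])
    em = EnergyModel(m, nonbonded=False)
    assert em.energy(m.coords) < 1e-12


def test_flat_bottom_wells_zero_inside_bounds(small_model, rng):
    rs = RestraintSet(
        distance=[
            DistanceRestraint(atom_a=(1, "H8"), atom_b=(3, "H6"),
                              category="noe", target=10.0, lower=2.0, upper=40.0)
        ],
        dihedral=[
            DihedralRestraint(
                atoms=((1, "O4'"), (1, "C1'"), (1, "N9"), (1, "C4")),
                center=151.7, halfwidth=60.0,
            )
        ],
    )
    em = EnergyModel(small_model, rs, nonbonded=False)
    # template geometry satisfies both wells -> restraint terms contribute 0
    terms = {}
    em.energy_grad(small_model.coords, terms)
    assert terms.get("distance_restraint", 0.0) == 0.0
    assert terms.get("dihedral_restraint", 0.0) == 0.0
    # random rigid placements that keep the distance inside the well
    for _ in range(5):
        R = random_rotation(rng)
        x = small_model.coords @ R.T + rng.normal(0, 5.0, 3)
        terms = {}
        em.energy_grad(x, terms)
        assert terms["distance_restraint"] == 0.0


def test_energy_invariant_under_rigid_motion(small_model, rng):
    em = EnergyModel(small_model)
    x = small_model.coords + rng.normal(0, 0.05, small_model.coords.shape)
    em.refresh_neighbors(x)
    e0 = em.energy(x)
    for _ in range(3):
        R = random_rotation(rng)
        t = rng.normal(0, 10.0, 3)
        e1 = em.energy(x @ R.T + t)
        assert abs(e1 - e0) <= 1e-8 * max(abs(e0), 1.0)


def test_repulsion_is_lower_bound_only(small_model):
    rs = RestraintSet(
        repulsion=[
            DistanceRestraint(atom_a=(1, "H8"), atom_b=(3, "H6"),
                              category="repulsion", lower=3.5)
        ]
    )
    em = EnergyModel(small_model, rs, nonbonded=False)
    x = small_model.coords.copy()
    i = small_model.index(1, "H8")
    j = small_model.index(3, "H6")
    # move far apart: no penalty
    x[j] = x[i] + np.array([100.0, 0, 0])
    terms = {}
    em.energy_grad(x, terms)
    assert terms["distance_restraint"] == 0.0
    # too close: penalised
    x[j] = x[i] + np.array([2.0, 0, 0])
    terms = {}
    em.energy_grad(x, terms)
    assert terms["distance_restraint"] > 0.0


def test_update_distance_constants_rescales(small_model):
    rs = RestraintSet(
        distance=[
            DistanceRestraint(atom_a=(1, "H8"), atom_b=(3, "H6"),
                              category="noe", target=2.0, lower=1.5, upper=2.5)
        ]
    )
    em = EnergyModel(small_model, rs, nonbonded=False)
    x = small_model.coords  # pair is far outside the well
    t16 = {}
    em.energy_grad(x, t16)
    em.update_distance_constants(noe_nonexch=2.0)
    t2 = {}
    em.energy_grad(x, t2)
    assert t2["distance_restraint"] == pytest.approx(
        t16["distance_restraint"] * 2.0 / 16.0, rel=1e-9
    )
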