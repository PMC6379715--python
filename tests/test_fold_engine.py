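"""Fold-engine components: schedules, dynamics, minimization."""
import numpy as np
import pytest

from quadfold.energy import EnergyModel
from quadfold.fold_engine import (
    AnnealingSchedule,
    Stage,
    anneal,
    fold_ensemble,
    minimize,
)
from quadfold.model import StructureModel, build_extended_model
from quadfold.restraints import DistanceRestraint, RestraintSet


def _two_atom_model(sep=5.0):
    return StructureModel(
        res_ids=np.array([1, 1]),
        res_codes=np.array(["G", "G"], dtype=object),
        atom_names=np.array(["X1", "X2"], dtype=object),
        elements=np.array(["C", "C"], dtype=object),
        coords=np.array([[0.0, 0, 0], [sep, 0, 0]]),
    )


class _FreeAtomsEnergy(EnergyModel):
    """Energy model with no covalent template (two free atoms)."""

    def __init__(self, model, lo, hi, k=10.0):
        self.k_well = k
        self.lo = lo
        self.hi = hi
        self.model = model
        self.n = model.n_atoms
        self.nonbonded = False
        self._nb_pairs = None
        from quadfold.energy import ForceConstants

        self.k = ForceConstants()

    def energy_grad(self, coords, terms=None):
        d = coords[0] - coords[1]
        r = float(np.linalg.norm(d))
        dev = r - self.lo if r < self.lo else (r - self.hi if r > self.hi else 0.0)
        E = self.k_well * dev**2
        G = np.zeros_like(coords)
        if dev:
            f = 2 * self.k_well * dev / r * d
            G[0] = f
            G[1] = -f
        return E, G

    def masses(self, min_mass=12.0):
        return np.array([12.0, 12.0])

    def update_distance_constants(self, **kw):
        pass

    def refresh_neighbors(self, coords):
        pass


class TestSchedules:
    def test_refinement_protocol_staging(self):
        s = AnnealingSchedule.refinement_protocol()
        assert s.total_ps == pytest.approx(150.0)
        names = [st.name for st in s.stages]
        assert names == ["heat", "equil_hot", "ramp", "equil_ramped", "cool",
                         "equil_cold"]
        ramp = s.stages[2]
        assert ramp.k_start["noe_nonexch"] == 2.0
        assert ramp.k_end["noe_nonexch"] == 16.0
        assert ramp.k_end["noe_exch"] == 8.0

    def test_quick_preserves_shape(self):
        q = AnnealingSchedule.quick(0.1)
        assert len(q.stages) == 6
        assert q.total_ps < 20.0

    def test_invalid_stage(self):
        with pytest.raises(ValueError):
            Stage("bad", 300, 300, -1.0)


class TestAnneal:
    def test_two_free_atoms_settle_into_well(self):
        m = _two_atom_model(5.0)
        em = _FreeAtomsEnergy(m, 1.8, 2.2)
        sched = AnnealingSchedule(
            stages=(Stage("cool", 300, 10, 2.0),),
            save_window_ps=0.5, save_every_ps=0.1, rescale_every=10,
        )
        final, avg = anneal(m, None, sched, seed=4, energy_model=em)
        r = np.linalg.norm(final.coords[0] - final.coords[1])
        assert 1.6 < r < 2.4

    def test_cooling_only_keeps_satisfied_structure(
        self, tp3_t6_structure, tp3_t6_topology
    ):
        from quadfold.restraints import TP3_T6_ABSENT_CONTACTS, assemble

        rs = assemble(tp3_t6_topology, absent_contacts=TP3_T6_ABSENT_CONTACTS)
        em = EnergyModel(tp3_t6_structure, rs)
        sched = AnnealingSchedule(
            stages=(Stage("cool", 200, 5, 1.5),),
            save_window_ps=0.4, save_every_ps=0.1, rescale_every=10,
        )
        final, avg = anneal(tp3_t6_structure, rs, sched, seed=2, energy_model=em)
        assert em.restraint_violations(final.coords, 0.2) == []

    def test_empty_schedule_identity(self, tp3_t6_structure):
        sched = AnnealingSchedule(stages=())
        final, avg = anneal(tp3_t6_structure, None, sched, seed=1)
        assert np.array_equal(final.coords, tp3_t6_structure.coords)


class TestMinimize:
    def test_harmonic_dimer_reaches_analytic_minimum(self):
        m = _two_atom_model(6.0)
        em = _FreeAtomsEnergy(m, 2.0, 2.0)  # pure harmonic at r0=2
        out = minimize(m, None, grad_tol=1e-4, energy_model=em)
        assert np.linalg.norm(out.coords[0] - out.coords[1]) == pytest.approx(
            2.0, abs=1e-4
        )

    def test_infinite_tolerance_returns_input(self, tp3_t6_structure):
        out = minimize(tp3_t6_structure, None, grad_tol=np.inf)
        assert out is tp3_t6_structure

    def test_ideal_structure_already_near_minimum(
        self, tp3_t6_structure, tp3_t6_topology
    ):
        from quadfold.restraints import TP3_T6_ABSENT_CONTACTS, assemble

        rs = assemble(tp3_t6_topology, absent_contacts=TP3_T6_ABSENT_CONTACTS)
        em = EnergyModel(tp3_t6_structure, rs)
        em.refresh_neighbors(tp3_t6_structure.coords)
        e0 = em.energy(tp3_t6_structure.coords)
        out = minimize(tp3_t6_structure, rs, grad_tol=0.5, max_iter=400,
                       energy_model=em)
        e1 = em.energy(out.coords)
        assert e1 <= e0


class TestFoldEnsemble:
    def test_single_run_single_model(self, tp3_t6_topology, tp3_t6_restraints):
        ens = fold_ensemble(
            tp3_t6_topology.sequence, tp3_t6_restraints,
            n_start=1, n_keep=1, seed=5,
            schedule=AnnealingSchedule.quick(0.02), rigid_steps=2000,
            convergence_max_violations=None,
        )
        assert len(ens) == 1
        assert len(ens.energies) == 1

    def test_n_keep_validation(self, tp3_t6_topology, tp3_t6_restraints):
        with pytest.raises(ValueError):
            fold_ensemble(tp3_t6_topology.sequence, tp3_t6_restraints,
                          n_start=1, n_keep=2)
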