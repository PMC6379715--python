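"""Restraint-driven folding: distance-geometry embedding followed by
restrained simulated annealing and minimization.

The default :meth:`AnnealingSchedule.refinement_protocol` encodes the
distance-restrained molecular-dynamics refinement used for the TP3-T6
structure: heat 300 K -> 1000 K over 14 ps, equilibrate 6 ps with distance
force constants at 2 kcal/mol/A^2, ramp the non-exchangeable/exchangeable
constants to 16/8 kcal/mol/A^2 over 20 ps, equilibrate 50 ps at 1000 K,
cool to 300 K over 42 ps, equilibrate 18 ps and average coordinates saved
every 0.5 ps over the last 10 ps.  Dihedral (50 kcal/mol/rad^2) and
planarity (1 kcal/mol/A^2) restraints are maintained throughout.
:meth:`AnnealingSchedule.quick` is the same shape scaled down; it is the
default for ensemble runs, where annealing refines structures that the
rigid-unit assembly stage (:func:`rigid_assembly`) has already folded.

Dynamics are velocity-Verlet with a deterministic velocity-rescaling
thermostat, so a (inputs, seed) pair reproduces an ensemble bit-exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .distgeo import build_bounds, embed
from .energy import ACC, KB, EnergyModel
from .model import Ensemble, StructureModel, build_extended_model
from .sequences import Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stage:
    name: str
    t_start: float              # K
    t_end: float                # K
    duration_ps: float
    k_start: dict = field(default_factory=dict)   # category -> force constant
    k_end: dict | None = None                     # None: hold k_start
    #: van-der-Waals radius scale ramp (None: leave the energy model as is);
    #: scaled-down radii during hot stages let the chain pass through itself
    nb_scale_start: float | None = None
    nb_scale_end: float | None = None

    def __post_init__(self):
        if self.duration_ps <= 0:
            raise ValueError(f"stage {self.name}: duration must be > 0")
        if self.t_start <= 0 or self.t_end <= 0:
            raise ValueError(f"stage {self.name}: temperatures must be > 0")


@dataclass(frozen=True)
class AnnealingSchedule:
    stages: tuple[Stage, ...]
    timestep_fs: float = 2.0
    save_window_ps: float = 10.0
    save_every_ps: float = 0.5
    rescale_every: int = 50

    @property
    def total_ps(self) -> float:
        return sum(s.duration_ps for s in self.stages)

    @classmethod
    def refinement_protocol(cls) -> "AnnealingSchedule":
        lo = {"noe_nonexch": 2.0, "noe_exch": 2.0, "hbond": 2.0, "repulsion_restraint": 2.0}
        hi = {"noe_nonexch": 16.0, "noe_exch": 8.0, "hbond": 8.0, "repulsion_restraint": 16.0}
        return cls(
            stages=(
                Stage("heat", 300, 1000, 14, lo),
                Stage("equil_hot", 1000, 1000, 6, lo),
                Stage("ramp", 1000, 1000, 20, lo, hi),
                Stage("equil_ramped", 1000, 1000, 50, hi),
                Stage("cool", 1000, 300, 42, hi),
                Stage("equil_cold", 300, 300, 18, hi),
            ),
            save_window_ps=10.0,
            save_every_ps=0.5,
        )

    @classmethod
    def quick(cls, scale: float = 0.08) -> "AnnealingSchedule":
        """The refinement protocol compressed by ``scale`` in time."""
        ref = cls.refinement_protocol()
        stages = tuple(
            replace(s, duration_ps=max(s.duration_ps * scale, 0.2)) for s in ref.stages
        )
        return cls(
            stages=stages,
            save_window_ps=max(10.0 * scale, 0.4),
            save_every_ps=max(0.5 * scale, 0.1),
            rescale_every=25,
        )


class DynamicsBlowup(RuntimeError):
    pass


def _interp(a: float, b: float, f: float) -> float:
    return a + (b - a) * f


def minimize(
    model: StructureModel,
    restraints=None,
    grad_tol: float = 0.1,
    max_iter: int = 50000,
    energy_model: EnergyModel | None = None,
) -> StructureModel:
    """Minimize until the gradient max-norm drops below ``grad_tol``
    (kcal/mol/A), using L-BFGS-B with the analytic gradient."""
    if not np.isfinite(grad_tol):
        return model
    from scipy.optimize import minimize as _sp_min

    em = energy_model or EnergyModel(model, restraints)
    shape = model.coords.shape

    def fun(x):
        e, g = em.energy_grad(x.reshape(shape))
        return e, g.ravel()

    # the objective is only smooth for a fixed neighbour list, so optimise
    # in rounds, refreshing the list between rounds
    x = model.coords.ravel().copy()
    done = 0
    nit = 0
    while done < max_iter:
        if em.nonbonded:
            em.refresh_neighbors(x.reshape(shape))
        chunk = min(200, max_iter - done)
        res = _sp_min(
            fun, x, jac=True, method="L-BFGS-B",
            options={"maxiter": chunk, "gtol": grad_tol, "ftol": 1e-14, "maxls": 80},
        )
        moved = float(np.abs(res.x - x).max())
        x = res.x
        nit += res.nit
        done += chunk
        if em.nonbonded:
            em.refresh_neighbors(x.reshape(shape))
        _, g = em.energy_grad(x.reshape(shape))
        if np.abs(g).max() < grad_tol:
            break
        if res.nit == 0 and moved < 1e-10:
            break  # stalled with the current list; nothing more to gain
    coords = x.reshape(shape)
    _, g = em.energy_grad(coords)
    if np.abs(g).max() > grad_tol:
        log.warning(
            "minimization stopped at max|grad|=%.3g (> %.3g) after %s iterations",
            np.abs(g).max(), grad_tol, nit,
        )
    return model.with_coords(coords)


def anneal(
    model: StructureModel,
    restraints,
    schedule: AnnealingSchedule,
    seed: int,
    energy_model: EnergyModel | None = None,
):
    """Velocity-Verlet restrained dynamics over the schedule.

    Returns ``(final_model, window_average_model)``; the average is over
    coordinates saved every ``save_every_ps`` during the final
    ``save_window_ps`` of the schedule.
    """
    em = energy_model or EnergyModel(model, restraints)
    if schedule.total_ps == 0 or not schedule.stages:
        return model, model
    rng = np.random.default_rng(seed)
    dt = schedule.timestep_fs
    m = em.masses()[:, None]
    x = model.coords.copy()
    t0 = schedule.stages[0].t_start
    v = rng.normal(size=x.shape) * np.sqrt(KB * t0 * ACC / m)
    v -= v.mean(axis=0)

    total_steps = int(round(schedule.total_ps * 1000 / dt))
    save_start = schedule.total_ps - schedule.save_window_ps
    save_every_steps = max(int(round(schedule.save_every_ps * 1000 / dt)), 1)
    saved = []

    em.refresh_neighbors(x)
    e, g = em.energy_grad(x)
    acc = -g * ACC / m
    step = 0
    for stage in schedule.stages:
        n_steps = int(round(stage.duration_ps * 1000 / dt))
        for i in range(n_steps):
            f = i / max(n_steps - 1, 1)
            if stage.k_end:
                em.update_distance_constants(
                    **{
                        c: _interp(stage.k_start.get(c, 0.0), stage.k_end[c], f)
                        for c in stage.k_end
                    }
                )
            elif i == 0 and stage.k_start:
                em.update_distance_constants(**stage.k_start)
            if stage.nb_scale_start is not None:
                end = (
                    stage.nb_scale_end
                    if stage.nb_scale_end is not None
                    else stage.nb_scale_start
                )
                em._nb_scale = _interp(stage.nb_scale_start, end, f)
            v += 0.5 * dt * acc
            x += dt * v
            if em.nonbonded and step % 20 == 0:
                em.refresh_neighbors(x)
            e, g = em.energy_grad(x)
            acc = -g * ACC / m
            v += 0.5 * dt * acc
            if step % schedule.rescale_every == 0:
                t_target = _interp(stage.t_start, stage.t_end, f)
                ke = 0.5 * float(np.sum(m * v**2)) / ACC
                t_now = 2 * ke / (3 * x.shape[0] * KB)
                if t_now > 1e-9:
                    v *= np.sqrt(t_target / t_now)
            if not np.isfinite(e) or np.linalg.norm(x) > 1e6:
                raise DynamicsBlowup(
                    f"dynamics diverged at stage {stage.name!r} step {i}; "
                    "try a smaller timestep"
                )
            step += 1
            t_ps = step * dt / 1000.0
            if t_ps >= save_start - 1e-9 and step % save_every_steps == 0:
                saved.append(x.copy())
        log.info("stage %-12s done: T target %.0f K, E %.1f kcal/mol",
                 stage.name, stage.t_end, e)
    avg = np.mean(saved, axis=0) if saved else x.copy()
    return model.with_coords(x), model.with_coords(avg)


# ---------------------------------------------------------------------------
# rigid-unit assembly stage
# ---------------------------------------------------------------------------

def _quat_to_R(q):
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=-2,
    )


def _quat_mul(q, p):
    w1, x1, y1, z1 = q.T
    w2, x2, y2, z2 = p.T
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def rigid_assembly(
    skeleton: StructureModel,
    restraints,
    start_coords: np.ndarray,
    seed: int,
    steps: int = 30000,
    t_start: float = 40.0,
    steric_ramp: tuple[float, float] | None = (0.15, 0.5),
) -> np.ndarray:
    """Simulated annealing with each nucleotide as a rigid unit.

    Residues keep ideal template geometry (glycosidic torsions at their
    restrained centres); forces come from the distance restraints, soft
    backbone-link springs and a quadratic steric floor, and act on the 6
    rigid degrees of freedom per residue.  This assembles the global fold
    before all-atom refinement; the temperature scale is dimensionless.
    """
    from scipy.spatial import cKDTree

    from .templates import VDW_RADIUS, get_template

    rng = np.random.default_rng(seed)
    residues = skeleton.residues
    nres = len(residues)
    n = skeleton.n_atoms
    chi_of = {d.atoms[0][0]: d.center for d in restraints.dihedral}
    tmplC = np.zeros((n, 3))
    res_of = np.zeros(n, dtype=int)
    for ri, (rid, code) in enumerate(residues):
        t = get_template(code, five_prime=(ri == 0))
        X = t.with_chi(chi_of.get(rid, 240.0))
        X = X - X.mean(axis=0)
        idx = np.array([skeleton.index(rid, nm) for nm in t.atom_names])
        tmplC[idx] = X
        res_of[idx] = ri

    pairs = []
    for r in restraints.all_distance_like():
        if r.ambiguity_group:
            continue
        i = skeleton.index(*r.atom_a)
        j = skeleton.index(*r.atom_b)
        k = {"noe": 8.0, "hbond": 60.0, "repulsion": 16.0}[r.category]
        pairs.append((i, j, r.lower or 0.0,
                      r.upper if r.upper is not None else 999.0, k))
    for (r1, _), (r2, _) in zip(residues, residues[1:]):
        if not skeleton.has_atom(r2, "P"):
            continue
        for a, b, d0, tol in (("O3'", "P", 1.607, 0.01), ("C3'", "P", 2.66, 0.05),
                              ("O3'", "O5'", 2.56, 0.05)):
            pairs.append((skeleton.index(r1, a), skeleton.index(r2, b),
                          d0 - tol, d0 + tol, 100.0))
    pairs = np.array(pairs)
    pi = pairs[:, 0].astype(int)
    pj = pairs[:, 1].astype(int)
    plo, phi_, pk = pairs[:, 2], pairs[:, 3], pairs[:, 4]
    hidx = np.nonzero(skeleton.heavy_mask())[0]
    radii = np.array([VDW_RADIUS[e] for e in skeleton.elements])

    def steric_list(X):
        raw = cKDTree(X[hidx]).query_pairs(3.4, output_type="ndarray")
        a = hidx[raw[:, 0]]
        b = hidx[raw[:, 1]]
        keep = res_of[a] != res_of[b]
        return a[keep], b[keep]

    def forces(X, sp, k_st=10.0):
        F = np.zeros((n, 3))
        E = 0.0
        d = X[pi] - X[pj]
        r = np.linalg.norm(d, axis=1)
        dev = np.where(r < plo, r - plo, np.where(r > phi_, r - phi_, 0.0))
        E += float(np.sum(pk * dev**2))
        f = (2 * pk * dev / np.maximum(r, 1e-9))[:, None] * d
        for c in range(3):
            F[:, c] -= np.bincount(pi, f[:, c], minlength=n)
            F[:, c] += np.bincount(pj, f[:, c], minlength=n)
        si, sj = sp
        if len(si) and k_st > 0:
            d = X[si] - X[sj]
            r = np.linalg.norm(d, axis=1)
            r0 = 0.8 * (radii[si] + radii[sj])
            dev = np.minimum(r - r0, 0.0)
            E += float(np.sum(k_st * dev**2))
            f = (2 * k_st * dev / np.maximum(r, 1e-9))[:, None] * d
            for c in range(3):
                F[:, c] -= np.bincount(si, f[:, c], minlength=n)
                F[:, c] += np.bincount(sj, f[:, c], minlength=n)
        return E, F

    # initial rigid placements from the embedded coordinates
    from .geometry import kabsch

    Rs = np.zeros((nres, 3, 3))
    ts = np.zeros((nres, 3))
    qs = np.zeros((nres, 4))
    aidx = [np.nonzero(res_of == ri)[0] for ri in range(nres)]
    for ri in range(nres):
        R, t, _ = kabsch(tmplC[aidx[ri]], start_coords[aidx[ri]])
        Rs[ri] = R
        ts[ri] = t
        tr = np.trace(R)
        w0 = np.sqrt(max(1 + tr, 1e-12)) / 2
        qs[ri] = [w0, (R[2, 1] - R[1, 2]) / (4 * w0), (R[0, 2] - R[2, 0]) / (4 * w0),
                  (R[1, 0] - R[0, 1]) / (4 * w0)]
        qs[ri] /= np.linalg.norm(qs[ri])
    masses = np.array([len(a) for a in aidx], dtype=float)
    inert = np.array([float(np.sum(tmplC[a] ** 2)) for a in aidx])
    v = rng.normal(size=(nres, 3)) * 0.02
    w = rng.normal(size=(nres, 3)) * 0.005
    dt = 0.02
    X = np.einsum("nij,nj->ni", Rs[res_of], tmplC) + ts[res_of]
    sp = steric_list(X)
    for step in range(steps):
        if step % 25 == 0:
            sp = steric_list(X)
        frac = step / steps
        t_target = t_start * np.exp(-5.0 * frac) + 0.005
        if steric_ramp is not None:
            f0, f1 = steric_ramp
            k_st = 10.0 * float(np.clip((frac - f0) / max(f1 - f0, 1e-9), 0.0, 1.0))
        else:
            k_st = 10.0
        E, F = forces(X, sp, k_st)
        tq = np.cross(X - ts[res_of], F)
        Fb = np.zeros((nres, 3))
        Tb = np.zeros((nres, 3))
        for c in range(3):
            Fb[:, c] = np.bincount(res_of, F[:, c], minlength=nres)
            Tb[:, c] = np.bincount(res_of, tq[:, c], minlength=nres)
        v += dt * Fb / masses[:, None]
        w += dt * Tb / inert[:, None]
        if step % 20 == 0:
            ke = 0.5 * float(np.sum(masses[:, None] * v**2) + np.sum(inert[:, None] * w**2))
            if ke > 1e-12:
                lam = min(np.sqrt(t_target * nres / ke), 1.2)
                v *= lam
                w *= lam
        ts += dt * v
        ang = np.linalg.norm(w, axis=1) * dt
        half = 0.5 * ang
        axis = np.where(ang[:, None] > 1e-12, w / np.maximum(np.linalg.norm(w, axis=1), 1e-12)[:, None], 0.0)
        dq = np.concatenate([np.cos(half)[:, None], np.sin(half)[:, None] * axis], axis=1)
        qs = _quat_mul(dq, qs)
        qs /= np.linalg.norm(qs, axis=1)[:, None]
        Rs = _quat_to_R(qs)
        X = np.einsum("nij,nj->ni", Rs[res_of], tmplC) + ts[res_of]
    return X


def regularize(
    model: StructureModel,
    restraints,
    energy_model: EnergyModel,
    k_multipliers=(4.0, 16.0, 64.0, 256.0, 1024.0),
    max_iter: int = 800,
) -> StructureModel:
    """Restraint-weight continuation: re-minimize while geometrically
    ramping the distance force constants, then restore protocol constants.

    The final structure satisfies the distance restraints as tightly as
    the covalent geometry permits (the refinement-stage analogue of the
    force-constant ramp used during annealing).
    """
    m = model
    base = {"noe_nonexch": 16.0, "noe_exch": 8.0, "hbond": 8.0}
    for mult in k_multipliers:
        energy_model.update_distance_constants(
            **{k: v * mult for k, v in base.items()}
        )
        m = minimize(m, restraints, grad_tol=0.05 * mult, max_iter=max_iter,
                     energy_model=energy_model)
    energy_model.update_distance_constants(**base)
    return m


# ---------------------------------------------------------------------------
# full calculation
# ---------------------------------------------------------------------------

def fold_ensemble(
    sequence: Sequence,
    restraints,
    n_start: int = 100,
    n_keep: int = 10,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    skeleton: StructureModel | None = None,
    rigid_steps: int = 30000,
    convergence_max_violations: int | None = 120,
) -> Ensemble:
    """Fold ``n_start`` independent models and keep the ``n_keep`` of
    lowest final energy, sorted ascending.

    Each run embeds the (shared) bounds matrix with its own derived seed,
    assembles the fold with the rigid-unit annealing stage, refines with
    restrained all-atom dynamics over ``schedule``, regularizes by
    restraint-weight continuation, and scores the result with the
    protocol-constant energy model.  Failed runs are logged and skipped;
    fewer survivors than ``n_keep`` is an error.
    """
    if n_keep > n_start:
        raise ValueError("n_keep must be <= n_start")
    schedule = schedule or AnnealingSchedule.quick(0.05)
    if skeleton is None:
        skeleton = build_extended_model(
            [(i + 1, c) for i, c in enumerate(sequence.residues)]
        )
    bm = build_bounds(skeleton, restraints)
    em = EnergyModel(skeleton, restraints)
    seeds = np.random.SeedSequence(seed).generate_state(n_start).tolist()
    results = []
    for run, s in enumerate(seeds):
        try:
            m0 = embed(bm, seed=s, skeleton=skeleton, n_metrize=1000)
            x1 = rigid_assembly(skeleton, restraints, m0.coords, seed=s,
                                steps=rigid_steps) if rigid_steps else m0.coords
            m1 = minimize(skeleton.with_coords(x1), restraints, grad_tol=0.5,
                          max_iter=1000, energy_model=em)
            _, avg = anneal(m1, restraints, schedule, seed=s, energy_model=em)
            m2 = minimize(avg, restraints, grad_tol=0.1, max_iter=2000,
                          energy_model=em)
            # a run that cannot approach restraint satisfaction has not
            # converged: count it as failed rather than keep a misfold
            n_viol = len(em.restraint_violations(m2.coords, 0.2))
            if (convergence_max_violations is not None
                    and n_viol > convergence_max_violations):
                log.warning(
                    "run %d/%d: not converged (%d violations > 0.2 A), skipped",
                    run + 1, n_start, n_viol,
                )
                continue
            mfin = regularize(m2, restraints, em)
            em.refresh_neighbors(mfin.coords)
            e = em.energy(mfin.coords)
            results.append((e, s, mfin))
            log.info("run %d/%d: E = %.2f kcal/mol", run + 1, n_start, e)
        except Exception as exc:  # noqa: BLE001 - individual runs may fail
            log.warning("run %d/%d failed: %s", run + 1, n_start, exc)
    if len(results) < n_keep:
        raise RuntimeError(
            f"only {len(results)} of {n_start} runs succeeded; need {n_keep}"
        )
    results.sort(key=lambda t: t[0])
    kept = results[:n_keep]
    return Ensemble(
        models=[m.with_coords(m.coords, model_id=i + 1) for i, (_, _, m) in enumerate(kept)],
        energies=[e for e, _, _ in kept],
        seeds=[s for _, s, _ in kept],
    )


class StructureCalculation:
    """Model object tying a sequence + restraint set to a fold calculation.

    Mirrors the modelling-object idiom: construct from data, ``fit()``
    returns a :class:`FoldResults` carrying the ensemble and diagnostics.
    """

    def __init__(
        self,
        sequence: Sequence,
        restraints,
        schedule: AnnealingSchedule | None = None,
    ):
        self.sequence = sequence
        self.restraints = restraints
        self.schedule = schedule or AnnealingSchedule.refinement_protocol()
        self.skeleton = build_extended_model(
            [(i + 1, c) for i, c in enumerate(sequence.residues)]
        )

    @classmethod
    def from_topology(cls, topology, peaks=(), absent_contacts=(), schedule=None):
        from .restraints import assemble

        rs = assemble(topology, peaks=peaks, absent_contacts=absent_contacts)
        return cls(topology.sequence, rs, schedule=schedule)

    def fit(self, n_start: int = 100, n_keep: int = 10, seed: int = 0,
            rigid_steps: int = 30000,
            convergence_max_violations: int | None = 120) -> "FoldResults":
        ens = fold_ensemble(
            self.sequence,
            self.restraints,
            n_start=n_start,
            n_keep=n_keep,
            schedule=self.schedule,
            seed=seed,
            skeleton=self.skeleton,
            rigid_steps=rigid_steps,
            convergence_max_violations=convergence_max_violations,
        )
        return FoldResults(self, ens, seed=seed)


class FoldResults:
    """Fitted ensemble plus validation statistics."""

    def __init__(self, calculation: StructureCalculation, ensemble: Ensemble, seed: int):
        self.calculation = calculation
        self.ensemble = ensemble
        self.seed = seed
        self._report = None

    @property
    def best_model(self) -> StructureModel:
        return self.ensemble[0]

    @property
    def energies(self) -> list[float]:
        return list(self.ensemble.energies)

    def validate(self, core_selection: str = "tetrad_guanines"):
        from .structure_analysis import validate_ensemble

        if self._report is None:
            self._report = validate_ensemble(
                self.ensemble, self.calculation.restraints, core_selection=core_selection
            )
        return self._report

    def summary(self) -> str:
        rep = self.validate() if len(self.ensemble) >= 2 else None
        counts = self.calculation.restraints.counts()
        lines = [
            "Restraint-driven structure calculation",
            "=" * 42,
            f"sequence            {self.calculation.sequence.id} "
            f"({len(self.calculation.sequence)} nt)",
            f"models kept         {len(self.ensemble)}",
            f"energy range        {min(self.energies):.1f} .. {max(self.energies):.1f} kcal/mol",
            f"seed                {self.seed}",
            "",
            "Restraints",
            f"  hydrogen bond     {counts['hbond']}",
            f"  dihedral          {counts['dihedral']}",
            f"  planarity         {counts['planarity']}",
            f"  repulsion         {counts['repulsion']}",
            f"  NOE (intra/inter) {counts['noe_intra_nonexchangeable'] + counts['noe_intra_exchangeable']}"
            f"/{counts['noe_inter_nonexchangeable'] + counts['noe_inter_exchangeable']}",
        ]
        if rep is not None:
            lines += [
                "",
                "Ensemble statistics (mean +/- sd)",
                f"  NOE violations > 0.2 A   {rep.noe_violations[0]:.2f} +/- {rep.noe_violations[1]:.2f}",
                f"  bond length dev (A)      {rep.bond_dev[0]:.4f} +/- {rep.bond_dev[1]:.4f}",
                f"  bond angle dev (deg)     {rep.angle_dev[0]:.3f} +/- {rep.angle_dev[1]:.3f}",
                f"  improper dev (deg)       {rep.improper_dev[0]:.3f} +/- {rep.improper_dev[1]:.3f}",
                f"  pairwise RMSD core (A)   {rep.rmsd_core[0]:.3f} +/- {rep.rmsd_core[1]:.3f}",
                f"  pairwise RMSD all (A)    {rep.rmsd_all[0]:.3f} +/- {rep.rmsd_all[1]:.3f}",
            ]
        else:
            lines += ["", "Ensemble statistics unavailable (single model)"]
        return "\n".join(lines)

    def plot_energies(self, ax=None):
        """Bar plot of the kept models' final energies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(range(1, len(self.energies) + 1), self.energies)
        ax.set_xlabel("model (energy rank)")
        ax.set_ylabel("restraint + covalent energy (kcal/mol)")
        return ax
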