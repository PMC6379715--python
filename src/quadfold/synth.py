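"""Idealised all-atom quadruplex generation and end-to-end fixtures.

``build_ideal_structure`` realises any valid :class:`QuadruplexTopology`
as an all-atom model: tetrad guanines are placed on stacked square layers
whose in-plane pose is solved once from the Hoogsteen hydrogen-bond
targets (H21-N7 2.0 A, N2-N7 2.9 A, H1-O6 2.0 A, N1-O6 2.9 A), glycosidic
torsions are set to 60 deg (syn) or 240 deg (anti), capping bases are
posed from their declared donor/acceptor distances, and loop/bulge/flank
residues are placed by closure minimization against the covalent
templates with all structured bases pinned.

The generator is deterministic: same topology, parameters and seed give
bit-identical coordinates.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import EnergyModel, ForceConstants
from .geometry import best_fit_plane, kabsch, rotation_about_axis, rotation_z
from .model import StructureModel
from .templates import get_template
from .topology import QuadruplexTopology, _corner_and_sense

log = logging.getLogger(__name__)

#: Hoogsteen donor->acceptor atom pairs and target distances (Angstrom)
HOOGSTEEN_BONDS = (("H21", "N7", 2.0), ("N2", "N7", 2.9), ("H1", "O6", 2.0), ("N1", "O6", 2.9))


@dataclass(frozen=True)
class GeneratorParams:
    """Geometric parameters of the idealised scaffold.

    Helical values (rise 3.3 A, twist 30 deg) and the C1' half-diagonal
    (6.7 A) are literature-typical quadruplex dimensions, not fitted
    quantities.
    """

    c1_half_diagonal: float = 6.7
    rise: float = 3.3
    twist: float = 30.0
    handedness: int = 1            # +1 right-handed helical progression
    closure_iterations: int = 3000
    perturbation_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if not -90 < self.twist < 90:
            raise ValueError("twist must lie in (-90, 90) degrees")


def _base_frame(code: str):
    """Base atoms + C1' of a template residue in a base-plane frame.

    Returns (atom_names, coords) with centroid at origin, base normal on
    +z (sign fixed by the ring geometry) and N9/N1 defining +x.
    """
    tmpl = get_template(code)
    names = [n for n in tmpl.base_atoms] + ["C1'"]
    idx = [tmpl.index(n) for n in names]
    X = tmpl.coords[idx].copy()
    base_only = X[:-1]
    c, nrm, _ = best_fit_plane(base_only)
    ngly = tmpl.glycosidic_nitrogen
    p_n = X[names.index(ngly)]
    if code in ("A", "G", "I"):
        ref = np.cross(
            X[names.index("C8")] - p_n, X[names.index("C4")] - p_n
        )
    else:
        ref = np.cross(
            X[names.index("C6")] - p_n, X[names.index("C2")] - p_n
        )
    if np.dot(nrm, ref) < 0:
        nrm = -nrm
    z = nrm / np.linalg.norm(nrm)
    x = p_n - c
    x = x - np.dot(x, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return names, (X - c) @ R.T


def _pose_atoms(frame_coords, px, py, theta):
    return frame_coords @ rotation_z(theta).T + np.array([px, py, 0.0])


@lru_cache(maxsize=None)
def _canonical_tetrad():
    """In-plane pose (px, py, theta) of a corner-0 guanine and the feasible
    donor->acceptor corner advance sign, solved from the Hoogsteen bond
    targets with a C1' radius of 6.7 A."""
    from scipy.optimize import least_squares

    names, F = _base_frame("G")

    def residuals(v, s):
        A = _pose_atoms(F, *v)
        B = A @ rotation_z(s * 90.0).T
        res = []
        for dn, an, d0 in HOOGSTEEN_BONDS:
            res.append(np.linalg.norm(A[names.index(dn)] - B[names.index(an)]) - d0)
        r_c1 = np.linalg.norm(A[names.index("C1'")][:2])
        res.append(0.3 * (r_c1 - 6.7))
        return res

    best = None
    for s in (+1, -1):
        for th0 in (0.0, 90.0, 180.0, 270.0):
            sol = least_squares(residuals, x0=[5.0, 0.0, th0], args=(s,), xtol=1e-12)
            cost = float(sol.cost)
            if best is None or cost < best[0]:
                best = (cost, s, tuple(sol.x))
    cost, s, pose = best
    # feasibility: every bond must land inside its flat-bottom well
    A = _pose_atoms(F, *pose)
    B = A @ rotation_z(s * 90.0).T
    for dn, an, d0 in HOOGSTEEN_BONDS:
        d = float(np.linalg.norm(A[names.index(dn)] - B[names.index(an)]))
        well = 0.2 if dn.startswith("H") else 0.3
        if abs(d - d0) > well:
            raise RuntimeError(
                f"canonical tetrad solve infeasible: {dn}-{an} = {d:.2f} A "
                f"(target {d0} +/- {well})"
            )
    return names, F, pose, s


def _tetrad_slots(params: GeneratorParams):
    """Slot transform helpers for placing base frames in the lab."""
    names, F, (px, py, theta), s_adv = _canonical_tetrad()
    P0 = _pose_atoms(F, px, py, theta)
    alpha = float(np.degrees(np.arctan2(P0[names.index("C1'")][1], P0[names.index("C1'")][0])))

    def slot(corner: int, layer: int, normal: int) -> np.ndarray:
        if normal == +1:
            A = P0 @ rotation_z(90.0 * corner).T
        else:
            # mirror layer: flip through x and counter-rotate so the C1'
            # azimuth of every column matches the unflipped layers
            A = P0 @ rotation_z(-90.0 * corner).T
            A = A @ rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0).T
            A = A @ rotation_z(2.0 * alpha).T
        # +1 handedness = right-handed helical progression of the stack
        phase = -params.handedness * params.twist * layer
        A = A @ rotation_z(phase).T
        A = A + np.array([0.0, 0.0, -params.rise * layer])
        return A

    return names, slot, s_adv


def _place_residue_on_base(code: str, chi: float, target_names, target_base: np.ndarray,
                           five_prime: bool = False) -> np.ndarray:
    """Full-nucleotide coordinates with base atoms superposed on targets."""
    tmpl = get_template(code, five_prime=five_prime)
    X = tmpl.with_chi(chi)
    sel = [n for n in target_names if n != "C1'" and tmpl.has_atom(n)]
    mob = np.array([X[tmpl.index(n)] for n in sel])
    tgt = np.array([target_base[list(target_names).index(n)] for n in sel])
    R, t, _ = kabsch(mob, tgt)
    return X @ R.T + t


def _pair_is_cis(model_coords_a, names_a, code_a, model_coords_b, names_b, code_b) -> bool:
    """cis/trans of the glycosidic bonds across a base pair.

    cis (same side of the pairing axis) corresponds to Hoogsteen geometry
    for an edge pairing, trans to reverse-Hoogsteen.
    """
    def gly(coords, names, code):
        n = "N9" if code in ("A", "G", "I") else "N1"
        return coords[names.index(n)], coords[names.index("C1'")]

    na, ca = gly(model_coords_a, names_a, code_a)
    nb, cb = gly(model_coords_b, names_b, code_b)
    axis = nb - na
    axis /= np.linalg.norm(axis)
    va = ca - na
    vb = cb - nb
    va -= np.dot(va, axis) * axis
    vb -= np.dot(vb, axis) * axis
    return bool(np.dot(va, vb) > 0)


def _solve_capping_group(top, residues, bonds, z_cap, anchors, chi_of):
    """Pose capping bases in the plane z=z_cap from declared bonds.

    ``bonds`` are ((pos, atom), (pos, atom), target) triples; ``anchors``
    maps residue position -> lab C1' anchor point.  Flip states are chosen
    by enumerating combinations and keeping the lowest-residual solution
    whose pair geometry matches the declared bonding modes.
    """
    from scipy.optimize import least_squares

    frames = {}
    for p in residues:
        code = top.sequence[p]
        names, F = _base_frame(code)
        frames[p] = (code, names, F)

    modes = {}
    for cap in top.capping:
        if cap.mode in ("hoogsteen", "reverse_hoogsteen") and all(
            q in residues for q in cap.partners[:2]
        ):
            modes[tuple(cap.partners[:2])] = cap.mode

    def build(v, flips):
        placed = {}
        for k, p in enumerate(residues):
            code, names, F = frames[p]
            Fk = F.copy()
            if flips[k] < 0:
                Fk = Fk @ rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0).T
            A = _pose_atoms(Fk, v[3 * k], v[3 * k + 1], np.degrees(v[3 * k + 2]))
            A = A + np.array([0.0, 0.0, z_cap])
            placed[p] = A
        return placed

    bonded_atoms = {(pa, na) for (pa, na), _, _ in bonds} | {
        (pb, nb) for _, (pb, nb), _ in bonds
    }
    # atoms taking part in any declared bond are allowed close contacts;
    # everything else repels at 0.75 x summed van-der-Waals radii
    from .templates import VDW_RADIUS

    steric = {}
    for p in residues:
        code, names, F = frames[p]
        keep = [k for k, nm in enumerate(names)
                if nm != "C1'" and (p, nm) not in bonded_atoms]
        radii = np.array(
            [VDW_RADIUS["H" if names[k].startswith("H") else names[k][0]] for k in keep]
        )
        steric[p] = (keep, radii)

    heavy_of = {"H1": "N1", "H21": "N2", "H22": "N2", "H3": "N3",
                "H41": "N4", "H42": "N4", "H61": "N6", "H62": "N6"}

    def residuals(v, flips):
        placed = build(v, flips)
        res = []
        for (pa, na), (pb, nb), d0 in bonds:
            _, names_a, _ = frames[pa]
            _, names_b, _ = frames[pb]
            da = placed[pa][names_a.index(na)]
            db = placed[pb][names_b.index(nb)]
            res.append(np.linalg.norm(da - db) - d0)
            if na in heavy_of:
                # near-linear donor geometry: heavy-atom separation tracks
                # the proton distance plus one N-H bond length
                dh = placed[pa][names_a.index(heavy_of[na])]
                res.append(0.7 * (np.linalg.norm(dh - db) - (d0 + 0.95)))
        for p in residues:
            _, names, _ = frames[p]
            c1 = placed[p][names.index("C1'")]
            res.append(0.10 * (np.linalg.norm(c1[:2] - anchors[p][:2]) ))
            # keep bases from drifting far off the core axis
            ctr = placed[p][: len(names) - 1].mean(axis=0)
            res.append(0.05 * max(np.linalg.norm(ctr[:2]) - 5.0, 0.0))
        # steric hinge between distinct bases
        from scipy.spatial.distance import cdist

        for ai in range(len(residues)):
            for bi in range(ai + 1, len(residues)):
                pa, pb = residues[ai], residues[bi]
                ka, ra = steric[pa]
                kb, rb = steric[pb]
                D = cdist(placed[pa][ka], placed[pb][kb])
                floor = 0.75 * (ra[:, None] + rb[None, :])
                res.extend((2.0 * np.maximum(floor - D, 0.0)).ravel())
        return res

    best = None
    x0 = []
    for p in residues:
        a = anchors[p]
        x0 += [0.7 * a[0], 0.7 * a[1], 0.0]
    for flips in itertools.product((+1, -1), repeat=len(residues)):
        for dth in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            x_init = list(x0)
            for k in range(len(residues)):
                x_init[3 * k + 2] = dth
            sol = least_squares(residuals, x0=x_init, args=(flips,), xtol=1e-10)
            placed = build(sol.x, flips)
            ok_mode = True
            for (pa, pb), mode in modes.items():
                code_a, names_a, _ = frames[pa]
                code_b, names_b, _ = frames[pb]
                cis = _pair_is_cis(placed[pa], names_a, code_a, placed[pb], names_b, code_b)
                if (mode == "hoogsteen") != cis:
                    ok_mode = False
            key = (not ok_mode, float(sol.cost))
            if best is None or key < best[0]:
                best = (key, placed)
    (bad_mode, cost), placed = best
    if cost > 0.3:
        log.warning("capping pose solve residual %.3g is large", cost)
    return placed


class LoopClosureError(RuntimeError):
    pass


def build_ideal_structure(
    top: QuadruplexTopology, gp: GeneratorParams = GeneratorParams()
) -> StructureModel:
    """All-atom idealised model realising ``top``."""
    seq = top.sequence
    n = len(seq)
    chi_of = {
        p: (60.0 if top.glycosidic.get(p) == "syn" else 240.0) for p in range(1, n + 1)
    }
    strand_index = {p: top.strand_of(p) for p in top.tetrad_positions}
    corners, senses = _corner_and_sense(top.tetrads, strand_index)
    slot_names, slot, s_adv = _tetrad_slots(gp)

    placed: dict[int, np.ndarray] = {}       # residue -> full-atom coords
    base_targets: dict[int, np.ndarray] = {}  # residue -> posed base-frame atoms
    for li, quartet in enumerate(top.tetrads):
        normal = s_adv * senses[li]
        for p in quartet:
            tgt = slot(corners[strand_index[p]], li, normal)
            base_targets[p] = tgt
            placed[p] = _place_residue_on_base(
                seq[p], chi_of[p], slot_names, tgt, five_prime=(p == 1)
            )

    # capping groups: connected components of declared capping elements
    cap_bonds = []
    cap_residues: set[int] = set()
    tet = set(top.tetrad_positions)
    for cap in top.capping:
        use = cap.bonds[:1] if cap.mode == "ambiguous" else cap.bonds
        for hb in use:
            d0 = 2.0 if hb.donor[1].startswith("H") else 2.9
            cap_bonds.append((hb.donor, hb.acceptor, d0))
            for p in (hb.donor[0], hb.acceptor[0]):
                if p not in tet:
                    cap_residues.add(p)
    if cap_residues:
        stacks = {c.stack for c in top.capping}
        z_cap = gp.rise if "top" in stacks else -gp.rise * len(top.tetrads)
        anchors = {}
        for p in sorted(cap_residues):
            near = min(tet, key=lambda q: abs(q - p))
            tmpl_near = get_template(seq[near])
            anchors[p] = placed[near][tmpl_near.index("C1'")]
        posed = _solve_capping_group(top, sorted(cap_residues), cap_bonds, z_cap, anchors, chi_of)
        for p, tgt in posed.items():
            names = _base_frame(seq[p])[0]
            base_targets[p] = tgt
            placed[p] = _place_residue_on_base(
                seq[p], chi_of[p], names, tgt, five_prime=(p == 1)
            )

    # loops, bulges and flanks: arc initial placement
    unplaced = [p for p in range(1, n + 1) if p not in placed]
    for p in unplaced:
        before = [q for q in placed if q < p]
        after = [q for q in placed if q > p]
        tmpl = get_template(seq[p], five_prime=(p == 1))

        def c1_of(q):
            t = get_template(seq[q], five_prime=(q == 1))
            return placed[q][t.index("C1'")]

        if before and after:
            a, b = max(before), min(after)
            f = (p - a) / (b - a)
            target = (1 - f) * c1_of(a) + f * c1_of(b)
            r = np.linalg.norm(target[:2])
            if r > 1e-6:
                target = target * np.array([1.6, 1.6, 1.0]) if r < 12 else target
        elif before:
            a = max(before)
            target = c1_of(a) + np.array([0.0, 0.0, -2.0]) + 1.5 * (p - a) * _radial(c1_of(a))
        else:
            b = min(after)
            target = c1_of(b) + np.array([0.0, 0.0, 2.0]) + 1.5 * (b - p) * _radial(c1_of(b))
        X = tmpl.with_chi(chi_of[p])
        X = X - X[tmpl.index("C1'")] + target
        placed[p] = X

    model = _assemble(seq, placed)

    # closure minimization: covalent + sterics with structured bases pinned
    pin_idx = []
    pin_ref = []
    for p, tgt in base_targets.items():
        tmpl = get_template(seq[p], five_prime=(p == 1))
        for nm in slot_names if p in tet else _base_frame(seq[p])[0]:
            if nm == "C1'":
                continue
            i = model.index(p, nm)
            pin_idx.append(i)
            pin_ref.append(model.coords[i])
    from .restraints import DihedralRestraint, RestraintSet

    chi_rs = []
    for p in range(1, n + 1):
        code = seq[p]
        tmpl = get_template(code)
        o4, c1, ng, c_ref = tmpl.glycosidic_atoms
        structured = p in base_targets
        chi_rs.append(
            DihedralRestraint(
                atoms=((p, o4), (p, c1), (p, ng), (p, c_ref)),
                center=chi_of[p],
                halfwidth=8.0 if structured else 40.0,
                force_constant=60.0 if structured else 20.0,
            )
        )
    # maintain the Hoogsteen network actively during closure (also exempts
    # the bonded atom pairs from the steric floor)
    from .restraints import compile_hbond_restraints

    closure_rs = RestraintSet(distance=compile_hbond_restraints(top),
                              dihedral=chi_rs)
    consts = ForceConstants(pin=40.0, soft_sphere=30.0, soft_sphere_quad=60.0,
                            hbond=80.0)
    em = EnergyModel(
        model, closure_rs, constants=consts,
        pins=(np.array(pin_idx), np.array(pin_ref)), nonbonded=True,
    )
    from .fold_engine import minimize as _minimize

    closed = _minimize(model, closure_rs, grad_tol=0.15,
                       max_iter=max(gp.closure_iterations, 6000), energy_model=em)
    # residual backbone-link strain check
    bad_links = []
    for p in range(1, n):
        try:
            d = np.linalg.norm(closed.pos(p, "O3'") - closed.pos(p + 1, "P"))
        except KeyError:
            continue
        if abs(d - 1.607) > 0.8:
            bad_links.append((p, p + 1, round(float(d), 2)))
    if bad_links:
        raise LoopClosureError(
            f"backbone closure failed across links {bad_links}"
        )
    out = closed
    if gp.perturbation_sd > 0:
        out = perturb(out, gp.perturbation_sd, gp.seed)
    return out


def _radial(v: np.ndarray) -> np.ndarray:
    r = v.copy()
    r[2] = 0.0
    nrm = np.linalg.norm(r)
    return r / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])


def _assemble(seq, placed: dict[int, np.ndarray]) -> StructureModel:
    res_ids, codes, names, elems, coords = [], [], [], [], []
    for p in sorted(placed):
        code = seq[p]
        tmpl = get_template(code, five_prime=(p == 1))
        X = placed[p]
        for i in range(tmpl.n_atoms):
            res_ids.append(p)
            codes.append(code)
            names.append(tmpl.atom_names[i])
            elems.append(tmpl.elements[i])
            coords.append(X[i])
    return StructureModel(
        res_ids=np.array(res_ids),
        res_codes=np.array(codes, dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elems, dtype=object),
        coords=np.array(coords),
    )


@dataclass
class FixtureBundle:
    """Coherent synthetic dataset: structure -> peaks -> restraints -> curves."""

    name: str
    topology: QuadruplexTopology
    structure: StructureModel
    peaks: list
    restraints: object
    melt_heating: object
    melt_cooling: object
    tm_celsius: float
    dh_kcal: float

    def write(self, directory) -> None:
        from pathlib import Path

        from .noe import write_peaks
        from .pdbio import write_pdb

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_pdb(self.structure, d / "structure.pdb")
        (d / "topology.txt").write_text(self.topology.to_text())
        write_peaks(self.peaks, d / "peaks.tsv")
        (d / "restraints.tsv").write_text(self.restraints.to_tsv())
        (d / "melt_heating.csv").write_text(self.melt_heating.to_csv())
        (d / "melt_cooling.csv").write_text(self.melt_cooling.to_csv())
        (d / "README.txt").write_text(
            f"synthetic fixture {self.name!r}\n"
            f"two-state parameters: Tm {self.tm_celsius} C, dH {self.dh_kcal} kcal/mol\n"
            "structure: idealised generator output (deterministic)\n"
        )


#: reference melting parameters per fixture; the TP3/TP3-T6 Tm values are
#: the experimentally reported ones and drive the synthetic curves
FIXTURE_MELTING = {
    "tp3_t6": (60.2, 45.0),
    "tp3": (59.6, 45.0),
    "parallel_3layer": (55.0, 45.0),
    "antiparallel_2+2": (48.0, 35.0),
}


def make_fixture(
    name: str,
    directory=None,
    gp: GeneratorParams = GeneratorParams(),
    noise_sd: float = 0.002,
    seed: int = 0,
) -> FixtureBundle:
    """Build the registered synthetic fixture ``name``.

    The bundle is internally coherent: peaks are predicted from the ideal
    structure, restraints compiled from topology + peaks, and melting
    curves simulated with the documented two-state parameters.
    """
    from .folds import FOLD_SPECS, get_fold
    from .melting import simulate_melt
    from .noe import predict_peaks
    from .restraints import TP3_T6_ABSENT_CONTACTS, assemble

    if name not in FOLD_SPECS:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FOLD_SPECS)}")
    top = get_fold(name)
    structure = build_ideal_structure(top, gp)
    peaks = predict_peaks(structure)
    absent = TP3_T6_ABSENT_CONTACTS if name in ("tp3_t6", "tp3") else ()
    rs = assemble(top, peaks=peaks, absent_contacts=absent)
    tm, dh = FIXTURE_MELTING[name]
    heat = simulate_melt(tm, dh, noise_sd=noise_sd, seed=seed * 2 + 1)
    cool = simulate_melt(tm, dh, noise_sd=noise_sd, seed=seed * 2 + 2,
                         direction="cooling")
    bundle = FixtureBundle(
        name=name, topology=top, structure=structure, peaks=peaks,
        restraints=rs, melt_heating=heat, melt_cooling=cool,
        tm_celsius=tm, dh_kcal=dh,
    )
    if directory is not None:
        bundle.write(directory)
    return bundle


def perturb(m: StructureModel, sd: float, seed: int = 0) -> StructureModel:
    """Isotropic Gaussian coordinate noise; sd=0 is the identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return m.with_coords(m.coords.copy())
    rng = np.random.default_rng(seed)
    return m.with_coords(m.coords + rng.normal(0.0, sd, m.coords.shape))
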