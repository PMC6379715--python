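"""Topology and validation statistics derived from coordinates.

The analysis inverts the generator/fold direction: given an all-atom
model it detects Hoogsteen-cycled G-tetrads, classifies glycosidic
states, stacks tetrads into layers, assigns strand orientations, types
loops and grooves, flags bulges, finds capping pairs/triples, and
computes ensemble statistics (NOE violations, covalent deviations,
pairwise RMSDs) in the layout of an NMR structure-statistics table.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .geometry import angle, best_fit_plane, superposed_rmsd, torsion
from .model import Ensemble, StructureModel
from .noe import find_disjoint_4cycles
from .sequences import Sequence
from .topology import QuadruplexTopology, build_topology

#: hydrogen-bond geometric criteria
HBOND_DIST = 3.5          # donor-acceptor heavy-atom distance, Angstrom
HBOND_ANGLE = 120.0       # donor - H ... acceptor angle, degrees

#: groove-width thresholds on mean cycle-adjacent P-P separations,
#: calibrated once on the ideal generator geometry and frozen
GROOVE_NARROW_MAX = 13.0
GROOVE_WIDE_MIN = 17.0

BASE_DONORS = {
    "G": (("N1", "H1"), ("N2", "H21"), ("N2", "H22")),
    "I": (("N1", "H1"),),
    "A": (("N6", "H61"), ("N6", "H62")),
    "C": (("N4", "H41"), ("N4", "H42")),
    "T": (("N3", "H3"),),
    "U": (("N3", "H3"),),
}
BASE_ACCEPTORS = {
    "G": ("O6", "N7", "N3"),
    "I": ("O6", "N7", "N3"),
    "A": ("N1", "N3", "N7"),
    "C": ("O2", "N3"),
    "T": ("O2", "O4"),
    "U": ("O2", "O4"),
}
SUGAR_ACCEPTORS = ("O4'",)


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-residue measures
# ---------------------------------------------------------------------------

def glycosidic_chi(m: StructureModel) -> dict[int, tuple[float, str]]:
    """chi (O4'-C1'-N9-C4) and syn/anti state for every purine.

    syn if chi lies within 90 degrees of 60 (mod 360), anti otherwise.
    Residues with missing atoms are skipped.
    """
    out = {}
    for pos, code in m.residues:
        if code not in ("A", "G", "I"):
            continue
        try:
            chi = torsion(
                m.pos(pos, "O4'"), m.pos(pos, "C1'"), m.pos(pos, "N9"), m.pos(pos, "C4")
            )
        except KeyError:
            continue
        dev = (chi - 60.0) % 360.0
        state = "syn" if dev < 90.0 or dev > 270.0 else "anti"
        out[pos] = (chi, state)
    return out


def _fitted_base_atoms(m: StructureModel) -> dict:
    """Idealized base-atom positions per residue.

    Each residue's template base is rigidly superposed on the model's base
    heavy atoms; hydrogen (and heavy) base positions are then read off the
    fitted template.  For clean structures this is a no-op; for noisy
    coordinates it restores ideal base geometry before hydrogen-bond
    measurement ("hydrogens from templates").
    """
    from .geometry import kabsch
    from .templates import get_template

    out: dict[tuple[int, str], np.ndarray] = {}
    first = m.residues[0][0]
    for rid, code in m.residues:
        tmpl = get_template(code, five_prime=(rid == first))
        heavy = [n for n in tmpl.base_atoms if not n.startswith("H")]
        try:
            tgt = np.array([m.pos(rid, n) for n in heavy])
        except KeyError:
            continue
        mob = np.array([tmpl.coords[tmpl.index(n)] for n in heavy])
        R, t, _ = kabsch(mob, tgt)
        for n in tmpl.base_atoms:
            out[(rid, n)] = tmpl.coords[tmpl.index(n)] @ R.T + t
    return out


def _hbond_ok(m, don_res, don_heavy, don_h, acc_res, acc_atom,
              dist_cutoff=HBOND_DIST, angle_cutoff=HBOND_ANGLE,
              fitted: dict | None = None) -> bool:
    def pos(res, name):
        if fitted is not None and (res, name) in fitted:
            return fitted[(res, name)]
        return m.pos(res, name)

    try:
        d = float(np.linalg.norm(pos(don_res, don_heavy) - pos(acc_res, acc_atom)))
        if d >= dist_cutoff:
            return False
        ang = angle(pos(don_res, don_heavy), pos(don_res, don_h),
                    pos(acc_res, acc_atom))
        return ang > angle_cutoff
    except KeyError:
        return False


def detect_tetrads(
    m: StructureModel, dist_cutoff: float = HBOND_DIST, angle_cutoff: float = HBOND_ANGLE
) -> list[tuple[int, int, int, int]]:
    """Hoogsteen-cycled guanine quartets (canonical rotation, donor order)."""
    gs = [p for p, c in m.residues if c == "G"]
    fitted = _fitted_base_atoms(m)
    edges = []
    for a in gs:
        for b in gs:
            if a == b:
                continue
            n1_o6 = _hbond_ok(m, a, "N1", "H1", b, "O6", dist_cutoff, angle_cutoff,
                              fitted=fitted)
            n2_n7 = any(
                _hbond_ok(m, a, "N2", h, b, "N7", dist_cutoff, angle_cutoff,
                          fitted=fitted)
                for h in ("H21", "H22")
            )
            if n1_o6 and n2_n7:
                edges.append((a, b))
    return find_disjoint_4cycles(edges)


# ---------------------------------------------------------------------------
# base pairs / triples outside the core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasePair:
    residues: tuple[int, int]
    mode: str
    bonds: tuple[tuple[tuple[int, str], tuple[int, str]], ...]   # (donor, acceptor)


@dataclass(frozen=True)
class BaseTriple:
    residues: tuple[int, int, int]
    pairs: tuple[BasePair, ...]


def _pair_mode(m: StructureModel, pa: int, pb: int, bonds) -> str:
    """Watson-Crick / Hoogsteen / reverse-Hoogsteen from edge atoms and
    the cis/trans arrangement of the glycosidic bonds."""
    codes = {p: m.residue_code(p) for p in (pa, pb)}
    purines = [p for p in (pa, pb) if codes[p] in ("A", "G", "I")]
    hoogsteen_face = False
    wc_face = False
    for (dr, da), (ar, aa) in bonds:
        for res, at in ((dr, da), (ar, aa)):
            if codes[res] in ("A", "G", "I"):
                if at in ("N7", "O6", "N6"):
                    hoogsteen_face = True
                if at in ("N1", "N2"):
                    wc_face = True
    if not purines:
        return "ambiguous"
    if hoogsteen_face and not (wc_face and len(purines) == 1):
        # pairing on a purine Hoogsteen face: cis -> Hoogsteen,
        # trans -> reverse Hoogsteen
        def gly(p):
            n = "N9" if codes[p] in ("A", "G", "I") else "N1"
            return m.pos(p, n), m.pos(p, "C1'")

        na, ca = gly(pa)
        nb, cb = gly(pb)
        axis = nb - na
        axis = axis / np.linalg.norm(axis)
        va = ca - na
        vb = cb - nb
        va = va - np.dot(va, axis) * axis
        vb = vb - np.dot(vb, axis) * axis
        cis = bool(np.dot(va, vb) > 0)
        return "hoogsteen" if cis else "reverse_hoogsteen"
    if wc_face:
        return "watson_crick"
    return "ambiguous"


def detect_pairs_triples(
    m: StructureModel, exclude: set[int] | None = None
) -> list[BasePair | BaseTriple]:
    """Hydrogen-bonded base pairs (merged into triples) outside the tetrads.

    ``exclude`` defaults to the residues of detected tetrads.
    """
    if exclude is None:
        exclude = {p for q in detect_tetrads(m) for p in q}
    residues = [(p, c) for p, c in m.residues if p not in exclude]
    fitted = _fitted_base_atoms(m)
    pair_bonds: dict[tuple[int, int], list] = {}
    for (pa, ca), (pb, cb) in combinations(residues, 2):
        bonds = []
        for (da, db) in ((pa, pb), (pb, pa)):
            code_d = m.residue_code(da)
            code_a = m.residue_code(db)
            for heavy, h in BASE_DONORS.get(code_d, ()):
                for acc in BASE_ACCEPTORS.get(code_a, ()) + SUGAR_ACCEPTORS:
                    if _hbond_ok(m, da, heavy, h, db, acc, fitted=fitted):
                        bonds.append(((da, h), (db, acc)))
        if bonds:
            pair_bonds[(pa, pb)] = bonds
    pairs = [
        BasePair(
            residues=k,
            mode=_pair_mode(m, k[0], k[1], [((d[0], d[1]), (a[0], a[1])) for d, a in v]),
            bonds=tuple(v),
        )
        for k, v in sorted(pair_bonds.items())
    ]
    # merge pairs sharing a residue into triples
    out: list[BasePair | BaseTriple] = []
    used = set()
    for i, p1 in enumerate(pairs):
        if i in used:
            continue
        group = [p1]
        members = set(p1.residues)
        for j in range(i + 1, len(pairs)):
            if j in used:
                continue
            if members & set(pairs[j].residues):
                group.append(pairs[j])
                used.add(j)
                members |= set(pairs[j].residues)
        if len(group) == 1:
            out.append(p1)
        elif len(members) == 3:
            out.append(
                BaseTriple(residues=tuple(sorted(members)), pairs=tuple(group))
            )
        else:
            out.extend(group)
    return out


# ---------------------------------------------------------------------------
# full classification
# ---------------------------------------------------------------------------

def _stack_layers(m: StructureModel, quartets):
    """Order quartets along the stacking axis, first layer = the one
    containing the smallest residue position."""
    centroids = []
    for q in quartets:
        pts = np.array([m.pos(p, "N9") for p in q])
        centroids.append(pts.mean(axis=0))
    centroids = np.array(centroids)
    if len(quartets) == 1:
        return list(quartets)
    axis = centroids[-1] - centroids[0]
    if len(quartets) > 2:
        axis = np.linalg.svd(centroids - centroids.mean(axis=0))[2][0]
    order = np.argsort(centroids @ axis)
    ordered = [quartets[i] for i in order]
    if min(min(q) for q in ordered) != min(ordered[0]):
        ordered = ordered[::-1]
    return ordered


def classify_structure(m: StructureModel) -> QuadruplexTopology:
    """Re-derive the declarative topology of a folded model."""
    quartets = detect_tetrads(m)
    if len(quartets) < 2:
        raise ClassificationError(
            f"need at least 2 stacked tetrads to classify, found {len(quartets)}"
        )
    layers = _stack_layers(m, quartets)
    tet = sorted(p for q in layers for p in q)
    chi = glycosidic_chi(m)
    syn = [p for p in tet if chi[p][1] == "syn"]

    # bulges: single non-tetrad residues between stacked tetrad guanines
    bulges = []
    for p, code in m.residues:
        if p in tet or (p - 1) not in tet or (p + 1) not in tet:
            continue
        c_lo = np.array([m.pos(p - 1, "N9")])
        c_hi = np.array([m.pos(p + 1, "N9")])
        if np.linalg.norm(c_lo - c_hi) < 6.5:
            bulges.append(p)

    caps = detect_pairs_triples(m, exclude=set(tet))
    capping = []
    for item in caps:
        pair_list = item.pairs if isinstance(item, BaseTriple) else (item,)
        for bp in pair_list:
            capping.append(
                {
                    "mode": bp.mode,
                    "partners": bp.residues,
                    "bonds": [((d[0], d[1]), (a[0], a[1])) for d, a in bp.bonds],
                }
            )
    seq = Sequence(m.model_id and f"model{m.model_id}" or "model",
                   "".join(c for _, c in m.residues))
    spec = {
        "sequence_id": seq.id,
        "residues": seq.residues,
        "tetrads": layers,
        "syn": syn,
        "bulges": bulges,
        "capping": capping,
    }
    top = build_topology(spec)
    top.grooves = _measure_grooves(m, top)
    return top


def _measure_grooves(m: StructureModel, top: QuadruplexTopology):
    """Groove labels from mean phosphate separations of cycle-adjacent
    guanines, with frozen narrow/wide thresholds."""
    sid = {p: top.strand_of(p) for p in top.tetrad_positions}
    acc: dict[tuple[int, int], list[float]] = {}
    for q in top.tetrads:
        for k in range(4):
            a, b = q[k], q[(k + 1) % 4]
            try:
                d = float(np.linalg.norm(m.pos(a, "P") - m.pos(b, "P")))
            except KeyError:
                continue
            acc.setdefault(tuple(sorted((sid[a], sid[b]))), []).append(d)
    out = []
    for (sa, sb), ds in sorted(acc.items()):
        mean = float(np.mean(ds))
        if mean < GROOVE_NARROW_MAX:
            label = "narrow"
        elif mean > GROOVE_WIDE_MIN:
            label = "wide"
        else:
            label = "medium"
        out.append((sa, sb, label))
    return out


def fold_class(top: QuadruplexTopology) -> str:
    """Human-readable fold family from strand orientations."""
    ups = sum(1 for _, o in top.strands if o == "up")
    if ups in (0, 4):
        return "parallel"
    if ups in (1, 3):
        return "(3+1) hybrid"
    return "antiparallel"


# ---------------------------------------------------------------------------
# ensemble validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Ensemble statistics; every entry is (mean, sd)."""

    noe_violations: tuple[float, float]
    bond_dev: tuple[float, float]
    angle_dev: tuple[float, float]
    improper_dev: tuple[float, float]
    rmsd_core: tuple[float, float]
    rmsd_all: tuple[float, float]
    n_models: int = 0
    core_residues: tuple[int, ...] = ()

    def to_text(self) -> str:
        rows = [
            ("NOE violations number (>0.2 A)", self.noe_violations, "{:.1f}"),
            ("bond lengths (A)", self.bond_dev, "{:.3f}"),
            ("bond angles (deg)", self.angle_dev, "{:.3f}"),
            ("impropers (deg)", self.improper_dev, "{:.3f}"),
            ("pairwise rmsd, G-tetrad core (A)", self.rmsd_core, "{:.3f}"),
            ("pairwise rmsd, all residues (A)", self.rmsd_all, "{:.3f}"),
        ]
        lines = ["Structure statistics (mean +/- sd over models)"]
        for name, (mean, sd), fmt in rows:
            lines.append(f"  {name:<36} {fmt.format(mean)} +/- {fmt.format(sd)}")
        lines.append(f"  models: {self.n_models}; core residues: {list(self.core_residues)}")
        return "\n".join(lines)


def _mean_sd(values) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    return float(a.mean()), float(a.std())


def noe_violation_count(m: StructureModel, restraints, threshold: float = 0.2) -> int:
    """NOE distance restraints violated by more than ``threshold``."""
    n = 0
    for r in restraints.distance:
        if r.category != "noe" or r.ambiguity_group is not None:
            continue
        d = float(np.linalg.norm(m.pos(*r.atom_a) - m.pos(*r.atom_b)))
        if d > r.upper + threshold or d < r.lower - threshold:
            n += 1
    # ambiguity groups count once, on their effective (minimum) distance
    groups: dict[str, list] = {}
    for r in restraints.distance:
        if r.category == "noe" and r.ambiguity_group:
            groups.setdefault(r.ambiguity_group, []).append(r)
    for rs in groups.values():
        d = min(float(np.linalg.norm(m.pos(*r.atom_a) - m.pos(*r.atom_b))) for r in rs)
        if d > rs[0].upper + threshold or d < rs[0].lower - threshold:
            n += 1
    return n


def covalent_deviations(m: StructureModel):
    """Mean absolute deviations from template covalent geometry:
    (bond lengths A, bond angles deg, impropers deg)."""
    from .energy import EnergyModel, _torsion_and_grad, _wrap

    em = EnergyModel(m, nonbonded=False)
    x = m.coords
    d = np.linalg.norm(x[em.bonds[:, 0]] - x[em.bonds[:, 1]], axis=1)
    bond_dev = float(np.mean(np.abs(d - em.bond0)))
    i, j, k = em.angles.T
    v1 = x[i] - x[j]
    v2 = x[k] - x[j]
    cos = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    th = np.arccos(np.clip(cos, -1, 1))
    angle_dev = float(np.degrees(np.mean(np.abs(th - em.angle0))))
    phi, _ = _torsion_and_grad(x, em.impropers)
    imp_dev = float(np.degrees(np.mean(np.abs(_wrap(phi - em.improper0)))))
    return bond_dev, angle_dev, imp_dev


def pairwise_rmsd(ensemble: Ensemble, atom_mask: np.ndarray) -> tuple[float, float]:
    """Mean +/- sd of superposed RMSD over all model pairs."""
    vals = []
    for a, b in combinations(range(len(ensemble)), 2):
        vals.append(
            superposed_rmsd(
                ensemble[a].coords[atom_mask], ensemble[b].coords[atom_mask]
            )
        )
    return _mean_sd(vals)


def validate_ensemble(
    ensemble: Ensemble,
    restraints=None,
    core_selection: str | list[int] = "tetrad_guanines",
    violation_threshold: float = 0.2,
) -> ValidationReport:
    """Structure-statistics report over an ensemble of >= 2 models."""
    if len(ensemble) < 2:
        raise ValueError("validation needs at least 2 models")
    first = ensemble[0]
    if isinstance(core_selection, str):
        if core_selection != "tetrad_guanines":
            raise ValueError(f"unknown core selection {core_selection!r}")
        core = sorted({p for q in detect_tetrads(first) for p in q})
    else:
        core = sorted(core_selection)
    if restraints is not None:
        viol = _mean_sd([noe_violation_count(m, restraints, violation_threshold)
                         for m in ensemble])
    else:
        viol = (0.0, 0.0)
    devs = [covalent_deviations(m) for m in ensemble]
    heavy = first.heavy_mask()
    core_mask = heavy & np.isin(first.res_ids, core)
    return ValidationReport(
        noe_violations=viol,
        bond_dev=_mean_sd([d[0] for d in devs]),
        angle_dev=_mean_sd([d[1] for d in devs]),
        improper_dev=_mean_sd([d[2] for d in devs]),
        rmsd_core=pairwise_rmsd(ensemble, core_mask),
        rmsd_all=pairwise_rmsd(ensemble, heavy),
        n_models=len(ensemble),
        core_residues=tuple(core),
    )
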