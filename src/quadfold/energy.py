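"""Restraint + idealized covalent energy model.

The potential is deliberately minimal: harmonic bonds/angles/impropers at
template ideal values, a quartic soft-sphere repulsion between nonbonded
atoms, flat-bottom wells for distance and dihedral restraints, a
best-fit-plane penalty for planarity groups and a signed-volume penalty
that preserves template chirality.  No electrostatics, solvent or ions:
tetrad geometry is maintained by the hydrogen-bond and planarity
restraints alone.

Units: kcal/mol, Angstrom, degrees (converted internally), fs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import StructureModel
from .templates import LINK_ANGLES, LINK_O3_P, VDW_RADIUS, get_template

#: (kcal/mol/A per amu) -> A/fs^2
ACC = 4.184e-4
KB = 1.987204e-3  # kcal/mol/K


@dataclass
class ForceConstants:
    """Per-term force constants (kcal/mol/A^2 or kcal/mol/rad^2)."""

    bond: float = 300.0
    angle: float = 80.0
    improper: float = 40.0
    ring_torsion: float = 15.0
    chirality: float = 50.0
    noe_nonexch: float = 16.0
    noe_exch: float = 8.0
    hbond: float = 8.0
    repulsion_restraint: float = 16.0
    dihedral: float = 50.0
    planarity: float = 1.0
    soft_sphere: float = 4.0
    soft_sphere_quad: float = 8.0
    pin: float = 25.0


def _torsion_and_grad(coords, quads):
    """Torsions (radians) and gradients for (m,4) atom-index quadruples.

    Returns (phi (m,), dphi/dp (m,4,3)).
    """
    p = coords[quads]  # (m,4,3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(-y, x)
    sq1 = np.einsum("ij,ij->i", n1, n1)
    sq2 = np.einsum("ij,ij->i", n2, n2)
    dp0 = -(nb2 / np.maximum(sq1, 1e-12))[:, None] * n1
    dp3 = (nb2 / np.maximum(sq2, 1e-12))[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2**2, 1e-12)
    c32 = np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2**2, 1e-12)
    dp1 = -(1.0 + c12)[:, None] * dp0 + c32[:, None] * dp3
    dp2 = -(dp0 + dp1 + dp3)
    grad = np.stack([dp0, dp1, dp2, dp3], axis=1)
    return phi, grad




def _scatter_add(G: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """G[idx] += vals, fast path for repeated indices (bincount-based)."""
    n = G.shape[0]
    for c in range(3):
        G[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


def _wrap(dphi):
    """Wrap angle differences (radians) into (-pi, pi]."""
    return (dphi + np.pi) % (2 * np.pi) - np.pi


class EnergyModel:
    """Energy and analytic gradient for one atom set.

    Built once from a :class:`StructureModel` skeleton (atom identities
    only; coordinates are passed per evaluation) and an optional
    RestraintSet.  ``pins`` optionally holds (indices, reference
    coordinates) for harmonic position restraints.
    """

    def __init__(
        self,
        model: StructureModel,
        restraints=None,
        constants: ForceConstants | None = None,
        pins: tuple[np.ndarray, np.ndarray] | None = None,
        nonbonded: bool = True,
    ):
        self.k = constants or ForceConstants()
        self.n = model.n_atoms
        self.model = model
        self._build_covalent(model)
        self._build_restraints(model, restraints)
        self.pins = None
        if pins is not None:
            idx, ref = pins
            self.pins = (np.asarray(idx, dtype=int), np.asarray(ref, dtype=float))
        self.nonbonded = nonbonded
        if nonbonded:
            self._build_nonbonded(model)
        self._nb_pairs = None
        self._nb_count = 0

    # ------------------------------------------------------------------
    def _build_covalent(self, model: StructureModel):
        bonds, b0 = [], []
        angles, a0 = [], []
        impropers, i0 = [], []
        rings, r0 = [], []
        chirals, chir_sign, chir_thresh = [], [], []
        residues = model.residues
        offsets = {}
        for rid, code in residues:
            tmpl = get_template(code, five_prime=(rid == residues[0][0]))
            idx = np.array([model.index(rid, n) for n in tmpl.atom_names])
            offsets[rid] = (tmpl, idx)
            for i, j in tmpl.bonds:
                bonds.append((idx[i], idx[j]))
                b0.append(tmpl.bond_length(i, j))
            for i, j, l in tmpl.angles:
                angles.append((idx[i], idx[j], idx[l]))
                v1 = tmpl.coords[i] - tmpl.coords[j]
                v2 = tmpl.coords[l] - tmpl.coords[j]
                a0.append(
                    np.arccos(
                        np.clip(
                            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1
                        )
                    )
                )
            for quad in tmpl.impropers:
                impropers.append(tuple(idx[q] for q in quad))
                from .geometry import torsion as _t

                i0.append(np.radians(_t(*(tmpl.coords[q] for q in quad))))
            for c, n1, n2, n3, sign, vol in tmpl.chiral_centers:
                chirals.append((idx[c], idx[n1], idx[n2], idx[n3]))
                chir_sign.append(sign)
                chir_thresh.append(0.5 * vol)
            for quad, phi0 in tmpl.ring_torsions:
                rings.append(tuple(idx[q] for q in quad))
                r0.append(np.radians(phi0))
        # phosphodiester linkage between consecutive residues
        for (r1, c1), (r2, c2) in zip(residues, residues[1:]):
            if r2 != r1 + 1 or not model.has_atom(r2, "P"):
                continue
            bonds.append((model.index(r1, "O3'"), model.index(r2, "P")))
            b0.append(LINK_O3_P)
            for (a, b, c), theta in LINK_ANGLES.items():
                ra = r1 if a in ("C3'", "O3'") else r2
                rb = r1 if b == "O3'" else r2
                rc = r2
                try:
                    angles.append(
                        (model.index(ra, a), model.index(rb, b), model.index(rc, c))
                    )
                    a0.append(np.radians(theta))
                except KeyError:
                    pass
        self.bonds = np.array(bonds, dtype=int)
        self.bond0 = np.array(b0)
        self.angles = np.array(angles, dtype=int)
        self.angle0 = np.array(a0)
        self.impropers = np.array(impropers, dtype=int) if impropers else np.empty((0, 4), int)
        self.improper0 = np.array(i0)
        self.chirals = np.array(chirals, dtype=int) if chirals else np.empty((0, 4), int)
        self.chiral_sign = np.array(chir_sign)
        self.chiral_thresh = np.array(chir_thresh)
        self.rings = np.array(rings, dtype=int) if rings else np.empty((0, 4), int)
        self.ring0 = np.array(r0)

    def _build_restraints(self, model: StructureModel, restraints):
        self.dist_pairs = np.empty((0, 2), int)
        self.dist_lo = np.empty(0)
        self.dist_hi = np.empty(0)
        self.dist_k = np.empty(0)
        self.groups: list[tuple[np.ndarray, float, float, float]] = []
        self.tors_quads = np.empty((0, 4), int)
        self.tors_center = np.empty(0)
        self.tors_half = np.empty(0)
        self.tors_k = np.empty(0)
        self.planar_groups: list[tuple[np.ndarray, float]] = []
        self._restraint_pairs_set: set[tuple[int, int]] = set()
        self._dist_cats: list[str] = []
        self._group_cats: list[str] = []
        self._group_k: list[float] = []
        if restraints is None:
            return
        pairs, lo, hi, cats = [], [], [], []
        by_group: dict[str, list] = {}
        for r in restraints.all_distance_like():
            try:
                i = model.index(*r.atom_a)
                j = model.index(*r.atom_b)
            except KeyError as e:
                raise KeyError(f"restraint references missing atom: {e}") from None
            if r.category == "noe":
                cat = "noe_exch" if r.exchangeable else "noe_nonexch"
            elif r.category == "hbond":
                cat = "hbond"
            else:
                cat = "repulsion_restraint"
            lo_v = r.lower if r.lower is not None else 0.0
            hi_v = r.upper if r.upper is not None else np.inf
            if r.ambiguity_group:
                by_group.setdefault(r.ambiguity_group, []).append((i, j, lo_v, hi_v, cat))
                continue
            pairs.append((i, j))
            lo.append(lo_v)
            hi.append(hi_v)
            cats.append(cat)
            self._restraint_pairs_set.add((min(i, j), max(i, j)))
        self._dist_cats = cats
        if pairs:
            self.dist_pairs = np.array(pairs, dtype=int)
            self.dist_lo = np.array(lo)
            self.dist_hi = np.array(hi)
        self._group_cats = []
        for g, members in by_group.items():
            arr = np.array([(i, j) for i, j, *_ in members], dtype=int)
            _, _, lo_v, hi_v, cat = members[0]
            self.groups.append((arr, lo_v, hi_v, cat))
            self._group_cats.append(cat)
            for i, j, *_ in members:
                self._restraint_pairs_set.add((min(i, j), max(i, j)))
        self.update_distance_constants()
        quads, c0, hw, tk = [], [], [], []
        for d in restraints.dihedral:
            quads.append(tuple(model.index(*a) for a in d.atoms))
            c0.append(np.radians(d.center))
            hw.append(np.radians(d.halfwidth))
            tk.append(self.k.dihedral if d.force_constant is None else d.force_constant)
        if quads:
            self.tors_quads = np.array(quads, dtype=int)
            self.tors_center = np.array(c0)
            self.tors_half = np.array(hw)
            self.tors_k = np.array(tk)
        for g in restraints.planarity:
            idx = np.array([model.index(*a) for a in g.atoms], dtype=int)
            self.planar_groups.append((idx, g.weight * self.k.planarity))

    def update_distance_constants(self, **overrides):
        """Refresh per-restraint force constants from ``self.k`` (optionally
        overriding categories, e.g. ``noe_nonexch=16``)."""
        for cat, v in overrides.items():
            setattr(self.k, cat, float(v))
        self.dist_k = np.array(
            [getattr(self.k, c) for c in self._dist_cats], dtype=float
        ) if self._dist_cats else np.empty(0)
        self._group_k = [getattr(self.k, c) for c in self._group_cats]

    def _build_nonbonded(self, model: StructureModel):
        # exclusions: 1-2, 1-3, 1-4 and hydrogen-bond-restrained pairs
        n = self.n
        adj = [set() for _ in range(n)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        excl = set()
        for i in range(n):
            for j in adj[i]:
                excl.add((min(i, j), max(i, j)))
                for l in adj[j]:
                    if l != i:
                        excl.add((min(i, l), max(i, l)))
                        for m_ in adj[l]:
                            if m_ not in (i, j):
                                excl.add((min(i, m_), max(i, m_)))
        excl |= self._restraint_pairs_set
        self._nb_excl = excl
        self.radii = np.array(
            [VDW_RADIUS[e] for e in model.elements], dtype=float
        )
        self._nb_scale = 0.85
        self._nb_cutoff = self._nb_scale * 2 * self.radii.max()

    def _neighbor_pairs(self, coords):
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        raw = tree.query_pairs(self._nb_cutoff + 0.6, output_type="ndarray")
        if len(raw) == 0:
            return np.empty((0, 2), int)
        keep = [
            (i, j) for i, j in raw if (i, j) not in self._nb_excl
        ]
        return np.array(keep, dtype=int) if keep else np.empty((0, 2), int)

    def refresh_neighbors(self, coords):
        self._nb_pairs = self._neighbor_pairs(coords)
        self._nb_count = 0

    # ------------------------------------------------------------------
    def energy_grad(self, coords: np.ndarray, terms: dict | None = None):
        """Total energy (kcal/mol) and gradient (kcal/mol/A)."""
        E = 0.0
        G = np.zeros_like(coords)

        def add(name, e):
            nonlocal E
            E += e
            if terms is not None:
                terms[name] = terms.get(name, 0.0) + e

        # bonds
        if len(self.bonds):
            d = coords[self.bonds[:, 0]] - coords[self.bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dev = r - self.bond0
            add("bond", float(self.k.bond * np.sum(dev**2)))
            f = (2 * self.k.bond * dev / np.maximum(r, 1e-9))[:, None] * d
            _scatter_add(G, self.bonds[:, 0], f)
            _scatter_add(G, self.bonds[:, 1], -f)
        # angles
        if len(self.angles):
            i, j, l = self.angles.T
            v1 = coords[i] - coords[j]
            v2 = coords[l] - coords[j]
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            cos = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
            cos = np.clip(cos, -0.999999, 0.999999)
            th = np.arccos(cos)
            dev = th - self.angle0
            add("angle", float(self.k.angle * np.sum(dev**2)))
            pref = 2 * self.k.angle * dev
            sin = np.sqrt(1 - cos**2)
            d1 = (cos[:, None] * v1 / n1[:, None] ** 2 - v2 / (n1 * n2)[:, None]) / sin[:, None]
            d2 = (cos[:, None] * v2 / n2[:, None] ** 2 - v1 / (n1 * n2)[:, None]) / sin[:, None]
            _scatter_add(G, i, pref[:, None] * d1)
            _scatter_add(G, l, pref[:, None] * d2)
            _scatter_add(G, j, -pref[:, None] * (d1 + d2))
        # impropers
        if len(self.impropers):
            phi, dphi = _torsion_and_grad(coords, self.impropers)
            dev = _wrap(phi - self.improper0)
            add("improper", float(self.k.improper * np.sum(dev**2)))
            pref = 2 * self.k.improper * dev
            for c in range(4):
                _scatter_add(G, self.impropers[:, c], pref[:, None] * dphi[:, c])
        # sugar ring torsions (pucker)
        if len(self.rings):
            phi, dphi = _torsion_and_grad(coords, self.rings)
            dev = _wrap(phi - self.ring0)
            add("ring_torsion", float(self.k.ring_torsion * np.sum(dev**2)))
            pref = 2 * self.k.ring_torsion * dev
            for c in range(4):
                _scatter_add(G, self.rings[:, c], pref[:, None] * dphi[:, c])
        # chirality (keep signed volume away from inversion)
        if len(self.chirals):
            c, a, b, d_ = self.chirals.T
            u = coords[a] - coords[c]
            v = coords[b] - coords[c]
            w = coords[d_] - coords[c]
            vol = np.einsum("ij,ij->i", u, np.cross(v, w)) * self.chiral_sign
            viol = np.minimum(vol - self.chiral_thresh, 0.0)
            add("chirality", float(self.k.chirality * np.sum(viol**2)))
            pref = 2 * self.k.chirality * viol * self.chiral_sign
            du = np.cross(v, w)
            dv = np.cross(w, u)
            dw = np.cross(u, v)
            _scatter_add(G, a, pref[:, None] * du)
            _scatter_add(G, b, pref[:, None] * dv)
            _scatter_add(G, d_, pref[:, None] * dw)
            _scatter_add(G, c, -pref[:, None] * (du + dv + dw))
        # flat-bottom distance restraints
        if len(self.dist_pairs):
            d = coords[self.dist_pairs[:, 0]] - coords[self.dist_pairs[:, 1]]
            r = np.linalg.norm(d, axis=1)
            dev = np.where(r < self.dist_lo, r - self.dist_lo,
                           np.where(r > self.dist_hi, r - self.dist_hi, 0.0))
            add("distance_restraint", float(np.sum(self.dist_k * dev**2)))
            f = (2 * self.dist_k * dev / np.maximum(r, 1e-9))[:, None] * d
            _scatter_add(G, self.dist_pairs[:, 0], f)
            _scatter_add(G, self.dist_pairs[:, 1], -f)
        # ambiguous OR groups: the effective distance is the minimum member
        for (arr, lo_v, hi_v, _cat), k in zip(self.groups, self._group_k):
            d = coords[arr[:, 0]] - coords[arr[:, 1]]
            r = np.linalg.norm(d, axis=1)
            m = int(np.argmin(r))
            rm = r[m]
            dev = rm - lo_v if rm < lo_v else (rm - hi_v if rm > hi_v else 0.0)
            add("distance_restraint", float(k * dev**2))
            if dev != 0.0:
                f = 2 * k * dev / max(rm, 1e-9) * d[m]
                G[arr[m, 0]] += f
                G[arr[m, 1]] -= f
        # flat-bottom dihedral wells
        if len(self.tors_quads):
            phi, dphi = _torsion_and_grad(coords, self.tors_quads)
            diff = _wrap(phi - self.tors_center)
            dev = np.sign(diff) * np.maximum(np.abs(diff) - self.tors_half, 0.0)
            add("dihedral_restraint", float(np.sum(self.tors_k * dev**2)))
            pref = 2 * self.tors_k * dev
            for c in range(4):
                _scatter_add(G, self.tors_quads[:, c], pref[:, None] * dphi[:, c])
        # planarity: smallest eigenvalue of the group scatter matrix
        for idx, w in self.planar_groups:
            X = coords[idx]
            c = X.mean(axis=0)
            Y = X - c
            S = Y.T @ Y
            vals, vecs = np.linalg.eigh(S)
            nvec = vecs[:, 0]
            dev = Y @ nvec
            add("planarity", float(w * np.sum(dev**2)))
            G[idx] += 2 * w * dev[:, None] * nvec[None, :]
        # soft-sphere nonbonded repulsion
        if self.nonbonded:
            if self._nb_pairs is None:
                self.refresh_neighbors(coords)
            pairs = self._nb_pairs
            if len(pairs):
                d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
                r = np.linalg.norm(d, axis=1)
                r0 = self._nb_scale * (self.radii[pairs[:, 0]] + self.radii[pairs[:, 1]])
                viol = np.minimum(r - r0, 0.0)
                add("soft_sphere", float(
                    self.k.soft_sphere * np.sum(viol**4)
                    + self.k.soft_sphere_quad * np.sum(viol**2)
                ))
                f = ((4 * self.k.soft_sphere * viol**3
                      + 2 * self.k.soft_sphere_quad * viol)
                     / np.maximum(r, 1e-9))[:, None] * d
                _scatter_add(G, pairs[:, 0], f)
                _scatter_add(G, pairs[:, 1], -f)
        # position pins
        if self.pins is not None:
            idx, ref = self.pins
            d = coords[idx] - ref
            add("pin", float(self.k.pin * np.sum(d**2)))
            G[idx] += 2 * self.k.pin * d
        return E, G

    def energy(self, coords):
        return self.energy_grad(coords)[0]

    # -- diagnostics -----------------------------------------------------
    def restraint_violations(self, coords, threshold: float = 0.2):
        """Distance restraints violated by more than ``threshold`` Angstrom."""
        out = []
        if len(self.dist_pairs):
            d = np.linalg.norm(
                coords[self.dist_pairs[:, 0]] - coords[self.dist_pairs[:, 1]], axis=1
            )
            over = np.where(d > self.dist_hi, d - self.dist_hi, self.dist_lo - d)
            for m in np.nonzero(over > threshold)[0]:
                out.append((tuple(self.dist_pairs[m]), float(over[m])))
        for arr, lo_v, hi_v, _cat in self.groups:
            r = np.linalg.norm(coords[arr[:, 0]] - coords[arr[:, 1]], axis=1).min()
            over = max(r - hi_v, lo_v - r)
            if over > threshold:
                out.append((tuple(arr[0]), float(over)))
        return out

    def masses(self, min_mass: float = 12.0) -> np.ndarray:
        """Atomic masses, floored (hydrogen mass repartitioning) for a 2 fs step."""
        from .templates import ELEMENT_MASS

        m = np.array([ELEMENT_MASS[e] for e in self.model.elements])
        return np.maximum(m, min_mass)
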