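"""Residue template library for deoxyribonucleotides.

Templates carry ideal coordinates, connectivity and derived internal
coordinates (bond lengths, angles, impropers, chiral volumes) for
A/C/G/T/U/I 2'-deoxyribonucleotides.  Ideal geometry comes from the
Chemical Component Dictionary shipped with biotite, normalised here to
in-chain polymer form (no 3'-phosphate cap, 5'-phosphate optional).

Atom names follow PDB v3 nucleic-acid conventions with ASCII primes
(O4', H1', H2'', ...).  Residue positions are 1-based everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import torsion

#: one-letter code -> CCD component id
CCD_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU", "I": "DI"}

PURINES = {"A", "G", "I"}
PYRIMIDINES = {"C", "T", "U"}

#: exchangeable (imino/amino/hydroxyl) proton names
EXCHANGEABLE_H = {
    "H1", "H3", "H21", "H22", "H41", "H42", "H61", "H62", "HO3'", "HO5'",
}

#: atoms removed to obtain the in-chain residue (CCD components are free
#: nucleotides with a 3'-OH proton and a triprotic 5'-phosphate)
_STRIP_INTERNAL = {"OP3", "HOP3", "HOP2", "HO5'", "HO3'"}
#: additionally removed at a phosphate-free 5' terminus
_STRIP_5P = {"P", "OP1", "OP2"}

ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}
VDW_RADIUS = {"H": 1.1, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8}


@dataclass
class ResidueTemplate:
    """Ideal-geometry template for one residue type.

    ``bonds`` are index pairs into ``atom_names``; ``angles`` are (i, j, k)
    triples centred on j; ``impropers`` are (i, j, k, l) quadruples around a
    trivalent centre j; ``chiral_centers`` store (center, n1, n2, n3, sign)
    where sign is the sign of the signed volume det[r_n1-r_c, r_n2-r_c,
    r_n3-r_c] in the ideal geometry.
    """

    code: str
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    base_atoms: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = {n: i for i, n in enumerate(self.atom_names)}
        adj = [[] for _ in self.atom_names]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        self.adjacency = [sorted(a) for a in adj]
        self.angles = []
        for j, nbrs in enumerate(self.adjacency):
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    self.angles.append((nbrs[a], j, nbrs[b]))
        self.impropers = []
        for j, nbrs in enumerate(self.adjacency):
            if len(nbrs) == 3 and self.elements[j] != "P":
                self.impropers.append((nbrs[0], j, nbrs[1], nbrs[2]))
        self.chiral_centers = []
        for j, nbrs in enumerate(self.adjacency):
            if self.elements[j] != "C":
                continue
            heavy = [n for n in nbrs if self.elements[n] != "H"]
            hyd = [n for n in nbrs if self.elements[n] == "H"]
            if len(heavy) >= 3:
                trip = heavy[:3]
            elif len(heavy) == 2 and len(hyd) == 2:
                # prochiral CH2: fix which named proton sits on which face
                trip = [heavy[0], heavy[1], hyd[0]]
            else:
                continue
            v = np.linalg.det(
                np.stack([self.coords[k] - self.coords[j] for k in trip])
            )
            if abs(v) > 0.1:
                self.chiral_centers.append(
                    (j, *trip, float(np.sign(v)), float(abs(v)))
                )
        # furanose ring torsions (fix the sugar pucker)
        ring = ["C1'", "C2'", "C3'", "C4'", "O4'"]
        self.ring_torsions = []
        if all(n in self._index for n in ring):
            idx = [self._index[n] for n in ring]
            from .geometry import torsion as _torsion

            for k in range(5):
                quad = (idx[k], idx[(k + 1) % 5], idx[(k + 2) % 5], idx[(k + 3) % 5])
                self.ring_torsions.append(
                    (quad, _torsion(*(self.coords[q] for q in quad)))
                )

    # -- lookups ---------------------------------------------------------
    def index(self, atom_name: str) -> int:
        try:
            return self._index[atom_name]
        except KeyError:
            raise KeyError(
                f"atom {atom_name!r} not in template for residue {self.code}"
            ) from None

    def has_atom(self, atom_name: str) -> bool:
        return atom_name in self._index

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASS[e] for e in self.elements])

    def bond_length(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    @property
    def glycosidic_atoms(self) -> tuple[str, str, str, str]:
        """chi torsion atoms: O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)."""
        if self.code in PURINES:
            return ("O4'", "C1'", "N9", "C4")
        return ("O4'", "C1'", "N1", "C2")

    @property
    def glycosidic_nitrogen(self) -> str:
        return "N9" if self.code in PURINES else "N1"

    def chi(self) -> float:
        a = [self.coords[self.index(n)] for n in self.glycosidic_atoms]
        return torsion(*a)

    def with_chi(self, chi_deg: float) -> np.ndarray:
        """Template coordinates with the glycosidic torsion set to ``chi_deg``.

        The base is kept fixed; sugar and backbone rotate about the
        glycosidic bond.
        """
        o4, c1, n_g, c_ref = self.glycosidic_atoms
        delta = chi_deg - self.chi()
        from .geometry import rotation_about_axis

        pivot = self.coords[self.index(n_g)]
        axis = self.coords[self.index(c1)] - pivot
        # rotating the sugar side by +delta about N->C1' increases chi by delta
        R = rotation_about_axis(axis, delta)
        out = self.coords.copy()
        base = {self.index(n) for n in self.base_atoms}
        for i in range(self.n_atoms):
            if i not in base:
                out[i] = (out[i] - pivot) @ R.T + pivot
        return out


def _base_atom_names(atom_names, elements):
    sugar_or_backbone = set()
    for n, e in zip(atom_names, elements):
        if "'" in n or n in ("P", "OP1", "OP2", "OP3", "HOP2", "HOP3"):
            sugar_or_backbone.add(n)
    return [n for n in atom_names if n not in sugar_or_backbone]


@lru_cache(maxsize=None)
def get_template(code: str, five_prime: bool = False) -> ResidueTemplate:
    """Template for residue ``code`` in {A,C,G,T,U,I}.

    ``five_prime=True`` yields the phosphate-free 5'-terminal form.
    Terminal hydroxyl protons are not modelled.
    """
    code = code.upper()
    if code not in CCD_NAME:
        raise KeyError(f"unknown residue code {code!r} (expected one of {sorted(CCD_NAME)})")
    import biotite.structure.info as info

    arr = info.residue(CCD_NAME[code])
    names = [str(n) for n in arr.atom_name]
    strip = set(_STRIP_INTERNAL)
    if five_prime:
        strip |= _STRIP_5P
        strip.discard("HO5'")
    keep = [i for i, n in enumerate(names) if n not in strip]
    kept_names = [names[i] for i in keep]
    remap = {i: k for k, i in enumerate(keep)}
    elements = [str(arr.element[i]).capitalize() for i in keep]
    coords = np.asarray(arr.coord[keep], dtype=float)
    bonds = []
    for i, j, _ in arr.bonds.as_array():
        if i in remap and j in remap:
            bonds.append((remap[i], remap[j]))
    _normalise_amino_names(kept_names, coords)
    return ResidueTemplate(
        code=code,
        name=CCD_NAME[code],
        atom_names=kept_names,
        elements=elements,
        coords=coords,
        bonds=bonds,
        base_atoms=_base_atom_names(kept_names, elements),
    )


#: amino proton pairs and the frame (N_amino, C, ring N) fixing their naming:
#: by convention the "1" proton (H21/H41/H61) is cis to the ring nitrogen
_AMINO_FRAMES = {
    "H21": ("H22", "N2", "C2", "N1"),
    "H41": ("H42", "N4", "C4", "N3"),
    "H61": ("H62", "N6", "C6", "N1"),
}


def _normalise_amino_names(names: list[str], coords: np.ndarray) -> None:
    """Swap amino proton names in place where the source geometry has the
    trans proton labelled as the cis one."""
    from .geometry import torsion as _torsion

    index = {n: i for i, n in enumerate(names)}
    for h1, (h2, n_am, c, n_ring) in _AMINO_FRAMES.items():
        if h1 not in index or h2 not in index:
            continue
        d = _torsion(
            coords[index[h1]], coords[index[n_am]], coords[index[c]], coords[index[n_ring]]
        )
        if 90.0 < d < 270.0:  # labelled proton is trans: swap
            i, j = index[h1], index[h2]
            names[i], names[j] = h2, h1


def is_exchangeable(atom_name: str) -> bool:
    return atom_name in EXCHANGEABLE_H


#: O3'(n) - P(n+1) backbone linkage ideal length (Angstrom)
LINK_O3_P = 1.607
#: ideal angles across the phosphodiester linkage, degrees
LINK_ANGLES = {("C3'", "O3'", "P"): 119.7, ("O3'", "P", "O5'"): 104.0,
               ("O3'", "P", "OP1"): 108.1, ("O3'", "P", "OP2"): 108.1}
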