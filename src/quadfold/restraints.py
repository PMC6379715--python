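"""Compilation of the complete NMR restraint system for a quadruplex fold.

Five restraint families drive the structure calculation:

* NOE distance restraints from classified cross-peaks.  Non-exchangeable
  protons: strong (2.7 +/- 0.8), medium (3.8 +/- 0.9), weak (5.5 +/- 1.7) A;
  exchangeable protons: strong (3.6 +/- 0.9), medium (4.8 +/- 1.2),
  weak (5.5 +/- 1.7) A.
* Hoogsteen hydrogen-bond restraints, four per directed tetrad edge:
  H21-N7 and H1-O6 at (2.0 +/- 0.2) A, N2-N7 and N1-O6 at (2.9 +/- 0.3) A;
  capping pairs contribute their declared donor/acceptor distances, and an
  ambiguously assigned donor contributes a single restraint with OR
  semantics over its acceptor alternatives.
* Glycosidic dihedral restraints: chi (O4'-C1'-N9-C4) held at 60 deg (syn)
  or 240 deg (anti), halfwidth 70 deg for outer-tetrad and 40 deg for
  inner-tetrad guanines.
* Planarity restraints, one group per tetrad layer plus one per planar
  capping pair.
* Repulsion restraints: lower-bound-only (> 3.5 A) separations encoding
  the absence of expected cross-peaks.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

from .templates import get_template, is_exchangeable
from .topology import AtomRef, QuadruplexTopology

NOE_CLASSES = ("strong", "medium", "weak")


@dataclass(frozen=True)
class RestraintParameters:
    """Distance/dihedral calibration constants for restraint compilation."""

    noe_classes_nonexch: dict = field(
        default_factory=lambda: {
            "strong": (2.7, 0.8, 0.8),
            "medium": (3.8, 0.9, 0.9),
            "weak": (5.5, 1.7, 1.7),
        }
    )
    noe_classes_exch: dict = field(
        default_factory=lambda: {
            "strong": (3.6, 0.9, 0.9),
            "medium": (4.8, 1.2, 1.2),
            "weak": (5.5, 1.7, 1.7),
        }
    )
    hbond_short: tuple = (2.0, 0.2, 0.2)
    hbond_long: tuple = (2.9, 0.3, 0.3)
    chi_center: dict = field(default_factory=lambda: {"syn": 60.0, "anti": 240.0})
    chi_width_outer: float = 70.0
    chi_width_inner: float = 40.0
    chi_force_constant: float = 50.0      # kcal/mol/rad^2
    planarity_weight: float = 1.0         # kcal/mol/A^2
    repulsion_min: float = 3.5

    def __post_init__(self):
        for table in (self.noe_classes_nonexch, self.noe_classes_exch):
            for cls, (t, minus, plus) in table.items():
                if not (t > 0 and 0 < minus <= t and plus > 0):
                    raise ValueError(f"invalid NOE class bounds {cls}: {(t, minus, plus)}")
        for w in (self.chi_width_outer, self.chi_width_inner):
            if not 0 < w < 180:
                raise ValueError("chi halfwidths must lie in (0, 180)")

    def noe_bounds(self, cls: str, exchangeable: bool):
        table = self.noe_classes_exch if exchangeable else self.noe_classes_nonexch
        if cls not in table:
            raise ValueError(f"unknown NOE intensity class {cls!r}")
        t, minus, plus = table[cls]
        return t, t - minus, t + plus


@dataclass(frozen=True, order=True)
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    category: str                       # noe | hbond | repulsion
    target: float | None = None
    lower: float | None = None
    upper: float | None = None
    exchangeable: bool = False
    ambiguity_group: str | None = None

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError(f"restraint references a single atom {self.atom_a}")
        if self.category == "repulsion":
            if self.lower is None or self.upper is not None or self.target is not None:
                raise ValueError("repulsion restraints are lower-bound-only")
        else:
            if not (self.lower <= self.target <= self.upper):
                raise ValueError(
                    f"bounds must bracket target: {self.lower}, {self.target}, {self.upper}"
                )


@dataclass(frozen=True)
class DihedralRestraint:
    atoms: tuple[AtomRef, AtomRef, AtomRef, AtomRef]
    center: float
    halfwidth: float
    force_constant: float = 50.0

    def __post_init__(self):
        object.__setattr__(self, "center", self.center % 360.0)


@dataclass(frozen=True)
class PlanarityGroup:
    name: str
    atoms: tuple[AtomRef, ...]
    weight: float = 1.0

    def __post_init__(self):
        if len(self.atoms) < 3:
            raise ValueError("planarity group needs at least 3 atoms")


def _pair_key(a: AtomRef, b: AtomRef):
    return (a, b) if a <= b else (b, a)


def _check_atom(top: QuadruplexTopology, ref: AtomRef):
    pos, name = ref
    code = top.sequence[pos]
    tmpl = get_template(code, five_prime=(pos == 1))
    if not tmpl.has_atom(name):
        raise KeyError(f"residue {pos} ({code}) has no atom {name!r} in its template")


# ---------------------------------------------------------------------------
# compilers
# ---------------------------------------------------------------------------

def compile_hbond_restraints(
    top: QuadruplexTopology, params: RestraintParameters = RestraintParameters()
) -> list[DistanceRestraint]:
    """Hydrogen-bond distance restraints for tetrads and capping elements."""
    out: list[DistanceRestraint] = []
    for quartet in top.tetrads:
        for k, donor in enumerate(quartet):
            acceptor = quartet[(k + 1) % 4]
            for datom, aatom, (t, minus, plus) in (
                ("H21", "N7", params.hbond_short),
                ("N2", "N7", params.hbond_long),
                ("H1", "O6", params.hbond_short),
                ("N1", "O6", params.hbond_long),
            ):
                a, b = (donor, datom), (acceptor, aatom)
                _check_atom(top, a), _check_atom(top, b)
                out.append(
                    DistanceRestraint(
                        atom_a=a, atom_b=b, category="hbond",
                        target=t, lower=t - minus, upper=t + plus,
                    )
                )
    for ci, cap in enumerate(top.capping):
        if cap.mode == "ambiguous":
            donor = cap.bonds[0].donor
            t, minus, plus = (
                params.hbond_short if donor[1].startswith("H") else params.hbond_long
            )
            group = f"cap{ci}_{donor[0]}{donor[1]}"
            for alt in cap.alternatives:
                _check_atom(top, donor), _check_atom(top, alt)
                out.append(
                    DistanceRestraint(
                        atom_a=donor, atom_b=alt, category="hbond",
                        target=t, lower=t - minus, upper=t + plus,
                        ambiguity_group=group,
                    )
                )
        else:
            for hb in cap.bonds:
                t, minus, plus = (
                    params.hbond_short if hb.donor[1].startswith("H") else params.hbond_long
                )
                _check_atom(top, hb.donor), _check_atom(top, hb.acceptor)
                out.append(
                    DistanceRestraint(
                        atom_a=hb.donor, atom_b=hb.acceptor, category="hbond",
                        target=t, lower=t - minus, upper=t + plus,
                    )
                )
    return out


def compile_dihedral_restraints(
    top: QuadruplexTopology, params: RestraintParameters = RestraintParameters()
) -> list[DihedralRestraint]:
    """One glycosidic chi restraint per tetrad guanine and capping guanine."""
    out: list[DihedralRestraint] = []
    layer_class = top.layer_class
    targets = [(p, layer_class[p]) for p in top.tetrad_positions]
    targets += [(p, "outer") for p in sorted(top.capping_guanines())]
    for pos, cls in targets:
        state = top.glycosidic.get(pos)
        if state is None:
            raise ValueError(f"guanine {pos} lacks a glycosidic state")
        width = params.chi_width_outer if cls == "outer" else params.chi_width_inner
        atoms = tuple((pos, n) for n in ("O4'", "C1'", "N9", "C4"))
        for a in atoms:
            _check_atom(top, a)
        out.append(
            DihedralRestraint(
                atoms=atoms,
                center=params.chi_center[state],
                halfwidth=width,
                force_constant=params.chi_force_constant,
            )
        )
    return out


def noe_peaks_to_restraints(
    peaks, params: RestraintParameters = RestraintParameters()
) -> list[DistanceRestraint]:
    """Convert classified NOE peaks to flat-bottom distance restraints.

    Duplicate observations of one proton pair (e.g. across mixing times)
    collapse to the tightest class (smallest target distance).
    """
    best: dict[tuple, DistanceRestraint] = {}
    for pk in peaks:
        t, lo, hi = params.noe_bounds(pk.intensity_class, pk.exchangeable)
        a, b = _pair_key(pk.proton_a, pk.proton_b)
        r = DistanceRestraint(
            atom_a=a, atom_b=b, category="noe",
            target=t, lower=lo, upper=hi, exchangeable=pk.exchangeable,
        )
        prev = best.get((a, b))
        if prev is None or r.target < prev.target:
            best[(a, b)] = r
    return sorted(best.values())


def compile_repulsion(
    absent_contacts, params: RestraintParameters = RestraintParameters()
) -> list[DistanceRestraint]:
    """Lower-bound-only restraints for proton pairs with no cross-peak."""
    seen = set()
    out = []
    for a, b in absent_contacts:
        key = _pair_key(tuple(a), tuple(b))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            DistanceRestraint(
                atom_a=key[0], atom_b=key[1], category="repulsion",
                lower=params.repulsion_min,
            )
        )
    return sorted(out)


def compile_planarity(
    top: QuadruplexTopology, params: RestraintParameters = RestraintParameters()
) -> list[PlanarityGroup]:
    """One group per tetrad layer plus one per planar capping pair."""
    groups = []
    for li, quartet in enumerate(top.tetrads):
        atoms = []
        for pos in quartet:
            tmpl = get_template(top.sequence[pos])
            atoms.extend(
                (pos, n)
                for n, e in zip(tmpl.atom_names, tmpl.elements)
                if n in tmpl.base_atoms and e != "H"
            )
        groups.append(
            PlanarityGroup(
                name="tetrad_" + "-".join(f"G{p}" for p in quartet),
                atoms=tuple(atoms),
                weight=params.planarity_weight,
            )
        )
    for cap in top.capping:
        if not cap.planar:
            continue
        atoms = []
        for pos in cap.partners:
            tmpl = get_template(top.sequence[pos])
            atoms.extend(
                (pos, n)
                for n, e in zip(tmpl.atom_names, tmpl.elements)
                if n in tmpl.base_atoms and e != "H"
            )
        label = "-".join(f"{top.sequence[p]}{p}" for p in cap.partners)
        groups.append(
            PlanarityGroup(name=f"pair_{label}", atoms=tuple(atoms),
                           weight=params.planarity_weight)
        )
    return groups


# ---------------------------------------------------------------------------
# the assembled set
# ---------------------------------------------------------------------------

@dataclass
class RestraintSet:
    distance: list[DistanceRestraint] = field(default_factory=list)   # noe + hbond
    dihedral: list[DihedralRestraint] = field(default_factory=list)
    planarity: list[PlanarityGroup] = field(default_factory=list)
    repulsion: list[DistanceRestraint] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in list(self.distance) + list(self.repulsion):
            key = (_pair_key(r.atom_a, r.atom_b), r.category)
            if key in seen:
                raise ValueError(f"duplicate restraint {key}")
            seen.add(key)

    # -- counts ---------------------------------------------------------
    @property
    def noe(self) -> list[DistanceRestraint]:
        return [r for r in self.distance if r.category == "noe"]

    @property
    def hbond(self) -> list[DistanceRestraint]:
        return [r for r in self.distance if r.category == "hbond"]

    def counts(self) -> dict:
        """Restraint tallies in the layout of an NMR-restraints table."""
        noe = self.noe
        def tally(intra: bool, exch: bool) -> int:
            return sum(
                1
                for r in noe
                if (r.atom_a[0] == r.atom_b[0]) == intra and r.exchangeable == exch
            )
        hb = self.hbond
        groups = {r.ambiguity_group for r in hb if r.ambiguity_group}
        hbond_count = sum(1 for r in hb if r.ambiguity_group is None) + len(groups)
        return {
            "noe_intra_exchangeable": tally(True, True),
            "noe_intra_nonexchangeable": tally(True, False),
            "noe_inter_exchangeable": tally(False, True),
            "noe_inter_nonexchangeable": tally(False, False),
            "hbond": hbond_count,
            "dihedral": len(self.dihedral),
            "planarity": len(self.planarity),
            "repulsion": len(self.repulsion),
        }

    def all_distance_like(self) -> list[DistanceRestraint]:
        return list(self.distance) + list(self.repulsion)

    # -- serialization --------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["category\tres_a\tatom_a\tres_b\tatom_b\ttarget\tlower\tupper\texch\tgroup"]
        def fmt(x):
            return "" if x is None else repr(float(x))
        for r in self.all_distance_like():
            lines.append(
                "\t".join(
                    [
                        r.category,
                        str(r.atom_a[0]), r.atom_a[1],
                        str(r.atom_b[0]), r.atom_b[1],
                        fmt(r.target), fmt(r.lower), fmt(r.upper),
                        "1" if r.exchangeable else "0",
                        r.ambiguity_group or "",
                    ]
                )
            )
        for d in self.dihedral:
            sel = ";".join(f"{p}:{n}" for p, n in d.atoms)
            lines.append(
                f"dihedral\t{sel}\t\t\t\t{d.center:g}\t{d.halfwidth:g}\t{d.force_constant:g}\t\t"
            )
        for g in self.planarity:
            sel = ";".join(f"{p}:{n}" for p, n in g.atoms)
            lines.append(f"planarity\t{g.name}\t{sel}\t\t\t{g.weight:g}\t\t\t\t")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "RestraintSet":
        distance, repulsion, dihedral, planarity = [], [], [], []
        lines = text.strip().splitlines()[1:]
        for ln in lines:
            f = ln.split("\t")
            cat = f[0]
            if cat in ("noe", "hbond"):
                distance.append(
                    DistanceRestraint(
                        atom_a=(int(f[1]), f[2]), atom_b=(int(f[3]), f[4]),
                        category=cat,
                        target=float(f[5]), lower=float(f[6]), upper=float(f[7]),
                        exchangeable=f[8] == "1",
                        ambiguity_group=f[9] or None,
                    )
                )
            elif cat == "repulsion":
                repulsion.append(
                    DistanceRestraint(
                        atom_a=(int(f[1]), f[2]), atom_b=(int(f[3]), f[4]),
                        category=cat, lower=float(f[6]),
                    )
                )
            elif cat == "dihedral":
                atoms = tuple(
                    (int(p), n) for p, n in (t.split(":") for t in f[1].split(";"))
                )
                dihedral.append(
                    DihedralRestraint(
                        atoms=atoms, center=float(f[5]), halfwidth=float(f[6]),
                        force_constant=float(f[7]),
                    )
                )
            elif cat == "planarity":
                atoms = tuple(
                    (int(p), n) for p, n in (t.split(":") for t in f[2].split(";"))
                )
                planarity.append(PlanarityGroup(name=f[1], atoms=atoms, weight=float(f[5])))
            else:
                raise ValueError(f"unknown restraint category {cat!r}")
        return cls(distance=distance, dihedral=dihedral, planarity=planarity,
                   repulsion=repulsion)

    def to_xplor(self) -> str:
        """Distance restraints in a CNS/XPLOR-style assign dialect."""
        lines = []
        for r in self.distance:
            d, dm, dp = r.target, r.target - r.lower, r.upper - r.target
            lines.append(
                f"assign (resid {r.atom_a[0]} and name {r.atom_a[1]}) "
                f"(resid {r.atom_b[0]} and name {r.atom_b[1]}) "
                f"{d:.2f} {dm:.2f} {dp:.2f}"
                + (f" ! or-group {r.ambiguity_group}" if r.ambiguity_group else "")
            )
        for r in self.repulsion:
            lines.append(
                f"assign (resid {r.atom_a[0]} and name {r.atom_a[1]}) "
                f"(resid {r.atom_b[0]} and name {r.atom_b[1]}) "
                f"{r.lower:.2f} 0.00 999.00 ! repulsion (lower bound only)"
            )
        return "\n".join(lines) + "\n"


def assemble(
    top: QuadruplexTopology,
    peaks=(),
    absent_contacts=(),
    params: RestraintParameters = RestraintParameters(),
) -> RestraintSet:
    """Compile the full restraint system for a topology plus peak list."""
    noe = noe_peaks_to_restraints(peaks, params) if peaks else []
    hbond = compile_hbond_restraints(top, params)
    # an observed NOE between atoms also restrained as an H-bond keeps both
    # entries in their own categories; drop NOE duplicates of H-bond pairs
    hb_pairs = {_pair_key(r.atom_a, r.atom_b) for r in hbond}
    noe = [r for r in noe if _pair_key(r.atom_a, r.atom_b) not in hb_pairs]
    rs = RestraintSet(
        distance=sorted(noe) + sorted(hbond),
        dihedral=compile_dihedral_restraints(top, params),
        planarity=compile_planarity(top, params),
        repulsion=compile_repulsion(absent_contacts, params),
        provenance=[f"topology {top.sequence.id}", f"{len(peaks)} peaks"],
    )
    return rs


#: the two proton pairs whose cross-peaks are absent in the TP3-T6 spectra
TP3_T6_ABSENT_CONTACTS = (
    ((20, "H71"), (14, "H1")),
    ((20, "H71"), (2, "H1")),
)
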