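"""Declarative G-quadruplex fold topology.

A :class:`QuadruplexTopology` captures everything the restraint compiler and
the ideal-structure generator need: stacked tetrad layers given as ordered
quartets (the list order is the hydrogen-bond donor->acceptor cycle),
glycosidic states, strand orientations, loop types, groove labels, bulges
and capping pairs/triples with explicit donor/acceptor atoms.

Conventions
-----------
* layers are listed top to bottom; layer 0 and the last layer are "outer",
  the rest "inner";
* within a quartet, member ``k`` donates its Hoogsteen hydrogen bonds
  (N1-H1...O6, N2-H21...N7) to member ``k+1`` (cyclically);
* strand orientations are labels relative to the first strand, which is
  always called "up".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .sequences import Sequence

GROOVE_LABELS = ("wide", "medium", "narrow")
LOOP_TYPES = ("edgewise", "propeller", "diagonal")
BOND_MODES = ("hoogsteen", "reverse_hoogsteen", "watson_crick", "ambiguous")

AtomRef = tuple[int, str]  # (1-based residue position, atom name)


class TopologyError(ValueError):
    """Raised when a fold description violates a structural invariant."""


@dataclass(frozen=True)
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef


@dataclass(frozen=True)
class CappingElement:
    """A declared base pair (or the pairwise part of a triple).

    ``bonds`` are explicit donor->acceptor atom pairs.  For
    ``mode="ambiguous"`` a single donor is assigned towards any of
    ``alternatives`` (OR semantics).
    """

    partners: tuple[int, ...]
    mode: str
    bonds: tuple[HydrogenBond, ...] = ()
    alternatives: tuple[AtomRef, ...] = ()
    planar: bool = False
    stack: str = "top"

    def __post_init__(self):
        if self.mode not in BOND_MODES:
            raise TopologyError(f"unknown bonding mode {self.mode!r}")
        if self.mode == "ambiguous" and len(self.bonds) != 1:
            raise TopologyError("ambiguous capping element needs exactly one donor bond")


@dataclass
class QuadruplexTopology:
    sequence: Sequence
    tetrads: list[tuple[int, int, int, int]]
    glycosidic: dict[int, str]                      # position -> syn|anti
    strands: list[tuple[tuple[int, int], str]]      # ((start, end), up|down)
    loops: list[tuple[tuple[int, int], str]]        # ((start, end), type)
    grooves: list[tuple[int, int, str]] = field(default_factory=list)
    bulges: list[int] = field(default_factory=list)
    capping: list[CappingElement] = field(default_factory=list)

    # ---- derived ------------------------------------------------------
    @property
    def tetrad_positions(self) -> list[int]:
        return sorted(p for q in self.tetrads for p in q)

    @property
    def layer_class(self) -> dict[int, str]:
        out: dict[int, str] = {}
        last = len(self.tetrads) - 1
        for li, quartet in enumerate(self.tetrads):
            cls = "outer" if li in (0, last) else "inner"
            for p in quartet:
                out[p] = cls
        return out

    @property
    def n_tetrads(self) -> int:
        return len(self.tetrads)

    def strand_of(self, pos: int) -> int:
        for i, ((s, e), _) in enumerate(self.strands):
            if s <= pos <= e:
                return i
        raise TopologyError(f"position {pos} not on any strand")

    def capping_guanines(self) -> dict[int, str]:
        """Glycosidic states declared for non-tetrad guanines in capping elements."""
        tet = set(self.tetrad_positions)
        out = {}
        for cap in self.capping:
            for p in cap.partners:
                if p not in tet and self.sequence[p] == "G" and p in self.glycosidic:
                    out[p] = self.glycosidic[p]
        return out

    # ---- serialization (quadfold-topology v1) -------------------------
    def to_text(self) -> str:
        lines = ["quadfold-topology v1"]
        lines.append(f"sequence {self.sequence.id} {self.sequence.residues}")
        for q in self.tetrads:
            lines.append("tetrad " + " ".join(str(p) for p in q))
        syn = sorted(p for p, s in self.glycosidic.items() if s == "syn")
        anti = sorted(p for p, s in self.glycosidic.items() if s == "anti")
        if syn:
            lines.append("syn " + " ".join(map(str, syn)))
        if anti:
            lines.append("anti " + " ".join(map(str, anti)))
        for (s, e), o in self.strands:
            lines.append(f"strand {s}-{e} {o}")
        for (s, e), t in self.loops:
            lines.append(f"loop {s}-{e} {t}")
        for a, b, g in self.grooves:
            lines.append(f"groove {a} {b} {g}")
        for b in self.bulges:
            lines.append(f"bulge {b}")
        for cap in self.capping:
            parts = [
                "capping",
                cap.mode,
                "partners=" + ",".join(map(str, cap.partners)),
            ]
            if cap.bonds:
                parts.append(
                    "bonds="
                    + ";".join(
                        f"{d[0]}:{d[1]}>{a[0]}:{a[1]}" for d, a in
                        ((hb.donor, hb.acceptor) for hb in cap.bonds)
                    )
                )
            if cap.alternatives:
                parts.append(
                    "alternatives=" + ";".join(f"{p}:{a}" for p, a in cap.alternatives)
                )
            if cap.planar:
                parts.append("planar")
            if cap.stack != "top":
                parts.append(f"stack={cap.stack}")
            lines.append(" ".join(parts))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "QuadruplexTopology":
        return build_topology(parse_topology_text(text))


def parse_topology_text(text: str) -> dict:
    """Parse the flat quadfold-topology v1 dialect into a spec dict."""
    spec: dict = {"tetrads": [], "syn": [], "anti": [], "strands": [], "loops": [],
                  "grooves": [], "bulges": [], "capping": []}
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].startswith("quadfold-topology"):
        raise TopologyError("missing 'quadfold-topology v1' header")
    if lines[0].split()[1] != "v1":
        raise TopologyError(f"unsupported topology format version in {lines[0]!r}")
    for ln in lines[1:]:
        tok = ln.split()
        key = tok[0]
        if key == "sequence":
            spec["sequence_id"], spec["residues"] = tok[1], tok[2]
        elif key == "tetrad":
            spec["tetrads"].append(tuple(int(t) for t in tok[1:5]))
        elif key in ("syn", "anti"):
            spec[key].extend(int(t) for t in tok[1:])
        elif key == "strand":
            s, e = tok[1].split("-")
            spec["strands"].append(((int(s), int(e)), tok[2]))
        elif key == "loop":
            s, e = tok[1].split("-")
            spec["loops"].append(((int(s), int(e)), tok[2]))
        elif key == "groove":
            spec["grooves"].append((int(tok[1]), int(tok[2]), tok[3]))
        elif key == "bulge":
            spec["bulges"].extend(int(t) for t in tok[1:])
        elif key == "capping":
            entry: dict = {"mode": tok[1], "planar": False, "stack": "top"}
            for t in tok[2:]:
                if t == "planar":
                    entry["planar"] = True
                elif t.startswith("partners="):
                    entry["partners"] = tuple(int(x) for x in t[9:].split(","))
                elif t.startswith("bonds="):
                    bonds = []
                    for b in t[6:].split(";"):
                        d, a = b.split(">")
                        dp, dn = d.split(":")
                        ap, an = a.split(":")
                        bonds.append(((int(dp), dn), (int(ap), an)))
                    entry["bonds"] = bonds
                elif t.startswith("alternatives="):
                    alts = []
                    for b in t[13:].split(";"):
                        p, a = b.split(":")
                        alts.append((int(p), a))
                    entry["alternatives"] = alts
                elif t.startswith("stack="):
                    entry["stack"] = t[6:]
            spec["capping"].append(entry)
        else:
            raise TopologyError(f"unknown topology line {ln!r}")
    return spec


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------

def _derive_strands(seq: Sequence, tetrad_positions: list[int], bulges: list[int]):
    """Group tetrad guanines into 4 strands (contiguous runs, bulges allowed)."""
    members = sorted(set(tetrad_positions))
    allowed = set(members) | set(bulges)
    runs: list[list[int]] = []
    for p in members:
        if runs and all(q in allowed for q in range(runs[-1][-1] + 1, p + 1)):
            runs[-1].append(p)
        else:
            runs.append([p])
    return [(r[0], r[-1]) for r in runs]


def _corner_and_sense(tetrads, strand_index: dict[int, int]):
    """Corner (0-3) of each strand and per-layer cycle sense.

    The reference layer-0 quartet order defines the corners; every other
    layer must visit the four corners in a consistent rotational order,
    with sense +1 (same as layer 0) or -1 (reversed).
    """
    corners = {strand_index[p]: k for k, p in enumerate(tetrads[0])}
    if len(corners) != 4:
        raise TopologyError("layer 0 quartet does not involve four distinct strands")
    senses = [1]
    for li, quartet in enumerate(tetrads[1:], start=1):
        cs = [corners[strand_index[p]] for p in quartet]
        diffs = {(cs[(k + 1) % 4] - cs[k]) % 4 for k in range(4)}
        if diffs == {1}:
            senses.append(1)
        elif diffs == {3}:
            senses.append(-1)
        else:
            raise TopologyError(
                f"layer {li} quartet {quartet} is not a rotation of the strand corners"
            )
    return corners, senses


def _derive_orientations(tetrads, glycosidic, strand_spans, strand_index):
    """Strand orientations implied by a consistent Hoogsteen cycle.

    With the donor->acceptor sense of each layer fixed by the quartet
    orders, a guanine's base normal follows from its layer's sense and the
    strand polarity follows from (normal, glycosidic state).  Orientations
    are normalised so strand 0 is "up".
    """
    corners, senses = _corner_and_sense(tetrads, strand_index)
    orient: dict[int, set[str]] = {i: set() for i in range(len(strand_spans))}
    for li, quartet in enumerate(tetrads):
        for p in quartet:
            state = glycosidic.get(p)
            if state is None:
                raise TopologyError(f"tetrad guanine {p} lacks a glycosidic state")
            # normal sign n = sense; residue is 'up' iff (anti and n=+1) or (syn and n=-1)
            up = (state == "anti") == (senses[li] == 1)
            orient[strand_index[p]].add("up" if up else "down")
    labels = []
    for i in range(len(strand_spans)):
        if len(orient[i]) != 1:
            raise TopologyError(
                f"strand {i} has inconsistent orientation across layers: {orient[i]}"
            )
        labels.append(orient[i].pop())
    if labels[0] == "down":  # global mirror: normalise first strand to 'up'
        labels = ["up" if l == "down" else "down" for l in labels]
    return labels, corners, senses


def expected_grooves(top: QuadruplexTopology) -> list[tuple[int, int, str]]:
    """Groove labels for the four adjacent strand pairs.

    Parallel neighbours flank a medium groove.  For antiparallel
    neighbours the donor->acceptor direction of the top tetrad
    disambiguates: the groove crossed by a *syn* top-tetrad donor is
    narrow, that crossed by an *anti* donor is wide.
    """
    if len(top.strands) != 4:
        raise TopologyError("groove typing needs exactly 4 strands")
    strand_index = {p: top.strand_of(p) for p in top.tetrad_positions}
    corners, _ = _corner_and_sense(top.tetrads, strand_index)
    by_corner = {c: s for s, c in corners.items()}
    first = top.strand_of(min(top.tetrad_positions))
    order = [(corners[first] + k) % 4 for k in range(4)]
    orientations = {i: o for i, (_, o) in enumerate(top.strands)}
    top_layer = top.tetrads[0]
    donor_of_pair: dict[frozenset, int] = {}
    for k, p in enumerate(top_layer):
        q = top_layer[(k + 1) % 4]
        donor_of_pair[frozenset((strand_index[p], strand_index[q]))] = p
    out = []
    for k in range(4):
        a, b = by_corner[order[k]], by_corner[order[(k + 1) % 4]]
        if orientations[a] == orientations[b]:
            label = "medium"
        else:
            donor = donor_of_pair[frozenset((a, b))]
            label = "narrow" if top.glycosidic[donor] == "syn" else "wide"
        out.append((a, b, label))
    return out


def build_topology(spec: dict) -> QuadruplexTopology:
    """Validated constructor from a flat spec dict (see parse_topology_text).

    Derives strands (and their orientations), groove labels and loop spans
    whenever they are omitted.
    """
    seq = Sequence(spec.get("sequence_id", "seq"), spec["residues"])
    tetrads = [tuple(q) for q in spec["tetrads"]]
    offenders = []
    seen: set[int] = set()
    for q in tetrads:
        if len(set(q)) != 4:
            raise TopologyError(f"quartet {q} has repeated positions")
        for p in q:
            if not 1 <= p <= len(seq):
                offenders.append((p, "outside sequence"))
            elif seq[p] != "G":
                offenders.append((p, f"is {seq[p]}, not G"))
            if p in seen:
                offenders.append((p, "appears in more than one layer"))
            seen.add(p)
    if offenders:
        raise TopologyError(f"invalid tetrad members: {offenders}")
    bulges = sorted(spec.get("bulges", []))
    for b in bulges:
        if b in seen:
            raise TopologyError(f"position {b} cannot be both tetrad member and bulge")

    glycosidic = {p: "syn" for p in spec.get("syn", [])}
    glycosidic.update({p: "anti" for p in spec.get("anti", [])})
    for p in sorted(seen):
        glycosidic.setdefault(p, "anti")

    spans = [tuple(s) for s, _ in spec.get("strands", [])] or _derive_strands(
        seq, sorted(seen), bulges
    )
    if len(spans) != 4:
        raise TopologyError(f"expected 4 strands, found {len(spans)}: {spans}")
    strand_index = {}
    for p in sorted(seen):
        for i, (s, e) in enumerate(spans):
            if s <= p <= e:
                strand_index[p] = i
                break
        else:
            raise TopologyError(f"tetrad guanine {p} lies on no strand")

    given_orient = [o for _, o in spec.get("strands", []) if o]
    if given_orient and len(given_orient) == 4:
        orientations = list(given_orient)
        _corner_and_sense(tetrads, strand_index)  # validates layer consistency
    else:
        orientations, _, _ = _derive_orientations(tetrads, glycosidic, spans, strand_index)
    strands = [((s, e), o) for (s, e), o in zip(spans, orientations)]

    # loops: spans between consecutive strands; types follow the geometry
    # (same-orientation neighbours -> propeller, antiparallel neighbours ->
    # edgewise, opposite corners -> diagonal) unless declared
    corners, _ = _corner_and_sense(tetrads, strand_index)
    loop_specs = spec.get("loops", [])
    loops = []
    for i in range(3):
        s = spans[i][1] + 1
        e = spans[i + 1][0] - 1
        declared = [t for (ls, le), t in loop_specs if (ls, le) == (s, e)]
        if loop_specs and not declared:
            raise TopologyError(
                f"loop span {s}-{e} between strands {i} and {i + 1} missing from spec "
                f"(declared: {[sp for sp, _ in loop_specs]})"
            )
        if declared:
            ltype = declared[0]
        elif (corners[i] - corners[i + 1]) % 4 == 2:
            ltype = "diagonal"
        else:
            ltype = "propeller" if orientations[i] == orientations[i + 1] else "edgewise"
        if ltype not in LOOP_TYPES:
            raise TopologyError(f"unknown loop type {ltype!r}")
        if e < s:
            raise TopologyError(f"strands {i} and {i + 1} leave no room for a loop")
        loops.append(((s, e), ltype))

    capping = []
    for entry in spec.get("capping", []):
        capping.append(
            CappingElement(
                partners=tuple(entry["partners"]),
                mode=entry["mode"],
                bonds=tuple(HydrogenBond(tuple(d), tuple(a)) for d, a in entry.get("bonds", [])),
                alternatives=tuple(tuple(a) for a in entry.get("alternatives", [])),
                planar=entry.get("planar", False),
                stack=entry.get("stack", "top"),
            )
        )

    top = QuadruplexTopology(
        sequence=seq,
        tetrads=tetrads,
        glycosidic=glycosidic,
        strands=strands,
        loops=loops,
        bulges=bulges,
        capping=capping,
    )
    top.grooves = [tuple(g) for g in spec.get("grooves", [])] or expected_grooves(top)
    return top
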