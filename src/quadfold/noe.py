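"""Forward NOESY prediction and inversion of peak lists into topologies.

``predict_peaks`` enumerates proton pairs within the weak-class ceiling
and bins them into strong/medium/weak by the midpoints of the restraint
calibration targets.  ``tetrads_from_connectivity`` inverts imino(H1) ->
aromatic(H8) connectivities into cyclic G-tetrad alignments: sequence-
adjacent contacts (trivial stacking) are ignored and, when the peak list
carries imino-imino information, each candidate edge must be corroborated
by an H1-H1 cross-peak, mirroring how tetrad alignments are confirmed
experimentally.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import StructureModel
from .templates import is_exchangeable
from .topology import AtomRef, QuadruplexTopology

#: distance -> class boundaries (Angstrom): midpoints of the calibration targets
BINS_NONEXCH = (3.0, 4.5)
BINS_EXCH = (4.2, 5.15)
DEFAULT_CUTOFF = 5.5


@dataclass(frozen=True)
class NoePeak:
    proton_a: AtomRef
    proton_b: AtomRef
    intensity_class: str
    exchangeable: bool
    mixing_time_ms: float | None = None

    def __post_init__(self):
        if self.proton_a == self.proton_b:
            raise ValueError("peak references a single proton")
        if self.intensity_class not in ("strong", "medium", "weak"):
            raise ValueError(f"unknown intensity class {self.intensity_class!r}")


def classify_distance(d: float, exchangeable: bool) -> str:
    s, m = BINS_EXCH if exchangeable else BINS_NONEXCH
    return "strong" if d < s else ("medium" if d < m else "weak")


#: amino protons: exchange-broadened, excluded from distance calibration
#: (their structural information enters through hydrogen-bond restraints)
AMINO_H = {"H21", "H22", "H41", "H42", "H61", "H62"}


def predict_peaks(
    m: StructureModel, cutoff: float = DEFAULT_CUTOFF, include_amino: bool = False
) -> list[NoePeak]:
    """All proton-pair cross-peaks expected below ``cutoff`` Angstrom.

    Geminal pairs (fixed separation) are never emitted; amino-proton
    peaks are omitted unless ``include_amino`` because their intensities
    do not calibrate reliably to distances.
    """
    from scipy.spatial.distance import cdist

    from .templates import get_template

    hmask = np.array([e == "H" for e in m.elements])
    idx = np.nonzero(hmask)[0]
    coords = m.coords[idx]
    D = cdist(coords, coords)
    # geminal protons (sharing a bonded heavy atom) have fixed separations
    # and are never reported as cross-peaks
    geminal: set[tuple[int, int]] = set()
    first_res = m.residues[0][0]
    for rid, code in m.residues:
        tmpl = get_template(code, five_prime=(rid == first_res))
        for j, nbrs in enumerate(tmpl.adjacency):
            hs = [n for n in nbrs if tmpl.elements[n] == "H"]
            for a_ in range(len(hs)):
                for b_ in range(a_ + 1, len(hs)):
                    geminal.add(
                        (m.index(rid, tmpl.atom_names[hs[a_]]),
                         m.index(rid, tmpl.atom_names[hs[b_]]))
                    )
    peaks = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            d = D[a, b]
            if d >= cutoff:
                continue
            ia, ib = idx[a], idx[b]
            if (ia, ib) in geminal or (ib, ia) in geminal:
                continue
            if not include_amino and (
                str(m.atom_names[ia]) in AMINO_H or str(m.atom_names[ib]) in AMINO_H
            ):
                continue
            ra = (int(m.res_ids[ia]), str(m.atom_names[ia]))
            rb = (int(m.res_ids[ib]), str(m.atom_names[ib]))
            if rb < ra:
                ra, rb = rb, ra
            exch = is_exchangeable(ra[1]) or is_exchangeable(rb[1])
            peaks.append(
                NoePeak(
                    proton_a=ra, proton_b=rb,
                    intensity_class=classify_distance(d, exch),
                    exchangeable=exch,
                )
            )
    return sorted(peaks, key=lambda p: (p.proton_a, p.proton_b))


# ---------------------------------------------------------------------------
# TSV interface (shared with the restraints module)
# ---------------------------------------------------------------------------

def peaks_to_tsv(peaks: list[NoePeak]) -> str:
    lines = ["res_a\tatom_a\tres_b\tatom_b\tclass\texchangeable\tmixing_time_ms"]
    for p in peaks:
        mt = "" if p.mixing_time_ms is None else f"{p.mixing_time_ms:g}"
        lines.append(
            f"{p.proton_a[0]}\t{p.proton_a[1]}\t{p.proton_b[0]}\t{p.proton_b[1]}"
            f"\t{p.intensity_class}\t{int(p.exchangeable)}\t{mt}"
        )
    return "\n".join(lines) + "\n"


def peaks_from_tsv(text: str) -> list[NoePeak]:
    peaks = []
    for ln in text.strip().splitlines()[1:]:
        f = ln.split("\t")
        peaks.append(
            NoePeak(
                proton_a=(int(f[0]), f[1]),
                proton_b=(int(f[2]), f[3]),
                intensity_class=f[4],
                exchangeable=f[5] == "1",
                mixing_time_ms=float(f[6]) if len(f) > 6 and f[6] else None,
            )
        )
    return peaks


def read_peaks(path: str | Path) -> list[NoePeak]:
    return peaks_from_tsv(Path(path).read_text())


def write_peaks(peaks: list[NoePeak], path: str | Path) -> None:
    Path(path).write_text(peaks_to_tsv(peaks))


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

class AmbiguousConnectivityError(ValueError):
    def __init__(self, cycles):
        self.cycles = cycles
        super().__init__(
            f"conflicting tetrad candidates share residues: {cycles}"
        )


def find_disjoint_4cycles(edges) -> list[tuple[int, int, int, int]]:
    """All directed 4-cycles of an edge list, canonically rotated.

    Cycles are returned sorted by smallest member; any two cycles sharing
    a vertex raise :class:`AmbiguousConnectivityError`.
    """
    import networkx as nx

    G = nx.DiGraph()
    G.add_edges_from(edges)
    cycles = set()
    for cyc in nx.simple_cycles(G, length_bound=4):
        if len(cyc) != 4:
            continue
        k = int(np.argmin(cyc))
        cycles.add(tuple(cyc[k:] + cyc[:k]))
    cycles = sorted(cycles)
    used: dict[int, tuple] = {}
    for cyc in cycles:
        for v in cyc:
            if v in used and used[v] != cyc:
                raise AmbiguousConnectivityError([used[v], cyc])
            used[v] = cyc
    return cycles


def tetrads_from_connectivity(peaks: list[NoePeak]) -> list[tuple[int, int, int, int]]:
    """Cyclic G-tetrad alignments from imino->aromatic connectivities.

    A directed edge a->b is taken from an H1(a)-H8(b) cross-peak with
    |a-b| > 1 (sequence neighbours always show trivial stacking NOEs).
    If the peak list contains any imino-imino peaks, an edge is only
    accepted when the corresponding H1(a)-H1(b) peak is present.
    """
    h1h8 = set()
    h1h1 = set()
    for p in peaks:
        (ra, na), (rb, nb) = p.proton_a, p.proton_b
        if {na, nb} == {"H1", "H8"}:
            if na == "H1":
                h1h8.add((ra, rb))
            else:
                h1h8.add((rb, ra))
        elif na == "H1" and nb == "H1":
            h1h1.add(frozenset((ra, rb)))
    edges = []
    for a, b in sorted(h1h8):
        if abs(a - b) <= 1:
            continue
        if h1h1 and frozenset((a, b)) not in h1h1:
            continue
        edges.append((a, b))
    return find_disjoint_4cycles(edges)


def syn_anti_from_peaks(peaks: list[NoePeak]) -> dict[int, str]:
    """Glycosidic states from intra-residue aromatic-anomeric intensities.

    A strong intra-residue H8-H1' peak marks a syn purine; medium or weak
    marks anti.  Residues without such a peak are omitted.
    """
    out: dict[int, str] = {}
    for p in peaks:
        (ra, na), (rb, nb) = p.proton_a, p.proton_b
        if ra == rb and {na, nb} == {"H8", "H1'"}:
            out[ra] = "syn" if p.intensity_class == "strong" else "anti"
    return out


def count_imino_protons(top: QuadruplexTopology) -> int:
    """Number of hydrogen-bond-protected imino protons in the tetrad core
    (one per tetrad guanine)."""
    return len(top.tetrad_positions)


def capping_imino_protons(top: QuadruplexTopology) -> list[int]:
    """Residues outside the core whose imino proton donates in a declared
    capping hydrogen bond (observable as extra protected iminos)."""
    tet = set(top.tetrad_positions)
    out = set()
    for cap in top.capping:
        for hb in cap.bonds:
            pos, atom = hb.donor
            if pos not in tet and atom in ("H1", "H3"):
                out.add(pos)
    return sorted(out)
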