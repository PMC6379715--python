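"""Sequences and putative G-quadruplex (pG4) motif scanning.

The canonical motif is G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+ : four tracts of at
least three consecutive guanines joined by 1-7 nt loops.  The scanner can
additionally tolerate a single non-G interruption (a prospective bulge)
strictly inside a tract, mirroring single-residue bulges seen in
non-canonical promoter quadruplexes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

#: I = 2'-deoxyinosine, supported for substitution analysis
ALPHABET = set("ACGTUI")


@dataclass(frozen=True)
class Sequence:
    """A nucleic-acid sequence with 1-based numbering (position 1 = 5')."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must have length >= 1")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


#: the 23-nt PARP1-promoter G-rich sequence and its T6 variant used for
#: structure determination
TP3 = Sequence("TP3", "TGGGGGCCGAGGCGGGGCTTGGG")
TP3_T6 = Sequence("TP3-T6", "TGGGGTCCGAGGCGGGGCTTGGG")


@dataclass(frozen=True)
class MotifMatch:
    """One pG4 motif hit.

    Spans are 1-based closed intervals ordered 5'->3'; tract and loop spans
    tile the interval [tract1.start, tract4.end] without gaps.
    """

    sequence_id: str
    tract_spans: tuple[tuple[int, int], ...]
    loop_spans: tuple[tuple[int, int], ...]
    bulge_positions: tuple[int, ...] = ()

    @property
    def canonical(self) -> bool:
        return len(self.bulge_positions) == 0

    @property
    def start(self) -> int:
        return self.tract_spans[0][0]

    @property
    def end(self) -> int:
        return self.tract_spans[-1][1]


def read_fasta(path: str | Path) -> list[Sequence]:
    import biotite.sequence.io.fasta as fasta

    f = fasta.FastaFile.read(str(path))
    return [Sequence(header.split()[0], str(seq)) for header, seq in f.items()]


def matches_to_bed(matches: list[MotifMatch]) -> str:
    """BED6-style lines (0-based half-open) for motif matches."""
    lines = []
    for i, m in enumerate(matches):
        lines.append(
            "\t".join(
                [
                    m.sequence_id,
                    str(m.start - 1),
                    str(m.end),
                    f"pG4_{i + 1}" + ("" if m.canonical else "_bulged"),
                    "0",
                    "+",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _candidate_tracts(s: str, start: int, min_tract: int, max_bulges: int):
    """All tracts beginning at 0-based ``start``.

    Yields (end_exclusive, bulge_positions) with >=min_tract G's, at most
    ``max_bulges`` non-G interior residues, first/last residue G.
    """
    n = len(s)
    if start >= n or s[start] != "G":
        return
    g = 0
    bulges: list[int] = []
    for e in range(start, n):
        if s[e] == "G":
            g += 1
            if g >= min_tract:
                yield e + 1, tuple(bulges)
        else:
            if len(bulges) >= max_bulges:
                return
            bulges.append(e)


def scan_pg4(
    seq: Sequence,
    max_loop: int = 7,
    min_tract: int = 3,
    max_bulges_per_tract: int = 0,
    min_loop: int = 1,
) -> list[MotifMatch]:
    """Scan for pG4 motifs, greedily 5'->3'.

    Overlapping candidates are resolved by earliest start, then fewest total
    bulges, then shortest total span; accepted matches do not overlap.  Only
    single-residue interruptions are supported (``max_bulges_per_tract`` of
    0 or 1); a bulge never sits at a tract edge.
    """
    if max_loop < 1:
        raise ValueError("max_loop must be >= 1")
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    if max_bulges_per_tract not in (0, 1):
        raise ValueError("only 0 or 1 bulges per tract are supported")
    s = seq.residues
    n = len(s)
    out: list[MotifMatch] = []
    pos = 0
    while pos < n:
        hit = _best_match_from(s, pos, max_loop, min_tract, max_bulges_per_tract, min_loop)
        if hit is None:
            break
        tracts, bulges = hit
        loops = tuple(
            (tracts[k][1] + 1, tracts[k + 1][0] - 1) for k in range(3)
        )
        out.append(
            MotifMatch(
                sequence_id=seq.id,
                tract_spans=tracts,
                loop_spans=loops,
                bulge_positions=bulges,
            )
        )
        pos = tracts[-1][1]  # 1-based end == 0-based index after the match
    return out


def _best_match_from(s, pos, max_loop, min_tract, max_bulges, min_loop):
    """Earliest/fewest-bulge/shortest match starting at or after 0-based pos.

    Returns (tract_spans, bulge_positions) in 1-based coordinates, or None.
    """
    n = len(s)

    @lru_cache(maxsize=None)
    def best(k: int, start: int):
        """Lexicographically minimal (bulges, end) completing tracts k..3
        with tract k starting exactly at 0-based ``start``; returns
        (bulges, end_exclusive, tract_choice, next_start) or None."""
        result = None
        for e, bl in _candidate_tracts(s, start, min_tract, max_bulges):
            if k == 3:
                cand = (len(bl), e, (start, e, bl), None)
            else:
                cand = None
                for s2 in range(e + min_loop, min(e + max_loop, n - 1) + 1):
                    sub = best(k + 1, s2)
                    if sub is None:
                        continue
                    c = (len(bl) + sub[0], sub[1], (start, e, bl), s2)
                    if cand is None or (c[0], c[1]) < (cand[0], cand[1]):
                        cand = c
                if cand is None:
                    continue
            if result is None or (cand[0], cand[1]) < (result[0], result[1]):
                result = cand
        return result

    for start in range(pos, n):
        if s[start] != "G":
            continue
        res = best(0, start)
        if res is None:
            continue
        # walk parent pointers
        tracts = []
        bulges: list[int] = []
        k, st = 0, start
        node = res
        while node is not None:
            _, _, (ts, te, bl), nxt = node
            tracts.append((ts + 1, te))  # 1-based closed
            bulges.extend(b + 1 for b in bl)
            if nxt is None:
                break
            k += 1
            node = best(k, nxt)
        best.cache_clear()
        return tuple(tracts), tuple(sorted(bulges))
    best.cache_clear()
    return None
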