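"""pG4 motif scanning against an independent regular-expression oracle."""
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadfold.sequences import (
    TP3,
    TP3_T6,
    MotifMatch,
    Sequence,
    matches_to_bed,
    scan_pg4,
)


def regex_scan(s: str, max_loop=7, min_tract=3):
    """Leftmost-lazy regex oracle for the canonical (bulge-free) motif."""
    pat = re.compile(
        "G{%d,}?" % min_tract
        + ("[ACGTU]{1,%d}?G{%d,}?" % (max_loop, min_tract)) * 3
    )
    out = []
    pos = 0
    while True:
        m = pat.search(s, pos)
        if m is None:
            return out
        out.append((m.start() + 1, m.end()))  # 1-based closed
        pos = m.end()


class TestScanExamples:
    def test_tp3_has_no_canonical_motif(self):
        assert scan_pg4(TP3, max_loop=7, max_bulges_per_tract=0) == []

    def test_tp3_bulged_match_uses_a10(self):
        matches = scan_pg4(TP3, max_loop=7, max_bulges_per_tract=1)
        assert len(matches) == 1
        m = matches[0]
        assert m.bulge_positions == (10,)
        assert (9, 12) in m.tract_spans
        assert not m.canonical

    def test_no_g_tract(self):
        assert scan_pg4(Sequence("x", "AAAA")) == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            Sequence("x", "ACGTX")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            Sequence("x", "")

    def test_spans_tile_without_gaps(self):
        (m,) = scan_pg4(TP3_T6, max_loop=7, max_bulges_per_tract=1)
        covered = []
        spans = sorted(list(m.tract_spans) + list(m.loop_spans))
        for s, e in spans:
            covered.extend(range(s, e + 1))
        assert covered == list(range(m.start, m.end + 1))


@settings(max_examples=300, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=60),
    st.integers(min_value=1, max_value=7),
)
def test_bulge_free_scan_matches_regex_oracle(s, max_loop):
    got = [
        (m.start, m.end) for m in scan_pg4(Sequence("t", s), max_loop=max_loop,
                                           max_bulges_per_tract=0)
    ]
    assert got == regex_scan(s, max_loop=max_loop)


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=60))
def test_matches_never_overlap_and_tracts_hold_enough_g(s):
    matches = scan_pg4(Sequence("t", s), max_bulges_per_tract=1)
    last_end = 0
    for m in matches:
        assert m.start > last_end
        last_end = m.end
        for ts, te in m.tract_spans:
            gs = sum(1 for p in range(ts, te + 1) if s[p - 1] == "G")
            assert gs >= 3
        for b in m.bulge_positions:
            assert s[b - 1] != "G"
            assert any(ts < b < te for ts, te in m.tract_spans)


def test_bed_export_is_zero_based_half_open():
    (m,) = scan_pg4(TP3_T6, max_bulges_per_tract=1)
    line = matches_to_bed([m]).strip().split("\t")
    assert line[0] == "TP3-T6"
    assert int(line[1]) == m.start - 1
    assert int(line[2]) == m.end


def test_fasta_roundtrip(tmp_path):
    from quadfold.sequences import read_fasta

    p = tmp_path / "seqs.fa"
    p.write_text(">TP3 promoter sequence\nTGGGGGCCGAGGCGGGGCTTGGG\n")
    (seq,) = read_fasta(p)
    assert seq.id == "TP3"
    assert seq.residues == TP3.residues
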