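"""NOESY prediction and inversion into tetrad alignments."""
import itertools

import numpy as np
import pytest

from quadfold.noe import (
    AmbiguousConnectivityError,
    NoePeak,
    capping_imino_protons,
    count_imino_protons,
    find_disjoint_4cycles,
    predict_peaks,
    syn_anti_from_peaks,
    tetrads_from_connectivity,
)

FIG_EDGES = [
    (3, 21), (21, 15), (15, 12), (12, 3),
    (4, 11), (11, 16), (16, 22), (22, 4),
    (5, 9), (9, 17), (17, 23), (23, 5),
]


def _edge_peaks(edges):
    return [
        NoePeak((a, "H1"), (b, "H8"), "medium", True) for a, b in edges
    ]


class TestPrediction:
    def test_contains_twelve_intra_tetrad_imino_aromatic_peaks(self, tp3_t6_peaks):
        got = set()
        for p in tp3_t6_peaks:
            (ra, na), (rb, nb) = p.proton_a, p.proton_b
            if {na, nb} == {"H1", "H8"} and ra != rb:
                pair = (ra, rb) if na == "H1" else (rb, ra)
                if pair in FIG_EDGES:
                    got.add(pair)
        assert got == set(FIG_EDGES)

    def test_syn_guanines_have_strong_intra_h8_h1prime(self, tp3_t6_peaks):
        for p in tp3_t6_peaks:
            (ra, na), (rb, nb) = p.proton_a, p.proton_b
            if ra == rb == 3 and {na, nb} == {"H8", "H1'"}:
                assert p.intensity_class == "strong"
                return
        pytest.fail("no intra-residue H8-H1' peak for syn G3")

    def test_two_distant_residues_give_nothing(self):
        from quadfold.model import build_extended_model

        m = build_extended_model([(1, "G"), (5, "G")])
        m.coords[m.res_ids == 5] += 100.0
        peaks = predict_peaks(m)
        inter = [p for p in peaks if p.proton_a[0] != p.proton_b[0]]
        assert inter == []

    def test_no_contradictory_duplicates(self, tp3_t6_peaks):
        seen = {}
        for p in tp3_t6_peaks:
            key = frozenset((p.proton_a, p.proton_b))
            assert key not in seen
            seen[key] = p.intensity_class

    def test_tsv_roundtrip(self, tp3_t6_peaks):
        from quadfold.noe import peaks_from_tsv, peaks_to_tsv

        again = peaks_from_tsv(peaks_to_tsv(tp3_t6_peaks))
        assert again == tp3_t6_peaks


class TestInversion:
    def test_figure_edges_give_three_quartets(self):
        assert tetrads_from_connectivity(_edge_peaks(FIG_EDGES)) == [
            (3, 21, 15, 12), (4, 11, 16, 22), (5, 9, 17, 23)
        ]

    def test_empty_peaks(self):
        assert tetrads_from_connectivity([]) == []

    def test_shuffle_invariance(self, rng):
        peaks = _edge_peaks(FIG_EDGES)
        expected = tetrads_from_connectivity(peaks)
        for _ in range(100):
            rng.shuffle(peaks)
            assert tetrads_from_connectivity(peaks) == expected

    def test_predicted_peaks_invert_to_specified_quartets(
        self, tp3_t6_topology, tp3_t6_peaks
    ):
        assert tetrads_from_connectivity(tp3_t6_peaks) == tp3_t6_topology.tetrads

    def test_conflicting_cycles_raise(self):
        edges = FIG_EDGES + [(2, 21), (15, 14), (14, 2), (12, 2)]
        # feed as curated edge list (no imino-imino corroboration available)
        with pytest.raises(AmbiguousConnectivityError):
            tetrads_from_connectivity(_edge_peaks(edges))

    def test_cycle_finder_equals_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 20))
            density = rng.uniform(0.05, 0.25)
            edges = [
                (int(a), int(b))
                for a in range(n)
                for b in range(n)
                if a != b and rng.random() < density
            ]
            eset = set(edges)
            brute = set()
            for quad in itertools.permutations(range(n), 4):
                if quad[0] != min(quad):
                    continue
                if all(
                    (quad[k], quad[(k + 1) % 4]) in eset for k in range(4)
                ):
                    brute.add(quad)
            try:
                got = set(find_disjoint_4cycles(edges))
            except AmbiguousConnectivityError:
                # brute force must then contain two vertex-sharing cycles
                shared = any(
                    set(a) & set(b) for a, b in itertools.combinations(brute, 2)
                )
                assert shared
                continue
            assert got == brute


class TestSynAnti:
    def test_ideal_structure_syn_set(self, tp3_t6_peaks):
        states = syn_anti_from_peaks(tp3_t6_peaks)
        syn = sorted(p for p, s in states.items() if s == "syn")
        assert syn == [3, 9, 11, 15, 21]

    def test_no_intra_peaks_empty(self):
        assert syn_anti_from_peaks(_edge_peaks(FIG_EDGES)) == {}

    def test_single_strong_peak(self):
        states = syn_anti_from_peaks(
            [NoePeak((9, "H1'"), (9, "H8"), "strong", False)]
        )
        assert states == {9: "syn"}


class TestIminoCounts:
    def test_tp3_t6(self, tp3_t6_topology):
        assert count_imino_protons(tp3_t6_topology) == 12
        assert capping_imino_protons(tp3_t6_topology) == [2, 14]

    def test_two_tetrads(self):
        from quadfold.folds import get_fold

        assert count_imino_protons(get_fold("antiparallel_2+2")) == 8
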