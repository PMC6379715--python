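"""Restraint compilation: counts, bounds, dedup and serialization."""
import numpy as np
import pytest

from quadfold.folds import get_fold, tp3_t6_spec
from quadfold.noe import NoePeak
from quadfold.restraints import (
    RestraintParameters,
    RestraintSet,
    assemble,
    compile_dihedral_restraints,
    compile_hbond_restraints,
    compile_planarity,
    compile_repulsion,
    noe_peaks_to_restraints,
)
from quadfold.topology import build_topology


@pytest.fixture(scope="module")
def top():
    return get_fold("tp3_t6")


class TestHbondCompilation:
    def test_tp3_t6_total_53(self, top):
        rs = RestraintSet(distance=compile_hbond_restraints(top))
        assert rs.counts()["hbond"] == 53

    def test_isolated_tetrad_gives_16(self):
        one = build_topology(
            {"sequence_id": "x", "residues": "GGGTGGGTGGGTGGG",
             "tetrads": [(1, 5, 9, 13)], "syn": []}
        )
        # brute force: four directed Hoogsteen edges, four distances each
        assert len(compile_hbond_restraints(one)) == 4 * 4

    def test_no_tetrads_no_capping_empty(self):
        two = build_topology(
            {"sequence_id": "x", "residues": "GGTTGGTGTGGTTGG",
             "tetrads": [(1, 6, 10, 15), (2, 14, 11, 5)], "syn": [1, 5, 10, 14]}
        )
        two.tetrads = []
        two.capping = []
        assert compile_hbond_restraints(two) == []

    def test_ambiguous_group_counts_once(self, top):
        rows = compile_hbond_restraints(top)
        groups = {r.ambiguity_group for r in rows if r.ambiguity_group}
        assert len(groups) == 1
        alt_rows = [r for r in rows if r.ambiguity_group]
        assert len(alt_rows) == 3  # T20 O2 / O4 / O4'

    def test_count_formula_on_random_valid_topologies(self, rng):
        # hbond count = 16 * n_tetrads + declared capping bonds + groups
        for _ in range(20):
            n_layers = int(rng.integers(2, 4))
            seq = "".join("GGG" + "TT" for _ in range(4))[:-2]
            # four tracts of length 3 -> up to 3 layers
            tracts = [(1, 3), (6, 8), (11, 13), (16, 18)]
            tetrads = [tuple(t[0] + l for t in tracts) for l in range(n_layers)]
            spec = {"sequence_id": "r", "residues": seq, "tetrads": tetrads, "syn": []}
            t = build_topology(spec)
            rows = compile_hbond_restraints(t)
            assert len(rows) == 16 * n_layers

    def test_missing_atom_errors_with_residue(self, top):
        import dataclasses

        from quadfold.topology import CappingElement, HydrogenBond

        bad = dataclasses.replace(top)
        bad.capping = [
            CappingElement(partners=(14, 2), mode="hoogsteen",
                           bonds=(HydrogenBond((14, "HX9"), (2, "O6")),))
        ]
        with pytest.raises(KeyError, match="HX9"):
            compile_hbond_restraints(bad)


class TestDihedralCompilation:
    def test_tp3_t6_total_13(self, top):
        assert len(compile_dihedral_restraints(top)) == 13

    def test_inner_anti_center_and_width(self, top):
        rows = compile_dihedral_restraints(top)
        g4 = [d for d in rows if d.atoms[0][0] == 4][0]
        assert g4.center == 240.0 and g4.halfwidth == 40.0
        g3 = [d for d in rows if d.atoms[0][0] == 3][0]
        assert g3.center == 60.0 and g3.halfwidth == 70.0

    def test_zero_tetrads_empty(self, top):
        import dataclasses

        t = dataclasses.replace(top)
        t.tetrads = []
        t.capping = []
        assert compile_dihedral_restraints(t) == []


class TestNoeConversion:
    def test_nonexchangeable_strong_bounds(self):
        (r,) = noe_peaks_to_restraints(
            [NoePeak((3, "H8"), (3, "H1'"), "strong", False)]
        )
        assert (r.target, r.lower, r.upper) == (2.7, pytest.approx(1.9), 3.5)

    def test_exchangeable_medium_bounds(self):
        (r,) = noe_peaks_to_restraints(
            [NoePeak((3, "H1"), (21, "H8"), "medium", True)]
        )
        assert (r.target, r.lower, r.upper) == (4.8, pytest.approx(3.6), 6.0)

    def test_duplicate_peaks_collapse_to_tightest(self):
        rows = noe_peaks_to_restraints(
            [
                NoePeak((3, "H8"), (4, "H1'"), "medium", False, 100.0),
                NoePeak((4, "H1'"), (3, "H8"), "strong", False, 250.0),
            ]
        )
        assert len(rows) == 1
        assert rows[0].target == 2.7

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            NoePeak((1, "H8"), (2, "H8"), "huge", False)


class TestRepulsionAndPlanarity:
    def test_paper_pairs_give_two(self, top):
        from quadfold.restraints import TP3_T6_ABSENT_CONTACTS

        rows = compile_repulsion(TP3_T6_ABSENT_CONTACTS)
        assert len(rows) == 2
        assert all(r.upper is None and r.lower == 3.5 for r in rows)

    def test_duplicate_pair_deduped(self):
        rows = compile_repulsion([((1, "H1"), (2, "H8")), ((2, "H8"), (1, "H1"))])
        assert len(rows) == 1

    def test_planarity_one_per_layer_plus_planar_capping(self, top):
        groups = compile_planarity(top)
        assert len(groups) == 4
        assert all(len(g.atoms) >= 3 for g in groups)


class TestAssemble:
    def test_counts_layout(self, top, tp3_t6_peaks):
        from quadfold.restraints import TP3_T6_ABSENT_CONTACTS

        rs = assemble(top, peaks=tp3_t6_peaks, absent_contacts=TP3_T6_ABSENT_CONTACTS)
        c = rs.counts()
        assert c["hbond"] == 53
        assert c["dihedral"] == 13
        assert c["planarity"] == 4
        assert c["repulsion"] == 2
        total_noe = sum(v for k, v in c.items() if k.startswith("noe"))
        assert total_noe == len(rs.noe)

    def test_order_independent(self, top, tp3_t6_peaks, rng):
        from quadfold.restraints import TP3_T6_ABSENT_CONTACTS

        shuffled = list(tp3_t6_peaks)
        rng.shuffle(shuffled)
        a = assemble(top, peaks=tp3_t6_peaks, absent_contacts=TP3_T6_ABSENT_CONTACTS)
        b = assemble(top, peaks=shuffled, absent_contacts=TP3_T6_ABSENT_CONTACTS)
        assert a.distance == b.distance
        assert a.dihedral == b.dihedral

    def test_tsv_roundtrip_bit_exact(self, top, tp3_t6_peaks):
        rs = assemble(top, peaks=tp3_t6_peaks)
        again = RestraintSet.from_tsv(rs.to_tsv())
        assert again.distance == rs.distance
        assert again.dihedral == rs.dihedral
        assert again.repulsion == rs.repulsion
        assert [g.atoms for g in again.planarity] == [g.atoms for g in rs.planarity]

    def test_every_restraint_atom_exists_in_templates(self, top, tp3_t6_restraints):
        from quadfold.templates import get_template

        seq = top.sequence
        for r in tp3_t6_restraints.all_distance_like():
            for pos, name in (r.atom_a, r.atom_b):
                tmpl = get_template(seq[pos], five_prime=(pos == 1))
                assert tmpl.has_atom(name), (pos, name)

    def test_xplor_export_mentions_every_pair(self, top):
        rs = assemble(top)
        text = rs.to_xplor()
        assert text.count("assign") == len(rs.distance) + len(rs.repulsion)
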