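"""Coordinate-based topology re-derivation and ensemble validation."""
import numpy as np
import pytest

from quadfold.folds import get_fold
from quadfold.geometry import random_rotation, superposed_rmsd
from quadfold.model import Ensemble, build_extended_model
from quadfold.structure_analysis import (
    ClassificationError,
    classify_structure,
    detect_pairs_triples,
    detect_tetrads,
    fold_class,
    glycosidic_chi,
    pairwise_rmsd,
    validate_ensemble,
)
from quadfold.synth import GeneratorParams, build_ideal_structure, perturb


class TestGlycosidicChi:
    def test_template_anti_guanine(self):
        m = build_extended_model([(1, "G")])
        chi, state = glycosidic_chi(m)[1]
        assert state == "anti"
        assert 150 < chi < 330

    def test_ideal_structure_syn_set(self, tp3_t6_structure):
        states = glycosidic_chi(tp3_t6_structure)
        syn = sorted(p for p, (c, s) in states.items() if s == "syn")
        assert syn == [3, 9, 11, 15, 21]

    def test_boundary_windows(self, tp3_t6_structure):
        for p, (chi, state) in glycosidic_chi(tp3_t6_structure).items():
            dev = (chi - 60.0) % 360.0
            expect_syn = dev < 90.0 or dev > 270.0
            assert (state == "syn") == expect_syn


class TestDetectTetrads:
    def test_ideal_structure(self, tp3_t6_topology, tp3_t6_structure):
        assert detect_tetrads(tp3_t6_structure) == tp3_t6_topology.tetrads

    def test_single_strand_has_none(self):
        m = build_extended_model([(i, "G") for i in range(1, 6)])
        assert detect_tetrads(m) == []

    def test_robust_to_coordinate_noise(self, tp3_t6_topology, tp3_t6_structure):
        noisy = perturb(tp3_t6_structure, sd=0.3, seed=42)
        assert detect_tetrads(noisy) == tp3_t6_topology.tetrads

    def test_invariant_under_rigid_motion(self, tp3_t6_structure, rng):
        R = random_rotation(rng)
        moved = tp3_t6_structure.with_coords(
            tp3_t6_structure.coords @ R.T + rng.normal(0, 20, 3)
        )
        assert detect_tetrads(moved) == detect_tetrads(tp3_t6_structure)


class TestClassification:
    def test_tp3_t6_roundtrip(self, tp3_t6_topology, tp3_t6_structure):
        derived = classify_structure(tp3_t6_structure)
        top = tp3_t6_topology
        assert derived.tetrads == top.tetrads
        derived_syn = {p for p in derived.tetrad_positions
                       if derived.glycosidic[p] == "syn"}
        assert derived_syn == {3, 9, 11, 15, 21}
        assert derived.loops == top.loops
        assert derived.bulges == [10]
        assert fold_class(derived) == "(3+1) hybrid"
        labels = {frozenset((a, b)): g for a, b, g in derived.grooves}
        assert labels[frozenset((0, 1))] == "wide"
        assert labels[frozenset((1, 2))] == "narrow"

    @pytest.mark.parametrize(
        "name,expected_class,expected_loops",
        [
            ("parallel_3layer", "parallel", ["propeller"] * 3),
            ("antiparallel_2+2", "antiparallel", ["edgewise"] * 3),
        ],
    )
    def test_other_architectures(self, name, expected_class, expected_loops):
        top = get_fold(name)
        m = build_ideal_structure(top, GeneratorParams())
        derived = classify_structure(m)
        assert derived.tetrads == top.tetrads
        assert fold_class(derived) == expected_class
        assert [t for _, t in derived.loops] == expected_loops

    def test_too_few_tetrads_raises(self):
        m = build_extended_model([(i, "G") for i in range(1, 6)])
        with pytest.raises(ClassificationError):
            classify_structure(m)


class TestPairsTriples:
    def test_capping_triple(self, tp3_t6_topology, tp3_t6_structure):
        tet = set(tp3_t6_topology.tetrad_positions)
        items = detect_pairs_triples(tp3_t6_structure, exclude=tet)
        triples = [i for i in items if hasattr(i, "pairs")]
        assert len(triples) == 1
        tri = triples[0]
        assert tri.residues == (2, 14, 20)
        modes = {p.residues: p.mode for p in tri.pairs}
        assert modes[(2, 14)] == "reverse_hoogsteen"

    def test_t14_a2_variant_is_hoogsteen(self):
        top = get_fold("tp3_t6_t14a2")
        m = build_ideal_structure(top, GeneratorParams())
        tet = set(top.tetrad_positions)
        items = detect_pairs_triples(m, exclude=tet)
        pair_modes = {}
        for it in items:
            for bp in (it.pairs if hasattr(it, "pairs") else (it,)):
                pair_modes[bp.residues] = bp.mode
        assert pair_modes.get((2, 14)) == "hoogsteen"

    def test_no_capping_no_pairs(self):
        top = get_fold("parallel_3layer")
        m = build_ideal_structure(top, GeneratorParams())
        tet = set(top.tetrad_positions)
        items = detect_pairs_triples(m, exclude=tet)
        assert all(
            not hasattr(i, "pairs") or len(i.residues) < 3 for i in items
        )


class TestValidation:
    def test_identical_models_zero_rmsd(self, tp3_t6_structure):
        ens = Ensemble(models=[tp3_t6_structure.with_coords(tp3_t6_structure.coords, i)
                               for i in (1, 2, 3)])
        rep = validate_ensemble(ens)
        assert rep.rmsd_core[0] == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_core[1] == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_all[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motions_superpose_to_zero(self, tp3_t6_structure, rng):
        models = [tp3_t6_structure]
        for i in (2, 3):
            R = random_rotation(rng)
            models.append(
                tp3_t6_structure.with_coords(
                    tp3_t6_structure.coords @ R.T + rng.normal(0, 15, 3), i
                )
            )
        rep = validate_ensemble(Ensemble(models=models))
        assert rep.rmsd_all[0] < 1e-6

    def test_rmsd_pseudometric(self, tp3_t6_structure, rng):
        heavy = tp3_t6_structure.heavy_mask()
        base = tp3_t6_structure.coords[heavy]
        pts = [base + rng.normal(0, s, base.shape) for s in (0.2, 0.5, 1.0)]
        def d(a, b):
            return superposed_rmsd(a, b)
        for a, b, c in [(0, 1, 2), (1, 2, 0)]:
            assert d(pts[a], pts[b]) == pytest.approx(d(pts[b], pts[a]), abs=1e-9)
            assert d(pts[a], pts[c]) <= d(pts[a], pts[b]) + d(pts[b], pts[c]) + 1e-9

    def test_violation_counts_monotone_in_bounds(self, tp3_t6_structure,
                                                  tp3_t6_restraints):
        import dataclasses

        from quadfold.structure_analysis import noe_violation_count

        wide = dataclasses.replace(tp3_t6_restraints)
        wide.distance = [
            dataclasses.replace(r, lower=max((r.lower or 0) - 0.5, 0.0),
                                upper=(r.upper or 999) + 0.5)
            for r in tp3_t6_restraints.distance
        ]
        noisy = perturb(tp3_t6_structure, sd=0.4, seed=5)
        assert noe_violation_count(noisy, wide) <= noe_violation_count(
            noisy, tp3_t6_restraints
        )

    def test_atom_mismatch_rejected(self, tp3_t6_structure):
        other = build_extended_model([(1, "G"), (2, "G")])
        with pytest.raises(ValueError):
            Ensemble(models=[tp3_t6_structure, other])
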