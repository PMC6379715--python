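"""Topology construction, derived orientations/grooves and serialization."""
import pytest

from quadfold.folds import get_fold, tp3_t6_spec
from quadfold.topology import (
    QuadruplexTopology,
    TopologyError,
    build_topology,
    expected_grooves,
)


class TestBuildTopology:
    def test_tp3_t6_derivations(self, tp3_t6_topology):
        top = tp3_t6_topology
        assert len(top.tetrad_positions) == 12
        assert len(top.tetrads) == 3
        assert [t for _, t in top.loops] == ["edgewise", "edgewise", "propeller"]
        assert top.bulges == [10]
        # strand orientations follow from the Hoogsteen cycle consistency
        assert [o for _, o in top.strands] == ["up", "down", "up", "up"]

    def test_layer_classes(self, tp3_t6_topology):
        lc = tp3_t6_topology.layer_class
        assert all(lc[p] == "outer" for p in (3, 21, 15, 12))
        assert all(lc[p] == "inner" for p in (4, 11, 16, 22))
        assert all(lc[p] == "outer" for p in (5, 9, 17, 23))

    def test_non_g_tetrad_member_rejected(self):
        spec = tp3_t6_spec()
        spec["tetrads"][0] = (7, 21, 15, 12)  # position 7 is C
        with pytest.raises(TopologyError, match="7"):
            build_topology(spec)

    def test_overlapping_layers_rejected(self):
        spec = tp3_t6_spec()
        spec["tetrads"][1] = (3, 11, 16, 22)  # 3 already in layer 0
        with pytest.raises(TopologyError):
            build_topology(spec)

    def test_position_cannot_be_tetrad_and_bulge(self):
        spec = tp3_t6_spec()
        spec["bulges"] = [11]
        with pytest.raises(TopologyError):
            build_topology(spec)

    def test_serialisation_roundtrip_idempotent(self, tp3_t6_topology):
        text = tp3_t6_topology.to_text()
        again = QuadruplexTopology.from_text(text)
        assert again.to_text() == text
        assert again.tetrads == tp3_t6_topology.tetrads
        assert again.glycosidic == tp3_t6_topology.glycosidic

    def test_version_guard(self):
        with pytest.raises(TopologyError, match="version"):
            QuadruplexTopology.from_text("quadfold-topology v9\n")


class TestGrooves:
    def _labels(self, top):
        return {frozenset((a, b)): g for a, b, g in expected_grooves(top)}

    def test_tp3_t6_w_m_n_m(self, tp3_t6_topology):
        labels = self._labels(tp3_t6_topology)
        # TCC edgewise loop crosses the wide groove (strands 0-1), the CG
        # edgewise loop the narrow groove (strands 1-2)
        assert labels[frozenset((0, 1))] == "wide"
        assert labels[frozenset((1, 2))] == "narrow"
        assert labels[frozenset((2, 3))] == "medium"
        assert labels[frozenset((3, 0))] == "medium"

    def test_all_parallel_all_medium(self):
        top = get_fold("parallel_3layer")
        assert [g for _, _, g in expected_grooves(top)] == ["medium"] * 4

    def test_reversed_cycle_swaps_wide_and_narrow(self):
        spec = tp3_t6_spec()
        spec["tetrads"] = [tuple(reversed(q)) for q in spec["tetrads"]]
        top = build_topology(spec)
        labels = self._labels(top)
        assert labels[frozenset((0, 1))] == "narrow"
        assert labels[frozenset((1, 2))] == "wide"

    def test_one_wide_one_narrow_per_antiparallel_adjacency(self):
        for name in ("tp3_t6", "antiparallel_2+2"):
            top = get_fold(name)
            orient = {i: o for i, (_, o) in enumerate(top.strands)}
            for a, b, g in expected_grooves(top):
                if orient[a] == orient[b]:
                    assert g == "medium"
                else:
                    assert g in ("wide", "narrow")
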