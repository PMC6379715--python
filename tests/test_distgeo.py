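"""Distance-geometry oracles: smoothing, embedding, determinism."""
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from quadfold.distgeo import (
    BoundsMatrix,
    InfeasibleBoundsError,
    build_bounds,
    embed,
    smooth_upper_bounds,
)


def _exact_bm(points):
    D = squareform(pdist(points))
    return BoundsMatrix(
        lower=D.copy(), upper=D.copy(),
        chirals=np.empty((0, 4), int), chiral_sign=np.empty(0),
        chiral_thresh=np.empty(0),
    )


class TestSmoothing:
    def test_three_atom_chain_example(self):
        U = np.full((3, 3), 999.0)
        np.fill_diagonal(U, 0.0)
        U[0, 1] = U[1, 0] = 1.5
        U[1, 2] = U[2, 1] = 1.5
        S = smooth_upper_bounds(U)
        assert S[0, 2] == pytest.approx(3.0)

    def test_matches_shortest_path_oracle(self, rng):
        n = 30
        U = rng.uniform(1.0, 20.0, (n, n))
        U = (U + U.T) / 2
        np.fill_diagonal(U, 0.0)
        S = smooth_upper_bounds(U)
        oracle = shortest_path(U, method="J")
        assert np.allclose(S, oracle, atol=1e-9)

    def test_fixed_point(self, rng):
        n = 20
        U = rng.uniform(1.0, 30.0, (n, n))
        U = (U + U.T) / 2
        np.fill_diagonal(U, 0.0)
        S = smooth_upper_bounds(U)
        assert np.allclose(smooth_upper_bounds(S), S)


class TestEmbedding:
    def test_exact_tetrahedron(self):
        pts = np.array(
            [[0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0], [0.75, 0.43, 1.2]], dtype=float
        )
        bm = _exact_bm(pts)
        X = embed(bm, seed=0, n_metrize=0)
        D = squareform(pdist(X))
        assert np.allclose(D, squareform(pdist(pts)), atol=1e-6)

    def test_exact_bounds_from_ideal_structure(self, tp3_t6_structure):
        heavy = tp3_t6_structure.heavy_mask()
        pts = tp3_t6_structure.coords[heavy][::3]  # subsample for speed
        bm = _exact_bm(pts)
        X = embed(bm, seed=3, n_metrize=0)
        D = squareform(pdist(X))
        assert np.abs(D - squareform(pdist(pts))).max() < 1e-3

    def test_same_seed_identical(self):
        pts = np.array(
            [[0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0], [0.75, 0.43, 1.2],
             [2.0, 2.0, 2.0]], dtype=float
        )
        D = squareform(pdist(pts))
        bm = BoundsMatrix(
            lower=np.maximum(D - 0.5, 0.0), upper=D + 0.5,
            chirals=np.empty((0, 4), int), chiral_sign=np.empty(0),
            chiral_thresh=np.empty(0),
        )
        X1 = embed(bm, seed=11)
        X2 = embed(bm, seed=11)
        assert np.array_equal(X1, X2)
        X3 = embed(bm, seed=12)
        assert not np.array_equal(X1, X3)


class TestBuildBounds:
    def test_covalent_dominates_looser_restraint(self, tp3_t6_topology):
        from quadfold.model import build_extended_model
        from quadfold.restraints import DistanceRestraint, RestraintSet

        seq = tp3_t6_topology.sequence
        skel = build_extended_model([(i + 1, c) for i, c in enumerate(seq.residues)])
        # a "restraint" on a covalently bonded pair with looser bounds
        rs = RestraintSet(
            distance=[
                DistanceRestraint(atom_a=(3, "N9"), atom_b=(3, "C1'"),
                                  category="noe", target=3.0, lower=2.0, upper=4.0)
            ]
        )
        bm = build_bounds(skel, rs)
        i = skel.index(3, "N9")
        j = skel.index(3, "C1'")
        assert bm.upper[i, j] < 1.6  # covalent bond length retained

    def test_infeasible_bounds_error_lists_pairs(self):
        from quadfold.model import build_extended_model
        from quadfold.restraints import DistanceRestraint, RestraintSet

        skel = build_extended_model([(1, "G"), (2, "G")])
        rs = RestraintSet(
            distance=[
                # two contradictory restraints on one long-range pair:
                DistanceRestraint(atom_a=(1, "H8"), atom_b=(2, "H8"),
                                  category="noe", target=2.0, lower=1.9, upper=2.1),
                DistanceRestraint(atom_a=(1, "H8"), atom_b=(2, "H8"),
                                  category="hbond", target=9.0, lower=8.5, upper=9.5),
            ]
        )
        with pytest.raises(InfeasibleBoundsError):
            build_bounds(skel, rs)

    def test_tp3_t6_full_restraints_feasible(self, tp3_t6_topology, tp3_t6_restraints):
        from quadfold.model import build_extended_model

        seq = tp3_t6_topology.sequence
        skel = build_extended_model([(i + 1, c) for i, c in enumerate(seq.residues)])
        bm = build_bounds(skel, tp3_t6_restraints)  # raises if infeasible
        assert np.all(bm.lower <= bm.upper + 1e-9)
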