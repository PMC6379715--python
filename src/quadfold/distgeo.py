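"""Metric-matrix distance geometry: bounds, smoothing, embedding.

A :class:`BoundsMatrix` holds per-atom-pair lower/upper distance bounds.
Covalent 1-2/1-3 distances are fixed from the residue templates (within
0.01 A), restraint bounds are merged tighter-wins, and upper bounds are
triangle-smoothed to the all-pairs-shortest-path fixed point.  Embedding
draws a random distance matrix within the bounds (with progressive
re-smoothing for a metrized subset), converts it to a Gram matrix and
takes the top-3 eigenvector projection; the mirror image is resolved by
the template chirality score.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel
from .model import StructureModel
from .templates import VDW_RADIUS


class InfeasibleBoundsError(ValueError):
    def __init__(self, pairs):
        self.pairs = pairs
        preview = ", ".join(str(p) for p in pairs[:5])
        super().__init__(
            f"{len(pairs)} atom pairs have lower > upper bound after merging "
            f"(first: {preview}); inspect the conflicting restraints"
        )


@dataclass
class BoundsMatrix:
    lower: np.ndarray           # (n, n)
    upper: np.ndarray           # (n, n)
    chirals: np.ndarray         # (m, 4) template chiral quadruples
    chiral_sign: np.ndarray     # (m,)
    chiral_thresh: np.ndarray   # (m,) minimum allowed signed volume

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    def check(self):
        bad = np.argwhere(self.lower > self.upper + 1e-9)
        bad = [tuple(p) for p in bad if p[0] < p[1]]
        if bad:
            raise InfeasibleBoundsError(bad)


def smooth_upper_bounds(upper: np.ndarray) -> np.ndarray:
    """Triangle smoothing of upper bounds (Floyd-Warshall fixed point)."""
    U = upper.copy()
    n = U.shape[0]
    for k in range(n):
        np.minimum(U, U[:, k, None] + U[None, k, :], out=U)
    return U


def smooth_lower_bounds(lower: np.ndarray, upper: np.ndarray, passes: int = 1) -> np.ndarray:
    """Inverse-triangle smoothing: l(i,j) >= max_k l(i,k) - u(k,j)."""
    L = lower.copy()
    for _ in range(passes):
        # one vectorised sweep over intermediates
        cand = (L[:, :, None] - upper[None, :, :]).max(axis=1)
        L = np.maximum(L, np.maximum(cand, cand.T))
    np.fill_diagonal(L, 0.0)
    return L


def build_bounds(skeleton: StructureModel, restraints=None) -> BoundsMatrix:
    """Bounds matrix for an atom set and a restraint set.

    Tighter bounds win when covalent geometry and restraints address the
    same pair; infeasible merges raise listing the offending pairs.
    """
    n = skeleton.n_atoms
    em = EnergyModel(skeleton, restraints, nonbonded=False)
    radii = np.array([VDW_RADIUS[e] for e in skeleton.elements])
    lower = 0.7 * (radii[:, None] + radii[None, :])
    upper = np.full((n, n), 999.0)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)

    fixed = np.zeros((n, n), dtype=bool)

    def fix(i, j, d, tol=0.01):
        lower[i, j] = lower[j, i] = d - tol
        upper[i, j] = upper[j, i] = min(upper[i, j], d + tol)
        fixed[i, j] = fixed[j, i] = True

    blen: dict[tuple[int, int], float] = {}
    for (i, j), d in zip(em.bonds, em.bond0):
        fix(i, j, d)
        blen[(int(i), int(j))] = blen[(int(j), int(i))] = float(d)
    for (i, j, k), th in zip(em.angles, em.angle0):
        d1 = blen[(int(i), int(j))]
        d2 = blen[(int(j), int(k))]
        d13 = np.sqrt(d1**2 + d2**2 - 2 * d1 * d2 * np.cos(th))
        fix(i, k, d13)

    if restraints is not None:
        for r in restraints.all_distance_like():
            i = skeleton.index(*r.atom_a)
            j = skeleton.index(*r.atom_b)
            if r.ambiguity_group is not None:
                continue  # OR semantics cannot tighten a single pair
            if fixed[i, j]:
                continue  # covalent 1-2/1-3 geometry dominates restraints
            if r.lower is not None:
                lower[i, j] = lower[j, i] = max(lower[i, j], r.lower)
            if r.upper is not None:
                upper[i, j] = upper[j, i] = min(upper[i, j], r.upper)

    upper = smooth_upper_bounds(upper)
    lower = smooth_lower_bounds(lower, upper)
    bm = BoundsMatrix(lower=lower, upper=upper,
                      chirals=em.chirals, chiral_sign=em.chiral_sign,
                      chiral_thresh=em.chiral_thresh)
    bm.check()
    return bm


def _chirality_score(coords: np.ndarray, bm: BoundsMatrix) -> float:
    if len(bm.chirals) == 0:
        return 0.0
    c, a, b, d = bm.chirals.T
    u = coords[a] - coords[c]
    v = coords[b] - coords[c]
    w = coords[d] - coords[c]
    vol = np.einsum("ij,ij->i", u, np.cross(v, w)) * bm.chiral_sign
    return float(np.sum(np.minimum(vol - bm.chiral_thresh, 0.0) ** 2))


class EmbeddingError(RuntimeError):
    pass


def refine_against_bounds(
    coords: np.ndarray,
    bm: BoundsMatrix,
    max_iter: int = 150,
    chirality_weight: float = 10.0,
) -> np.ndarray:
    """Gradient refinement of coordinates against the full bounds matrix.

    Minimises the summed squared bound violations over all atom pairs plus
    a chirality penalty; this is the classical distance-geometry error
    function and repairs the distortions of a raw metric-matrix embedding.
    """
    from scipy.optimize import minimize as _sp_min

    n = bm.n
    L, U = bm.lower, bm.upper
    iu = np.triu_indices(n, k=1)

    def fun(x):
        X = x.reshape(n, 3)
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff) + 1e-12)
        over = np.maximum(D - U, 0.0)
        under = np.maximum(L - D, 0.0)
        viol = over - under
        E = float(np.sum(viol[iu] ** 2))
        W = 2.0 * viol / D
        G = np.einsum("ij,ijk->ik", W, diff)
        # chirality
        if len(bm.chirals):
            c, a, b, d = bm.chirals.T
            u = X[a] - X[c]
            v = X[b] - X[c]
            w = X[d] - X[c]
            vol = np.einsum("ij,ij->i", u, np.cross(v, w)) * bm.chiral_sign
            bad = np.minimum(vol - bm.chiral_thresh, 0.0)
            E += chirality_weight * float(np.sum(bad**2))
            pref = 2 * chirality_weight * bad * bm.chiral_sign
            du = np.cross(v, w)
            dv = np.cross(w, u)
            dw = np.cross(u, v)
            np.add.at(G, a, pref[:, None] * du)
            np.add.at(G, b, pref[:, None] * dv)
            np.add.at(G, d, pref[:, None] * dw)
            np.add.at(G, c, -pref[:, None] * (du + dv + dw))
        return E, G.ravel()

    res = _sp_min(fun, coords.ravel(), jac=True, method="L-BFGS-B",
                  options={"maxiter": max_iter, "ftol": 1e-12})
    return res.x.reshape(n, 3)


def embed(
    bm: BoundsMatrix,
    seed: int,
    skeleton: StructureModel | None = None,
    n_metrize: int = 150,
) -> np.ndarray | StructureModel:
    """Embed a bounds matrix into 3D coordinates.

    A random subset of ``n_metrize`` pairs is metrized (distance fixed by a
    uniform draw, upper bounds re-smoothed through the fixed pair); the
    remaining distances are drawn independently.  Deterministic for a
    given seed.  Returns coordinates, or a StructureModel when a skeleton
    is supplied.
    """
    rng = np.random.default_rng(seed)
    n = bm.n
    L = bm.lower.copy()
    U = bm.upper.copy()
    if n_metrize > 0 and n > 2:
        ii = rng.integers(0, n, size=n_metrize)
        jj = rng.integers(0, n, size=n_metrize)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            d = rng.uniform(max(L[i, j], 0.0), max(U[i, j], L[i, j]))
            L[i, j] = L[j, i] = U[i, j] = U[j, i] = d
            # re-smooth upper bounds through the fixed pair
            np.minimum(U, U[:, i, None] + d + U[None, j, :], out=U)
            np.minimum(U, U[:, j, None] + d + U[None, i, :], out=U)
    D = rng.uniform(np.minimum(L, U), np.maximum(L, U))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    # classical MDS
    D2 = D**2
    row = D2.mean(axis=1)
    grand = D2.mean()
    B = -0.5 * (D2 - row[:, None] - row[None, :] + grand)
    vals, vecs = np.linalg.eigh(B)
    top = vals[-3:]
    if np.all(top <= 0):
        raise EmbeddingError(
            "bounds matrix is not embeddable (no positive Gram eigenvalues); "
            "inspect the distance bounds"
        )
    top = np.maximum(top, 0.0)
    coords = vecs[:, -3:] * np.sqrt(top)[None, :]
    # mirror-image resolution by chirality
    mirror = coords * np.array([1.0, 1.0, -1.0])
    s1 = _chirality_score(coords, bm)
    s2 = _chirality_score(mirror, bm)
    if s2 < s1:
        coords = mirror
    elif s2 == s1 and len(bm.chirals):
        c, a, b, d = bm.chirals[0]
        u = coords[a] - coords[c]
        v = coords[b] - coords[c]
        w = coords[d] - coords[c]
        if float(np.dot(u, np.cross(v, w))) < 0:
            coords = mirror
    if skeleton is not None:
        return skeleton.with_coords(coords)
    return coords
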