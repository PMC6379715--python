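"""All-atom coordinate containers: StructureModel and Ensemble."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .templates import get_template


@dataclass
class StructureModel:
    """One all-atom model.

    Flat per-atom arrays; residue positions are 1-based and residue codes
    are one-letter (A/C/G/T/U/I).
    """

    res_ids: np.ndarray          # (n,) int
    res_codes: np.ndarray        # (n,) str, one-letter
    atom_names: np.ndarray       # (n,) str
    elements: np.ndarray         # (n,) str
    coords: np.ndarray           # (n,3) float
    model_id: int = 1

    def __post_init__(self):
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_codes = np.asarray(self.res_codes, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        self._index: dict[tuple[int, str], int] = {}
        for i, (r, a) in enumerate(zip(self.res_ids, self.atom_names)):
            key = (int(r), str(a))
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in model")
            self._index[key] = i

    # -- lookups ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    @property
    def residues(self) -> list[tuple[int, str]]:
        """Ordered (position, code) list."""
        seen: dict[int, str] = {}
        for r, c in zip(self.res_ids, self.res_codes):
            seen.setdefault(int(r), str(c))
        return sorted(seen.items())

    def residue_code(self, res_id: int) -> str:
        for r, c in self.residues:
            if r == res_id:
                return c
        raise KeyError(f"residue {res_id} not in model")

    def index(self, res_id: int, atom_name: str) -> int:
        try:
            return self._index[(int(res_id), atom_name)]
        except KeyError:
            raise KeyError(f"atom ({res_id}, {atom_name}) not in model") from None

    def has_atom(self, res_id: int, atom_name: str) -> bool:
        return (int(res_id), atom_name) in self._index

    def pos(self, res_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.index(res_id, atom_name)]

    def atom_indices(self, res_id: int) -> np.ndarray:
        return np.nonzero(self.res_ids == res_id)[0]

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        m = replace(self, coords=np.asarray(coords, dtype=float))
        if model_id is not None:
            m.model_id = model_id
        return m

    def same_atoms_as(self, other: "StructureModel") -> bool:
        return (
            len(self.res_ids) == len(other.res_ids)
            and np.array_equal(self.res_ids, other.res_ids)
            and all(a == b for a, b in zip(self.atom_names, other.atom_names))
        )


def build_extended_model(sequence_residues: list[tuple[int, str]]) -> StructureModel:
    """Assemble template residues along x into an arbitrary extended chain.

    Used as the atom-bookkeeping skeleton (the coordinates are placeholders
    for embedding / generation to overwrite).
    """
    res_ids, codes, names, elems, coords = [], [], [], [], []
    x0 = 0.0
    for k, (rid, code) in enumerate(sequence_residues):
        tmpl = get_template(code, five_prime=(k == 0))
        c = tmpl.coords - tmpl.coords.mean(axis=0)
        c = c + np.array([x0, 0.0, 0.0])
        x0 += 6.5
        for i in range(tmpl.n_atoms):
            res_ids.append(rid)
            codes.append(code)
            names.append(tmpl.atom_names[i])
            elems.append(tmpl.elements[i])
            coords.append(c[i])
    return StructureModel(
        res_ids=np.array(res_ids),
        res_codes=np.array(codes, dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elems, dtype=object),
        coords=np.array(coords),
    )


@dataclass
class Ensemble:
    """Ordered collection of models sharing one atom set."""

    models: list[StructureModel]
    energies: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.models:
            first = self.models[0]
            for m in self.models[1:]:
                if not m.same_atoms_as(first):
                    raise ValueError("ensemble models have mismatching atom sets")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]
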