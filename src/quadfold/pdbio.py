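"""Multi-MODEL PDB reading/writing for quadruplex ensembles.

Reading goes through gemmi (tolerant of deposited files); writing is
fixed-width PDB v3 with REMARK lines recording per-model energy and seed
provenance.  Primes are normalised to ASCII apostrophes (O4* -> O4').
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import Ensemble, StructureModel

PDB_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU", "I": "DI"}
CODE_FROM_PDB = {v: k for k, v in PDB_RESNAME.items()}
CODE_FROM_PDB.update({"ADE": "A", "GUA": "G", "CYT": "C", "THY": "T", "URA": "U"})


class PdbFormatError(ValueError):
    pass


def _norm_atom_name(name: str) -> str:
    return name.replace("*", "'").strip()


def read_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an Ensemble."""
    import gemmi

    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise PdbFormatError(f"empty or missing PDB file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise PdbFormatError(f"cannot parse {path}: {e}") from None
    models = []
    for mi, gm in enumerate(st, start=1):
        res_ids, codes, names, elems, coords = [], [], [], [], []
        for chain in gm:
            for res in chain:
                code = CODE_FROM_PDB.get(res.name.strip(), None)
                if code is None:
                    code = res.name.strip()[-1]
                for atom in res:
                    res_ids.append(res.seqid.num)
                    codes.append(code)
                    names.append(_norm_atom_name(atom.name))
                    elems.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if res_ids:
            models.append(
                StructureModel(
                    res_ids=np.array(res_ids),
                    res_codes=np.array(codes, dtype=object),
                    atom_names=np.array(names, dtype=object),
                    elements=np.array(elems, dtype=object),
                    coords=np.array(coords),
                    model_id=mi,
                )
            )
    if not models:
        raise PdbFormatError(f"no coordinates found in {path}")
    return Ensemble(models=models)


def _atom_record(serial, name, resname, chain, resid, x, y, z, element) -> str:
    for v in (x, y, z):
        if abs(v) >= 10000.0:
            raise PdbFormatError(
                f"coordinate {v:.3f} exceeds the PDB fixed-width limit (+/-9999.999)"
            )
    # PDB v3 alignment: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def write_pdb(
    ensemble: Ensemble | StructureModel,
    path: str | Path,
    model_wrappers: bool | None = None,
    remarks: list[str] | None = None,
) -> None:
    """Write an ensemble (or a single model) as fixed-width PDB v3.

    ``model_wrappers=None`` wraps in MODEL/ENDMDL records only when more
    than one model is present.
    """
    if isinstance(ensemble, StructureModel):
        ensemble = Ensemble(models=[ensemble])
    if model_wrappers is None:
        model_wrappers = len(ensemble) > 1
    lines = []
    for r in remarks or []:
        lines.append(f"REMARK   3 {r}")
    for i, m in enumerate(ensemble):
        if ensemble.energies and i < len(ensemble.energies):
            seed = ensemble.seeds[i] if i < len(ensemble.seeds) else "-"
            lines.append(
                f"REMARK   3 MODEL {i + 1} ENERGY {ensemble.energies[i]:.3f} SEED {seed}"
            )
    for i, m in enumerate(ensemble):
        if model_wrappers:
            lines.append(f"MODEL     {i + 1:4d}")
        serial = 1
        last_res = None
        for j in range(m.n_atoms):
            resid = int(m.res_ids[j])
            code = str(m.res_codes[j])
            lines.append(
                _atom_record(
                    serial,
                    str(m.atom_names[j]),
                    PDB_RESNAME.get(code, code),
                    "A",
                    resid,
                    *map(float, m.coords[j]),
                    str(m.elements[j]),
                )
            )
            serial += 1
            last_res = (code, resid)
        lines.append(
            f"TER   {serial:5d}      {PDB_RESNAME.get(last_res[0], last_res[0]):>3s} "
            f"A{last_res[1]:4d}"
        )
        if model_wrappers:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
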