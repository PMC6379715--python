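"""End-to-end workflows.

``run_structure_pipeline`` stitches restraint compilation, ensemble
folding, validation and topology re-derivation into one reproducible run
directory.  ``compare_variants`` reproduces the substitution logic used
to probe capping pairs: a variant keeps a declared pair only if every
donor/acceptor atom of its hydrogen bonds still exists in the substituted
residue templates (inosine, for instance, lacks the N2 amino donor).
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .fold_engine import AnnealingSchedule, StructureCalculation
from .sequences import Sequence
from .templates import get_template
from .topology import CappingElement, QuadruplexTopology, build_topology, parse_topology_text

log = logging.getLogger(__name__)


def run_structure_pipeline(
    topology_file: str | Path,
    peaks_file: str | Path,
    out_dir: str | Path,
    n_start: int = 100,
    n_keep: int = 10,
    schedule: AnnealingSchedule | None = None,
    absent_contacts=(),
    seed: int = 0,
    rigid_steps: int = 30000,
    convergence_max_violations: int | None = 120,
):
    """topology + peaks -> restraints -> ensemble -> validation report.

    Writes ensemble.pdb, report.txt, derived_topology.txt and a manifest
    with provenance into ``out_dir`` and returns the FoldResults.
    """
    from .noe import read_peaks
    from .pdbio import write_pdb
    from .restraints import assemble
    from .structure_analysis import classify_structure, fold_class

    topology_file = Path(topology_file)
    peaks_file = Path(peaks_file)
    for f in (topology_file, peaks_file):
        if not f.exists():
            raise FileNotFoundError(f"pipeline input missing: {f}")
    top = QuadruplexTopology.from_text(topology_file.read_text())
    peaks = read_peaks(peaks_file)
    try:
        rs = assemble(top, peaks=peaks, absent_contacts=absent_contacts)
    except Exception as e:
        raise RuntimeError(f"restraint compilation failed: {e}") from e
    calc = StructureCalculation(top.sequence, rs, schedule=schedule)
    results = calc.fit(n_start=n_start, n_keep=n_keep, seed=seed,
                       rigid_steps=rigid_steps,
                       convergence_max_violations=convergence_max_violations)
    try:
        derived = classify_structure(results.best_model)
        derived_text = f"# fold class: {fold_class(derived)}\n" + derived.to_text()
        derived_class = fold_class(derived)
    except Exception as e:  # noqa: BLE001 - classification of a poor fold may fail
        log.warning("topology re-derivation failed: %s", e)
        derived_text = f"# fold class: undetermined ({e})\n"
        derived_class = "undetermined"

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pdb(results.ensemble, out / "ensemble.pdb")
    (out / "report.txt").write_text(results.summary() + "\n")
    (out / "derived_topology.txt").write_text(derived_text)
    manifest = {
        "seed": seed,
        "n_start": n_start,
        "n_keep": n_keep,
        "topology_sha1": hashlib.sha1(topology_file.read_bytes()).hexdigest(),
        "peaks_sha1": hashlib.sha1(peaks_file.read_bytes()).hexdigest(),
        "restraint_counts": rs.counts(),
        "energies": results.energies,
        "fold_class": derived_class,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------

#: known alternative capping pairs by (partner codes): Hoogsteen T.A
ALTERNATIVE_PAIRS = {
    ("T", "A"): (
        "hoogsteen",
        lambda pa, pb: (
            ((pa, "H3"), (pb, "N7")),
            ((pb, "H62"), (pa, "O4")),
        ),
    ),
}


@dataclass
class PairPrediction:
    partners: tuple[int, ...]
    codes: tuple[str, ...]
    mode: str
    feasible: bool
    missing: list[str] = field(default_factory=list)
    note: str = ""


@dataclass
class VariantReport:
    substitutions: dict[int, str]
    sequence: str
    pairs: list[PairPrediction]
    broken_fold: bool = False


def _bond_feasible(seq: Sequence, bond) -> tuple[bool, list[str]]:
    missing = []
    for pos, atom in (bond.donor, bond.acceptor):
        tmpl = get_template(seq[pos], five_prime=(pos == 1))
        if not tmpl.has_atom(atom):
            missing.append(f"{seq[pos]}{pos}:{atom}")
    return not missing, missing


def compare_variants(
    base: QuadruplexTopology, substitutions_list: list[dict[int, str]]
) -> list[VariantReport]:
    """Predict which capping pairs survive each substitution set.

    This is donor/acceptor feasibility analysis on the residue templates,
    not re-folding.  A substitution at a tetrad position triggers a
    warning: the fold itself is then assumed broken, outside this model.
    """
    reports = []
    tet = set(base.tetrad_positions)
    for subs in substitutions_list:
        residues = list(base.sequence.residues)
        broken = False
        for pos, code in subs.items():
            if pos in tet:
                warnings.warn(
                    f"substitution {code}{pos} hits a tetrad guanine; "
                    "fold assumed broken", stacklevel=2,
                )
                broken = True
            residues[pos - 1] = code
        seq = Sequence(base.sequence.id + "-" + "".join(
            f"{c}{p}" for p, c in sorted(subs.items())), "".join(residues))
        pairs = []
        for cap in base.capping:
            if cap.mode == "ambiguous":
                continue
            partners = cap.partners[:2]
            codes = tuple(seq[p] for p in partners)
            missing_all: list[str] = []
            ok = True
            for hb in cap.bonds:
                good, missing = _bond_feasible(seq, hb)
                ok = ok and good
                missing_all.extend(missing)
            if ok:
                pairs.append(
                    PairPrediction(partners=partners, codes=codes, mode=cap.mode,
                                   feasible=True)
                )
                continue
            # the declared pair is lost; look for a known alternative
            alt = ALTERNATIVE_PAIRS.get(codes) or ALTERNATIVE_PAIRS.get(codes[::-1])
            if alt is not None:
                mode, make = alt
                a, b = partners if codes in ALTERNATIVE_PAIRS else partners[::-1]
                bonds = make(a, b)
                feasible = all(
                    get_template(seq[p], five_prime=(p == 1)).has_atom(at)
                    for p, at in [x for bond in bonds for x in bond]
                )
                pairs.append(
                    PairPrediction(
                        partners=partners, codes=codes, mode=mode, feasible=feasible,
                        note="alternative pairing predicted for substituted bases",
                    )
                )
            else:
                pairs.append(
                    PairPrediction(partners=partners, codes=codes, mode=cap.mode,
                                   feasible=False, missing=missing_all)
                )
        reports.append(
            VariantReport(substitutions=dict(subs), sequence=seq.residues,
                          pairs=pairs, broken_fold=broken)
        )
    return reports
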