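"""PDB reading and writing for multi-model duplex structures.

Reading goes through Biopython's strict PDB parser and converts to the
package's :class:`~duplexlens.structures.Structure` container, renumbering
residues 1-based per chain (the convention used throughout the analysis
modules).  Writing emits fixed-width PDB 3.3 records with MODEL/ENDMDL
delimiters; 8-oxoguanine residues are written as HETATM records under the
chemical-component code 8OG.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from duplexlens.errors import ParseError
from duplexlens.structures import Atom, Residue, Structure, normalize_nomenclature

__all__ = ["read_structure", "write_structure"]

_STANDARD_NUC = {"DA", "DC", "DG", "DT"}


def read_structure(path: str | Path, format: str = "pdb",
                   normalize: bool = True, ignore_unknown: bool = True) -> Structure:
    """Read a (multi-model) PDB file into a Structure.

    MODEL/ENDMDL records delimit coordinate frames; a file without MODEL
    records yields a single-model Structure.  Residues are renumbered
    1-based per chain in file order.  For altloc-disordered atoms the first
    conformer (altloc A or blank) is kept and a warning is issued.

    Raises
    ------
    ParseError
        If the file is missing or a record is malformed (the underlying
        parser's message names the offending line).
    TopologyError
        If models disagree in atom names or order.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as e:
        raise ParseError(f"{path}: {e}") from e
    models = []
    for bio_model in bio:
        model = {}
        for bio_chain in bio_model:
            residues = []
            for k, bio_res in enumerate(bio_chain, start=1):
                atoms = []
                for bio_atom in bio_res:
                    if bio_atom.is_disordered():
                        alt = bio_atom.disordered_get_id_list()
                        keep = "A" if "A" in alt else alt[0]
                        warnings.warn(
                            f"{path.name}: keeping altloc {keep} of atom "
                            f"{bio_atom.get_id()} in {bio_res.get_resname()}"
                        )
                        bio_atom = bio_atom.disordered_get(keep)
                    element = (bio_atom.element or "").strip() or bio_atom.get_id()[0]
                    atoms.append(Atom(bio_atom.get_id(), element, np.asarray(bio_atom.coord, float)))
                residues.append(Residue(k, bio_res.get_resname().strip(), atoms))
            if residues:
                model[bio_chain.id] = residues
        models.append(model)
    if not models:
        raise ParseError(f"{path}: no models found")
    s = Structure(models, meta=f"read from {path.name}")
    if normalize:
        s = normalize_nomenclature(s, ignore_unknown=ignore_unknown)
    return s


def _pdb_atom_name(name: str) -> str:
    """Column-align an atom name into the 4-character PDB field."""
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB 3.3 with one MODEL per frame."""
    path = Path(path)
    lines = []
    if s.meta:
        lines.append(f"REMARK   6 {s.meta[:68]}")
    multi = s.n_models > 1
    for im in range(s.n_models):
        if multi:
            lines.append(f"MODEL     {im + 1:4d}")
        serial = 1
        for cid, residues in s.models[im].items():
            for r in residues:
                record = "ATOM  " if r.code in _STANDARD_NUC else "HETATM"
                for a in r.atoms:
                    x, y, z = a.xyz
                    lines.append(
                        f"{record}{serial:5d} {_pdb_atom_name(a.name)} "
                        f"{r.code:>3s} {cid[0]}{r.index:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {a.element:>2s}"
                    )
                    serial += 1
            last = residues[-1]
            lines.append(
                f"TER   {serial:5d}      {last.code:>3s} {cid[0]}{last.index:4d}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
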