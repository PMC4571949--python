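"""Chromophore-pocket geometry from protein coordinates.

Two reports on a coordinate file containing a lysine-bound retinal
chromophore: (i) the residues whose minimum heavy-atom distance to any
chromophore atom falls within a cutoff (the binding-pocket neighborhood),
and (ii) for a stated list of candidate counterion residues, the minimum
distance from each residue's side-chain oxygen atoms to the chromophore's
Schiff-base nitrogen, ranked ascending — the quantity that decides which
acidic residue could plausibly stabilize the protonated Schiff base.

Coordinates are parsed with biotite (fixed-column PDB, first model,
first-listed altloc); hydrogens are excluded by default since model and
crystal structures disagree on their placement.
"""

from __future__ import annotations

from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "load_structure",
    "save_structure",
    "residues_within_cutoff",
    "schiff_base_distances",
    "ChromophoreNotFoundError",
]

#: side-chain oxygen atom names by standard PDB conventions (backbone O/OXT excluded)
SIDE_CHAIN_OXYGENS = {"OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH"}


class ChromophoreNotFoundError(ValueError):
    """The chromophore selector matched no atoms."""


def load_structure(path: str | Path) -> struc.AtomArray:
    """Read a PDB file: first model, first altloc."""
    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    if not np.all(np.isfinite(atoms.coord)):
        raise ValueError(f"{path}: non-finite coordinates")
    return atoms


def save_structure(atoms: struc.AtomArray, path: str | Path) -> None:
    pdb = pdbio.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def _chromophore_mask(atoms: struc.AtomArray, selector) -> np.ndarray:
    """Boolean mask of chromophore atoms.

    ``selector`` may be a residue name ("LYR"), a residue number, or
    "NAME:NUMBER".
    """
    if isinstance(selector, int):
        mask = atoms.res_id == selector
    else:
        sel = str(selector)
        if ":" in sel:
            name, num = sel.split(":", 1)
            mask = (atoms.res_name == name.upper()) & (atoms.res_id == int(num))
        else:
            mask = atoms.res_name == sel.upper()
    if not mask.any():
        raise ChromophoreNotFoundError(f"chromophore selector {selector!r} matched nothing")
    return mask


def _heavy(atoms: struc.AtomArray) -> np.ndarray:
    return atoms.element != "H"


def _residue_id(atoms: struc.AtomArray, i: int) -> tuple:
    ins = getattr(atoms, "ins_code", None)
    code = str(ins[i]) if ins is not None else ""
    return (str(atoms.chain_id[i]), int(atoms.res_id[i]), code)


def residues_within_cutoff(
    atoms: struc.AtomArray,
    chromophore_selector,
    cutoff: float,
    include_hydrogens: bool = False,
) -> list[tuple[tuple, str, float]]:
    """Residues whose closest atom lies within ``cutoff`` Å of the chromophore.

    Returns ``[((chain, resnum, inscode), resname, min distance), ...]``
    sorted ascending by distance; the chromophore-bearing residue itself
    is excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    chrom = _chromophore_mask(atoms, chromophore_selector)
    keep = np.ones(len(atoms), dtype=bool) if include_hydrogens else _heavy(atoms)
    chrom_xyz = atoms.coord[chrom & keep]
    out = {}
    others = np.nonzero(~chrom & keep)[0]
    if others.size:
        dmat = cdist(atoms.coord[others], chrom_xyz)
        dmin_per_atom = dmat.min(axis=1)
        for idx, dmin in zip(others, dmin_per_atom):
            rid = _residue_id(atoms, idx)
            key = (rid, str(atoms.res_name[idx]))
            if key not in out or dmin < out[key]:
                out[key] = float(dmin)
    hits = [(rid, rn, d) for (rid, rn), d in out.items() if d <= cutoff]
    hits.sort(key=lambda t: (t[2], t[0]))
    return hits


def schiff_base_distances(
    atoms: struc.AtomArray,
    chromophore_selector,
    nitrogen_atom_name: str,
    residue_list: list[int],
) -> list[tuple[int, str, float | None]]:
    """Ranked side-chain-oxygen → Schiff-base-nitrogen distances.

    For each residue number in ``residue_list``, the minimum distance from
    its side-chain oxygen atoms to the named nitrogen atom of the
    chromophore residue.  Residues without a side-chain oxygen are flagged
    with ``None`` and sorted last.  Returns
    ``[(resnum, resname, distance-or-None), ...]``.
    """
    chrom = _chromophore_mask(atoms, chromophore_selector)
    nmask = chrom & (atoms.atom_name == nitrogen_atom_name)
    if not nmask.any():
        raise ChromophoreNotFoundError(
            f"nitrogen atom {nitrogen_atom_name!r} absent from chromophore residue"
        )
    n_xyz = atoms.coord[nmask][0]
    results: list[tuple[int, str, float | None]] = []
    for resnum in residue_list:
        rmask = (atoms.res_id == resnum) & ~chrom
        if not rmask.any():
            raise ValueError(f"residue {resnum} not found in structure")
        resname = str(atoms.res_name[np.nonzero(rmask)[0][0]])
        omask = rmask & np.isin(atoms.atom_name, sorted(SIDE_CHAIN_OXYGENS))
        if not omask.any():
            results.append((resnum, resname, None))
            continue
        d = np.linalg.norm(atoms.coord[omask] - n_xyz, axis=1).min()
        results.append((resnum, resname, float(d)))
    results.sort(key=lambda t: (t[2] is None, t[2] if t[2] is not None else 0.0, t[0]))
    return results
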