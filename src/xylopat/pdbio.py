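"""PDB reading/writing for built conformations and posed systems (biotite)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

from .cellulose import PosedSystem
from .helix import Conformation
from .residues3d import Atom

__all__ = ["conformation_to_atom_array", "write_pdb", "read_pdb", "write_posed_pdb"]

_RES_NAME = {"xylose": "XYL", "glucose": "GLC"}
_KIND = {v: k for k, v in _RES_NAME.items()}


def conformation_to_atom_array(conf: Conformation) -> bts.AtomArray:
    n = len(conf.atoms)
    arr = bts.AtomArray(n)
    arr.coord = conf.coords().astype(np.float32)
    arr.chain_id = np.array([conf.chain_id[:1] or "X"] * n)  # PDB: 1 char
    arr.res_id = np.array([a.residue_index for a in conf.atoms])
    arr.res_name = np.array([_RES_NAME.get(conf.kind, "UNK")] * n)
    arr.atom_name = np.array([a.name for a in conf.atoms])
    arr.element = np.array([a.element for a in conf.atoms])
    arr.hetero = np.full(n, True)
    return arr


def _conf_from_array(arr: bts.AtomArray, chain_id: str) -> Conformation:
    mask = arr.chain_id == chain_id
    sub = arr[mask]
    atoms = [
        Atom(
            name=str(sub.atom_name[i]),
            element=str(sub.element[i]),
            residue_index=int(sub.res_id[i]),
            xyz=np.asarray(sub.coord[i], dtype=float),
        )
        for i in range(sub.array_length())
    ]
    dp = max(a.residue_index for a in atoms)
    linkages = [(i, i + 1) for i in range(1, dp)]
    kind = _KIND.get(str(sub.res_name[0]), "xylose")
    return Conformation(atoms=atoms, linkages=linkages, chain_id=chain_id, kind=kind)


def write_pdb(conf: Conformation, path: Union[str, Path]) -> None:
    pdb = PDBFile()
    pdb.set_structure(conformation_to_atom_array(conf))
    pdb.write(str(path))


def write_posed_pdb(posed: PosedSystem, path: Union[str, Path]) -> None:
    """One PDB with the xylan chain plus every cellulose chain.

    Chain identifiers are remapped to single letters (xylan = X, cellulose =
    A, B, ...) to fit the PDB chain-id column.
    """
    arrays = [conformation_to_atom_array(posed.xylan)]
    arrays[0].chain_id[:] = "X"
    letters = "ABCDEFGHIJKLMNOPQRSTUVWYZ"
    for i, ch in enumerate(posed.cellulose):
        a = conformation_to_atom_array(ch)
        a.chain_id[:] = letters[i % len(letters)]
        arrays.append(a)
    merged = arrays[0]
    for a in arrays[1:]:
        merged += a
    pdb = PDBFile()
    pdb.set_structure(merged)
    pdb.write(str(path))


def read_pdb(path: Union[str, Path]) -> list[Conformation]:
    """Read every chain of a PDB file back into Conformation objects."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    return [
        _conf_from_array(arr, cid) for cid in np.unique(arr.chain_id)
    ]
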