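"""Spatial proximity of basic residues to cysteine thiols in 3D structures.

Basic side chains (Arg, Lys, His) near a cysteine thiol stabilise the
thiolate anion and lower the cysteine's pKa, so the distance from each Cys SG
atom to the nearest basic side-chain nitrogen is the structural counterpart of
the sequence-level basic-flank scan.  The default metric measures SG to the
charge-carrying nitrogens (Arg NE/NH1/NH2; Lys NZ; His ND1/NE2), matching how
such contacts are conventionally quoted (e.g. guanidinium-to-thiol); an
all-atom minimum-distance mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: Side-chain nitrogen atoms carrying the basic charge, per residue type.
BASIC_SIDECHAIN_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}


@dataclass
class StructureModel:
    """Atoms of one structural model (coordinates in Angstroms)."""

    chain: np.ndarray      # str per atom
    res_number: np.ndarray  # int per atom
    res_name: np.ndarray   # str per atom (3-letter)
    atom_name: np.ndarray  # str per atom
    element: np.ndarray    # str per atom
    coords: np.ndarray     # (n, 3) float
    model_number: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.res_number)

    def chains(self) -> list[str]:
        return sorted(set(self.chain.tolist()))


def _check_coordinate_fields(path: str | Path) -> None:
    """Pre-scan ATOM records so coordinate errors carry a line number."""
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n_atoms += 1
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise ValueError(
                        f"{path} line {lineno}: malformed coordinate field {fld!r}"
                    ) from None
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM records")


def read_structure(path: str | Path, *, include_hetero: bool = False) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Only the first model is read; alternate locations are resolved to the
    highest-occupancy conformer; HETATM records are ignored by default.
    Raises if the file has no ATOM records or a malformed coordinate field
    (reported with its line number).
    """
    _check_coordinate_fields(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    model = StructureModel(
        chain=atoms.chain_id.astype(str),
        res_number=atoms.res_id.astype(int),
        res_name=atoms.res_name.astype(str),
        atom_name=atoms.atom_name.astype(str),
        element=atoms.element.astype(str),
        coords=np.asarray(atoms.coord, dtype=float),
    )
    keys = set()
    for ch, rn, an in zip(model.chain, model.res_number, model.atom_name):
        key = (ch, int(rn), an)
        if key in keys:
            logger.warning("duplicate atom %s; keeping first occurrence", key)
        keys.add(key)
    return model


def cys_basic_proximity(
    model: StructureModel,
    chain: str,
    cutoff: float = 8.0,
    metric: str = "basic-N",
) -> dict[int, list[tuple[str, int, float]]]:
    """Basic residues near each cysteine thiol of a chain.

    For every Cys residue with an SG atom, the distance to each His/Lys/Arg
    residue of the chain is the minimum over that residue's basic side-chain
    nitrogens (``metric="basic-N"``) or over all its atoms
    (``metric="all-atom"``).  Residues within ``cutoff`` Angstroms are
    returned per cysteine, sorted by ascending distance.  Cysteines lacking an
    SG atom are skipped with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if metric not in ("basic-N", "all-atom"):
        raise ValueError(f"unknown metric {metric!r}")
    in_chain = model.chain == chain
    if not np.any(in_chain):
        raise ValueError(f"chain {chain!r} not present (have {model.chains()})")

    cys_mask = in_chain & (model.res_name == "CYS")
    cys_residues = sorted(set(model.res_number[cys_mask].tolist()))

    basic_atoms: dict[tuple[str, int], np.ndarray] = {}
    for res3, atom_names in BASIC_SIDECHAIN_ATOMS.items():
        res_mask = in_chain & (model.res_name == res3)
        for rn in sorted(set(model.res_number[res_mask].tolist())):
            sel = res_mask & (model.res_number == rn)
            if metric == "basic-N":
                sel = sel & np.isin(model.atom_name, atom_names)
            if np.any(sel):
                basic_atoms[(res3, rn)] = model.coords[sel]

    out: dict[int, list[tuple[str, int, float]]] = {}
    for rn in cys_residues:
        sg = cys_mask & (model.res_number == rn) & (model.atom_name == "SG")
        if not np.any(sg):
            logger.warning("chain %s Cys %d lacks an SG atom; skipped", chain, rn)
            continue
        sg_xyz = model.coords[sg][0]
        neighbors = []
        for (res3, brn), xyz in basic_atoms.items():
            d = float(np.sqrt(((xyz - sg_xyz) ** 2).sum(axis=1)).min())
            if d <= cutoff:
                neighbors.append((res3, brn, d))
        neighbors.sort(key=lambda t: (t[2], t[1]))
        out[rn] = neighbors
    return out
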