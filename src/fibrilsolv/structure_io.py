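"""Reading, writing and slicing of fibril atomic models.

The package-wide structure representation is :class:`FibrilModel`: a flat,
ordered list of :class:`AtomRecord` objects with chain-level layer and
protofilament annotations.  Author residue numbering is authoritative
everywhere; no renumbering ever happens, and all residue intervals are
closed on both ends.

Parsing of PDB and mmCIF files is delegated to :mod:`biotite`; the model is
converted to a plain record list so that downstream numerics never depend on
the reader.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as _struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

__all__ = [
    "AtomRecord",
    "FibrilModel",
    "StructureFormatError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "resolve_altlocs",
    "select_segment",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or is empty."""


class SelectionError(KeyError):
    """Raised when a chain/residue selection matches nothing."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or hydrogen) atom with author numbering.

    ``coords`` is a length-3 tuple in Å; it is kept immutable so records can
    be shared freely between derived models.
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coords, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates {self.coords}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def moved_to(self, xyz) -> "AtomRecord":
        x, y, z = (float(v) for v in xyz)
        return replace(self, coords=(x, y, z))


@dataclass
class FibrilModel:
    """Ordered collection of atoms grouped implicitly by chain and residue."""

    atoms: list[AtomRecord] = field(default_factory=list)
    label: str = ""
    layer_of_chain: dict[str, int] = field(default_factory=dict)
    protofilament_of_chain: dict[str, int] = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> "FibrilModel":
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        if not atoms:
            raise SelectionError(f"chain {chain_id!r} not present (have {self.chain_ids()})")
        return FibrilModel(
            atoms,
            label=self.label,
            layer_of_chain=_subset(self.layer_of_chain, {chain_id}),
            protofilament_of_chain=_subset(self.protofilament_of_chain, {chain_id}),
        )

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str, list[AtomRecord]]]:
        """Residues in file order as ``(chain_id, res_seq, res_name, atoms)``."""
        groups: dict[tuple[str, int], list[AtomRecord]] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            groups.setdefault((a.chain_id, a.res_seq), []).append(a)
        return [(c, s, atoms[0].res_name, atoms) for (c, s), atoms in groups.items()]

    def n_residues(self, chain_id: str | None = None) -> int:
        return len(self.residues(chain_id))

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    # -- derived models ----------------------------------------------------

    def with_atoms(self, atoms: list[AtomRecord]) -> "FibrilModel":
        chains = {a.chain_id for a in atoms}
        return FibrilModel(
            list(atoms),
            label=self.label,
            layer_of_chain=_subset(self.layer_of_chain, chains),
            protofilament_of_chain=_subset(self.protofilament_of_chain, chains),
        )

    def without_hydrogens(self) -> "FibrilModel":
        return self.with_atoms([a for a in self.atoms if not a.is_hydrogen])

    def without_heteroatoms(self) -> "FibrilModel":
        return self.with_atoms([a for a in self.atoms if not a.is_hetero])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FibrilModel":
        """Rigid motion ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_xyz = self.coords() @ R.T + t
        atoms = [a.moved_to(xyz) for a, xyz in zip(self.atoms, new_xyz)]
        return FibrilModel(
            atoms,
            label=self.label,
            layer_of_chain=dict(self.layer_of_chain),
            protofilament_of_chain=dict(self.protofilament_of_chain),
        )

    def validate(self) -> None:
        """Check model invariants; raises ``ValueError`` on violation."""
        for cid in self.chain_ids():
            seqs = [s for _, s, _, _ in self.residues(cid)]
            if any(b <= a for a, b in zip(seqs, seqs[1:])):
                raise ValueError(f"chain {cid}: residue numbers not strictly increasing: {seqs}")
        for cid, _layer in self.layer_of_chain.items():
            if cid not in self.protofilament_of_chain:
                raise ValueError(f"chain {cid} has a layer index but no protofilament index")


def _subset(mapping: dict[str, int], keys) -> dict[str, int]:
    return {k: v for k, v in mapping.items() if k in keys}


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _detect_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    raise StructureFormatError(f"cannot infer format from extension {ext!r} of {path}")


def read_structure(path, format: str = "auto") -> FibrilModel:
    """Read a PDB or mmCIF file into a :class:`FibrilModel`.

    All ATOM records are loaded; HETATM records are loaded with
    ``is_hetero`` set.  Hydrogens are retained (drop them explicitly with
    :meth:`FibrilModel.without_hydrogens` before any area computation).
    Alternate locations are all kept; resolve with :func:`resolve_altlocs`.
    """
    path = str(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        if format == "pdb":
            f = _pdb.PDBFile.read(path)
            arr = f.get_structure(model=1, altloc="all", extra_fields=["atom_id", "occupancy"])
        else:
            f = _pdbx.CIFFile.read(path)
            arr = _pdbx.get_structure(
                f, model=1, altloc="all", use_author_fields=True,
                extra_fields=["atom_id", "occupancy"],
            )
    except Exception as exc:  # biotite raises a mix of exception types
        raise StructureFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureFormatError(f"{path}: file parsed but contains no atoms")
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                alt_loc=str(arr.altloc_id[i]).strip(),
                res_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                res_seq=int(arr.res_id[i]),
                coords=tuple(float(v) for v in arr.coord[i]),
                occupancy=float(min(1.0, max(0.0, arr.occupancy[i]))),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return FibrilModel(atoms, label=os.path.splitext(os.path.basename(path))[0])


def _to_atom_array(model: FibrilModel) -> _struc.AtomArray:
    n = model.n_atoms
    arr = _struc.AtomArray(n)
    arr.coord = model.coords().astype(np.float32)
    arr.set_annotation("chain_id", np.array([a.chain_id for a in model.atoms], dtype="U4"))
    arr.set_annotation("res_id", np.array([a.res_seq for a in model.atoms], dtype=int))
    arr.set_annotation("res_name", np.array([a.res_name for a in model.atoms], dtype="U5"))
    arr.set_annotation("atom_name", np.array([a.name for a in model.atoms], dtype="U6"))
    arr.set_annotation("element", np.array([a.element for a in model.atoms], dtype="U2"))
    arr.set_annotation("hetero", np.array([a.is_hetero for a in model.atoms], dtype=bool))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms], dtype=float))
    arr.set_annotation("altloc_id", np.array([a.alt_loc or " " for a in model.atoms], dtype="U1"))
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("ins_code", np.array([""] * n, dtype="U1"))
    return arr


def write_structure(model: FibrilModel, path) -> None:
    """Write the model as a PDB file (coordinates rounded to 1e-3 Å)."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    f = _pdb.PDBFile()
    f.set_structure(_to_atom_array(model))
    f.write(str(path))


def resolve_altlocs(model: FibrilModel, policy: str = "first_conformer") -> FibrilModel:
    """Keep at most one atom per (chain, res_seq, atom name).

    ``first_conformer`` keeps the alphabetically first alternate location id;
    ``highest_occupancy`` keeps the highest-occupancy one (ties broken
    alphabetically).  Atoms without an altloc id pass through unchanged.
    Deterministic; a model without altlocs is returned as an equal copy.
    """
    if policy not in ("first_conformer", "highest_occupancy"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    for a in model.atoms:
        key = (a.chain_id, a.res_seq, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
            continue
        cur = best[key]
        if policy == "first_conformer":
            if (a.alt_loc or "~") < (cur.alt_loc or "~"):
                best[key] = a
        else:
            if (a.occupancy, -_ord(a.alt_loc)) > (cur.occupancy, -_ord(cur.alt_loc)):
                best[key] = a
    return model.with_atoms([best[k] for k in order])


def _ord(alt_loc: str) -> int:
    return ord(alt_loc) if alt_loc else 0x7F


def select_segment(
    model: FibrilModel,
    chain_id: str,
    start_res: int,
    end_res: int,
    atom_filter="all",
) -> FibrilModel:
    """Closed residue interval ``[start_res, end_res]`` on author numbering.

    ``atom_filter`` is either the string ``"all"`` or a set of atom names
    (e.g. ``{"CA"}``).  File order is preserved.
    """
    if start_res > end_res:
        raise ValueError(f"start_res {start_res} > end_res {end_res}")
    if all(a.chain_id != chain_id for a in model.atoms):
        raise SelectionError(f"chain {chain_id!r} not present (have {model.chain_ids()})")
    names = None if atom_filter == "all" else set(atom_filter)
    atoms = [
        a
        for a in model.atoms
        if a.chain_id == chain_id
        and start_res <= a.res_seq <= end_res
        and (names is None or a.name in names)
    ]
    if not atoms:
        raise SelectionError(
            f"selection {chain_id}:{start_res}-{end_res} (atoms={atom_filter!r}) matched no atoms"
        )
    return model.with_atoms(atoms)
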