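"""Registry and evaluation helpers for the analyzed deposited fibril models.

The four published tau-fibril structures the analysis targets are identified
by their PDB accessions.  Coordinate files are NOT bundled: place
``<accession>.cif`` (or ``.pdb``) under ``data/structures/`` — e.g. from
``https://files.rcsb.org/download/9O8E.cif`` — and the helpers here prepare
the stack (altloc resolution, hydrogen/heteroatom removal, expansion to at
least three layers when only a single layer is deposited) and evaluate the
central-chain energetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import FibrilModel, read_structure, resolve_altlocs
from .fibril_geometry import (
    AxisFrame, HelicalParams, apply_helical_symmetry, central_chain_ids,
)
from .surface_area import buried_areas
from .solvation_energetics import (
    AspTable, apply_charge_compensation, builtin_compensation_specs,
    chain_summary, residue_energies,
)

__all__ = ["DepositedStructure", "REGISTRY", "find_structure", "load_stack",
           "evaluate_energy"]

DEFAULT_SEARCH_DIRS = ("data/structures", "structures")


@dataclass(frozen=True)
class DepositedStructure:
    accession: str
    core: tuple[int, int]  # author-numbered ordered-core span (closed)
    rise: float | None = None  # published helical parameters, if analyzed here
    twist: float | None = None
    compensation: str | None = None  # builtin spec name
    paired: bool = False


REGISTRY = {
    "9o8e": DepositedStructure("9o8e", core=(341, 449), rise=4.839, twist=-1.03,
                               compensation="9o8e"),
    "9o8h": DepositedStructure("9o8h", core=(273, 341), rise=2.39525, twist=179.634,
                               compensation="9o8h", paired=True),
    "7sp1": DepositedStructure("7sp1", core=(391, 426), compensation="7sp1",
                               paired=True),
    "5o3l": DepositedStructure("5o3l", core=(306, 378), paired=True),
}


def find_structure(accession: str, search_dirs=None) -> Path | None:
    """Locate a local coordinate file for an accession, or None."""
    acc = accession.lower()
    for d in search_dirs or DEFAULT_SEARCH_DIRS:
        for ext in (".cif", ".pdb", ".ent"):
            for name in (acc, acc.upper()):
                p = Path(d) / f"{name}{ext}"
                if p.exists():
                    return p
    return None


def load_stack(accession: str, path, altloc_policy: str = "first_conformer") -> FibrilModel:
    """Read, clean and (if needed) expand a deposited model to >= 3 layers."""
    entry = REGISTRY[accession.lower()]
    model = resolve_altlocs(read_structure(path), policy=altloc_policy)
    model = model.without_hydrogens().without_heteroatoms()
    if len(model.chain_ids()) >= 3:
        return model
    if entry.rise is None or entry.twist is None:
        raise ValueError(
            f"{accession}: single-layer deposition and no registered helical "
            "parameters to expand with"
        )
    params = HelicalParams(rise=entry.rise, twist=entry.twist)
    return apply_helical_symmetry(model, params, 5, AxisFrame())


def evaluate_energy(
    accession: str,
    path,
    n_sphere_points: int = 960,
    asp: AspTable | None = None,
) -> dict:
    """Plain and charge-compensated central-chain ΔG° for one accession.

    For paired-protofilament depositions the central chains are summarized
    separately and averaged.  Returns a dict with ``dG_chain_plain``,
    ``dG_chain_compensated``, ``dG_residue_plain``,
    ``dG_residue_compensated`` and ``n_ordered_residues``.
    """
    entry = REGISTRY[accession.lower()]
    asp = asp or AspTable.default()
    stack = load_stack(accession, path)
    chains = central_chain_ids(stack)
    spec = builtin_compensation_specs()[entry.compensation] if entry.compensation else None
    plain_chain, comp_chain, n_res = [], [], []
    for cid in chains:
        areas = buried_areas(stack, cid, n_sphere_points=n_sphere_points)
        plain = chain_summary(residue_energies(areas, asp), cid, label=accession)
        plain_chain.append(plain.dG_chain)
        n_res.append(plain.n_ordered_residues)
        if spec is not None:
            comp = chain_summary(apply_charge_compensation(areas, asp, spec), cid,
                                 label=accession)
            comp_chain.append(comp.dG_chain)
    dg_plain = float(np.mean(plain_chain))
    n = int(round(np.mean(n_res)))
    out = {
        "accession": accession,
        "central_chains": chains,
        "n_ordered_residues": n,
        "dG_chain_plain": dg_plain,
        "dG_residue_plain": dg_plain / n,
    }
    if comp_chain:
        dg_comp = float(np.mean(comp_chain))
        out["dG_chain_compensated"] = dg_comp
        out["dG_residue_compensated"] = dg_comp / n
    return out
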