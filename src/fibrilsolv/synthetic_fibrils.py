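"""Synthetic fibril models and independent brute-force oracles.

Layers are built by placing residues along a 2D path (straight, C- or
S-shaped) at ~4.8 Å Cα spacing, with idealized full heavy-atom side chains
extended alternately to the two sides of the path.  The geometry is
deliberately non-physical (no β-sheet hydrogen bonding, fixed bond lengths)
but exercises everything the analysis assumes: stacking by rise/twist,
paired protofilaments, and charged residues exposed on one face.

``brute_force_sasa`` re-implements the SASA definition with a different
point set and naive all-pairs occlusion, serving as an independent oracle
for :mod:`fibrilsolv.surface_area`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomRecord, FibrilModel
from .fibril_geometry import AxisFrame, HelicalParams, apply_helical_symmetry
from .surface_area import RadiusSet, buried_areas
from .solvation_energetics import AspTable, CompensationSpec

__all__ = [
    "FibrilRecipe",
    "make_layer",
    "make_fibril",
    "brute_force_sasa",
    "make_energy_fixture",
    "RESIDUE_TEMPLATES",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: side-chain heavy atoms per residue, in template build order
RESIDUE_TEMPLATES = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

CA_SPACING = 4.8  # in-plane Cα-Cα spacing, Å


@dataclass(frozen=True)
class FibrilRecipe:
    sequence: str
    path_shape: str = "straight"
    rise: float = 4.8
    twist: float = -1.0
    n_layers: int = 5
    protofilaments: int = 1
    seed: int = 0
    jitter: float = 0.0  # Gaussian sigma in Å, applied per coordinate

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence.upper() if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(set(bad))}")
        if self.path_shape not in ("straight", "c_shape", "s_shape"):
            raise ValueError(f"unknown path shape {self.path_shape!r}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.protofilaments not in (1, 2):
            raise ValueError("protofilaments must be 1 or 2")


def _path_points(shape: str, n: int, spacing: float = CA_SPACING) -> np.ndarray:
    """2D path walked at fixed step; curvature depends on the shape."""
    if shape == "straight":
        turns = np.zeros(n)
    elif shape == "c_shape":
        total = 0.9 * np.pi
        turns = np.full(n, total / max(n - 1, 1))
    else:  # s_shape: bend one way, then the other
        total = 0.9 * np.pi
        dpsi = total / max(n - 1, 1) * 2.0
        turns = np.array([dpsi if i < n // 2 else -dpsi for i in range(n)])
    pts = np.zeros((n, 3))
    psi = 0.0
    for i in range(1, n):
        psi += turns[i - 1]
        pts[i] = pts[i - 1] + spacing * np.array([np.cos(psi), np.sin(psi), 0.0])
    return pts


def _element_of(atom_name: str) -> str:
    return next(ch for ch in atom_name if ch.isalpha())


def make_layer(recipe: FibrilRecipe) -> FibrilModel:
    """One fibril layer: one chain per protofilament, full heavy-atom residues.

    Side chains extend alternately to the two sides of the path normal so
    that every other residue's side chain (charged ones included) faces the
    same side.  A second protofilament is the first rotated 180° about the
    fibril (z) axis.  Deterministic for a fixed recipe.
    """
    seq = recipe.sequence.upper()
    n = len(seq)
    path = _path_points(recipe.path_shape, n)
    # shift the path off the z-axis so a 2-fold mate never overlaps
    span = float(np.linalg.norm(path.max(axis=0) - path.min(axis=0)))
    centroid = path.mean(axis=0)
    path = path - centroid + np.array([0.5 * span + 8.0, 0.0, 0.0])

    rng = np.random.default_rng(recipe.seed)
    z = np.array([0.0, 0.0, 1.0])
    atoms: list[AtomRecord] = []
    serial = 1
    for i, letter in enumerate(seq):
        res = ONE_TO_THREE[letter]
        ca = path[i]
        nxt = path[min(i + 1, n - 1)]
        prv = path[max(i - 1, 0)]
        tangent = nxt - prv
        nrm = np.linalg.norm(tangent)
        tangent = tangent / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        normal = np.cross(z, tangent)
        side = normal * (1.0 if i % 2 == 0 else -1.0)

        placed = [("N", ca - 1.45 * tangent), ("CA", ca), ("C", ca + 1.45 * tangent)]
        placed.append(("O", ca + 1.45 * tangent + 1.23 * z))
        for j, name in enumerate(RESIDUE_TEMPLATES[res]):
            pos = ca + side * (1.53 + 1.30 * j) + z * (0.40 * (j % 2))
            placed.append((name, pos))
        for name, pos in placed:
            if recipe.jitter > 0:
                pos = pos + rng.normal(scale=recipe.jitter, size=3)
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=_element_of(name), alt_loc="",
                    res_name=res, chain_id="A", res_seq=i + 1,
                    coords=tuple(float(v) for v in pos),
                )
            )
            serial += 1

    model = FibrilModel(atoms, label="synthetic", protofilament_of_chain={"A": 0})
    if recipe.protofilaments == 2:
        flip = np.diag([-1.0, -1.0, 1.0])  # 2-fold about z
        mate_atoms = []
        for a in model.transformed(flip, np.zeros(3)).atoms:
            mate_atoms.append(
                AtomRecord(
                    serial=serial, name=a.name, element=a.element, alt_loc="",
                    res_name=a.res_name, chain_id="B", res_seq=a.res_seq,
                    coords=a.coords,
                )
            )
            serial += 1
        model = FibrilModel(
            atoms + mate_atoms,
            label="synthetic",
            protofilament_of_chain={"A": 0, "B": 1},
        )
    return model


def make_fibril(recipe: FibrilRecipe) -> FibrilModel:
    """A full stack: ``make_layer`` expanded by the recipe's rise/twist."""
    layer = make_layer(recipe)
    params = HelicalParams(
        rise=recipe.rise,
        twist=recipe.twist,
        symmetry_class="pseudo_21_paired"
        if abs(abs(recipe.twist) - 180.0) <= 15.0
        else "C1_single",
    )
    return apply_helical_symmetry(layer, params, recipe.n_layers, AxisFrame())


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_ORACLE_POINT_SEED = 20240917  # fixed: the oracle is deterministic by design


def brute_force_sasa(
    model: FibrilModel, radii: RadiusSet | None = None, n_points: int = 10000
) -> np.ndarray:
    """Naive SASA oracle: random (fixed-seed) sphere points, all-pairs occlusion.

    Independent of :func:`fibrilsolv.surface_area.sasa`: different point
    set, no neighbour lists.  Slow by design; keep models small.
    """
    if n_points < 10000:
        raise ValueError("oracle requires n_points >= 10000")
    if any(a.is_hydrogen for a in model.atoms):
        raise ValueError("model contains hydrogens")
    radii = radii or RadiusSet()
    rng = np.random.default_rng(_ORACLE_POINT_SEED)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    centers = model.coords()
    r_exp = radii.expanded_radii(model)
    n = model.n_atoms
    out = np.empty(n)
    for i in range(n):
        surf = centers[i] + r_exp[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(centers[j] - centers[i]) >= r_exp[i] + r_exp[j]:
                continue
            d2 = ((surf - centers[j]) ** 2).sum(axis=1)
            exposed &= d2 >= r_exp[j] ** 2
        out[i] = exposed.mean() * 4.0 * np.pi * r_exp[i] ** 2
    return out


def make_energy_fixture(
    n_sphere_points: int = 240,
) -> tuple[FibrilModel, CompensationSpec, float]:
    """A lysine-ladder fibril plus the expected compensation delta.

    Returns ``(stack, spec, expected_ddG)`` where ``expected_ddG`` is the
    change in ΔG° per chain caused by compensating every lysine of the
    central chain, computed here by direct re-summation of the nullified
    nitrogen terms — an independent bookkeeping path from
    :func:`fibrilsolv.solvation_energetics.apply_charge_compensation`.
    """
    recipe = FibrilRecipe(sequence="LKLLKLLKLL", path_shape="straight",
                          rise=4.8, twist=-1.0, n_layers=5)
    stack = make_fibril(recipe)
    central = [c for c, k in stack.layer_of_chain.items() if k == recipe.n_layers // 2]
    chain_id = central[0]
    areas = buried_areas(stack, chain_id, n_sphere_points=n_sphere_points)
    asp = AspTable.default()
    lys_seqs = [s for _, s, name, _ in stack.residues(chain_id) if name == "LYS"]
    spec = CompensationSpec.from_residues([(s, "K") for s in lys_seqs], label="fixture")
    sigma_nz = asp.parameters["charged_N_plus"]
    expected_ddg = 0.0
    buried = areas.buried
    for i, a in enumerate(areas.atoms):
        if a.res_name == "LYS" and a.name == "NZ" and a.res_seq in lys_seqs:
            term = -sigma_nz * buried[i]
            if term > 0:
                expected_ddg -= term
    return stack, spec, float(expected_ddg)
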