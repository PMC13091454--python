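"""Per-atom solvent-accessible and buried surface areas.

SASA is computed with the Shrake-Rupley method: quasi-uniform points on
each atom's probe-expanded sphere are tested against neighbouring expanded
spheres.  The point set is a deterministic spiral (Fibonacci) lattice, so
results are exactly reproducible for a fixed point count — no RNG anywhere.

Burial of an atom is measured against a *reference* state: the SASA of its
residue extracted in situ together with its two covalently adjacent
residues.  This tripeptide-like host stands in for the fully solvated
unfolded chain, so a fully extended isolated chain buries ~nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, FibrilModel

__all__ = [
    "RadiusSet",
    "AtomAreas",
    "sphere_points",
    "canonical_rotation",
    "sasa",
    "reference_areas",
    "buried_areas",
]

#: single published van der Waals set; implementation defaults, configurable
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_FALLBACK_RADIUS = 1.70
DEFAULT_N_POINTS = 960


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class RadiusSet:
    """Element -> van der Waals radius (Å) plus the probe radius."""

    radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    probe_radius: float = DEFAULT_PROBE_RADIUS
    fallback: float | None = DEFAULT_FALLBACK_RADIUS

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all van der Waals radii must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")

    def radius_of(self, element: str) -> float:
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        if self.fallback is not None:
            return self.fallback
        raise UnknownElementError(
            f"no van der Waals radius for element {element!r} and no fallback configured"
        )

    def expanded_radii(self, model: FibrilModel) -> np.ndarray:
        return np.array(
            [self.radius_of(a.element) + self.probe_radius for a in model.atoms], dtype=float
        )


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def canonical_rotation(coords: np.ndarray) -> np.ndarray:
    """Rotation into the principal-axes frame of a coordinate set.

    Evaluating SASA in this model-derived frame makes the estimate exactly
    invariant under rigid motion of the whole model (for generic geometries;
    symmetric degenerate cases are physically frame-independent anyway).
    Signs are fixed so the frame is a deterministic function of the shape.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending eigenvalue order
    # orient each axis by a rotation-invariant functional of the shape
    # (third moment of the projections, then a radius-weighted first moment)
    scale = max(float(np.abs(centered).max()), 1.0)
    r2 = (centered ** 2).sum(axis=1)
    for j in range(2):
        proj = centered @ v[:, j]
        m3 = float((proj ** 3).sum())
        if abs(m3) < 1e-9 * scale**3:
            m3 = float((proj * r2).sum())
        if m3 < 0:
            v[:, j] = -v[:, j]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])  # proper frame by construction
    return v.T


def sasa(
    model: FibrilModel,
    radii: RadiusSet | None = None,
    n_sphere_points: int = DEFAULT_N_POINTS,
    orientation="canonical",
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA (Å²), aligned with ``model.atoms``.

    The model must not contain hydrogens (drop them first); heteroatoms are
    treated like any other atom if present, so exclude them upstream when
    they should not occlude.

    ``orientation`` controls the frame the deterministic point lattice is
    applied in: ``"canonical"`` (default) evaluates in the model's
    principal-axes frame, which makes the estimate rigid-motion invariant;
    ``"fixed"`` uses the coordinates as given (monotonicity under added
    occluders is then exact); a 3x3 rotation evaluates in that frame.
    """
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60 for a meaningful estimate")
    if model.n_atoms == 0:
        raise ValueError("empty model")
    if any(a.is_hydrogen for a in model.atoms):
        raise ValueError("model contains hydrogens; call without_hydrogens() first")
    centers = model.coords()
    if isinstance(orientation, str):
        if orientation == "canonical":
            centers = centers @ canonical_rotation(centers).T
        elif orientation != "fixed":
            raise ValueError(f"unknown orientation {orientation!r}")
    else:
        centers = centers @ np.asarray(orientation, dtype=float).T
    r_exp = radii.expanded_radii(model) if radii else RadiusSet().expanded_radii(model)
    pts = sphere_points(n_sphere_points)
    tree = cKDTree(centers)
    r_max = float(r_exp.max())
    out = np.empty(model.n_atoms, dtype=float)
    for i in range(model.n_atoms):
        nbr = tree.query_ball_point(centers[i], r_exp[i] + r_max)
        nbr = [j for j in nbr if j != i]
        if nbr:
            nc = centers[nbr]
            nr = r_exp[nbr]
            keep = np.linalg.norm(nc - centers[i], axis=1) < r_exp[i] + nr
            nc, nr = nc[keep], nr[keep]
        else:
            nc = np.empty((0, 3))
            nr = np.empty(0)
        surf = centers[i] + r_exp[i] * pts
        if len(nc):
            d2 = ((surf[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr * nr)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * r_exp[i] ** 2
    return out


def reference_areas(
    chain: FibrilModel,
    radii: RadiusSet | None = None,
    n_sphere_points: int = DEFAULT_N_POINTS,
    orientation="canonical",
) -> np.ndarray:
    """Per-atom reference SASA of a single chain, aligned with its atoms.

    Each residue is evaluated in a minimal host: the residue plus its two
    neighbouring residues in chain order, extracted in situ.
    """
    cids = chain.chain_ids()
    if len(cids) != 1:
        raise ValueError(f"reference_areas expects a single chain, got {cids}")
    residues = chain.residues()
    index_of_atom = {id(a): k for k, a in enumerate(chain.atoms)}
    out = np.empty(chain.n_atoms, dtype=float)
    for ri, (_, _, _, res_atoms) in enumerate(residues):
        host_atoms: list[AtomRecord] = []
        for rj in range(max(0, ri - 1), min(len(residues), ri + 2)):
            host_atoms.extend(residues[rj][3])
        host = chain.with_atoms(host_atoms)
        host_sasa = sasa(host, radii, n_sphere_points, orientation=orientation)
        pos = {id(a): k for k, a in enumerate(host.atoms)}
        for a in res_atoms:
            out[index_of_atom[id(a)]] = host_sasa[pos[id(a)]]
    return out


@dataclass
class AtomAreas:
    """Reference, assembly and buried areas for the atoms of one chain."""

    atoms: list
    reference: np.ndarray
    assembly: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.atoms) == len(self.reference) == len(self.assembly)):
            raise ValueError("area arrays must align with the atom list")
        if np.any(self.assembly < -1e-9):
            raise ValueError("assembly areas must be non-negative")

    @property
    def buried(self) -> np.ndarray:
        return np.maximum(0.0, self.reference - self.assembly)

    @property
    def total_buried(self) -> float:
        return float(self.buried.sum())


def buried_areas(
    stack: FibrilModel,
    target_chain: str,
    radii: RadiusSet | None = None,
    n_sphere_points: int = DEFAULT_N_POINTS,
    include_hetero_occluders: bool = False,
) -> AtomAreas:
    """Buried area of every atom of ``target_chain`` within the stack.

    The assembly SASA is computed on the whole stack (all non-hydrogen
    protein atoms occlude; heteroatoms only when requested) and restricted
    to the target chain; the reference SASA comes from the in-situ
    tripeptide host on the isolated chain.
    """
    work = stack.without_hydrogens()
    if not include_hetero_occluders:
        work = work.without_heteroatoms()
    if all(a.chain_id != target_chain for a in work.atoms):
        raise KeyError(f"target chain {target_chain!r} not in stack (have {work.chain_ids()})")
    # one shared frame (canonical for the stack) keeps assembly <= reference
    # exact: the reference hosts are occluder subsets evaluated identically
    frame = canonical_rotation(work.coords())
    assembly_all = sasa(work, radii, n_sphere_points, orientation=frame)
    idx = [k for k, a in enumerate(work.atoms) if a.chain_id == target_chain]
    target_atoms = [work.atoms[k] for k in idx]
    assembly = assembly_all[idx]
    chain_model = work.with_atoms(target_atoms)
    reference = reference_areas(chain_model, radii, n_sphere_points, orientation=frame)
    return AtomAreas(atoms=target_atoms, reference=reference, assembly=assembly)
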