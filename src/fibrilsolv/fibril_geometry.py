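"""Helical stacking of fibril layers and recovery of rise/twist.

A fibril is modelled as ``n`` copies of one layer related by a screw motion:
rotation by ``twist`` degrees about the fibril axis plus translation by
``rise`` Å along it.  Expansion centres the input layer, i.e. the original
chains end up in the middle layer of the generated stack, so that the
central chains are occluded from both sides.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .structure_io import FibrilModel
from .structure_compare import kabsch_superpose

__all__ = [
    "HelicalParams",
    "AxisFrame",
    "apply_helical_symmetry",
    "estimate_helical_params",
    "central_chain_ids",
    "screw_decompose",
]

#: twist values within this many degrees of ±180° flag a pseudo-2₁ pairing
PSEUDO_21_TWIST_TOL = 15.0

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class HelicalParams:
    """Rise (Å) and twist (degrees) relating successive layers."""

    rise: float
    twist: float
    symmetry_class: str = "C1_single"

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if not -180.0 < self.twist <= 180.0:
            raise ValueError(f"twist must lie in (-180, 180], got {self.twist}")
        if self.symmetry_class not in ("C1_single", "pseudo_21_paired"):
            raise ValueError(f"unknown symmetry class {self.symmetry_class!r}")
        if self.symmetry_class == "pseudo_21_paired":
            if abs(abs(self.twist) - 180.0) > PSEUDO_21_TWIST_TOL:
                raise ValueError(
                    f"pseudo_21_paired requires |twist| near 180deg, got {self.twist}"
                )


@dataclass(frozen=True)
class AxisFrame:
    """A fibril axis: a point on the axis and a unit direction."""

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("axis direction must be non-zero")
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", tuple(d / n))

    @property
    def o(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


def _axis_rotation(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues form)."""
    u = np.asarray(direction, dtype=float)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def apply_helical_symmetry(
    layer: FibrilModel,
    params: HelicalParams,
    n_layers: int,
    frame: AxisFrame | None = None,
) -> FibrilModel:
    """Expand a single layer into an ``n_layers`` stack.

    Layer ``k`` (index 0..n_layers-1) is the input layer rotated by
    ``(k - n_layers//2) * twist`` about the axis and translated by the same
    multiple of ``rise`` along it, so the input layer becomes the central
    layer.  Chains are renamed deterministically (layer-major) and annotated
    with layer and protofilament indices.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    src_chains = layer.chain_ids()
    if not src_chains:
        raise ValueError("layer contains no chains")
    frame = frame or AxisFrame()
    proto_of_src = {
        cid: layer.protofilament_of_chain.get(cid, i) for i, cid in enumerate(src_chains)
    }
    if n_layers * len(src_chains) > len(_CHAIN_ALPHABET):
        raise ValueError("stack too large for unique single-character chain ids")

    atoms = []
    layer_map: dict[str, int] = {}
    proto_map: dict[str, int] = {}
    next_id = iter(_CHAIN_ALPHABET)
    for k in range(n_layers):
        off = k - n_layers // 2
        R = _axis_rotation(frame.d, off * params.twist)
        t = frame.o - R @ frame.o + off * params.rise * frame.d
        moved = layer.transformed(R, t)
        rename = {cid: next(next_id) for cid in src_chains}
        for a in moved.atoms:
            atoms.append(_dc_replace(a, chain_id=rename[a.chain_id]))
        for cid, new in rename.items():
            layer_map[new] = k
            proto_map[new] = proto_of_src[cid]
    return FibrilModel(
        atoms,
        label=layer.label,
        layer_of_chain=layer_map,
        protofilament_of_chain=proto_map,
    )


def screw_decompose(R: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Decompose the rigid map ``x -> R x + t`` into a screw motion.

    Returns ``(axis_direction, axis_origin, twist_deg, rise)`` with the axis
    oriented so that the rise is non-negative.  Robust near 180° rotations,
    where the antisymmetric part of ``R`` vanishes.
    """
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    # axis = eigenvector of R for eigenvalue 1
    w, v = np.linalg.eig(R)
    i = int(np.argmin(np.abs(w - 1.0)))
    u = np.real(v[:, i])
    u = u / np.linalg.norm(u)
    rise = float(t @ u)
    if rise < 0:
        u, rise = -u, -rise
    # signed angle about u via a test vector perpendicular to u
    probe = np.array([1.0, 0.0, 0.0])
    if abs(probe @ u) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    p = probe - (probe @ u) * u
    p /= np.linalg.norm(p)
    q = R @ p
    twist = float(np.degrees(np.arctan2(np.cross(p, q) @ u, p @ q)))
    # axis origin: least-squares point satisfying (I - R) o = t_perp
    t_perp = t - rise * u
    A = np.eye(3) - R
    origin, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    origin = origin - (origin @ u) * u
    return u, origin, twist, rise


def _layers_of(stack: FibrilModel) -> dict[int, list[str]]:
    """Chains grouped by layer index, inferring layers when unannotated."""
    if stack.layer_of_chain:
        out: dict[int, list[str]] = {}
        for cid in stack.chain_ids():
            if cid not in stack.layer_of_chain:
                raise ValueError(f"chain {cid} has no layer annotation")
            out.setdefault(stack.layer_of_chain[cid], []).append(cid)
        return dict(sorted(out.items()))
    # infer: one chain per layer, ordered by centroid projection on the
    # dominant axis of the chain-centroid cloud
    cids = stack.chain_ids()
    if len(cids) < 2:
        return {0: cids}
    cents = np.array([stack.chain(c).coords().mean(axis=0) for c in cids])
    centered = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj)
    return {k: [cids[i]] for k, i in enumerate(order)}


def _ca_coords_in_seq_order(chain: FibrilModel) -> tuple[list[int], np.ndarray]:
    seqs, xyz = [], []
    for _, res_seq, _, atoms in chain.residues():
        for a in atoms:
            if a.name == "CA":
                seqs.append(res_seq)
                xyz.append(a.coords)
                break
    return seqs, np.asarray(xyz, dtype=float)


def estimate_helical_params(stack: FibrilModel) -> HelicalParams:
    """Recover rise/twist from a multi-layer stack.

    For each consecutive layer pair the optimal rigid transform mapping
    layer ``k`` onto layer ``k+1`` (Kabsch on Cα atoms) is screw-decomposed;
    rise and twist are averaged over the pairs.  Layers must carry identical
    residue sets.
    """
    layers = _layers_of(stack)
    if len(layers) < 2:
        raise ValueError("need at least 2 layers to estimate helical parameters")
    keys = sorted(layers)
    per_layer: list[tuple[list[int], np.ndarray, np.ndarray]] = []
    for k in keys:
        seqs_all, ca_all, full_all = [], [], []
        for cid in layers[k]:
            chain = stack.chain(cid)
            s, c = _ca_coords_in_seq_order(chain)
            seqs_all.extend(s)
            ca_all.append(c)
            full_all.append(chain.coords())
        per_layer.append((seqs_all, np.vstack(ca_all), np.vstack(full_all)))
    ref_seqs = per_layer[0][0]
    for k, (seqs, _, _) in zip(keys, per_layer):
        if seqs != ref_seqs:
            raise ValueError(
                f"layer {k} residue set differs from layer {keys[0]} "
                f"({len(seqs)} vs {len(ref_seqs)} CA atoms)"
            )
    # a (near-)collinear Cα trace leaves the rotation about it unconstrained;
    # fall back to the full atom set in that case
    ca_ref = per_layer[0][1] - per_layer[0][1].mean(axis=0)
    sv = np.linalg.svd(ca_ref, compute_uv=False)
    use_ca = len(sv) > 1 and sv[1] > 1e-4 * sv[0]
    idx = 1 if use_ca else 2
    if not use_ca:
        if any(p[2].shape != per_layer[0][2].shape for p in per_layer):
            raise ValueError("layers have mismatched atom counts; cannot use all-atom fallback")
    # global axis from the best-conditioned span (largest rotation angle):
    # for near-identity per-layer rotations the pairwise axis is noise-dominated
    axis = None
    best_angle = -1.0
    for span in range(1, len(per_layer)):
        sup = kabsch_superpose(per_layer[span][idx], per_layer[0][idx])
        u, _, tw, rs = screw_decompose(sup.rotation, sup.translation)
        if abs(tw) > best_angle:
            best_angle = abs(tw)
            axis = u if rs >= 0 else -u
    rises, twists = [], []
    for pa, pb in zip(per_layer, per_layer[1:]):
        a, b = pa[idx], pb[idx]
        sup = kabsch_superpose(b, a)  # transform taking layer k onto layer k+1
        rises.append(float(sup.translation @ axis))
        # signed rotation angle about the shared axis
        probe = np.array([1.0, 0.0, 0.0])
        if abs(probe @ axis) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        p = probe - (probe @ axis) * axis
        p /= np.linalg.norm(p)
        q = sup.rotation @ p
        q = q - (q @ axis) * axis
        twists.append(float(np.degrees(np.arctan2(np.cross(p, q) @ axis, p @ q))))
    if np.mean(rises) < 0:  # orient the axis along the stacking direction
        rises = [-r for r in rises]
        twists = [-t for t in twists]
    rise = float(np.mean(rises))
    # twists may straddle the ±180° seam for pseudo-2₁ stacks: average on the circle
    ang = np.deg2rad(twists)
    twist = float(np.degrees(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))))
    if twist <= -180.0:
        twist += 360.0
    sym = "pseudo_21_paired" if abs(abs(twist) - 180.0) <= PSEUDO_21_TWIST_TOL else "C1_single"
    return HelicalParams(rise=rise, twist=twist, symmetry_class=sym)


def central_chain_ids(stack: FibrilModel) -> list[str]:
    """Chain ids of the middle layer (index ``n_layers // 2``).

    Only interior chains are occluded by both axial neighbours, so energies
    are evaluated there.  Requires at least 3 layers.
    """
    layers = _layers_of(stack)
    if len(layers) < 3:
        raise ValueError(
            f"no fully occluded layer: stack has {len(layers)} layer(s), need >= 3"
        )
    keys = sorted(layers)
    return list(layers[keys[len(keys) // 2]])
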