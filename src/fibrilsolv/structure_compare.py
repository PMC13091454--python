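"""Rigid-body superposition of residue segments and RMSD reporting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import FibrilModel, select_segment

__all__ = ["SuperpositionResult", "kabsch_superpose", "segment_rmsd"]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rigid map ``x_B -> R x_B + t`` onto the reference set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    pairing: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of point set B onto point set A.

    Points are paired by position.  The returned rotation is always proper:
    if the best orthogonal map would be a reflection, the smallest singular
    direction is flipped (standard Kabsch correction).
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def _segment_coords(
    model: FibrilModel, chain: str, start: int, end: int, atoms
) -> tuple[list[int], np.ndarray]:
    seg = select_segment(model, chain, start, end, atom_filter=atoms)
    seqs = [a.res_seq for a in seg.atoms]
    return seqs, seg.coords()


def segment_rmsd(
    model_a: FibrilModel,
    range_a: tuple[str, int, int],
    model_b: FibrilModel,
    range_b: tuple[str, int, int],
    atoms=("CA",),
    pairing: str = "by_order",
) -> SuperpositionResult:
    """Superpose two residue ranges paired strictly by position.

    The ranges may cover different sequence positions (the caller aligns
    e.g. residues 359-383 of one fold onto 318-342 of another); they must
    select equal atom counts under ``atoms``.
    """
    if pairing != "by_order":
        raise ValueError(f"unsupported pairing mode {pairing!r}")
    atom_set = "all" if atoms == "all" else set(atoms)
    seq_a, xyz_a = _segment_coords(model_a, *range_a, atom_set)
    seq_b, xyz_b = _segment_coords(model_b, *range_b, atom_set)
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"range {range_a} selects {len(seq_a)} atoms but range {range_b} "
            f"selects {len(seq_b)}; positional pairing needs equal counts"
        )
    res = kabsch_superpose(xyz_a, xyz_b)
    return SuperpositionResult(
        rotation=res.rotation,
        translation=res.translation,
        rmsd=res.rmsd,
        n_atoms=res.n_atoms,
        pairing=tuple(zip(seq_a, seq_b)),
    )
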