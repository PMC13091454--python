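"""Buried areas -> per-residue energies, chain summaries, charge compensation.

The stabilization energy of a residue is the negated sum over its atoms of
(atomic solvation parameter) x (buried area), so that stable fibrils come
out with negative ΔG°.  Charge compensation models a bound polyanion by
zeroing the *destabilizing* terms of specific charged nitrogen atoms:
Lys NZ (1), Arg NE/NH1/NH2 (3), His ND1/NE2 (2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .surface_area import AtomAreas

__all__ = [
    "AspTable",
    "ResidueEnergyProfile",
    "ChainEnergySummary",
    "CompensationSpec",
    "CompensationEntry",
    "residue_energies",
    "chain_summary",
    "apply_charge_compensation",
    "builtin_compensation_specs",
    "COMPENSATABLE_ATOMS",
]

ASP_CLASSES = ("apolar_C", "polar_N_O", "carboxylate_O_minus", "charged_N_plus", "sulfur")

#: nitrogen atoms whose penalty a bound polyanion can neutralize
COMPENSATABLE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

_CARBOXYLATE_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_HIS_N = {("HIS", "ND1"), ("HIS", "NE2")}


class ClassificationError(KeyError):
    pass


@dataclass(frozen=True)
class AspTable:
    """Atom-class -> solvation parameter σ (kcal·mol⁻¹·Å⁻²).

    ``histidine_charged`` controls the baseline class of His ring nitrogens
    (polar by default; charged when the table is configured that way).
    """

    parameters: dict = field(default_factory=dict)
    histidine_charged: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in ASP_CLASSES if c not in self.parameters]
        if missing:
            raise ValueError(f"ASP table missing classes: {missing}")
        if not self.parameters["apolar_C"] * self.parameters["charged_N_plus"] < 0:
            raise ValueError("apolar_C and charged_N_plus parameters must have opposite signs")

    @classmethod
    def default(cls) -> "AspTable":
        text = resources.files("fibrilsolv.data").joinpath("asp_default.yaml").read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "AspTable":
        doc = yaml.safe_load(text)
        return cls(
            parameters=dict(doc["parameters"]),
            histidine_charged=bool(doc.get("histidine_charged", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "AspTable":
        with open(path) as fh:
            return cls.from_yaml_text(fh.read())

    def classify(self, res_name: str, atom_name: str, element: str | None = None) -> str:
        """Map a heavy atom to its solvation class."""
        res = res_name.upper()
        name = atom_name.upper()
        el = (element or _element_from_name(name)).upper()
        if el == "C":
            return "apolar_C"
        if el == "S":
            return "sulfur"
        if el == "O":
            if (res, name) in _CARBOXYLATE_O or name == "OXT":
                return "carboxylate_O_minus"
            return "polar_N_O"
        if el == "N":
            if (res, name) in _CHARGED_N:
                return "charged_N_plus"
            if (res, name) in _HIS_N and self.histidine_charged:
                return "charged_N_plus"
            return "polar_N_O"
        raise ClassificationError(
            f"cannot classify atom ({res_name}, {atom_name}, element {el!r})"
        )

    def sigma(self, res_name: str, atom_name: str, element: str | None = None) -> float:
        return self.parameters[self.classify(res_name, atom_name, element)]

    def scaled(self, factor: float) -> "AspTable":
        return AspTable(
            parameters={k: v * factor for k, v in self.parameters.items()},
            histidine_charged=self.histidine_charged,
        )


def _element_from_name(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    raise ClassificationError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class ResidueEnergyProfile:
    """Per-residue ΔG contributions (kcal/mol) for one or more chains."""

    chain_ids: list
    res_seqs: list
    res_names: list
    energies: np.ndarray
    compensated: np.ndarray  # bool per residue

    def __post_init__(self) -> None:
        n = len(self.res_seqs)
        if not (len(self.chain_ids) == len(self.res_names) == len(self.energies) == n):
            raise ValueError("profile columns must align")

    def chain_total(self, chain_id: str) -> float:
        mask = np.array([c == chain_id for c in self.chain_ids])
        if not mask.any():
            raise KeyError(f"chain {chain_id!r} not in profile")
        return float(self.energies[mask].sum())

    def rows(self):
        return list(zip(self.chain_ids, self.res_seqs, self.res_names,
                        self.energies.tolist(), self.compensated.tolist()))


@dataclass(frozen=True)
class ChainEnergySummary:
    """ΔG° per chain and per ordered residue for one chain."""

    label: str
    dG_chain: float
    n_ordered_residues: int
    compensated: bool

    def __post_init__(self) -> None:
        if self.n_ordered_residues < 1:
            raise ValueError("chain has no ordered residues")

    @property
    def dG_residue(self) -> float:
        return self.dG_chain / self.n_ordered_residues


@dataclass(frozen=True)
class CompensationEntry:
    res_seq: int
    res_name: str  # 3-letter
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.res_name.upper() not in COMPENSATABLE_ATOMS:
            raise ValueError(
                f"residue {self.res_name}{self.res_seq} is not Lys/Arg/His; cannot compensate"
            )

    @property
    def atom_names(self) -> tuple[str, ...]:
        return COMPENSATABLE_ATOMS[self.res_name.upper()]


@dataclass(frozen=True)
class CompensationSpec:
    """Residues whose charged-nitrogen burial penalties are nullified."""

    entries: tuple = ()
    label: str = ""

    @classmethod
    def from_residues(cls, residues, label: str = "") -> "CompensationSpec":
        """Build from ``[(res_seq, res_name3), ...]`` or one-letter codes."""
        one_to_three = {"K": "LYS", "R": "ARG", "H": "HIS"}
        out = []
        for res_seq, res_name in residues:
            r3 = one_to_three.get(res_name.upper(), res_name.upper())
            out.append(CompensationEntry(res_seq=int(res_seq), res_name=r3))
        return cls(entries=tuple(out), label=label)

    @property
    def n_nitrogens(self) -> int:
        return sum(len(e.atom_names) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _atom_terms(areas: AtomAreas, asp: AspTable) -> np.ndarray:
    """Per-atom ΔG term: −σ·buried.  Raises on unclassifiable atoms."""
    buried = areas.buried
    terms = np.empty(len(areas.atoms), dtype=float)
    for i, a in enumerate(areas.atoms):
        terms[i] = -asp.sigma(a.res_name, a.name, a.element) * buried[i]
    return terms


def _aggregate(areas: AtomAreas, terms: np.ndarray, flagged: set) -> ResidueEnergyProfile:
    keys: list[tuple[str, int]] = []
    names: dict[tuple[str, int], str] = {}
    sums: dict[tuple[str, int], float] = {}
    for a, term in zip(areas.atoms, terms):
        key = (a.chain_id, a.res_seq)
        if key not in sums:
            keys.append(key)
            names[key] = a.res_name
            sums[key] = 0.0
        sums[key] += term
    return ResidueEnergyProfile(
        chain_ids=[k[0] for k in keys],
        res_seqs=[k[1] for k in keys],
        res_names=[names[k] for k in keys],
        energies=np.array([sums[k] for k in keys]),
        compensated=np.array([k in flagged for k in keys], dtype=bool),
    )


def residue_energies(areas: AtomAreas, asp: AspTable | None = None) -> ResidueEnergyProfile:
    """ΔG per residue: ``-Σ σ(class) · buried_area`` over the residue's atoms."""
    asp = asp or AspTable.default()
    return _aggregate(areas, _atom_terms(areas, asp), set())


def chain_summary(
    profile: ResidueEnergyProfile, chain_id: str, label: str = ""
) -> ChainEnergySummary:
    mask = [c == chain_id for c in profile.chain_ids]
    n = sum(mask)
    if n == 0:
        raise KeyError(f"chain {chain_id!r} not in profile")
    return ChainEnergySummary(
        label=label or chain_id,
        dG_chain=profile.chain_total(chain_id),
        n_ordered_residues=n,
        compensated=bool(np.any(profile.compensated[np.array(mask)])),
    )


def apply_charge_compensation(
    areas: AtomAreas, asp: AspTable | None = None, spec: CompensationSpec | None = None
) -> ResidueEnergyProfile:
    """Residue energies with designated nitrogen penalties removed.

    Identical to :func:`residue_energies` except that for every residue in
    the spec, the terms of its compensable nitrogens are set to 0 when
    positive (penalty removal); negative terms are left untouched.
    """
    asp = asp or AspTable.default()
    if spec is None or len(spec) == 0:
        return residue_energies(areas, asp)

    present: dict[tuple[str | None, int], str] = {}
    for a in areas.atoms:
        present[(a.chain_id, a.res_seq)] = a.res_name
        present[(None, a.res_seq)] = a.res_name
    bad = []
    for e in spec.entries:
        found = present.get((e.chain_id, e.res_seq))
        if found is None:
            bad.append(f"{e.res_name}{e.res_seq}: absent from model")
        elif found.upper() != e.res_name.upper():
            bad.append(f"{e.res_name}{e.res_seq}: model has {found}{e.res_seq}")
    if bad:
        raise ValueError("invalid compensation entries: " + "; ".join(bad))

    target_atoms = set()
    for e in spec.entries:
        for nm in e.atom_names:
            target_atoms.add((e.chain_id, e.res_seq, nm))

    terms = _atom_terms(areas, asp)
    flagged: set = set()
    for i, a in enumerate(areas.atoms):
        hit = (a.chain_id, a.res_seq, a.name) in target_atoms or (
            None, a.res_seq, a.name) in target_atoms
        if hit:
            flagged.add((a.chain_id, a.res_seq))
            if terms[i] > 0:
                terms[i] = 0.0
    return _aggregate(areas, terms, flagged)


def builtin_compensation_specs() -> dict:
    """Named compensation residue lists for the three RNA-tau fibril models.

    ``9o8e`` is the residue list reported with the deposited model (the
    evidently mistyped "K783" is read as K383, which tau numbering does
    contain); ``9o8e_density_proximity`` is the alternative reported list of
    residues projecting into the residual RNA density.
    """
    return {
        "7sp1": CompensationSpec.from_residues([(406, "R")], label="7sp1"),
        "9o8e": CompensationSpec.from_residues(
            [(343, "K"), (347, "K"), (349, "R"), (370, "K"),
             (375, "K"), (379, "R"), (383, "K"), (385, "K")],
            label="9o8e",
        ),
        "9o8e_density_proximity": CompensationSpec.from_residues(
            [(370, "K"), (374, "H"), (375, "K"), (379, "R"),
             (383, "K"), (385, "K"), (388, "H")],
            label="9o8e_density_proximity",
        ),
        "9o8h": CompensationSpec.from_residues(
            [(311, "K"), (317, "K"), (321, "K"), (329, "H"), (330, "H")],
            label="9o8h",
        ),
    }
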