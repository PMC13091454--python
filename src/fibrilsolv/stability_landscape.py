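"""Two-axis fibril stability map: ΔG° per chain vs ΔG° per residue.

Computed chain summaries and externally tabulated structures (an
Amyloid-Atlas-style table) are merged into one list of points, classified
against the stability band spanned by patient-derived (ex vivo) folds, and
exported as a machine-readable plot specification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import pandas as pd

__all__ = [
    "LandscapePoint",
    "StabilityBand",
    "SOURCE_CLASSES",
    "load_atlas_table",
    "classify_stability",
    "export_landscape",
    "load_landscape",
]

logger = logging.getLogger(__name__)

SOURCE_CLASSES = ("human_brain", "recombinant", "mouse_seeded", "cell_seeded", "this_work")

#: tolerance for the dG_chain ≈ n * dG_residue consistency check (table rounding)
_CONSISTENCY_TOL = 0.05


@dataclass(frozen=True)
class LandscapePoint:
    label: str
    source_class: str
    dG_chain: float
    dG_residue: float
    compensated: bool = False
    n_residues: int | None = None

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"unknown source class {self.source_class!r}; expected one of {SOURCE_CLASSES}"
            )
        if self.n_residues is not None:
            if abs(self.dG_residue * self.n_residues - self.dG_chain) > \
                    _CONSISTENCY_TOL * self.n_residues:
                raise ValueError(
                    f"{self.label}: dG_residue * n = {self.dG_residue * self.n_residues:.3f} "
                    f"inconsistent with dG_chain = {self.dG_chain:.3f}"
                )


@dataclass(frozen=True)
class StabilityBand:
    """ΔG°-per-chain interval spanned by ex vivo folds (inclusive ends)."""

    lower: float = -47.0
    upper: float = -29.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"band lower {self.lower} must be < upper {self.upper}")


def classify_stability(point: LandscapePoint, band: StabilityBand | None = None) -> str:
    """``below_band`` (more stable), ``in_band``, or ``above_band`` (less stable)."""
    band = band or StabilityBand()
    if point.dG_chain < band.lower:
        return "below_band"
    if point.dG_chain <= band.upper:
        return "in_band"
    return "above_band"


_COLUMN_ALIASES = {
    "label": ("label", "name", "pdb", "pdbid", "pdb_id", "structure", "id"),
    "source_class": ("source_class", "source", "class", "origin", "category"),
    "dG_chain": ("dg_chain", "dg_per_chain", "dgchain", "energy_per_chain",
                 "dg_kcal_mol_chain", "deltag_per_chain"),
    "dG_residue": ("dg_residue", "dg_per_residue", "dgresidue", "energy_per_residue",
                   "deltag_per_residue"),
}

_SOURCE_ALIASES = {
    "human_brain": ("human_brain", "human brain", "ex vivo", "ex_vivo", "exvivo", "brain",
                    "human"),
    "recombinant": ("recombinant", "in vitro", "in_vitro", "invitro"),
    "mouse_seeded": ("mouse_seeded", "mouse", "mouse brain seeded"),
    "cell_seeded": ("cell_seeded", "cell", "cell line", "cell line seeded"),
    "this_work": ("this_work", "this work", "computed"),
}


def _norm(s: str) -> str:
    return "".join(ch for ch in str(s).lower() if ch.isalnum())


def _map_columns(columns, mapping: dict | None) -> dict:
    out = dict(mapping or {})
    normed = {_norm(c): c for c in columns}
    for field, aliases in _COLUMN_ALIASES.items():
        if field in out:
            continue
        # exact normalized match first, then substring containment
        for alias in aliases:
            if _norm(alias) in normed:
                out[field] = normed[_norm(alias)]
                break
        else:
            for alias in aliases:
                hits = [c for n, c in normed.items() if _norm(alias) in n]
                if len(hits) == 1:
                    out[field] = hits[0]
                    break
    missing = [f for f in _COLUMN_ALIASES if f not in out]
    if missing:
        raise ValueError(
            f"cannot map required fields {missing} onto table columns {list(columns)}"
        )
    return out


def _normalize_source(raw: str) -> str:
    n = _norm(raw)
    for cls, aliases in _SOURCE_ALIASES.items():
        if n == _norm(cls) or any(n == _norm(a) for a in aliases):
            return cls
    for cls, aliases in _SOURCE_ALIASES.items():
        if any(_norm(a) in n for a in aliases):
            return cls
    return "recombinant"  # conservative default for unrecognised origins


def load_atlas_table(path, column_mapping: dict | None = None) -> list[LandscapePoint]:
    """Load an atlas-style delimited table into landscape points.

    Delimiter is sniffed (CSV/TSV).  Rows with missing energies are skipped
    and counted in a log message.  ``column_mapping`` may pin any of
    ``label/source_class/dG_chain/dG_residue`` to explicit column names.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _map_columns(df.columns, column_mapping)
    points, skipped = [], 0
    for _, row in df.iterrows():
        try:
            dgc = float(row[cols["dG_chain"]])
            dgr = float(row[cols["dG_residue"]])
        except (TypeError, ValueError):
            skipped += 1
            continue
        if pd.isna(dgc) or pd.isna(dgr):
            skipped += 1
            continue
        points.append(
            LandscapePoint(
                label=str(row[cols["label"]]),
                source_class=_normalize_source(row[cols["source_class"]]),
                dG_chain=dgc,
                dG_residue=dgr,
            )
        )
    if skipped:
        logger.info("load_atlas_table: skipped %d row(s) with missing energies", skipped)
    return points


def export_landscape(points, band: StabilityBand | None = None, out=None) -> dict:
    """Write (and return) a JSON plot specification for the energy map.

    Points sharing a label form a before/after compensation pair and are
    emitted as a link.  Ordering is deterministic (by label, plain before
    compensated).
    """
    points = list(points)
    if not points:
        raise ValueError("no landscape points to export")
    band = band or StabilityBand()
    points = sorted(points, key=lambda p: (p.label, p.compensated))
    by_label: dict[str, list[LandscapePoint]] = {}
    for p in points:
        by_label.setdefault(p.label, []).append(p)
    links = [
        {"label": lab, "pair": [asdict(p) for p in ps]}
        for lab, ps in sorted(by_label.items())
        if len(ps) == 2 and ps[0].compensated != ps[1].compensated
    ]
    spec = {
        "points": [
            {**asdict(p), "stability_class": classify_stability(p, band)} for p in points
        ],
        "band_lines": [band.lower, band.upper],
        "links": links,
    }
    if out is not None:
        with open(out, "w") as fh:
            json.dump(spec, fh, indent=2, sort_keys=True)
    return spec


def load_landscape(path) -> list[LandscapePoint]:
    """Reload points from an exported plot specification (exact roundtrip)."""
    with open(path) as fh:
        spec = json.load(fh)
    out = []
    for p in spec["points"]:
        p = dict(p)
        p.pop("stability_class", None)
        out.append(LandscapePoint(**p))
    return out
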