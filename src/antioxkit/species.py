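"""Canonical data model and CSV I/O for computed chemical species.

A *species table* holds one row per computed form of a molecule — the neutral
parent, the O–H-site phenoxyl radicals, the radical cation and the site
anions — in one or both solvation phases. These are the quantities a DFT
thermochemistry run produces; here they are consumed from a flat CSV so the
whole pipeline is desk-testable without any quantum-chemistry engine.

CSV schema (header row required)::

    molecule_id,form,site,phase,enthalpy_hartree,electronic_energy_hartree,homo_ev,lumo_ev

Empty cells mean "absent" for the optional columns. Site labels are opaque
strings; the flavonoid 3/5/7/3'/4' numbering used by the bundled petunidin
fixture is a fixture convention, not an engine requirement. Unicode prime
characters in site labels are normalised to ASCII apostrophes.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Form",
    "Phase",
    "SpeciesRecord",
    "PhaseReferences",
    "ReferenceEnthalpies",
    "default_references",
    "read_species_table",
    "write_species_table",
    "normalize_site",
    "SpeciesTableError",
    "SchemaError",
    "RowError",
    "DuplicateRecordError",
]


class Form(str, enum.Enum):
    """Chemical form of a computed species."""

    NEUTRAL = "neutral"
    RADICAL = "radical"
    RADICAL_CATION = "radical_cation"
    ANION = "anion"
    CATION = "cation"


class Phase(str, enum.Enum):
    GAS = "gas"
    WATER = "water"


#: forms that are tied to a specific O–H site
_SITE_FORMS = frozenset({Form.RADICAL, Form.ANION})

# characters users paste for the flavonoid prime: ASCII apostrophe kept,
# Unicode prime / right single quote / backtick folded onto it
_PRIME_CHARS = {"′": "'", "’": "'", "`": "'"}


def normalize_site(label: str | None) -> str | None:
    """Trim whitespace and fold Unicode prime variants to an apostrophe."""
    if label is None:
        return None
    out = label.strip()
    for ch, repl in _PRIME_CHARS.items():
        out = out.replace(ch, repl)
    return out or None


class SpeciesTableError(Exception):
    """Base class for species-table problems."""


class SchemaError(SpeciesTableError):
    """The CSV header does not match the documented schema."""


class RowError(SpeciesTableError):
    """A row holds an unparsable or invariant-violating value."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class DuplicateRecordError(SpeciesTableError):
    """Two rows share the same (molecule, form, site, phase) key."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One computed chemical species.

    ``enthalpy`` and ``electronic_energy`` are in hartree; ``homo``/``lumo``
    in eV. ``site`` must be present exactly for site-bound forms (radical,
    anion) and absent otherwise.
    """

    molecule_id: str
    form: Form
    phase: Phase
    enthalpy: float
    site: str | None = None
    electronic_energy: float | None = None
    homo: float | None = None
    lumo: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "form", Form(self.form))
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "site", normalize_site(self.site))
        if (self.site is not None) != (self.form in _SITE_FORMS):
            raise ValueError(
                f"site must be present iff form is radical/anion "
                f"(form={self.form.value}, site={self.site!r})"
            )
        if not math.isfinite(self.enthalpy):
            raise ValueError("enthalpy must be finite")
        if self.homo is not None and self.lumo is not None and not self.homo < self.lumo:
            raise ValueError(f"homo ({self.homo}) must lie below lumo ({self.lumo})")

    @property
    def key(self) -> tuple[str, Form, str | None, Phase]:
        return (self.molecule_id, self.form, self.site, self.phase)


# ---------------------------------------------------------------------------
# Reference enthalpies

# Gas-phase conventions standard in the phenolic-antioxidant DFT literature:
# H(H•) = electronic energy of the H atom (−0.49765 hartree at B3LYP-quality
# levels) plus its 5/2 RT translational+pV enthalpy; H(H+) carries only the
# thermal term; H(e−) from the electron convention. All in hartree, all
# overridable. Aqueous values depend on the solvation convention chosen for
# the proton/electron and must be supplied explicitly.
_GAS_H_ATOM = -0.49765 + 0.00236
_GAS_PROTON = 0.00236
_GAS_ELECTRON = 0.00120


@dataclass(frozen=True)
class PhaseReferences:
    """Reference enthalpies (hartree) of H•, H+ and e− in one phase."""

    h_atom: float
    proton: float
    electron: float

    def __post_init__(self):
        for name in ("h_atom", "proton", "electron"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ReferenceEnthalpies:
    """Per-phase reference enthalpies used by the mechanism equations."""

    gas: PhaseReferences = field(
        default_factory=lambda: PhaseReferences(_GAS_H_ATOM, _GAS_PROTON, _GAS_ELECTRON)
    )
    water: PhaseReferences | None = None

    def for_phase(self, phase: Phase) -> PhaseReferences:
        phase = Phase(phase)
        refs = self.gas if phase is Phase.GAS else self.water
        if refs is None:
            raise ValueError(
                f"no reference enthalpies configured for phase {phase.value!r}; "
                "aqueous references must be supplied explicitly"
            )
        return refs


def default_references() -> ReferenceEnthalpies:
    """Literature-convention gas references; no aqueous defaults."""
    return ReferenceEnthalpies()


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = (
    "molecule_id",
    "form",
    "site",
    "phase",
    "enthalpy_hartree",
    "electronic_energy_hartree",
    "homo_ev",
    "lumo_ev",
)
_REQUIRED = ("molecule_id", "form", "phase", "enthalpy_hartree")
_OPTIONAL_FLOATS = {
    "electronic_energy_hartree": "electronic_energy",
    "homo_ev": "homo",
    "lumo_ev": "lumo",
}


def _parse_float(raw: str, column: str, row_index: int) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RowError(row_index, f"non-numeric value {raw!r} in column {column!r}") from None


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a species-table CSV into validated :class:`SpeciesRecord` rows.

    Raises :class:`SchemaError` for a missing required column,
    :class:`RowError` (carrying the 1-based data-row index) for a bad value,
    and :class:`DuplicateRecordError` when two rows share a key.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}")
        records: list[SpeciesRecord] = []
        seen: set[tuple] = set()
        for idx, row in enumerate(reader, start=1):
            kwargs: dict = {
                "molecule_id": (row.get("molecule_id") or "").strip(),
                "form": (row.get("form") or "").strip(),
                "phase": (row.get("phase") or "").strip(),
                "site": (row.get("site") or "").strip() or None,
                "enthalpy": _parse_float(
                    (row.get("enthalpy_hartree") or "").strip(), "enthalpy_hartree", idx
                ),
            }
            for col, attr in _OPTIONAL_FLOATS.items():
                raw = (row.get(col) or "").strip()
                kwargs[attr] = _parse_float(raw, col, idx) if raw else None
            try:
                record = SpeciesRecord(**kwargs)
            except ValueError as exc:
                raise RowError(idx, str(exc)) from None
            if record.key in seen:
                raise DuplicateRecordError(
                    f"duplicate species key {record.key} at row {idx}"
                )
            seen.add(record.key)
            records.append(record)
    return records


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records to the standard CSV schema (empty cell = absent)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.molecule_id,
                    rec.form.value,
                    rec.site or "",
                    rec.phase.value,
                    repr(rec.enthalpy),
                    "" if rec.electronic_energy is None else repr(rec.electronic_energy),
                    "" if rec.homo is None else repr(rec.homo),
                    "" if rec.lumo is None else repr(rec.lumo),
                ]
            )


def select(
    records: Sequence[SpeciesRecord],
    *,
    molecule_id: str | None = None,
    form: Form | None = None,
    site: str | None = None,
    phase: Phase | None = None,
) -> list[SpeciesRecord]:
    """Filter a record collection on any subset of the key fields."""
    out = list(records)
    if molecule_id is not None:
        out = [r for r in out if r.molecule_id == molecule_id]
    if form is not None:
        out = [r for r in out if r.form is Form(form)]
    if site is not None:
        want = normalize_site(site)
        out = [r for r in out if r.site == want]
    if phase is not None:
        out = [r for r in out if r.phase is Phase(phase)]
    return out
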