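"""Structure-derived property counting on a molecular graph.

Thin, convention-pinned layer over RDKit. The conventions matter more than
the counting itself, because druglikeness rules were calibrated against
specific definitions:

* **HBA** is the original Lipinski N+O heavy-atom count — *not* filtered by
  lone-pair availability, so a charged aromatic oxygen (the pyrylium O+ of
  an anthocyanidin) counts.
* **HBD** is the number of hydrogens attached to N or O.
* **Rotatable bonds** are non-ring single bonds between two non-terminal
  heavy atoms (terminal = exactly one heavy neighbour), amide C–N excluded.
  An O–CH3 bond is therefore *not* rotatable (methyl is terminal) but the
  aryl–O bond feeding it is.
* **TPSA** is the Ertl fragment-contribution sum.
* **MW** uses standard atomic weights; the missing electron of a cation is
  ignored.
"""

from __future__ import annotations

from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

from .units import round_half_up

__all__ = [
    "StructureParseError",
    "parse_structure",
    "molecular_weight",
    "count_heavy_atoms",
    "count_hbd",
    "count_hba",
    "count_rotatable",
    "tpsa",
    "structure_properties",
]

# RDKit logs parse diagnostics to stderr; errors are surfaced as exceptions
RDLogger.DisableLog("rdApp.error")


class StructureParseError(ValueError):
    """A SMILES string could not be parsed into a valid molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"cannot parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string; aromaticity perceived, implicit H assigned.

    Raises :class:`StructureParseError` carrying the offending atom/token
    position when RDKit can localise the problem.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise StructureParseError(smiles, "syntax error (e.g. unclosed ring or branch)")
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        p = problems[0]
        detail = p.Message()
        if hasattr(p, "GetAtomIdx"):
            detail += f" (atom index {p.GetAtomIdx()})"
        raise StructureParseError(smiles, detail)
    Chem.SanitizeMol(mol)
    return mol


def _as_mol(structure: str | Chem.Mol) -> Chem.Mol:
    return parse_structure(structure) if isinstance(structure, str) else structure


def molecular_weight(structure: str | Chem.Mol) -> float:
    """Average molecular weight in Dalton (electron mass of ions ignored)."""
    return Descriptors.MolWt(_as_mol(structure))


def count_heavy_atoms(structure: str | Chem.Mol) -> int:
    return _as_mol(structure).GetNumHeavyAtoms()


def count_hbd(structure: str | Chem.Mol) -> int:
    """Hydrogen-bond donors: hydrogens attached to N or O."""
    return Lipinski.NHOHCount(_as_mol(structure))


def count_hba(structure: str | Chem.Mol) -> int:
    """Hydrogen-bond acceptors by the Lipinski N+O atom-count convention."""
    return Lipinski.NOCount(_as_mol(structure))


def count_rotatable(structure: str | Chem.Mol) -> int:
    """Rotatable bonds by the strict non-terminal/non-amide definition."""
    return rdMolDescriptors.CalcNumRotatableBonds(
        _as_mol(structure), rdMolDescriptors.NumRotatableBondsOptions.Strict
    )


def tpsa(structure: str | Chem.Mol) -> float:
    """Topological polar surface area (Å²), Ertl fragment contributions."""
    return rdMolDescriptors.CalcTPSA(_as_mol(structure))


def structure_properties(structure: str | Chem.Mol) -> dict[str, float | int]:
    """All countable properties of one structure (MW rounded to 2 decimals)."""
    mol = _as_mol(structure)
    return {
        "natoms": count_heavy_atoms(mol),
        "mw": round_half_up(molecular_weight(mol), 2),
        "nhbd": count_hbd(mol),
        "nhba": count_hba(mol),
        "nrotb": count_rotatable(mol),
        "tpsa": tpsa(mol),
    }
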