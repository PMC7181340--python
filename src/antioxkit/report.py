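"""Report generation: descriptor, antioxidant and druglikeness tables.

The presentation layer does no arithmetic — every number in a report is
produced by an operation in the computational modules and only *rounded*
here (2 decimals half-up for eV and kcal/mol, 3 for the drug score).
Reports are byte-deterministic for identical inputs: no timestamps, sorted
JSON keys, fixed row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import descriptors as desc
from . import druglikeness as dl
from . import mechanisms as mech
from . import properties as props_mod
from . import sites as sites_mod
from .fixtures import PetunidinFixture, petunidin_fixture
from .species import Phase, PhaseReferences, ReferenceEnthalpies, read_species_table
from .units import round_half_up

__all__ = [
    "RunConfig",
    "load_config",
    "run_descriptors",
    "run_antioxidant",
    "run_druglike",
    "report_all",
]


@dataclass
class RunConfig:
    """Inputs, policy flags and output selection for one pipeline run.

    With no input paths the bundled petunidin fixture is used. Flags default
    to the published-table-matching behaviour.
    """

    species_table: Path | None = None
    site_evidence: Path | None = None
    properties_file: Path | None = None
    smiles: str | None = None
    phases: tuple[str, ...] = ("gas", "water")
    reference_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    include_electron: bool = False
    exclude_nonpositive_pa: bool = True
    literal_spline_params: bool = False
    out_dir: Path = Path("antioxkit-report")
    formats: tuple[str, ...] = ("csv", "json")

    def __post_init__(self):
        for name in ("species_table", "site_evidence", "properties_file"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        self.out_dir = Path(self.out_dir)

    @property
    def use_fixture(self) -> bool:
        return self.species_table is None

    def references(self) -> ReferenceEnthalpies:
        """Resolve reference enthalpies: overrides on top of defaults."""
        if not self.reference_overrides:
            from .fixtures import FIXTURE_REFERENCES
            from .species import default_references

            return FIXTURE_REFERENCES if self.use_fixture else default_references()
        phases = {}
        for phase, vals in self.reference_overrides.items():
            phases[phase] = PhaseReferences(
                h_atom=vals["h_atom"],
                proton=vals["proton"],
                electron=vals.get("electron", 0.0),
            )
        return ReferenceEnthalpies(
            gas=phases.get("gas", ReferenceEnthalpies().gas),
            water=phases.get("water"),
        )


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _write(df: pd.DataFrame, config: RunConfig, name: str) -> list[Path]:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out = []
    if "csv" in config.formats:
        path = config.out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        out.append(path)
    return out


def _write_json(payload: dict, config: RunConfig, name: str) -> list[Path]:
    if "json" not in config.formats:
        return []
    config.out_dir.mkdir(parents=True, exist_ok=True)
    path = config.out_dir / f"{name}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n")
    return [path]


_DESCRIPTOR_ROWS = (
    ("IP", "ip"),
    ("EA", "ea"),
    ("hardness", "hardness"),
    ("softness", "softness"),
    ("electronegativity", "electronegativity"),
    ("chemical_potential", "chemical_potential"),
    ("electrophilicity", "electrophilicity"),
)


def run_descriptors(config: RunConfig, fixture: PetunidinFixture | None = None) -> dict:
    """Global-descriptor report: descriptor × (molecule, method) table.

    Fixture runs evaluate both methods for both bundled molecules from
    their IP/EA pairs; file runs use the orbital (Koopmans) route from the
    neutral species' frontier orbitals.
    """
    bundles: list[tuple[str, str, desc.ReactivityDescriptors]] = []
    wavelengths: dict[str, float] = {}
    if config.use_fixture:
        fx = fixture or petunidin_fixture()
        for (molecule, method), (ip, ea) in sorted(fx.ip_ea.items()):
            bundles.append((molecule, method, desc.global_descriptors(ip, ea, method)))
        wavelengths = {
            "gas": desc.gap_to_wavelength(fx.gap_gas_ev),
            "water": desc.gap_to_wavelength(fx.gap_water_ev),
        }
    else:
        records = read_species_table(config.species_table)
        neutrals = [r for r in records if r.homo is not None and r.lumo is not None]
        if not neutrals:
            raise ValueError(
                "species table carries no HOMO/LUMO values; cannot compute "
                "orbital-method descriptors"
            )
        for rec in neutrals:
            ip, ea = desc.koopmans_ip_ea(rec.homo, rec.lumo)
            bundles.append(
                (rec.molecule_id, "orbital", desc.global_descriptors(ip, ea, "orbital"))
            )
            gap = rec.lumo - rec.homo
            if gap > 0:
                wavelengths[f"{rec.molecule_id}/{rec.phase.value}"] = desc.gap_to_wavelength(gap)

    rows = []
    for label, attr in _DESCRIPTOR_ROWS:
        row: dict[str, Any] = {"descriptor": label}
        for molecule, method, bundle in bundles:
            row[f"{molecule}/{method}"] = bundle.rounded()[attr]
        rows.append(row)
    table = pd.DataFrame(rows)
    payload = {
        "descriptors_ev": {
            f"{molecule}/{method}": bundle.rounded() for molecule, method, bundle in bundles
        },
        "wavelength_nm": {k: round_half_up(v, 1) for k, v in wavelengths.items()},
    }
    files = _write(table, config, "descriptors") + _write_json(payload, config, "descriptors")
    return {"table": table, "payload": payload, "files": files}


def run_antioxidant(config: RunConfig, fixture: PetunidinFixture | None = None) -> dict:
    """Antioxidant report: per-site mechanism parameters and the verdict."""
    refs = config.references()
    if config.use_fixture:
        fx = fixture or petunidin_fixture()
        species = list(fx.species)
    else:
        species = read_species_table(config.species_table)

    frames = []
    verdicts: dict[str, Any] = {}
    orderings: dict[str, str] = {}
    warnings_list: list[str] = []
    policy = mech.MechanismPolicy(exclude_nonpositive=config.exclude_nonpositive_pa)
    for phase_name in config.phases:
        phase = Phase(phase_name)
        subset = [r for r in species if r.phase is phase]
        if not subset:
            warnings_list.append(f"no species for phase {phase.value!r}; skipped")
            continue
        table = mech.site_table(
            subset, refs, phase=phase, include_electron=config.include_electron
        )
        frame = mech.site_table_frame(table)
        for col in ("bde", "aip", "pde", "pa", "ete"):
            frame[col] = frame[col].map(
                lambda v: None if pd.isna(v) else round_half_up(v, 2)
            )
        frames.append(frame)
        ranked = sorted((t for t in table if t.bde is not None), key=lambda t: t.bde)
        orderings[phase.value] = " < ".join(t.site for t in ranked)
        verdict = mech.preferred_mechanism(table, policy)
        verdicts[phase.value] = {
            "mechanism": verdict.mechanism.value,
            "first_step_kcal": round_half_up(verdict.first_step_parameter, 2),
            "excluded": [
                {"mechanism": m.value, "reason": reason} for m, reason in verdict.excluded
            ],
        }

    table_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    payload = {
        "site_ordering_by_bde": orderings,
        "mechanism_verdict": verdicts,
        "warnings": warnings_list,
    }
    if config.use_fixture:
        fx = fixture or petunidin_fixture()
        parent = mech.site_table(fx.species_for(Phase.GAS), refs, phase=Phase.GAS)
        for name, variant_records in (
            ("amino", fx.amino_species),
            ("glucoside", fx.glucoside_species),
        ):
            variant = mech.site_table(list(variant_records), refs, phase=Phase.GAS)
            effect = mech.substituent_effect(parent, variant)
            payload.setdefault("substituent_effects", {})[name] = {
                "delta_bde_kcal": {
                    s: round_half_up(d, 2) for s, d in sorted(effect.delta_bde.items())
                },
                "not_comparable": list(effect.not_comparable),
                "verdict": effect.verdict.value,
            }
    files = _write(table_df, config, "site_thermo") + _write_json(
        payload, config, "antioxidant"
    )
    return {"table": table_df, "payload": payload, "files": files}


def run_druglike(config: RunConfig, fixture: PetunidinFixture | None = None) -> dict:
    """Druglikeness report: rule checks, bioactivity classes, drug score."""
    bioactivity: dict[str, float] = {}
    if config.use_fixture:
        fx = fixture or petunidin_fixture()
        counted = props_mod.structure_properties(fx.smiles)
        rule_props = fx.properties
        score_props = fx.osiris_properties
        bioactivity = fx.bioactivity
    else:
        counted = (
            props_mod.structure_properties(config.smiles) if config.smiles else {}
        )
        if config.properties_file is None:
            raise ValueError(
                "druglikeness needs a properties file (logP/logS/druglikeness "
                "are external-predictor inputs that cannot be computed from "
                "the structure)"
            )
        raw = json.loads(Path(config.properties_file).read_text())
        bioactivity = raw.pop("bioactivity", {})
        merged = {**counted, **raw}
        merged.pop("heavy_atoms", None)
        rule_props = score_props = dl.MolecularProperties(**merged)

    ro5 = dl.lipinski_violations(rule_props)
    veber = dl.veber_check(rule_props)
    score = dl.drug_score(score_props, literal_params=config.literal_spline_params)
    rules_df = pd.DataFrame(
        [
            {"rule": r.name, "observed": r.observed, "passed": r.passed}
            for r in ro5.rules + veber.rules
        ]
    )
    payload = {
        "structure_counts": {
            k: (round_half_up(v, 2) if isinstance(v, float) else v)
            for k, v in counted.items()
        },
        "lipinski_violations": ro5.violations,
        "veber_pass": veber.passed,
        "bioactivity_classes": {
            target: dl.bioactivity_class(score_val).value
            for target, score_val in sorted(bioactivity.items())
        },
        "drug_score": round_half_up(score, 3),
    }
    files = _write(rules_df, config, "rules") + _write_json(payload, config, "druglike")
    return {"table": rules_df, "payload": payload, "files": files}


def report_all(config: RunConfig) -> dict:
    """Run every report and write one consolidated JSON."""
    fx = petunidin_fixture() if config.use_fixture else None
    out = {
        "descriptors": run_descriptors(config, fx),
        "antioxidant": run_antioxidant(config, fx),
        "druglike": run_druglike(config, fx),
    }
    consolidated = {name: section["payload"] for name, section in out.items()}
    files = _write_json(consolidated, config, "report")
    out["files"] = files
    return out
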