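"""Synthetic species tables with known thermochemical ground truth.

Real inputs to this pipeline are DFT thermochemistry runs. This module
*inverse-constructs* them: given target mechanism parameters, it solves the
defining equations backwards for species enthalpies, so that running the
forward pipeline must recover the targets exactly —

* radical(site)  = neutral + BDE − H(H•)
* radical cation = neutral + AIP
* anion(site)    = neutral + PA − H(H+)

PDE and ETE then *emerge* from the cycle (they are never prescribed
independently), which guarantees thermodynamic-cycle closure by
construction. The bundled petunidin fixture encodes the published gas-phase
parameters of the flavylium pigment petunidin (and its amino- and
glucosyl-substituted variants), its per-site evidence table, property
vectors and bioactivity scores, so the full pipeline runs end-to-end with no
quantum-chemistry engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .druglikeness import MolecularProperties, ToxicityRisk
from .mechanisms import CYCLE_TOL_KCAL
from .sites import SiteEvidence
from .species import (
    Form,
    Phase,
    PhaseReferences,
    ReferenceEnthalpies,
    SpeciesRecord,
)
from .units import HARTREE_TO_KCAL

__all__ = [
    "FixtureSpec",
    "make_species_set",
    "random_fixture_spec",
    "make_property_sets",
    "PetunidinFixture",
    "petunidin_fixture",
    "PETUNIDIN_SMILES",
    "FIXTURE_REFERENCES",
    "write_fixture_data",
]

# ---------------------------------------------------------------------------
# Inverse construction

#: canonical flavonoid O–H site order used by the bundled fixtures
CANONICAL_SITES = ("3", "5", "7", "3'", "4'")


@dataclass(frozen=True)
class FixtureSpec:
    """Targets for one inverse-constructed molecule+phase species set.

    ``bde`` and (optionally) ``pa``/``ete`` are per-site targets in
    kcal/mol; ``aip`` is the single ionization target. A site may prescribe
    PA or ETE but not both unless they agree with the closure identity.
    """

    molecule_id: str
    refs: PhaseReferences
    bde: dict[str, float]
    phase: Phase = Phase.GAS
    neutral_anchor: float = -1143.88
    aip: float | None = None
    pa: dict[str, float] = field(default_factory=dict)
    ete: dict[str, float] = field(default_factory=dict)
    homo: float | None = None
    lumo: float | None = None

    def __post_init__(self):
        if not self.bde:
            raise ValueError("at least one site BDE target is required")
        for name, targets in (("bde", self.bde), ("pa", self.pa), ("ete", self.ete)):
            for site, val in targets.items():
                if not np.isfinite(val):
                    raise ValueError(f"{name} target for site {site!r} is not finite")


def make_species_set(spec: FixtureSpec) -> list[SpeciesRecord]:
    """Solve species enthalpies from the targets (all in hartree).

    Raises ``ValueError`` for an over-constrained site where both PA and ETE
    are prescribed but disagree with the cycle identity
    ``PA + ETE = BDE + H(H+) − H(H•)``.
    """
    r = spec.refs
    h_n = spec.neutral_anchor
    records = [
        SpeciesRecord(
            molecule_id=spec.molecule_id,
            form=Form.NEUTRAL,
            phase=spec.phase,
            enthalpy=h_n,
            electronic_energy=h_n,
            homo=spec.homo,
            lumo=spec.lumo,
        )
    ]
    if spec.aip is not None:
        records.append(
            SpeciesRecord(
                molecule_id=spec.molecule_id,
                form=Form.RADICAL_CATION,
                phase=spec.phase,
                enthalpy=h_n + spec.aip / HARTREE_TO_KCAL,
            )
        )
    for site, bde_target in spec.bde.items():
        h_rad = h_n + bde_target / HARTREE_TO_KCAL - r.h_atom
        records.append(
            SpeciesRecord(
                molecule_id=spec.molecule_id,
                form=Form.RADICAL,
                site=site,
                phase=spec.phase,
                enthalpy=h_rad,
            )
        )
        pa_target = spec.pa.get(site)
        ete_target = spec.ete.get(site)
        if pa_target is not None and ete_target is not None:
            closure = bde_target + (r.proton - r.h_atom) * HARTREE_TO_KCAL
            if abs(pa_target + ete_target - closure) > CYCLE_TOL_KCAL:
                raise ValueError(
                    f"site {site!r} over-constrained: PA {pa_target} + ETE "
                    f"{ete_target} != BDE + H(H+) − H(H•) = {closure:.6f} kcal/mol"
                )
        if pa_target is not None:
            h_anion = h_n + pa_target / HARTREE_TO_KCAL - r.proton
        elif ete_target is not None:
            h_anion = h_rad - ete_target / HARTREE_TO_KCAL
        else:
            h_anion = None
        if h_anion is not None:
            records.append(
                SpeciesRecord(
                    molecule_id=spec.molecule_id,
                    form=Form.ANION,
                    site=site,
                    phase=spec.phase,
                    enthalpy=h_anion,
                )
            )
    return records


def random_fixture_spec(
    seed: int | np.random.Generator,
    molecule_id: str = "random",
    n_sites: int = 5,
    phase: Phase = Phase.GAS,
) -> FixtureSpec:
    """Seeded random targets over realistic phenolic ranges.

    BDEs 60–110 kcal/mol, AIP 120–260, PA drawn wide enough (−150 to 350)
    to exercise the sign-anomaly policy; references near the gas-phase
    literature conventions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = [str(i + 1) for i in range(n_sites)]
    refs = PhaseReferences(
        h_atom=float(-0.5 + rng.uniform(-0.01, 0.01)),
        proton=float(rng.uniform(0.0, 0.01)),
        electron=float(rng.uniform(0.0, 0.005)),
    )
    return FixtureSpec(
        molecule_id=molecule_id,
        refs=refs,
        phase=phase,
        neutral_anchor=float(rng.uniform(-2000.0, -300.0)),
        bde={s: float(rng.uniform(60.0, 110.0)) for s in sites},
        aip=float(rng.uniform(120.0, 260.0)),
        pa={s: float(rng.uniform(-150.0, 350.0)) for s in sites},
    )


# ---------------------------------------------------------------------------
# Property-set sampler for the druglikeness layer

_TOX_LEVELS = (ToxicityRisk.NONE, ToxicityRisk.MEDIUM, ToxicityRisk.HIGH)
_TOX_WEIGHTS = (0.7, 0.2, 0.1)


def make_property_sets(n: int, seed: int) -> list[MolecularProperties]:
    """Seeded sampler of druglikeness property vectors.

    Ranges straddle the transition regions of all four drug-score logistic
    terms (clogP around 5, logS around −5, MW around 500, druglikeness
    around 0) and all toxicity levels occur, so a sample of moderate size
    exercises the full dynamic range of the score.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        toxicity = {
            cat: _TOX_LEVELS[int(rng.choice(len(_TOX_LEVELS), p=_TOX_WEIGHTS))]
            for cat in ("mutagenic", "tumorigenic", "irritant", "reproductive")
        }
        out.append(
            MolecularProperties(
                mw=float(rng.uniform(100.0, 900.0)),
                milogp=float(rng.uniform(-2.0, 9.0)),
                logs=float(rng.uniform(-9.0, 1.0)),
                tpsa=float(rng.uniform(20.0, 220.0)),
                nhba=int(rng.integers(0, 15)),
                nhbd=int(rng.integers(0, 10)),
                nrotb=int(rng.integers(0, 15)),
                natoms=int(rng.integers(5, 60)),
                druglikeness=float(rng.uniform(-8.0, 8.0)),
                toxicity=toxicity,
            )
        )
    return out


# ---------------------------------------------------------------------------
# The petunidin fixture (published values transcribed)

PETUNIDIN_SMILES = "COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2O)cc(O)c1O"

# The published gas-phase two-step sums AIP+PDE = PA+ETE = 392.47 kcal/mol
# against BDE 78.72 imply H(H+) − H(H•) = 313.75 kcal/mol. The fixture
# adopts the simplest references realising that difference exactly, so the
# emergent PDE (162.56) and ETE (505.15) match the published table to the
# printed precision. This is a fixture convention, distinct from the
# package-level literature defaults.
_FIX_PHASE_REFS = PhaseReferences(
    h_atom=-313.75 / HARTREE_TO_KCAL, proton=0.0, electron=0.00120
)
FIXTURE_REFERENCES = ReferenceEnthalpies(gas=_FIX_PHASE_REFS, water=_FIX_PHASE_REFS)

# gas-phase site BDEs, kcal/mol (parent column; ordering 3 < 4' < 5 < 7 < 3')
_BDE_GAS = {"3": 78.72, "5": 85.06, "7": 88.94, "3'": 90.25, "4'": 79.84}
# aqueous: only site 3 (77.02) is published; other sites carry the same
# −1.70 kcal/mol solvation shift (synthetic)
_BDE_WATER = {s: (77.02 if s == "3" else round(v - 1.70, 2)) for s, v in _BDE_GAS.items()}
_AIP_GAS = 229.91
_PA_GAS_SITE3 = -112.68
# published PA exists for site 3 only; other sites shifted with their BDE
# (synthetic), keeping the emergent ETE site-independent
_PA_GAS = {s: round(_PA_GAS_SITE3 + (v - _BDE_GAS["3"]), 2) for s, v in _BDE_GAS.items()}

# substituted variants, site BDEs in kcal/mol: the methoxy→amino swap and
# the 3-O-glucoside (whose site 3 O–H no longer exists)
_BDE_AMINO = {"3": 74.26, "5": 80.21, "7": 84.18, "3'": 89.59, "4'": 79.01}
_BDE_GLUCOSIDE = {"5": 82.03, "7": 85.92, "3'": 88.11, "4'": 78.06}

# frontier orbitals of the neutral pigment, eV (gap 2.57)
_PT_HOMO, _PT_LUMO = -8.73, -6.16

# IP/EA pairs per molecule and method, eV. Q = quercetin comparison values.
IP_EA_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("PT", "orbital"): (8.73, 6.16),
    ("PT", "energy"): (9.97, 4.87),
    ("Q", "orbital"): (5.46, 1.85),
    ("Q", "energy"): (6.71, 0.55),
}

# per-site evidence: Wiberg O–H bond orders and pKa/DE are published; the
# site-oxygen natural charge is published for site 3 only (−0.555), the
# remaining charges are synthetic but keep site 3 the most negative
_SITE_EVIDENCE = {
    "3": dict(bond_order=0.6825, pka=5.99, de=390.99, atomic_charge=-0.555),
    "5": dict(bond_order=0.7180, pka=6.81, de=397.33, atomic_charge=-0.512),
    "7": dict(bond_order=0.7195, pka=7.80, de=401.21, atomic_charge=-0.498),
    "3'": dict(bond_order=0.7270, pka=8.69, de=402.53, atomic_charge=-0.487),
    "4'": dict(bond_order=0.7100, pka=11.97, de=392.11, atomic_charge=-0.524),
}

# bioactivity scores against the six standard target classes
BIOACTIVITY_SCORES = {
    "GPCR ligand": -0.15,
    "Ion channel modulator": -0.17,
    "Kinase inhibitor": 0.03,
    "Nuclear receptor ligand": 0.01,
    "Protease inhibitor": -0.29,
    "Enzyme inhibitor": -0.01,
}


@dataclass(frozen=True)
class PetunidinFixture:
    """Everything needed to run the full pipeline on petunidin.

    ``properties`` is the structure/count vector (Molinspiration-style,
    logP −0.73); ``osiris_properties`` is the fragment-score vector feeding
    the drug score (clogP 1.980, logS −2.338, druglikeness 1.310).
    """

    species: tuple[SpeciesRecord, ...]
    amino_species: tuple[SpeciesRecord, ...]
    glucoside_species: tuple[SpeciesRecord, ...]
    references: ReferenceEnthalpies
    site_evidence: tuple[SiteEvidence, ...]
    properties: MolecularProperties
    osiris_properties: MolecularProperties
    bioactivity: dict[str, float]
    ip_ea: dict[tuple[str, str], tuple[float, float]]
    smiles: str
    gap_gas_ev: float
    gap_water_ev: float

    def species_for(self, phase: Phase | str) -> list[SpeciesRecord]:
        phase = Phase(phase)
        return [r for r in self.species if r.phase is phase]


def _petunidin_spec(phase: Phase) -> FixtureSpec:
    gas = phase is Phase.GAS
    return FixtureSpec(
        molecule_id="PT",
        refs=_FIX_PHASE_REFS,
        phase=phase,
        neutral_anchor=-1143.88,
        bde=dict(_BDE_GAS if gas else _BDE_WATER),
        aip=_AIP_GAS,
        pa=dict(_PA_GAS),
        homo=_PT_HOMO if gas else None,
        lumo=_PT_LUMO if gas else None,
    )


def petunidin_fixture() -> PetunidinFixture:
    """Build the bundled petunidin fixture (deterministic, no I/O)."""
    species = tuple(
        make_species_set(_petunidin_spec(Phase.GAS))
        + make_species_set(_petunidin_spec(Phase.WATER))
    )
    amino = tuple(
        make_species_set(
            FixtureSpec(
                molecule_id="PT-NH2",
                refs=_FIX_PHASE_REFS,
                bde=dict(_BDE_AMINO),
                neutral_anchor=-1124.02,
            )
        )
    )
    glucoside = tuple(
        make_species_set(
            FixtureSpec(
                molecule_id="PT-3-glucoside",
                refs=_FIX_PHASE_REFS,
                bde=dict(_BDE_GLUCOSIDE),
                neutral_anchor=-1754.65,
            )
        )
    )
    evidence = tuple(
        SiteEvidence(site=s, bde=_BDE_GAS[s], **_SITE_EVIDENCE[s]) for s in CANONICAL_SITES
    )
    properties = MolecularProperties(
        mw=317.27,
        milogp=-0.73,
        tpsa=121.54,
        nhba=7,
        nhbd=5,
        nrotb=2,
        natoms=23,
        volume=260.36,
    )
    osiris = MolecularProperties(
        mw=317.27,
        milogp=1.980,
        logs=-2.338,
        druglikeness=1.310,
    )
    return PetunidinFixture(
        species=species,
        amino_species=amino,
        glucoside_species=glucoside,
        references=FIXTURE_REFERENCES,
        site_evidence=evidence,
        properties=properties,
        osiris_properties=osiris,
        bioactivity=dict(BIOACTIVITY_SCORES),
        ip_ea=dict(IP_EA_TABLE),
        smiles=PETUNIDIN_SMILES,
        gap_gas_ev=2.57,
        gap_water_ev=2.71,
    )


# ---------------------------------------------------------------------------
# Package-data writer (regenerates the shipped CSV/YAML fixture files)


def write_fixture_data(directory: str | Path) -> list[Path]:
    """Write the petunidin fixture to the standard file formats.

    Produces the species-table CSVs (parent gas+water, amino and glucoside
    variants), the site-evidence CSV and a YAML manifest of expected
    pipeline outputs with tolerances. Used to (re)generate the package-data
    copies; byte-deterministic.
    """
    import yaml

    from .sites import write_site_evidence
    from .species import write_species_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fx = petunidin_fixture()
    written = []

    paths = {
        "petunidin_species.csv": fx.species,
        "petunidin_amino_species.csv": fx.amino_species,
        "petunidin_glucoside_species.csv": fx.glucoside_species,
    }
    for name, records in paths.items():
        path = directory / name
        write_species_table(records, path)
        written.append(path)
    ev_path = directory / "petunidin_site_evidence.csv"
    write_site_evidence(fx.site_evidence, ev_path)
    written.append(ev_path)

    manifest = {
        "molecule": "petunidin (PT)",
        "references_hartree": {
            "h_atom": _FIX_PHASE_REFS.h_atom,
            "proton": _FIX_PHASE_REFS.proton,
            "electron": _FIX_PHASE_REFS.electron,
            "note": (
                "fixture convention: H(H+) - H(H.) = 313.75 kcal/mol exactly, "
                "as implied by the published two-step sums (392.47 kcal/mol)"
            ),
        },
        "expected": {
            "bde_gas_kcal": _BDE_GAS,
            "bde_water_site3_kcal": 77.02,
            "aip_gas_kcal": _AIP_GAS,
            "pde_gas_site3_kcal": 162.56,
            "pa_gas_site3_kcal": _PA_GAS_SITE3,
            "ete_gas_site3_kcal": 505.15,
            "site_order_by_bde": "3 < 4' < 5 < 7 < 3'",
            "preferred_mechanism": "HAT",
            "gap_gas_ev": 2.57,
            "wavelength_gas_nm": {"value": 483, "tol_nm": 1.0},
            "drug_score": {"value": 0.804, "tol": 0.005},
            "tpsa": {"value": 121.54, "tol": 2.5},
            "lipinski_violations": 0,
        },
        "synthetic_fields": [
            "aqueous BDEs at sites other than 3 (gas value - 1.70)",
            "aqueous AIP/PA (carried over from gas)",
            "PA at sites other than 3 (shifted with BDE)",
            "site-oxygen charges at sites other than 3",
        ],
        "documented_discrepancies": [
            "orbital-method electrophilicity printed as 29.54 eV; the "
            "defining equations give 21.57 eV from IP 8.73 / EA 6.16 "
            "(followed the equations)",
            "a few descriptor cells are last-digit truncated rather than "
            "rounded (softness 0.19 vs 0.196); reports round half-up",
        ],
    }
    manifest_path = directory / "petunidin_expected.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(manifest_path)
    return written
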