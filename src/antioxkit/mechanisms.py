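"""Thermochemistry of the radical-scavenging mechanisms of phenolic O–H sites.

A phenolic antioxidant ArOH can quench a free radical three ways, each
governed by the enthalpy of its first (or only) step:

* **HAT** — direct hydrogen atom transfer, governed by the O–H bond
  dissociation enthalpy ``BDE = H(ArO•) + H(H•) − H(ArOH)``;
* **SET-PT** — electron transfer then proton loss:
  ``AIP = H(ArOH•+) − H(ArOH)`` then ``PDE = H(ArO•) + H(H+) − H(ArOH•+)``;
* **SPLET** — proton loss then electron transfer:
  ``PA = H(ArO−) + H(H+) − H(ArOH)`` then ``ETE = H(ArO•) − H(ArO−)``.

All species enthalpies are in hartree; parameters are reported in kcal/mol.
The two-step routes close a thermodynamic cycle with HAT:
``AIP + PDE = PA + ETE = BDE + H(H+) − H(H•)`` — an exact identity used here
to validate consistency of an input species set.

The AIP as written omits the electron enthalpy of the detached electron;
``include_electron=True`` restores the thermodynamically complete convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .species import (
    Form,
    Phase,
    PhaseReferences,
    ReferenceEnthalpies,
    SpeciesRecord,
    select,
)
from .units import HARTREE_TO_KCAL

__all__ = [
    "SiteThermo",
    "Mechanism",
    "MechanismPolicy",
    "MechanismVerdict",
    "SubstituentEffect",
    "bde",
    "aip",
    "pde",
    "pa",
    "ete",
    "site_table",
    "site_table_frame",
    "preferred_mechanism",
    "substituent_effect",
    "CycleClosureError",
]

#: tolerance (kcal/mol) for the AIP+PDE = PA+ETE = BDE + H(H+) − H(H•) identity
CYCLE_TOL_KCAL = 1e-6


class CycleClosureError(ValueError):
    """A species set violates the HAT/SET-PT/SPLET thermodynamic cycle."""


def _to_kcal(hartree: float) -> float:
    return hartree * HARTREE_TO_KCAL


def _refs_for(refs: ReferenceEnthalpies | PhaseReferences, phase: Phase | str) -> PhaseReferences:
    if isinstance(refs, PhaseReferences):
        return refs
    return refs.for_phase(Phase(phase))


def _pair(
    a: float | SpeciesRecord, b: float | SpeciesRecord, phase: Phase | str
) -> tuple[float, float, Phase | str]:
    """Resolve two enthalpies that may arrive as records or bare hartree.

    When both are records they must share molecule and phase; a record's
    phase overrides the ``phase`` argument.
    """
    if isinstance(a, SpeciesRecord) and isinstance(b, SpeciesRecord):
        if a.phase is not b.phase:
            raise ValueError(
                f"phase mismatch between species: {a.phase.value} vs {b.phase.value}"
            )
        if a.molecule_id != b.molecule_id:
            raise ValueError(
                f"molecule mismatch between species: {a.molecule_id!r} vs {b.molecule_id!r}"
            )
    for rec in (a, b):
        if isinstance(rec, SpeciesRecord):
            phase = rec.phase
            break
    ha = a.enthalpy if isinstance(a, SpeciesRecord) else float(a)
    hb = b.enthalpy if isinstance(b, SpeciesRecord) else float(b)
    return ha, hb, phase


def bde(
    h_parent: float | SpeciesRecord,
    h_radical: float | SpeciesRecord,
    refs: ReferenceEnthalpies | PhaseReferences,
    phase: Phase | str = Phase.GAS,
) -> float:
    """O–H bond dissociation enthalpy in kcal/mol (HAT parameter)."""
    h_parent, h_radical, phase = _pair(h_parent, h_radical, phase)
    r = _refs_for(refs, phase)
    return _to_kcal(h_radical + r.h_atom - h_parent)


def aip(
    h_parent: float | SpeciesRecord,
    h_radical_cation: float | SpeciesRecord,
    refs: ReferenceEnthalpies | PhaseReferences,
    phase: Phase | str = Phase.GAS,
    include_electron: bool = False,
) -> float:
    """Adiabatic ionization potential in kcal/mol (SET / SET-PT first step).

    By default the detached electron's enthalpy is omitted, matching the
    common shorthand ``AIP = H(ArOH•+) − H(ArOH)``; pass
    ``include_electron=True`` for the complete convention.
    """
    h_parent, h_radical_cation, phase = _pair(h_parent, h_radical_cation, phase)
    r = _refs_for(refs, phase)
    value = h_radical_cation - h_parent
    if include_electron:
        value += r.electron
    return _to_kcal(value)


def pde(
    h_radical: float | SpeciesRecord,
    h_radical_cation: float | SpeciesRecord,
    refs: ReferenceEnthalpies | PhaseReferences,
    phase: Phase | str = Phase.GAS,
) -> float:
    """Proton dissociation enthalpy of the radical cation in kcal/mol."""
    h_radical, h_radical_cation, phase = _pair(h_radical, h_radical_cation, phase)
    r = _refs_for(refs, phase)
    return _to_kcal(h_radical + r.proton - h_radical_cation)


def pa(
    h_parent: float | SpeciesRecord,
    h_anion: float | SpeciesRecord,
    refs: ReferenceEnthalpies | PhaseReferences,
    phase: Phase | str = Phase.GAS,
) -> float:
    """Proton affinity (deprotonation enthalpy) in kcal/mol (SPLET step 1).

    Sign is preserved as computed: a negative value signals a reference
    convention under which deprotonation appears exothermic, and is flagged
    downstream by the mechanism-preference policy rather than rejected here.
    """
    h_parent, h_anion, phase = _pair(h_parent, h_anion, phase)
    r = _refs_for(refs, phase)
    return _to_kcal(h_anion + r.proton - h_parent)


def ete(
    h_anion: float | SpeciesRecord,
    h_radical: float | SpeciesRecord,
    phase: Phase | str = Phase.GAS,
) -> float:
    """Electron transfer enthalpy of the phenoxide anion in kcal/mol."""
    h_anion, h_radical, phase = _pair(h_anion, h_radical, phase)
    return _to_kcal(h_radical - h_anion)


@dataclass(frozen=True)
class SiteThermo:
    """Mechanism parameters of one O–H site (kcal/mol).

    ``aip`` is site-independent but repeated per site for flat tabulation.
    Parameters whose species are missing are ``None``.
    """

    molecule_id: str
    site: str
    phase: Phase
    bde: float | None = None
    aip: float | None = None
    pde: float | None = None
    pa: float | None = None
    ete: float | None = None


def site_table(
    records: Sequence[SpeciesRecord],
    refs: ReferenceEnthalpies,
    *,
    molecule_id: str | None = None,
    phase: Phase | str | None = None,
    include_electron: bool = False,
    check_cycle: bool = True,
) -> list[SiteThermo]:
    """Per-site mechanism parameters for one molecule in one phase.

    The record collection must contain exactly one neutral species and at
    least one site radical; the radical cation and site anions are optional
    (their parameters come out ``None``). When every species of a site is
    present, the thermodynamic-cycle identity is asserted to
    ``CYCLE_TOL_KCAL`` as a consistency check of the inputs.
    """
    records = select(records, molecule_id=molecule_id, phase=phase)
    if not records:
        raise ValueError("no species records after filtering")
    mols = {r.molecule_id for r in records}
    phases = {r.phase for r in records}
    if len(mols) > 1 or len(phases) > 1:
        raise ValueError(
            f"records span molecules {sorted(mols)} and phases "
            f"{sorted(p.value for p in phases)}; filter to one molecule+phase"
        )
    (mol,) = mols
    (ph,) = phases
    r = refs.for_phase(ph)

    neutrals = select(records, form=Form.NEUTRAL)
    if not neutrals:
        raise ValueError(f"no neutral species record for {mol!r} in {ph.value}")
    h_parent = neutrals[0].enthalpy
    cations = select(records, form=Form.RADICAL_CATION)
    h_rc = cations[0].enthalpy if cations else None

    radicals = {rec.site: rec for rec in select(records, form=Form.RADICAL)}
    anions = {rec.site: rec for rec in select(records, form=Form.ANION)}
    if not radicals:
        raise ValueError(f"no site radical records for {mol!r} in {ph.value}")

    aip_val = (
        aip(h_parent, h_rc, r, ph, include_electron=include_electron)
        if h_rc is not None
        else None
    )
    out: list[SiteThermo] = []
    for site, rad in radicals.items():
        bde_val = bde(h_parent, rad.enthalpy, r, ph)
        pde_val = pde(rad.enthalpy, h_rc, r, ph) if h_rc is not None else None
        an = anions.get(site)
        pa_val = pa(h_parent, an.enthalpy, r, ph) if an is not None else None
        ete_val = ete(an.enthalpy, rad.enthalpy, ph) if an is not None else None
        row = SiteThermo(
            molecule_id=mol, site=site, phase=ph,
            bde=bde_val, aip=aip_val, pde=pde_val, pa=pa_val, ete=ete_val,
        )
        if check_cycle and None not in (aip_val, pde_val, pa_val, ete_val):
            closure = bde_val + _to_kcal(r.proton - r.h_atom)
            for label, total in (("AIP+PDE", aip_val + pde_val), ("PA+ETE", pa_val + ete_val)):
                if abs(total - closure) > CYCLE_TOL_KCAL:
                    raise CycleClosureError(
                        f"site {site!r}: {label} = {total:.8f} kcal/mol but "
                        f"BDE + H(H+) − H(H•) = {closure:.8f}"
                    )
        out.append(row)
    return out


def site_table_frame(table: Iterable[SiteThermo]) -> pd.DataFrame:
    """Flat DataFrame view of a site-thermo table (kcal/mol, full precision)."""
    rows = [
        {
            "molecule_id": t.molecule_id,
            "site": t.site,
            "phase": t.phase.value,
            "bde": t.bde,
            "aip": t.aip,
            "pde": t.pde,
            "pa": t.pa,
            "ete": t.ete,
        }
        for t in table
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mechanism preference


class Mechanism(str, enum.Enum):
    HAT = "HAT"
    SET_PT = "SET-PT"
    SPLET = "SPLET"


@dataclass(frozen=True)
class MechanismPolicy:
    """How the preferred mechanism is selected.

    First-step costs compared: minimum site BDE (HAT), AIP (SET-PT) and
    minimum site PA (SPLET). Candidates with a non-positive first-step cost
    are thermochemically anomalous under the configured reference convention
    and are excluded (with a recorded reason) rather than allowed to win the
    minimum. Ties break in ``tie_order``.
    """

    exclude_nonpositive: bool = True
    tie_order: tuple[Mechanism, ...] = (Mechanism.HAT, Mechanism.SPLET, Mechanism.SET_PT)


@dataclass(frozen=True)
class MechanismVerdict:
    mechanism: Mechanism
    first_step_parameter: float
    candidates: dict[Mechanism, float] = field(default_factory=dict)
    excluded: tuple[tuple[Mechanism, str], ...] = ()


def preferred_mechanism(
    table: Sequence[SiteThermo],
    policy: MechanismPolicy | None = None,
) -> MechanismVerdict:
    """Select the thermodynamically preferred scavenging mechanism."""
    if policy is None:
        policy = MechanismPolicy()
    if not table:
        raise ValueError("empty site table")

    bdes = [t.bde for t in table if t.bde is not None]
    if not bdes:
        raise ValueError("site table carries no BDE values")
    candidates: dict[Mechanism, float] = {Mechanism.HAT: min(bdes)}
    aips = [t.aip for t in table if t.aip is not None]
    if aips:
        candidates[Mechanism.SET_PT] = min(aips)
    pas = [t.pa for t in table if t.pa is not None]
    if pas:
        candidates[Mechanism.SPLET] = min(pas)

    excluded: list[tuple[Mechanism, str]] = []
    viable: dict[Mechanism, float] = {}
    for mech, value in candidates.items():
        if policy.exclude_nonpositive and value <= 0:
            excluded.append(
                (mech, f"first-step parameter {value:.2f} kcal/mol is non-physical (≤ 0)")
            )
        else:
            viable[mech] = value
    if not viable:
        raise ValueError(
            "all candidate mechanisms excluded as non-physical; supply an "
            "explicit MechanismPolicy(exclude_nonpositive=False) to override"
        )
    best = min(viable.values())
    for mech in policy.tie_order:
        if mech in viable and viable[mech] == best:
            winner = mech
            break
    else:  # pragma: no cover - tie_order always covers all mechanisms
        winner = min(viable, key=viable.get)
    return MechanismVerdict(
        mechanism=winner,
        first_step_parameter=viable[winner],
        candidates=candidates,
        excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Substituent effects


class EffectVerdict(str, enum.Enum):
    ALL_LOWER = "all_lower"
    ALL_HIGHER = "all_higher"
    MIXED = "mixed"
    NONE = "none"


@dataclass(frozen=True)
class SubstituentEffect:
    """Per-site BDE change (variant − parent) with an overall verdict."""

    delta_bde: dict[str, float]
    not_comparable: tuple[str, ...]
    verdict: EffectVerdict


def substituent_effect(
    parent: Sequence[SiteThermo],
    variant: Sequence[SiteThermo],
) -> SubstituentEffect:
    """Compare site BDEs of a substituted variant against the parent.

    Sites present in only one table are reported as not comparable; disjoint
    site sets are an error. Verdict: ``all_lower``/``all_higher`` when every
    shared-site Δ is strictly negative/positive, ``none`` when all Δ are
    exactly zero, ``mixed`` otherwise.
    """
    p = {t.site: t.bde for t in parent if t.bde is not None}
    v = {t.site: t.bde for t in variant if t.bde is not None}
    shared = sorted(p.keys() & v.keys())
    if not shared:
        raise ValueError("parent and variant share no sites with BDE values")
    delta = {site: v[site] - p[site] for site in shared}
    not_comparable = tuple(sorted(p.keys() ^ v.keys()))
    values = list(delta.values())
    if all(d < 0 for d in values):
        verdict = EffectVerdict.ALL_LOWER
    elif all(d > 0 for d in values):
        verdict = EffectVerdict.ALL_HIGHER
    elif all(d == 0 for d in values):
        verdict = EffectVerdict.NONE
    else:
        verdict = EffectVerdict.MIXED
    return SubstituentEffect(delta_bde=delta, not_comparable=not_comparable, verdict=verdict)
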