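# antioxkit

Post-processing toolkit for the computational screening of phenolic
antioxidants: it turns the raw energetics of a DFT study (species
enthalpies, frontier-orbital energies) and external property predictions
into the quantities medicinal and food chemists actually argue about —
radical-scavenging mechanism, most labile O–H site, global reactivity, and
oral druglikeness. It ships a fully inverse-constructed fixture for the
anthocyanidin pigment **petunidin** (the purple colorant of bilberries and
blue tomatoes), so the whole pipeline runs end-to-end without a
quantum-chemistry engine.

## What it computes

**Antioxidant thermochemistry.** For each phenolic O–H site, from species
enthalpies in hartree (ArOH, ArO•, ArOH•⁺, ArO⁻ plus H•/H⁺/e⁻ references):

- HAT: BDE = H(ArO•) + H(H•) − H(ArOH)
- SET-PT: AIP = H(ArOH•⁺) − H(ArOH), then PDE = H(ArO•) + H(H⁺) − H(ArOH•⁺)
- SPLET: PA = H(ArO⁻) + H(H⁺) − H(ArOH), then ETE = H(ArO•) − H(ArO⁻)

reported in kcal/mol, with the exact cycle identity
AIP + PDE = PA + ETE = BDE + H(H⁺) − H(H•) enforced as a consistency check,
a mechanism-preference verdict (minimum first-step cost, sign-anomalous
candidates excluded), and substituent-effect comparisons (ΔBDE per site).

**Global reactivity descriptors.** From IP/EA — Koopmans (IP ≈ −E_HOMO,
EA ≈ −E_LUMO) or ΔSCF (IP = E⁺ − E⁰, EA = E⁰ − E⁻) — hardness
η = (IP−EA)/2, softness S = 1/2η, electronegativity χ = (IP+EA)/2, chemical
potential μ = −χ, electrophilicity ω = μ²/2η, and the HOMO–LUMO gap →
absorption wavelength λ = hc/E.

**Site reactivity.** Ranking of O–H sites by BDE, Wiberg bond order, pKa or
oxygen charge; a concordance measure across metrics; the pH rule
(deprotonated where pH > pKa, blood pH 7.4 default).

**Druglikeness.** RDKit-backed structure counting (MW, heavy atoms, HBD,
HBA by the Lipinski N+O convention, rotatable bonds, Ertl TPSA),
boundary-inclusive rule-of-five and Veber checks, bioactivity-score
classification, and the OSIRIS-style drug score
DS = Π(½ + ½·sᵢ)·Π tⱼ with logistic sᵢ = 1/(1+e^(a·pᵢ+b)) over clogP, logS,
MW and druglikeness, and toxicity multipliers tⱼ ∈ {1.0, 0.8, 0.6}.

## Worked example

```python
>>> import antioxkit as ak
>>> fx = ak.petunidin_fixture()
>>> table = ak.site_table(fx.species_for("gas"), fx.references, phase="gas")
>>> {t.site: round(t.bde, 2) for t in sorted(table, key=lambda t: t.bde)}
{'3': 78.72, "4'": 79.84, '5': 85.06, '7': 88.94, "3'": 90.25}
>>> ak.preferred_mechanism(table).mechanism
<Mechanism.HAT: 'HAT'>
>>> round(ak.drug_score(fx.osiris_properties), 3)
0.802
>>> ak.structure_properties(fx.smiles)
{'natoms': 23, 'mw': 317.27, 'nhbd': 5, 'nhba': 7, 'nrotb': 2, 'tpsa': 121.68000000000002}
```

Reading: the site-3 hydroxyl has the lowest bond dissociation enthalpy
(78.72 kcal/mol), so petunidin scavenges radicals by direct hydrogen atom
transfer from C3; the ionization (229.91 kcal/mol) and deprotonation routes
cost far more or are sign-anomalous, so HAT wins. The drug score of 0.802
(on a 0–1 scale) together with zero rule-of-five violations marks the
pigment as orally drug-like.

The same pipeline is scriptable from the shell:

```
antioxkit report-all --out-dir report/
```

writes descriptor, site-thermochemistry and druglikeness tables (CSV) plus
one consolidated `report.json`; pass `--species-table your.csv` to run on
your own data (schema in `antioxkit.species`).

## Layout

- `src/antioxkit/species.py` — species data model, reference enthalpies, CSV I/O
- `src/antioxkit/units.py` — energy conversions, report rounding
- `src/antioxkit/descriptors.py` — conceptual-DFT global descriptors
- `src/antioxkit/mechanisms.py` — BDE/AIP/PDE/PA/ETE, mechanism verdict, substituent effects
- `src/antioxkit/sites.py` — site ranking, concordance, protonation rule
- `src/antioxkit/properties.py` — structure counting (RDKit)
- `src/antioxkit/druglikeness.py` — rule engine, bioactivity classes, drug score
- `src/antioxkit/fixtures.py` — inverse-constructed species sets, petunidin bundle, property sampler
- `src/antioxkit/report.py`, `cli.py` — reports and the `antioxkit` command
- `docs/methods.md` — model assumptions, conventions and limitations
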