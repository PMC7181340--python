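# Methods

## Scope and model

antioxkit post-processes the energetics of phenolic antioxidants. It does
not run quantum chemistry: species enthalpies, frontier-orbital energies,
Wiberg bond orders, atomic charges, pKa values and fragment-based property
predictions (logP, logS, druglikeness, toxicity flags, bioactivity scores)
are *inputs*, consumed from flat CSV/JSON tables. Everything downstream —
mechanism thermochemistry, descriptor algebra, rankings, rule checks, the
drug score — is computed by the package.

## Antioxidant mechanism thermochemistry

For a phenol ArOH and one of its O–H sites, three scavenging routes are
costed by the enthalpies of their first (or only) step, in kcal/mol:

| route  | step 1                        | step 2 |
|--------|-------------------------------|--------|
| HAT    | BDE = H(ArO•) + H(H•) − H(ArOH) | —    |
| SET-PT | AIP = H(ArOH•⁺) − H(ArOH)     | PDE = H(ArO•) + H(H⁺) − H(ArOH•⁺) |
| SPLET  | PA = H(ArO⁻) + H(H⁺) − H(ArOH) | ETE = H(ArO•) − H(ArO⁻) |

All arithmetic is done in hartree and converted once (627.5095 kcal/mol per
hartree), avoiding double rounding against 2-decimal reports. Summing the
two-step routes gives the exact identity

    AIP + PDE = PA + ETE = BDE + H(H⁺) − H(H•),

which `site_table` asserts to 1e-6 kcal/mol whenever all species of a site
are present; violation means the input species set is internally
inconsistent (e.g. mixed reference conventions).

**Conventions.** The AIP is implemented as printed above, without the
detached electron's enthalpy; `include_electron=True` restores the complete
convention. Gas-phase defaults for the references follow the phenolic-DFT
literature: H(H•) = −0.49765 + 2.5RT hartree, H(H⁺) = 2.5RT = 0.00236,
H(e⁻) = 0.00120. Aqueous references have no default — they depend on the
chosen solvation convention for H⁺/e⁻ and must be supplied.

**Mechanism preference.** The verdict compares minimum site BDE (HAT), AIP
(SET-PT) and minimum site PA (SPLET) and takes the smallest. A
non-positive first-step cost is thermochemically anomalous under a
consistent reference convention (a negative PA typically signals a missing
proton-solvation term); such candidates are excluded with a recorded reason
rather than allowed to win the minimum, configurable via
`MechanismPolicy(exclude_nonpositive=False)`. Ties break in the fixed order
HAT > SPLET > SET-PT (routes with less experimental-assay ambiguity first).

**Substituent comparison** reports Δ = variant − parent per shared site;
`all_lower`/`all_higher` require strict inequality everywhere, identical
tables report `none`, anything else `mixed`. Sites present in only one
table (e.g. a glycosylated position that lost its O–H) are listed as not
comparable.

## Global reactivity descriptors

Two IP/EA routes: Koopmans (IP = −E_HOMO, EA = −E_LUMO) and ΔSCF from
charge-state energies. From either pair (eV): η = (IP−EA)/2, χ = (IP+EA)/2,
S = 1/2η, μ = −χ, ω = μ²/2η. Exact identities μ = −χ, 2ηS = 1 and
2ηω = χ² hold to machine precision and are property-tested. A degenerate
pair (IP = EA) yields flagged infinities with a warning rather than an
exception, so batch tables survive degenerate rows. The optical conversion
is λ[nm] = 1239.842 / E[eV].

Engines keep full precision; only reports round, half-up (ties away from
zero) to 2 decimals for eV and kcal/mol and 3 for the drug score. Published
descriptor tables in this field mix truncation and rounding in their last
digit, so cross-checks against printed values should use rounding-stable
cells only.

## Site reactivity

Sites are ranked by any one metric with a stable sort (ties keep input
order and are flagged). Default directions mark the most labile site:
ascending for BDE, bond order, pKa and DE, and ascending (most negative
first) for the site-oxygen charge — the common phrase "highest charge"
refers to the magnitude of the negative charge, so the sign convention is
made explicit here. Concordance is the fraction of metrics whose extremal
site agrees with the modal extremal site; strictly monotone-equivalent
metrics give 1 by construction. The protonation rule is the textbook
Henderson–Hasselbalch limit: deprotonated where pH > pKa, with pH = pKa
flagged as half-dissociated; blood pH defaults to 7.4.

## Structure counting and druglikeness

Structure work is delegated to RDKit behind a convention-pinning layer:
HBA is the original Lipinski N+O atom count (a charged aromatic oxygen like
the anthocyanidin pyrylium O⁺ counts); HBD is H on N/O; rotatable bonds are
non-ring single bonds between two non-terminal heavy atoms with amide C–N
excluded (so O–CH₃ is not rotatable but aryl–O is); TPSA is the Ertl
fragment sum; MW ignores the electron mass of ions. These are the
definitions against which the druglikeness rules were calibrated. The
public Ertl table carries no parameter for the aromatic O⁺ fragment, so
TPSA values for flavylium cations are convention-dependent at the ±2 Å²
level; downstream checks treat TPSA with that tolerance.

Rule-of-five (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) and Veber
(TPSA ≤ 140 Å², ROTB ≤ 10) thresholds are boundary-inclusive: a molecule
with HBD exactly 5 has zero violations. Bioactivity scores classify as
considerable (> 0), moderate ([−0.5, 0], both boundaries included) or
inactive (< −0.5).

**Drug score.** DS = Π(½ + ½sᵢ)·Πtⱼ with sᵢ = 1/(1 + e^(a·pᵢ+b)) over
clogP (a,b = 1, −5), logS (−1, −5), MW (0.012, −6) and druglikeness
(−1, 0), and toxicity multipliers 1.0/0.8/0.6 for none/medium/high risk in
each of four categories (mutagenic, tumorigenic, irritant, reproductive).
The logS and druglikeness parameter pairs are sign-corrected relative to a
commonly reprinted list whose literal signs make the score *fall* with
increasing solubility and druglikeness — inconsistent with the score's
definition and with published values; the literal pairs remain available
via `literal_params=True` as a regression reference. With the corrected
parameters DS is strictly increasing in logS and druglikeness, decreasing
in clogP and MW, multiplicative in toxicity, and confined to (0, 1); all
four properties at their logistic midpoints give exactly 0.75⁴ ≈ 0.316.

## Synthetic fixtures

`make_species_set` inverse-constructs a species table from target
parameters: radical = neutral + BDE − H(H•), radical cation = neutral +
AIP, anion = neutral + PA − H(H⁺) (all converted to hartree). PDE and ETE
are never prescribed — they emerge from the cycle, so closure holds by
construction; prescribing both PA and ETE for a site is accepted only when
they satisfy the closure identity, otherwise the spec is rejected as
over-constrained. Parameter recovery through the forward pipeline is exact
to better than 1e-10 kcal/mol (measured worst case 7e-11 over 1000 random
specs); the neutral anchor enthalpy is cosmetic and tested as irrelevant.

**Petunidin bundle.** The bundled fixture encodes the published study
values for petunidin: gas-phase site BDEs {3: 78.72, 5: 85.06, 7: 88.94,
3′: 90.25, 4′: 79.84}, AIP 229.91, PA(3) −112.68 kcal/mol, aqueous BDE(3)
77.02; frontier orbitals −8.73/−6.16 eV (gap 2.57 eV); per-site bond
orders, pKa and DE; property vectors (Molinspiration-style logP −0.73 for
the rule checks, OSIRIS-style clogP 1.980 / logS −2.338 / druglikeness
1.310 for the drug score); and six bioactivity scores. The published
two-step sums equal 392.47 kcal/mol, implying H(H⁺) − H(H•) = 313.75
kcal/mol; the fixture realises exactly that difference (H(H⁺) = 0,
H(H•) = −313.75/627.5095 hartree), so the emergent PDE (162.56) and ETE
(505.15) match the published values at printed precision. This fixture
reference convention is deliberately distinct from the package's
literature-convention defaults.

Synthetic (not published) fixture fields, so labelled in the shipped
manifest: aqueous BDEs at sites other than 3 (gas − 1.70 kcal/mol, the
site-3 solvation shift), aqueous AIP/PA (carried over from gas), PA at
sites other than 3 (shifted with BDE, making ETE site-independent), and
site-oxygen charges at sites other than 3 (chosen less negative than the
published −0.555 so site 3 stays extremal). Two substituted variants are
bundled for the substituent-effect path: an amino variant (all five BDEs
lower) and a 3-O-glucoside (four sites, site 3 absent).

`make_property_sets` samples druglikeness vectors uniformly across the
transition regions of all four drug-score terms (clogP −2…9, logS −9…1,
MW 100…900, druglikeness −8…8) with toxicity levels drawn 0.7/0.2/0.1;
a sample of 2000 spans drug scores below 0.05 and above 0.95 for any seed
tried, which is the span assertion used in the tests.

**What the fixture does and does not show.** Passing tests demonstrate the
*calculus* is correct — equations, conversions, rankings, rule boundaries
and their algebraic interrelations — on inputs engineered to be exactly
self-consistent. Real DFT outputs carry basis-set and functional error,
solvation-convention ambiguities and thermal-correction noise that the
fixture deliberately omits; the pipeline's validation on synthetic data
says nothing about the accuracy of any particular level of theory.

## Numerical choices

- Conversions through a single constant set (627.5095 kcal/mol, 27.2114 eV
  per hartree; 1239.842 eV·nm); unit identity is exact.
- Cycle tolerance 1e-6 kcal/mol (far above float error at molecular
  enthalpy magnitudes, far below chemical significance).
- Half-up rounding at the report boundary only; `Decimal`-based to avoid
  binary-float tie artifacts.
- Degenerate descriptor inputs (IP = EA) produce flagged infinities, not
  exceptions; overflow in the drug-score logistic saturates at 0/1.
- Ranking ties keep input order (stable sort) and set a `tied` flag.

## Problem sizes

The bundled study is small by design: 24 petunidin species (12 per phase),
5 sites, 2 variants. Property-based suites run 30–100 random cases per
invariant, the cycle-closure check 1000 seeded random fixtures, and the
property sampler span check 2000 draws; the whole suite completes in a few
seconds on one CPU.

## Known limitations

- No kinetics: rate constants, transition states and tunneling are outside
  the model; the mechanism verdict is purely thermodynamic.
- No local (Fukui-type) reactivity descriptors.
- pKa, NBO charges, bond orders, logP/logS/druglikeness/toxicity and
  bioactivity scores are consumed, never predicted.
- Aqueous-phase conclusions inherit whatever proton/electron solvation
  convention the user supplies; the package cannot detect a wrong one
  beyond cycle-closure failure.
- The drug score reproduces the OSIRIS aggregation formula, not the OSIRIS
  fragment database; druglikeness itself must come from such a tool.
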