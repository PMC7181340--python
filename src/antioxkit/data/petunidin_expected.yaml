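documented_discrepancies:
- orbital-method electrophilicity printed as 29.54 eV; the defining equations give
  21.57 eV from IP 8.73 / EA 6.16 (followed the equations)
- a few descriptor cells are last-digit truncated rather than rounded (softness 0.19
  vs 0.196); reports round half-up
expected:
  aip_gas_kcal: 229.91
  bde_gas_kcal:
    '3': 78.72
    3': 90.25
    4': 79.84
    '5': 85.06
    '7': 88.94
  bde_water_site3_kcal: 77.02
  drug_score:
    tol: 0.005
    value: 0.804
  ete_gas_site3_kcal: 505.15
  gap_gas_ev: 2.57
  lipinski_violations: 0
  pa_gas_site3_kcal: -112.68
  pde_gas_site3_kcal: 162.56
  preferred_mechanism: HAT
  site_order_by_bde: 3 < 4' < 5 < 7 < 3'
  tpsa:
    tol: 2.5
    value: 121.54
  wavelength_gas_nm:
    tol_nm: 1.0
    value: 483
molecule: petunidin (PT)
references_hartree:
  electron: 0.0012
  h_atom: -0.49999243039348407
  note: 'fixture convention: H(H+) - H(H.) = 313.75 kcal/mol exactly, as implied by
    the published two-step sums (392.47 kcal/mol)'
  proton: 0.0
synthetic_fields:
- aqueous BDEs at sites other than 3 (gas value - 1.70)
- aqueous AIP/PA (carried over from gas)
- PA at sites other than 3 (shifted with BDE)
- site-oxygen charges at sites other than 3
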