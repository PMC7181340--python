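molecule_id,form,site,phase,enthalpy_hartree,electronic_energy_hartree,homo_ev,lumo_ev
PT-NH2,neutral,,gas,-1124.02,-1124.02,,
PT-NH2,radical,3,gas,-1123.4016667317387,,,
PT-NH2,radical,5,gas,-1123.3921848035768,,,
PT-NH2,radical,7,gas,-1123.385858206131,,,
PT-NH2,radical,3',gas,-1123.3772368227096,,,
PT-NH2,radical,4',gas,-1123.394097125223,,,
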