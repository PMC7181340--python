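molecule_id,form,site,phase,enthalpy_hartree,electronic_energy_hartree,homo_ev,lumo_ev
PT-3-glucoside,neutral,,gas,-1754.65,-1754.65,,
PT-3-glucoside,radical,5,gas,-1754.0192844490803,,,
PT-3-glucoside,radical,7,gas,-1754.013085339744,,,
PT-3-glucoside,radical,3',gas,-1754.0095953527398,,,
PT-3-glucoside,radical,4',gas,-1754.0256110465261,,,
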