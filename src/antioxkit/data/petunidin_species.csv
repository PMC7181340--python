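molecule_id,form,site,phase,enthalpy_hartree,electronic_energy_hartree,homo_ev,lumo_ev
PT,neutral,,gas,-1143.88,-1143.88,-8.73,-6.16
PT,radical_cation,,gas,-1143.513615108616,,,
PT,radical,3,gas,-1143.2545592696208,,,
PT,anion,3,gas,-1144.0595670025714,,,
PT,radical,5,gas,-1143.2444558369239,,,
PT,anion,5,gas,-1144.0494635698744,,,
PT,radical,7,gas,-1143.2382726636013,,,
PT,anion,7,gas,-1144.0432803965518,,,
PT,radical,3',gas,-1143.2361850458044,,,
PT,anion,3',gas,-1144.0411927787547,,,
PT,radical,4',gas,-1143.2527744360846,,,
PT,anion,4',gas,-1144.057782169035,,,
PT,neutral,,water,-1143.88,-1143.88,,
PT,radical_cation,,water,-1143.513615108616,,,
PT,radical,3,water,-1143.257268391953,,,
PT,anion,3,water,-1144.0595670025714,,,
PT,radical,5,water,-1143.2471649592558,,,
PT,anion,5,water,-1144.0494635698744,,,
PT,radical,7,water,-1143.2409817859334,,,
PT,anion,7,water,-1144.0432803965518,,,
PT,radical,3',water,-1143.2388941681363,,,
PT,anion,3',water,-1144.0411927787547,,,
PT,radical,4',water,-1143.2554835584165,,,
PT,anion,4',water,-1144.057782169035,,,
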