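site,bde,bond_order,atomic_charge,pka,de
3,78.72,0.6825,-0.555,5.99,390.99
5,85.06,0.718,-0.512,6.81,397.33
7,88.94,0.7195,-0.498,7.8,401.21
3',90.25,0.727,-0.487,8.69,402.53
4',79.84,0.71,-0.524,11.97,392.11
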