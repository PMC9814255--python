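# Stationary-state energies (eV) of the stepwise G-C double proton transfer
# at zero induced separation, B3LYP+XDM/6-311++G** with implicit solvent
# (dielectric 8.0), referenced to the canonical pair.
# E_ts2 is placed at E_taut + 0.058 eV (the reverse barrier of the second
# step); the independently quoted second-barrier value 0.516 eV is not
# consistent with any referencing of these levels.
separation_A,E_can,E_ts1,E_int,E_ts2,E_taut
0.0,0.0,0.574,0.399,0.565,0.507
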