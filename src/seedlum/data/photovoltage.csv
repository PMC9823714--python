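species,germination_pct,photovoltage_mV
galega,35,0.78
galega,41,0.85
galega,43,0.86
clover,11,0.92
clover,15,1.02
clover,21,1.10
alfalfa,38,0.85
alfalfa,64,1.08
alfalfa,76,1.12
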