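species,scarification_cycles,germination_pct,flux_ru,flux_lm
galega,0,35,344,2.15e-06
galega,1,41,518,3.23e-06
galega,2,43,572,3.57e-06
clover,0,11,505,3.15e-06
clover,1,15,989,6.17e-06
clover,2,21,1516,9.46e-06
alfalfa,0,38,570,3.56e-06
alfalfa,1,64,1313,8.19e-06
alfalfa,2,76,2205,1.38e-05
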