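kaPP1: 0.0115
kaPP1a: 0.7054
kiPP1: 0.0018
kCdk1PP1: 0.7549
kPP1Gwl: 18.4724
kass: 617.2807
kdis: 0.0088
kcatB55: 1.0338
kGwlENSA: 20.8811
kPPXGwl: 0.156
kCdk1Sub: 0.008
kB55Sub: 0.0593
kCdk1Gwl: 0.2393
kB55Gwl: 496.5636
kCdk2Gwl: 0.1916
kCdc25S: 0.005
kCdc25F: 0.9411
kWee1S: 0.005
kWee1F: 47.2937
kCdk1Wee1: 1.3132
kCdk1Cdc25: 1.3132
kPPXY15: 0.005
kCdk2Wee1: 0.1096
kCdk2Cdc25: 0.1096
kB55Wee1: 0.5511
kB55Cdc25: 0.5511
CycBTot: 8.1808
Cdk2Tot: 1.0
PP1Tot: 1.0
ENSATot: 1.0
B55Tot: 0.25
GwlTot: 1.0
SubTot: 1.0
Kd: 0.025
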