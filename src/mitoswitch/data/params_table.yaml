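kaPP1: 0.01
kaPP1a: 0.7
kiPP1: 0.002
kCdk1PP1: 0.75
kPP1Gwl: 18.47
kass: 617.0
kdis: 0.009
kcatB55: 1.0
kGwlENSA: 21.0
kPPXGwl: 0.16
kCdk1Sub: 0.008
kB55Sub: 0.06
kCdk1Gwl: 0.24
kB55Gwl: 496.0
kCdk2Gwl: 0.19
kCdc25S: 0.005
kCdc25F: 0.94
kWee1S: 0.005
kWee1F: 47.0
kCdk1Wee1: 1.31
kCdk1Cdc25: 1.31
kPPXY15: 0.005
kCdk2Wee1: 0.11
kCdk2Cdc25: 0.11
kB55Wee1: 0.55
kB55Cdc25: 0.55
CycBTot: 8.18
Cdk2Tot: 1.0
PP1Tot: 1.0
ENSATot: 1.0
B55Tot: 0.25
GwlTot: 1.0
SubTot: 1.0
Kd: 0.025
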