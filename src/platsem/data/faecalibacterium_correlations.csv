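name,Sanger,454_V1V3,454_V3V5,qPCR
Sanger,1.0,0.828,0.866,0.642
454_V1V3,0.828,1.0,0.887,0.624
454_V3V5,0.866,0.887,1.0,0.610
qPCR,0.642,0.624,0.610,1.0
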