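name,msi_level,retention_index,effect_pH5,effect_pH7
trehalose,1,2730.0,0.4,1.5
glucose,1,1880.0,-0.4,-1.5
fructose,1,1860.0,-0.3,-1.2
mannose,1,1890.0,-0.3,-1.0
glutamate,1,1620.0,0.5,1.5
proline,1,1300.0,0.5,1.2
ornithine,1,1800.0,0.4,1.2
alanine,1,1100.0,0.3,1.0
aspartate,1,1520.0,-0.8,-1.0
lysine,1,1920.0,0.0,1.0
tryptophan,1,2220.0,0.0,1.0
nicotinamide,1,1700.0,-0.3,-1.2
adenine,1,1860.5,-0.3,-1.2
guanine,1,2100.0,0.8,-1.0
uracil,1,1340.0,-0.2,-1.0
citrate,1,1820.0,0.2,1.2
malate,1,1490.0,0.2,1.0
lactate,1,1050.0,0.3,1.0
pyruvate,1,1010.0,0.2,1.0
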