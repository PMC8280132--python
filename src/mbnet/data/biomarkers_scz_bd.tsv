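# metabolite	disease
acetate	SCZ
N-acetyl-d-mannosamine	SCZ
2,3-diphospho-d-glyceric-acid	SCZ
alpha-ketoglutaric-acid	SCZ
N-acetyl-l-alanine	SCZ
arginine	SCZ
choline	SCZ
formate	SCZ
glutamate	SCZ
amygdalin	SCZ
isocitric acid	SCZ
myo-inositol	SCZ
N-acetyl-glutamic-acid	SCZ
phenylalanine	SCZ
propionate	SCZ
pyruvate	SCZ
serine	SCZ
beta-alanine	SCZ
N-acetyl-l-phenyl-alanine	SCZ
lipoamide	SCZ
alpha-ketoisovaleric acid (MOA)	SCZ
l-glutamine	SCZ
acetate	BD
N-acetyl aspartyl-glutamic acid (NAAG)	BD
lactate	BD
phosphocholine	BD
alanine	BD
citrate	BD
cystine	BD
eicosanoic acid	BD
glucose	BD
glycerate	BD
β-hydroxybutyrate	BD
pyroglutamic acid	BD
sorbitol	BD
taurine	BD
tocopherol-alpha	BD
uridine	BD
l-threonine	BD
adenine	BD
glycine	BD
adenosine	BD
GABA	BD
mannitol	BD
pantothenate	BD
3-methyl-2-oxobutinoic acid	BD
guanine	BD
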