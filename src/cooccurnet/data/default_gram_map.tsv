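taxon_label	gram
Firmicutes	positive
Bacteroidetes	negative
Proteobacteria	negative
Verrucomicrobia	negative
Actinobacteria	positive
Cyanobacteria	negative
Tenericutes	variable
Lactobacillus	positive
Akkermansia	negative
Oscillospira	positive
Ruminococcus	positive
Bacteroides	negative
Prevotella	negative
Sutterella	negative
Lachnospira	positive
Rikenella	negative
Odoribacter	negative
Dorea	positive
S24-7	negative
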