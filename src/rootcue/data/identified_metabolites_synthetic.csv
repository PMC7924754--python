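compound,compound_class,direction,source_tag
DIMBOA,benzoxazinoid,postembryonic,main-text
DIMBOA-Glc,benzoxazinoid,postembryonic,main-text
DIM2BOA-Glc,benzoxazinoid,postembryonic,main-text
HDMBOA-Glc,benzoxazinoid,embryonic,main-text
HMBOA,benzoxazinoid,none,main-text
MBOA,benzoxazinoid,none,main-text
glucose,sugar,postembryonic,main-text
fructose,sugar,postembryonic,main-text
sucrose,sugar,postembryonic,main-text
leucine,amino acid,postembryonic,main-text
isoleucine,amino acid,postembryonic,synthetic-placeholder
tryptophan,amino acid,postembryonic,main-text
asparagine,amino acid,embryonic,synthetic-placeholder
chlorogenic acid,phenolic acid,embryonic,synthetic-placeholder
caffeic acid,phenolic acid,embryonic,synthetic-placeholder
ferulic acid,phenolic acid,embryonic,synthetic-placeholder
p-coumaric acid,phenolic acid,embryonic,synthetic-placeholder
rutin,flavonoid,embryonic,synthetic-placeholder
quercetin-3-O-glucoside,flavonoid,embryonic,synthetic-placeholder
valine,amino acid,none,synthetic-placeholder
phenylalanine,amino acid,none,synthetic-placeholder
glutamine,amino acid,none,synthetic-placeholder
alanine,amino acid,none,synthetic-placeholder
proline,amino acid,none,synthetic-placeholder
malic acid,organic acid,none,synthetic-placeholder
citric acid,organic acid,none,synthetic-placeholder
fumaric acid,organic acid,none,synthetic-placeholder
sinapic acid,phenolic acid,none,synthetic-placeholder
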