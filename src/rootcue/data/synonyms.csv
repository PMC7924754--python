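alias,canonical
dimboa-glucoside,dimboa-glc
dim2boa-glucoside,dim2boa-glc
hdmboa-glucoside,hdmboa-glc
d-glucose,glucose
d-fructose,fructose
co2,carbon dioxide
6-methoxy-2-benzoxazolinone,mboa
"2,4-dihydroxy-7-methoxy-1,4-benzoxazin-3-one",dimboa
(e)-b-caryophyllene,(e)-beta-caryophyllene
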