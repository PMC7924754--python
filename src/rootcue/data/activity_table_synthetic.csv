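compound,activity,source_tag
glucose,feeding stimulant,main-text
fructose,feeding stimulant,main-text
DIMBOA,host-recognition cue,main-text
DIMBOA-Glc,host-recognition cue,main-text
carbon dioxide,attractant,main-text
MBOA,host-recognition cue,synthetic-placeholder
(E)-beta-caryophyllene,attractant,synthetic-placeholder
linoleic acid,feeding stimulant,synthetic-placeholder
oleic acid,feeding stimulant,synthetic-placeholder
stearic acid,feeding stimulant,synthetic-placeholder
palmitic acid,feeding stimulant,synthetic-placeholder
beta-sitosterol,feeding stimulant,synthetic-placeholder
ethylene,attractant,synthetic-placeholder
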