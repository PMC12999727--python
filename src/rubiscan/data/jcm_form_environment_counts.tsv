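form	environment	count
IA	marine	18
IA	terrestrial	15
IA	rhizosphere_plant	6
IA	engineered	2
IA	organism_hosted	1
IC	marine	16
IC	terrestrial	5
IC	rhizosphere_plant	46
IC	organism_hosted	17
IC	engineered	11
IC	food	1
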