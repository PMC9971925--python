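class_id,preferred_label,synonyms
OPB:00340,Concentration of chemical,concentration
CHEBI:17138,glyceraldehyde 3-phosphate,triose phosphate
FMA:54537,Astrocyte,Astrocytus
CHEBI:15422,ATP,adenosine triphosphate
FMA:54527,Neuron,Neurocyte
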