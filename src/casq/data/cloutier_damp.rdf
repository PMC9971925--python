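<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:bqbiol="http://biomodels.net/biology-qualifiers/"
         xmlns:dcterms="http://purl.org/dc/terms/">
  <rdf:Description rdf:about="./cloutier_2009.cellml#dAMP_dATPn.ATPn">
    <bqbiol:isPropertyOf rdf:resource="./cloutier_2009.cellml#entity_15"/>
    <bqbiol:isVersionOf rdf:resource="https://identifiers.org/opb/OPB_00340"/>
    <dcterms:description>Rate of change in the concentration of adenosine triphosphate in the neuron of the brain</dcterms:description>
  </rdf:Description>
  <rdf:Description rdf:about="./cloutier_2009.cellml#entity_15">
    <bqbiol:isPartOf rdf:resource="./cloutier_2009.cellml#entity_1"/>
    <bqbiol:is rdf:resource="http://identifiers.org/chebi/CHEBI:15422"/>
  </rdf:Description>
  <rdf:Description rdf:about="./cloutier_2009.cellml#entity_1">
    <bqbiol:is rdf:resource="http://identifiers.org/fma/FMA:54527"/>
  </rdf:Description>
</rdf:RDF>
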