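# Pre-/probiotics layer: statements that a microbe affects BDNF levels,
# with their provenance document.
?st rdf:type ppkg:Affects
?st ppkg:microbe ?microbe
?st ppkg:mediator ?mediator
?st ppkg:doc ?doc
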