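# Microbiota layer: statements that a gut microbe increases a
# neurotransmitter, with their provenance document.
?st rdf:type mikg:Increases
?st mikg:microbe ?microbe
?st mikg:mediator ?mediator
?st mikg:doc ?doc
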