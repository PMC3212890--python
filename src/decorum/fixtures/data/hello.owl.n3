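@prefix foaf: <http://xmlns.com/foaf/0.1/> .
@prefix hello: <http://sadiframework.org/examples/hello.owl#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

hello:GreetedIndividual a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ;
            owl:onProperty hello:greeting ;
            owl:someValuesFrom xsd:string ] .

hello:GreetingParameters a owl:Class .

hello:NamedIndividual a owl:Class ;
    rdfs:subClassOf [ a owl:Restriction ;
            owl:minCardinality "1"^^xsd:nonNegativeInteger ;
            owl:onProperty foaf:name ] .

hello:punctuation a owl:DatatypeProperty .

hello:greeting a owl:DatatypeProperty .

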