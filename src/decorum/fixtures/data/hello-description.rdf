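<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
   xmlns:mygrid="http://www.mygrid.org.uk/mygrid-moby-service#"
   xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
>
  <rdf:Description rdf:about="http://sadiframework.org/examples/hello">
    <rdf:type rdf:resource="http://www.mygrid.org.uk/mygrid-moby-service#serviceDescription"/>
    <mygrid:hasServiceNameText>Hello</mygrid:hasServiceNameText>
    <mygrid:hasServiceDescriptionText>Attaches a greeting to any individual with a name.</mygrid:hasServiceDescriptionText>
    <mygrid:providedBy>sadiframework.org</mygrid:providedBy>
    <mygrid:hasOperation rdf:nodeID="N758170aca16348dcafa07f6594733e52"/>
  </rdf:Description>
  <rdf:Description rdf:nodeID="N843a28bd39af4cc5b60745e0e795054e">
    <mygrid:objectType rdf:resource="http://sadiframework.org/examples/hello.owl#NamedIndividual"/>
  </rdf:Description>
  <rdf:Description rdf:nodeID="N0e5d1279d7da4ecdb5e19759464c2275">
    <mygrid:objectType rdf:resource="http://sadiframework.org/examples/hello.owl#GreetedIndividual"/>
  </rdf:Description>
  <rdf:Description rdf:nodeID="N758170aca16348dcafa07f6594733e52">
    <mygrid:inputParameter rdf:nodeID="N843a28bd39af4cc5b60745e0e795054e"/>
    <mygrid:outputParameter rdf:nodeID="N0e5d1279d7da4ecdb5e19759464c2275"/>
  </rdf:Description>
</rdf:RDF>
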