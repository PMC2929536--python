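<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF
   xml:base="http://www.the_url_here.org/tma_example1.rdf"
   xmlns:dc="http://purl.org/dc/elements/1.1#"
   xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
   xmlns:tma="http://bioontology.org/ontologies/tma-minimal#"
>
  <rdf:Description rdf:about="http://www.institutionXYZ.org/block/RP2008-325">
    <tma:block_includes_core rdf:resource="#coreD4"/>
    <tma:includes_slide rdf:resource="#slide058"/>
    <rdf:type rdf:resource="http://bioontology.org/ontologies/tma-minimal#block"/>
  </rdf:Description>
  <rdf:Description rdf:about="http://www.institutionXYZ.org/tma/000001">
    <tma:includes_block rdf:resource="http://www.institutionXYZ.org/block/RP2008-325"/>
    <dc:creator>Michael J. Becich</dc:creator>
    <dc:title>All-Purpose Tissue Array</dc:title>
    <rdf:type rdf:resource="http://bioontology.org/ontologies/tma-minimal#tma"/>
  </rdf:Description>
  <rdf:Description rdf:about="#coreD4">
    <tma:diagnosis rdf:resource="#diagnosis1"/>
    <tma:donor_block rdf:resource="http://www.institutionXYZ.org/block/RP2007-228"/>
    <tma:drill_site>78,90</tma:drill_site>
    <tma:repository>Generic Tissue Bank</tma:repository>
    <rdf:type rdf:resource="http://bioontology.org/ontologies/tma-minimal#core_in_block"/>
  </rdf:Description>
  <rdf:Description rdf:about="#diagnosis1">
    <rdf:type rdf:resource="http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma"/>
  </rdf:Description>
  <rdf:Description rdf:about="#slide058-D4">
    <tma:derived_from_core rdf:resource="#coreD4"/>
    <tma:location>D4</tma:location>
    <rdf:type rdf:resource="http://bioontology.org/ontologies/tma-minimal#core_on_slide"/>
  </rdf:Description>
  <rdf:Description rdf:about="#slide058">
    <tma:slide_includes_core rdf:resource="#slide058-D4"/>
    <rdf:type rdf:resource="http://bioontology.org/ontologies/tma-minimal#slide"/>
  </rdf:Description>
</rdf:RDF>
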