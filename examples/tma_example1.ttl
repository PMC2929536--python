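@base <http://www.the_url_here.org/tma_example1.rdf> .
@prefix dc: <http://purl.org/dc/elements/1.1#> .
@prefix tma: <http://bioontology.org/ontologies/tma-minimal#> .

<http://www.institutionXYZ.org/tma/000001> a tma:tma ;
    tma:includes_block <http://www.institutionXYZ.org/block/RP2008-325> ;
    dc:creator "Michael J. Becich" ;
    dc:title "All-Purpose Tissue Array" .

<http://www.institutionXYZ.org/block/RP2008-325> a tma:block ;
    tma:block_includes_core <http://www.the_url_here.org/tma_example1.rdf#coreD4> ;
    tma:includes_slide <http://www.the_url_here.org/tma_example1.rdf#slide058> .

<http://www.the_url_here.org/tma_example1.rdf#diagnosis1> a <http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma> .

<http://www.the_url_here.org/tma_example1.rdf#slide058> a tma:slide ;
    tma:slide_includes_core <http://www.the_url_here.org/tma_example1.rdf#slide058-D4> .

<http://www.the_url_here.org/tma_example1.rdf#slide058-D4> a tma:core_on_slide ;
    tma:derived_from_core <http://www.the_url_here.org/tma_example1.rdf#coreD4> ;
    tma:location "D4" .

<http://www.the_url_here.org/tma_example1.rdf#coreD4> a tma:core_in_block ;
    tma:diagnosis <http://www.the_url_here.org/tma_example1.rdf#diagnosis1> ;
    tma:donor_block <http://www.institutionXYZ.org/block/RP2007-228> ;
    tma:drill_site "78,90" ;
    tma:repository "Generic Tissue Bank" .

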