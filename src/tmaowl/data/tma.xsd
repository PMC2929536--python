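<?xml version="1.0" encoding="UTF-8"?>
<!-- XML dialect for TMA hierarchy documents fed to the XML->OWL
     converter.  Core elements under a slide denote cores on that
     slide; core elements directly under a block denote cores in the
     block.  Unknown child elements are carried through as
     annotation-property candidates, hence the lax wildcards. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:element name="tma">
    <xs:complexType>
      <xs:sequence>
        <xs:any processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="identifier" type="xs:string" use="required"/>
      <xs:attribute name="title" type="xs:string"/>
      <xs:attribute name="creator" type="xs:string"/>
      <xs:attribute name="repository" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="block">
    <xs:complexType>
      <xs:sequence>
        <xs:any processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="identifier" type="xs:string" use="required"/>
      <xs:attribute name="donor_block" type="xs:anyURI"/>
      <xs:attribute name="diagnosis_term" type="xs:anyURI"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="slide">
    <xs:complexType>
      <xs:sequence>
        <xs:any processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="identifier" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="core">
    <xs:complexType>
      <xs:sequence>
        <xs:any processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="identifier" type="xs:string" use="required"/>
      <xs:attribute name="location" type="xs:string"/>
      <xs:attribute name="drill_site" type="xs:string"/>
      <xs:attribute name="donor_block" type="xs:anyURI"/>
      <xs:attribute name="diagnosis_term" type="xs:anyURI"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
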