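<?xml version="1.0" encoding="UTF-8"?>
<!-- Core project-definition dialect, version 1. Extension elements belong in
     a foreign namespace; extension attributes are permitted anywhere. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="boolish">
    <xs:restriction base="xs:string">
      <xs:enumeration value="true"/>
      <xs:enumeration value="false"/>
      <xs:enumeration value="1"/>
      <xs:enumeration value="0"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="fieldKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="text"/>
      <xs:enumeration value="long_text"/>
      <xs:enumeration value="dropdown"/>
      <xs:enumeration value="checkbox"/>
      <xs:enumeration value="radio"/>
      <xs:enumeration value="location"/>
      <xs:enumeration value="image"/>
      <xs:enumeration value="video"/>
      <xs:enumeration value="audio"/>
      <xs:enumeration value="barcode"/>
      <xs:enumeration value="branch_trigger"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="project">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="form" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="field" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="choice" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="name" type="xs:string" use="required"/>
                        <xs:attribute name="value" type="xs:string" use="required"/>
                        <xs:anyAttribute processContents="lax"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="jump" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="when" type="xs:string" use="required"/>
                        <xs:attribute name="to" type="xs:string" use="required"/>
                        <xs:anyAttribute processContents="lax"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:any namespace="##other" processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="type" type="fieldKind" use="required"/>
                  <xs:attribute name="label" type="xs:string" use="required"/>
                  <xs:attribute name="required" type="boolish"/>
                  <xs:attribute name="numeric">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="none"/>
                        <xs:enumeration value="integer"/>
                        <xs:enumeration value="decimal"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="min" type="xs:double"/>
                  <xs:attribute name="max" type="xs:double"/>
                  <xs:attribute name="date" type="xs:string"/>
                  <xs:attribute name="regex" type="xs:string"/>
                  <xs:attribute name="double-entry" type="boolish"/>
                  <xs:attribute name="chartable" type="boolish"/>
                  <xs:anyAttribute processContents="lax"/>
                </xs:complexType>
              </xs:element>
              <xs:any namespace="##other" processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="title" type="xs:string"/>
            <xs:attribute name="key" type="xs:string"/>
            <xs:attribute name="level" type="xs:positiveInteger"/>
            <xs:attribute name="branch-of" type="xs:string"/>
            <xs:attribute name="branch-at" type="xs:string"/>
            <xs:anyAttribute processContents="lax"/>
          </xs:complexType>
        </xs:element>
        <xs:any namespace="##other" processContents="lax" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="title" type="xs:string"/>
      <xs:attribute name="version" type="xs:string"/>
      <xs:attribute name="visibility">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="public"/>
            <xs:enumeration value="private"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="dialect" type="xs:string"/>
      <xs:anyAttribute processContents="lax"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
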