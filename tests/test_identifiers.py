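"""Identifier minting, shorthand expansion, and compaction."""

from urllib.parse import quote

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaowl.identifiers import (
    ExpansionError,
    MintingError,
    NamespaceMap,
    UriPolicy,
    compact,
    expand,
    is_internal,
    mint_uri,
    percent_encode,
)
from tmaowl.schema import DC_NS, TMA_NS

BASE = "http://www.the_url_here.org/tma_example1.rdf"
NSMAP = NamespaceMap(prefixes={"tma": TMA_NS, "dc": DC_NS}, base=BASE)


class TestMinting:
    def test_institution_tma_identifier(self):
        policy = UriPolicy(authority="www.institutionXYZ.org")
        iri = mint_uri(policy, ["tma", "rdf"], "123456")
        assert iri == "http://www.institutionXYZ.org/tma/rdf/123456"

    def test_empty_collection_path(self):
        assert mint_uri(UriPolicy(authority="a.org"), [], "x") == "http://a.org/x"

    def test_key_with_reserved_characters_is_encoded(self):
        iri = mint_uri(UriPolicy(authority="a.org"), ["tma"], "RP 2008/325")
        assert iri == "http://a.org/tma/RP%202008%2F325"

    def test_empty_key_rejected(self):
        with pytest.raises(MintingError):
            mint_uri(UriPolicy(authority="a.org"), ["tma"], "")

    def test_bare_percent_is_escaped_not_rejected(self):
        assert mint_uri(UriPolicy(authority="a.org"), [], "%x") == "http://a.org/%25x"

    def test_empty_path_segment_rejected(self):
        with pytest.raises(MintingError):
            mint_uri(UriPolicy(authority="a.org"), ["tma", ""], "1")

    def test_minting_is_deterministic(self):
        policy = UriPolicy(authority="bank.org", path_templates={"tma": ["tma"]})
        assert policy.mint("tma", "T-01") == policy.mint("tma", "T-01")

    def test_already_encoded_key_not_double_encoded(self):
        iri = mint_uri(UriPolicy(authority="a.org"), [], "RP%202008")
        assert iri == "http://a.org/RP%202008"

    @settings(derandomize=True, max_examples=200)
    @given(st.text(min_size=1).filter(lambda s: "%" not in s))
    def test_percent_encoding_matches_reference_encoder(self, key):
        # urllib.parse.quote over the RFC 3986 unreserved set is the
        # independent oracle (safe="" encodes '/' as well).
        assert percent_encode(key) == quote(key, safe="")


class TestExpansion:
    @pytest.mark.parametrize(
        "shorthand,expected",
        [
            ("#slide058", BASE + "#slide058"),
            ("tma:block", TMA_NS + "block"),
            ("dc:title", DC_NS + "title"),
        ],
    )
    def test_published_sample_expansions(self, shorthand, expected):
        assert expand(shorthand, NSMAP) == expected

    def test_absolute_iri_passes_through(self):
        iri = "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Prostate_Carcinoma"
        assert expand(iri, NSMAP) == iri

    def test_unknown_prefix_rejected(self):
        with pytest.raises(ExpansionError):
            expand("foaf:name", NSMAP)

    def test_bare_token_rejected(self):
        with pytest.raises(ExpansionError):
            expand("slide058", NSMAP)

    def test_fragment_without_base_rejected(self):
        with pytest.raises(ExpansionError):
            expand("#x", NamespaceMap())


class TestCompaction:
    def test_vocabulary_term_compacts_to_prefix_form(self):
        assert compact(TMA_NS + "block", NSMAP) == "tma:block"

    def test_base_fragment_compacts_to_hash_form(self):
        assert compact(BASE + "#slide058", NSMAP) == "#slide058"

    def test_unmatched_iri_unchanged(self):
        assert compact("http://elsewhere.org/x", NSMAP) == "http://elsewhere.org/x"

    def test_longest_namespace_wins(self):
        nested = NamespaceMap(prefixes={"a": "http://x.org/", "b": "http://x.org/deep/"})
        assert compact("http://x.org/deep/item", nested) == "b:item"

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet=st.characters(min_codepoint=33, max_codepoint=126),
                   min_size=1).filter(lambda s: "%" not in s))
    def test_expand_compact_round_trip_on_minted_iris(self, key):
        policy = UriPolicy(authority="bank.example.org")
        iri = mint_uri(policy, ["tma"], key)
        assert expand(compact(iri, NSMAP), NSMAP) == iri

    @pytest.mark.parametrize("shorthand", ["#slide058", "tma:block", "dc:title"])
    def test_compact_expand_round_trip_on_shorthands(self, shorthand):
        assert compact(expand(shorthand, NSMAP), NSMAP) == shorthand


class TestInternality:
    @pytest.mark.parametrize(
        "iri,base,expected",
        [
            ("http://x.org/doc.rdf#coreD4", "http://x.org/doc.rdf", True),
            ("http://www.institutionXYZ.org/block/RP2008-325",
             "http://x.org/doc.rdf", False),
            ("http://x.org/doc.rdf", "http://x.org/doc.rdf", True),
            ("http://x.org/doc.rdf2", "http://x.org/doc.rdf", False),
        ],
    )
    def test_internal_vs_external(self, iri, base, expected):
        assert is_internal(iri, base) is expected
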