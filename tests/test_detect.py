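"""Entity detection: cue lexicons, RRIDs, identifiers, resource linking."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from rtindex import detect


@pytest.fixture(scope="module")
def registry():
    return detect.default_registry()


def types_of(mentions):
    return {m.type for m in mentions}


class TestDetectEntities:
    def test_replication_in_triplicate_fires_both_types(self, registry):
        text = "All experiments were replicated in triplicate."
        found = types_of(detect.detect_entities(text, registry))
        assert {"replication_statement", "n_replications"} <= found

    def test_iacuc_cue_phrase(self, registry):
        text = "The protocol was approved by the Institutional Animal Care and Use Committee."
        assert "iacuc" in types_of(detect.detect_entities(text, registry))

    def test_inert_text_yields_nothing(self, registry):
        assert detect.detect_entities("The sky was clear that morning.", registry) == []

    def test_mentions_sorted_and_spans_valid(self, registry):
        text = "Subjects were randomly assigned and investigators were blinded."
        mentions = detect.detect_entities(text, registry)
        assert [m.start for m in mentions] == sorted(m.start for m in mentions)
        for m in mentions:
            assert text[m.start:m.end] == m.surface

    def test_only_known_types_emitted(self, registry):
        text = " ".join(
            "Mice were euthanized after consent was obtained from all subjects"
            " randomly assigned in triplicate with HeLa cells and ImageJ".split()
        )
        assert types_of(detect.detect_entities(text, registry)) <= detect.ENTITY_TYPES

    def test_same_type_overlaps_merged_to_widest(self, registry):
        text = "Cultures were authenticated by STR profiling before use."
        mentions = [
            m for m in detect.detect_entities(text, registry)
            if m.type == "cell_line_authentication"
        ]
        assert len(mentions) == 1
        assert "authenticated by STR profiling" in mentions[0].surface

    def test_failing_detector_reported_not_silent(self, registry):
        broken = detect.DetectorRegistry(dict(registry.detectors))

        def boom(text):
            raise RuntimeError("model unavailable")

        broken.register("blinding", boom)
        failures = []
        mentions = detect.detect_entities("blinded analysis", broken, failures=failures)
        assert failures and failures[0][0] == "blinding"
        assert "blinding" not in types_of(mentions)

    def test_registry_requires_full_coverage(self, registry):
        partial = {k: v for k, v in registry.detectors.items() if k != "sex"}
        with pytest.raises(ValueError, match="sex"):
            detect.DetectorRegistry(partial)

    def test_n_replications_numeric_attribute(self, registry):
        mentions = detect.detect_entities("Assays were run in triplicate.", registry)
        (m,) = [x for x in mentions if x.type == "n_replications"]
        assert m.attributes["value"] == 3


class TestDetectRRIDs:
    def test_scr_accession(self):
        (m,) = detect.detect_rrids("analysed with CellProfiler (RRID: SCR_007358) today")
        assert m.type == "rrid"
        assert m.attributes["accession"] == "SCR_007358"

    def test_malformed_short_accession_rejected(self):
        assert detect.detect_rrids("see RRID:AB_0 for details") == []

    def test_two_rrids_two_mentions(self):
        text = "tools (RRID:SCR_003070) and cells (RRID:CVCL_0030)"
        mentions = detect.detect_rrids(text)
        assert len(mentions) == 2
        assert mentions[0].span != mentions[1].span

    @pytest.mark.parametrize(
        "token",
        ["AB_2305186", "SCR_007358", "CVCL_0030", "Addgene_12260", "IMSR_JAX:000664", "MGI:87904"],
    )
    def test_accession_shapes(self, token):
        (m,) = detect.detect_rrids(f"reagent (RRID:{token})")
        assert m.attributes["accession"] == token


class TestDetectIdentifiers:
    def test_availability_statement(self):
        found = types_of(detect.detect_identifiers("The data is available upon request."))
        assert found == {"data_availability"}

    def test_supplementary_statement(self):
        text = "all data used within this study is available in the supplementary methods"
        assert "data_availability" in types_of(detect.detect_identifiers(text))

    def test_geo_accession_in_deposition_sentence(self):
        text = "Microarray data were deposited under GSE12345 before submission."
        mentions = [m for m in detect.detect_identifiers(text) if m.type == "data_id"]
        assert len(mentions) == 1
        # oracle: brute-force scan with the bundled accession-pattern list
        entries = detect.load_lexicon(detect._data_path("lexicons", "data_id.txt"))
        brute = [
            (m.start(), m.end())
            for pattern, is_regex in entries if is_regex
            for m in re.compile(pattern).finditer(text)
        ]
        assert brute == [mentions[0].span]

    @pytest.mark.parametrize(
        "text,expected_type",
        [
            ("code at https://github.com/lab/tool", "code_id"),
            ("steps at protocols.io/view/my-protocol", "protocol_id"),
            ("reads in PRJNA765432 archive", "data_id"),
        ],
    )
    def test_identifier_shapes(self, text, expected_type):
        assert expected_type in types_of(detect.detect_identifiers(text))


class TestLinkResources:
    def test_rrid_in_same_sentence_identifiable(self, registry):
        text = "Signals were processed in MATLAB (RRID:SCR_001622). Other work followed."
        mentions = detect.detect_entities(text, registry)
        linked = detect.link_resources(mentions, {}, text)
        (software,) = [m for m in linked if m.type == "software_tool"]
        assert software.attributes["identifiable"] is True

    def test_rrid_in_other_sentence_not_linked(self, registry):
        text = "Signals were processed in MATLAB. Cells were tracked (RRID:SCR_001622)."
        mentions = detect.detect_entities(text, registry)
        linked = detect.link_resources(mentions, {}, text)
        (software,) = [m for m in linked if m.type == "software_tool"]
        assert software.attributes["identifiable"] is False

    def test_catalog_hit_is_rrid_suggestion(self, registry):
        text = "Images were quantified with ImageJ."
        linked = detect.link_resources(detect.detect_entities(text, registry),
                                       detect.load_resource_catalog(), text)
        (software,) = [m for m in linked if m.type == "software_tool"]
        assert software.attributes["identifiable"] is True
        assert software.attributes["rrid"] == "SCR_003070"

    def test_no_rrid_no_catalog_unidentifiable(self, registry):
        text = "Blots used a mouse anti-GFAP antibody overnight."
        linked = detect.link_resources(detect.detect_entities(text, registry), {}, text)
        (ab,) = [m for m in linked if m.type == "antibody"]
        assert ab.attributes["identifiable"] is False


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.text(max_size=300))
def test_detection_deterministic_and_spans_valid(text):
    registry = detect.default_registry()
    first = detect.detect_entities(text, registry)
    second = detect.detect_entities(text, registry)
    assert [m.to_record() for m in first] == [m.to_record() for m in second]
    for m in first:
        assert 0 <= m.start < m.end <= len(text)
        assert text[m.start:m.end] == m.surface
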