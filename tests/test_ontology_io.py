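import dataclasses

import pytest

from famground import ontology_io
from famground.model import (
    Affix,
    AffixCategory,
    AffixPosition,
    EntityRef,
    Equivalence,
    Ontology,
    Relation,
    RelationType,
    ResourceError,
    Severity,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestLoadEntities:
    def test_basic(self, tmp_path):
        p = _write(tmp_path / "entities.csv", "AKT\nAMPK\nRAS\n")
        assert ontology_io.load_entities(p) == {"AKT", "AMPK", "RAS"}

    def test_empty_file_warns(self, tmp_path):
        p = _write(tmp_path / "entities.csv", "")
        issues = []
        assert ontology_io.load_entities(p, issues) == set()
        assert [i.code for i in issues] == ["empty_file"]
        assert issues[0].severity is Severity.WARNING

    def test_duplicate_entity(self, tmp_path):
        p = _write(tmp_path / "entities.csv", "AKT\nAKT\n")
        issues = []
        ontology_io.load_entities(p, issues)
        assert [i.code for i in issues] == ["duplicate_entity"]
        assert issues[0].location.endswith(":2")
        with pytest.raises(ResourceError):
            ontology_io.load_entities(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            ontology_io.load_entities(tmp_path / "nope.csv")


class TestLoadRelations:
    def test_isa_row(self, tmp_path):
        p = _write(tmp_path / "relations.csv", "HGNC,PLCG1,isa,FPLX,PLCG\n")
        rels = ontology_io.load_relations(p)
        assert rels == [
            Relation(EntityRef("HGNC", "PLCG1"), RelationType.ISA, EntityRef("FPLX", "PLCG"))
        ]

    def test_partof_row(self, tmp_path):
        p = _write(tmp_path / "relations.csv", "FPLX,AMPK_gamma,partof,FPLX,AMPK\n")
        (rel,) = ontology_io.load_relations(p)
        assert rel.rel is RelationType.PARTOF
        assert rel.subject.identifier == "AMPK_gamma"

    def test_unknown_relation_token(self, tmp_path):
        p = _write(tmp_path / "relations.csv", "HGNC,AKT1,memberof,FPLX,AKT\n")
        issues = []
        assert ontology_io.load_relations(p, issues) == []
        assert [i.code for i in issues] == ["invalid_relation"]

    def test_wrong_column_count(self, tmp_path):
        p = _write(tmp_path / "relations.csv", "HGNC,AKT1,isa\n")
        issues = []
        ontology_io.load_relations(p, issues)
        assert [i.code for i in issues] == ["malformed_row"]

    def test_file_order_preserved(self, tmp_path):
        p = _write(
            tmp_path / "relations.csv",
            "HGNC,B,isa,FPLX,F\nHGNC,A,isa,FPLX,F\n",
        )
        rels = ontology_io.load_relations(p)
        assert [r.subject.identifier for r in rels] == ["B", "A"]


class TestLoadGroundingMap:
    def test_verbatim_keys(self, tmp_path):
        p = _write(tmp_path / "grounding_map.csv", "NF-kB,FPLX,NFkappaB\n")
        gmap = ontology_io.load_grounding_map(p)
        assert gmap == {"NF-kB": EntityRef("FPLX", "NFkappaB")}

    def test_duplicate_synonym(self, tmp_path):
        p = _write(
            tmp_path / "grounding_map.csv",
            "ERKs,FPLX,ERK\nERKs,FPLX,MAPK\n",
        )
        issues = []
        ontology_io.load_grounding_map(p, issues)
        assert [i.code for i in issues] == ["duplicate_synonym"]

    def test_case_preserved_distinct_keys(self, tmp_path):
        p = _write(
            tmp_path / "grounding_map.csv",
            "Ras,FPLX,RAS\nRAS,FPLX,RAS\n",
        )
        assert len(ontology_io.load_grounding_map(p)) == 2


class TestLoadAffixes:
    def test_species_affix(self, tmp_path):
        p = _write(tmp_path / "gene_prefixes.csv", "mmu-{Gene name},prefix,species,mouse\n")
        (affix,) = ontology_io.load_affixes(p)
        assert affix.position is AffixPosition.PREFIX
        assert affix.category is AffixCategory.SPECIES
        assert affix.species_tag == "mouse"

    def test_missing_placeholder(self, tmp_path):
        p = _write(tmp_path / "gene_prefixes.csv", "mmu-,prefix,species,mouse\n")
        issues = []
        assert ontology_io.load_affixes(p, issues) == []
        assert [i.code for i in issues] == ["malformed_affix"]

    def test_suffix_affix(self, tmp_path):
        p = _write(tmp_path / "gene_prefixes.csv", "{Gene name} mRNA,suffix,mrna_grounding\n")
        (affix,) = ontology_io.load_affixes(p)
        assert affix.literal == " mRNA"


class TestValidate:
    def test_inpaper_fixture_valid(self, inpaper):
        assert ontology_io.validate(inpaper) == []

    def test_dangling_relation(self, inpaper):
        broken = dataclasses.replace(inpaper)
        broken.relations = inpaper.relations + [
            Relation(EntityRef("HGNC", "X"), RelationType.ISA, EntityRef("FPLX", "FOO"))
        ]
        codes = [i.code for i in ontology_io.validate(broken)]
        assert codes == ["dangling_relation"]

    def test_cycle_reported_with_nodes(self):
        o = Ontology(entities={"A", "B"})
        o.relations = [
            Relation(o.ref("A"), RelationType.ISA, o.ref("B")),
            Relation(o.ref("B"), RelationType.ISA, o.ref("A")),
        ]
        issues = ontology_io.validate(o)
        assert [i.code for i in issues] == ["cycle"]
        assert "FPLX:A" in issues[0].message and "FPLX:B" in issues[0].message

    def test_dangling_equivalence(self):
        o = Ontology(entities={"A"})
        o.equivalences = [Equivalence(EntityRef("RE", "R-1"), "MISSING")]
        assert [i.code for i in ontology_io.validate(o)] == ["dangling_equivalence"]

    def test_dangling_grounding(self):
        o = Ontology(entities={"A"}, grounding_map={"foo": EntityRef("FPLX", "MISSING")})
        assert [i.code for i in ontology_io.validate(o)] == ["dangling_grounding"]

    def test_mutations_each_flagged(self, inpaper):
        """Each invariant violated one at a time yields exactly its issue code."""
        mutants = {
            "dangling_relation": lambda o: o.relations.append(
                Relation(EntityRef("HGNC", "Z1"), RelationType.ISA, o.ref("NOPE"))
            ),
            "dangling_equivalence": lambda o: o.equivalences.append(
                Equivalence(EntityRef("PF", "PF00001"), "NOPE")
            ),
            "dangling_grounding": lambda o: o.grounding_map.update(
                {"zzz": EntityRef("FPLX", "NOPE")}
            ),
            "cycle": lambda o: o.relations.append(
                Relation(o.ref("AMPK"), RelationType.ISA, o.ref("AMPK_gamma"))
            ),
        }
        for code, mutate in mutants.items():
            o = Ontology(
                entities=set(inpaper.entities),
                relations=list(inpaper.relations),
                grounding_map=dict(inpaper.grounding_map),
                equivalences=list(inpaper.equivalences),
                affixes=list(inpaper.affixes),
            )
            mutate(o)
            assert [i.code for i in ontology_io.validate(o)] == [code]


class TestCsvRoundTrip:
    def test_load_save_round_trip(self, inpaper, resource_dir, tmp_path):
        loaded = ontology_io.load_ontology(resource_dir)
        assert loaded.entities == inpaper.entities
        assert set(loaded.relations) == set(inpaper.relations)
        assert loaded.grounding_map == inpaper.grounding_map
        assert set(loaded.equivalences) == set(inpaper.equivalences)
        assert set(loaded.affixes) == set(inpaper.affixes)
        # second write is byte-identical
        d2 = tmp_path / "again"
        ontology_io.write_ontology(loaded, d2)
        for name in sorted(p.name for p in resource_dir.iterdir()):
            assert (d2 / name).read_bytes() == (resource_dir / name).read_bytes()


class TestObo:
    def test_term_stanza_structure(self, inpaper):
        text = ontology_io.export_obo(inpaper)
        stanza = text.split("\n\n")
        (nfkb,) = [s for s in stanza if s.startswith("[Term]\nid: FPLX:NFkappaB")]
        assert "name: NFkappaB\n" in nfkb
        assert 'synonym: "NF-kB" EXACT []' in nfkb

    def test_isa_line_in_child_stanza(self, inpaper):
        text = ontology_io.export_obo(inpaper)
        (plcg,) = [s for s in text.split("\n\n") if s.startswith("[Term]\nid: FPLX:PLCG\n")]
        assert "is_a: FPLX:PLC ! PLC" in plcg

    def test_partof_as_relationship(self, inpaper):
        text = ontology_io.export_obo(inpaper)
        (gamma,) = [
            s for s in text.split("\n\n") if s.startswith("[Term]\nid: FPLX:AMPK_gamma\n")
        ]
        assert "relationship: part_of FPLX:AMPK ! AMPK" in gamma
        assert "[Typedef]" in text and "id: part_of" in text

    def test_xref_lines(self, inpaper):
        text = ontology_io.export_obo(inpaper)
        (ras,) = [s for s in text.split("\n\n") if s.startswith("[Term]\nid: FPLX:RAS\n")]
        assert "xref: IP:IPR020849" in ras

    def test_round_trip(self, inpaper):
        restored = ontology_io.parse_obo(ontology_io.export_obo(inpaper))
        assert restored.entities == inpaper.entities
        assert set(restored.relations) == set(inpaper.relations)
        assert restored.grounding_map == inpaper.grounding_map
        assert set(restored.equivalences) == set(inpaper.equivalences)

    def test_deterministic_output(self, inpaper):
        assert ontology_io.export_obo(inpaper) == ontology_io.export_obo(inpaper)

    def test_refuses_invalid(self):
        o = Ontology(entities={"A"}, grounding_map={"x": EntityRef("FPLX", "GONE")})
        with pytest.raises(ResourceError):
            ontology_io.export_obo(o)

    def test_malformed_stanza_reports_line(self):
        bad = "format-version: 1.2\n\n[Term]\nid: FPLX:A\nsynonym no-colon-space\n"
        with pytest.raises(ontology_io.OboParseError) as err:
            ontology_io.parse_obo(bad)
        assert err.value.lineno == 5

    def test_escaped_synonym_round_trip(self):
        o = Ontology(entities={"A"}, grounding_map={'say "hi"': EntityRef("FPLX", "A")})
        restored = ontology_io.parse_obo(ontology_io.export_obo(o))
        assert restored.grounding_map == o.grounding_map
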