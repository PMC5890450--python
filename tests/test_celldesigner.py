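import copy
import random
import xml.etree.ElementTree as ET

import pytest

from sigmap.celldesigner import (
    DEGRADATION_SINK,
    read_celldesigner,
    sif_records,
    write_celldesigner,
    write_gmt,
    write_sif,
)
from sigmap.errors import IntegrityError, MapParseError
from sigmap.fixtures import FixtureSpec, build_map, dna_repair_spec, make_map
from sigmap.hierarchy import Module, ModuleSet, modules_from_tags
from sigmap.model import (
    EntityClass,
    MapEntity,
    Reaction,
    ReactionClass,
    RegulationClass,
    SignallingMap,
)

from .conftest import protein


@pytest.fixture
def small_file(tmp_path, complex_map):
    path = tmp_path / "small.xml"
    write_celldesigner(complex_map, path)
    return path


class TestRead:
    def test_fixture_counts(self, tmp_path):
        """3 proteins + 1 complex of two of them, 2 reactions."""
        smap = SignallingMap(name="t", width=600, height=400)
        smap.add_entity(protein("p1", hugo="P1", x=10, y=10))
        smap.add_entity(protein("p2", hugo="P2", x=10, y=80))
        smap.add_entity(protein("p3", hugo="P3", x=300, y=10))
        smap.add_entity(
            MapEntity(id="c", name="C", entity_class=EntityClass.COMPLEX,
                      position=(150, 100), size=(120, 60), members=["p1", "p2"])
        )
        smap.add_reaction(Reaction(id="r1", reaction_class=ReactionClass.ASSOCIATION,
                                   reactants=["p1", "p2"], products=["c"]))
        smap.add_reaction(Reaction(id="r2", reactants=["c"], products=["p3"]))
        path = tmp_path / "m.xml"
        write_celldesigner(smap, path)
        got, report = read_celldesigner(path)
        assert len(got.entities) == 4
        assert len(got.reactions) == 2
        assert report.n_species == 4 and report.n_reactions == 2
        assert got.entities["c"].members == ["p1", "p2"]

    def test_empty_model(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text(
            '<?xml version="1.0"?><sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
            '<model id="empty"/></sbml>'
        )
        smap, report = read_celldesigner(path)
        assert smap.entities == {} and smap.reactions == {}

    def test_unsupported_construct_skipped_with_record(self, tmp_path, small_file):
        base, base_report = read_celldesigner(small_file)
        text = small_file.read_text()
        mutated = text.replace(
            "<listOfSpecies>", '<listOfSpecies><species name="no_id_here"/>', 1
        )
        mutated_path = tmp_path / "mutated.xml"
        mutated_path.write_text(mutated)
        got, report = read_celldesigner(mutated_path)
        assert got == base
        assert len(report.skipped) == len(base_report.skipped) + 1
        assert any("missing id" in s.reason for s in report.skipped)

    def test_malformed_xml_raises_with_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml>\n<model><unclosed>\n</sbml>")
        with pytest.raises(MapParseError) as err:
            read_celldesigner(path)
        assert err.value.line is not None

    def test_bare_sbml_gets_unknown_classes_and_warning(self, tmp_path):
        path = tmp_path / "bare.xml"
        path.write_text(
            '<?xml version="1.0"?><sbml xmlns="http://www.sbml.org/sbml/level2/version4">'
            '<model id="bare"><listOfSpecies><species id="s1" name="S1"/></listOfSpecies>'
            "</model></sbml>"
        )
        smap, report = read_celldesigner(path)
        assert smap.entities["s1"].entity_class is EntityClass.UNKNOWN
        assert any("CellDesigner extension" in w for w in report.warnings)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_round_trip_identity(self, tmp_path, seed):
        spec = dna_repair_spec(seed=seed)
        path, _ = make_map(spec, tmp_path / "m.xml")
        first, _ = read_celldesigner(path)
        rt_path = tmp_path / "rt.xml"
        write_celldesigner(first, rt_path)
        second, _ = read_celldesigner(rt_path)
        assert first == second
        # canonical writer is byte-stable
        write_celldesigner(second, tmp_path / "rt2.xml")
        assert rt_path.read_bytes() == (tmp_path / "rt2.xml").read_bytes()

    def test_round_trip_preserves_counts_classes_positions(self, tmp_path):
        smap, truth = build_map(dna_repair_spec(seed=3))
        path = tmp_path / "m.xml"
        write_celldesigner(smap, path)
        got, _ = read_celldesigner(path)
        assert len(got.entities) == truth["entity_count"]
        assert len(got.reactions) == truth["reaction_count"]
        for eid, ent in smap.entities.items():
            assert got.entities[eid].entity_class is ent.entity_class
            assert got.entities[eid].position == ent.position

    def test_fuzz_dropping_optional_subtree_never_fatal(self, small_file):
        tree = ET.parse(small_file)
        root = tree.getroot()
        parents = [
            (parent, child)
            for parent in root.iter()
            for child in list(parent)
        ]
        rng = random.Random(0)
        for parent, child in rng.sample(parents, min(25, len(parents))):
            mutated = copy.deepcopy(tree)
            # find and remove the matching child in the copy by position
            for p2 in mutated.getroot().iter():
                if p2.tag == parent.tag and child in list(parent):
                    for c2 in list(p2):
                        if c2.tag == child.tag:
                            p2.remove(c2)
                            break
                    break
            text = ET.tostring(mutated.getroot(), encoding="unicode")
            mutated_path = small_file.parent / "fuzz.xml"
            mutated_path.write_text(text)
            read_celldesigner(mutated_path)  # must not raise


class TestSif:
    def test_catalysed_transition_expands_to_two_lines(self, tmp_path, phospho_map):
        n = write_sif(phospho_map, tmp_path / "m.sif")
        lines = (tmp_path / "m.sif").read_text().splitlines()
        assert n == 2
        assert "a\tSTATE_TRANSITION\tA*" in lines
        assert "b\tCATALYSIS\tA*" in lines

    def test_no_reactions_no_lines(self, tmp_path):
        smap = SignallingMap(width=200, height=200)
        smap.add_entity(protein("x"))
        assert write_sif(smap, tmp_path / "m.sif") == 0

    def test_association_two_lines(self, tmp_path):
        smap = SignallingMap(width=500, height=300)
        smap.add_entity(protein("a", x=10))
        smap.add_entity(protein("b", x=10, y=60))
        smap.add_entity(
            MapEntity(id="ab", name="ab", entity_class=EntityClass.COMPLEX,
                      position=(200, 30), size=(100, 50), members=["a", "b"])
        )
        smap.add_reaction(Reaction(id="r", reaction_class=ReactionClass.ASSOCIATION,
                                   reactants=["a", "b"], products=["ab"]))
        assert write_sif(smap, tmp_path / "m.sif") == 2

    def test_degradation_targets_sink_token(self, tmp_path):
        smap = SignallingMap(width=200, height=200)
        smap.add_entity(protein("dead"))
        smap.add_reaction(Reaction(id="r", reaction_class=ReactionClass.DEGRADATION,
                                   reactants=["dead"], products=[]))
        write_sif(smap, tmp_path / "m.sif")
        assert f"dead\tDEGRADATION\t{DEGRADATION_SINK}" in (tmp_path / "m.sif").read_text()

    def test_line_count_matches_brute_force_expansion(self):
        smap, _ = build_map(dna_repair_spec(seed=5))
        expected = 0
        for rxn in smap.reactions.values():
            n_targets = len(rxn.products) or 1  # degradation hits the sink token
            expected += (len(rxn.reactants) + len(rxn.regulators)) * n_targets
        assert len(sif_records(smap)) == expected

    def test_deterministic_lexicographic_order(self, tmp_path, phospho_map):
        records = sif_records(phospho_map)
        assert records == sorted(records)


class TestGmt:
    def test_18_modules_give_18_lines(self, tmp_path):
        smap, _ = build_map(dna_repair_spec(seed=0))
        mset = modules_from_tags(smap)
        n = write_gmt(mset, smap, tmp_path / "m.gmt")
        assert n == 18

    def test_empty_module_set_zero_lines(self, tmp_path):
        smap = SignallingMap(width=100, height=100)
        assert write_gmt(ModuleSet(), smap, tmp_path / "m.gmt") == 0

    def test_gene_in_complex_and_free_appears_once(self, tmp_path, complex_map):
        for ent in complex_map.entities.values():
            ent.annotation.module_tags = [("m", "only")]
        mset = modules_from_tags(complex_map)
        write_gmt(mset, complex_map, tmp_path / "m.gmt")
        line = (tmp_path / "m.gmt").read_text().splitlines()[0]
        genes = line.split("\t")[2:]
        assert sorted(genes) == ["P1", "P2", "P3"]
        assert len(genes) == len(set(genes))

    def test_missing_entity_raises(self, tmp_path, complex_map):
        mset = ModuleSet(modules=[Module(name="bad", entity_ids={"ghost"})])
        with pytest.raises(IntegrityError):
            write_gmt(mset, complex_map, tmp_path / "m.gmt")

    def test_description_is_layer_or_na(self, tmp_path):
        smap, _ = build_map(dna_repair_spec(seed=0))
        from sigmap.fixtures import dna_repair_layer_of
        mset = modules_from_tags(smap, layer_of=dna_repair_layer_of())
        write_gmt(mset, smap, tmp_path / "m.gmt")
        rows = [l.split("\t") for l in (tmp_path / "m.gmt").read_text().splitlines()]
        assert {r[1] for r in rows} == {"repair_machinery", "cell_cycle", "checkpoints"}
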