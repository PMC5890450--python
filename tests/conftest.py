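import pytest

from sigmap.annotation import Annotation, Reference, ReferenceKind
from sigmap.model import (
    EntityClass,
    MapEntity,
    Reaction,
    ReactionClass,
    RegulationClass,
    SignallingMap,
)


def protein(eid, hugo=None, x=0.0, y=0.0, **kw):
    return MapEntity(
        id=eid,
        name=kw.pop("name", eid),
        entity_class=EntityClass.PROTEIN,
        hugo_symbol=hugo,
        position=(x, y),
        size=(80.0, 40.0),
        **kw,
    )


@pytest.fixture
def phospho_map():
    """Phosphorylation of A catalysed by B: A -> A* (cat B)."""
    smap = SignallingMap(name="phospho", width=500, height=300)
    smap.add_entity(protein("a", hugo="A", x=20, y=20))
    smap.add_entity(
        protein("a_star", hugo="A", x=200, y=20, name="A*", modifications=["phosphorylated"])
    )
    smap.add_entity(protein("b", hugo="B", x=110, y=120))
    smap.add_reaction(
        Reaction(
            id="r1",
            reaction_class=ReactionClass.STATE_TRANSITION,
            reactants=["a"],
            products=["a_star"],
            regulators=[("b", RegulationClass.CATALYSIS)],
        )
    )
    smap.validate()
    return smap


@pytest.fixture
def chain_map():
    """e1 -r1-> e2 -r2-> e3 (a simple reaction chain)."""
    smap = SignallingMap(name="chain", width=600, height=200)
    for i, x in ((1, 20), (2, 220), (3, 420)):
        smap.add_entity(protein(f"e{i}", hugo=f"E{i}", x=x, y=20))
    smap.add_reaction(Reaction(id="r1", reactants=["e1"], products=["e2"]))
    smap.add_reaction(Reaction(id="r2", reactants=["e2"], products=["e3"]))
    smap.validate()
    return smap


@pytest.fixture
def complex_map():
    """Complex C = {P1, P2} reacting to P3; plus a free phenotype node."""
    smap = SignallingMap(name="cplx", width=600, height=400)
    smap.add_entity(protein("p1", hugo="P1", x=20, y=20))
    smap.add_entity(protein("p2", hugo="P2", x=20, y=90))
    smap.add_entity(protein("p3", hugo="P3", x=400, y=50))
    smap.add_entity(
        MapEntity(
            id="c",
            name="C",
            entity_class=EntityClass.COMPLEX,
            position=(150, 40),
            size=(120, 60),
            members=["p1", "p2"],
        )
    )
    smap.add_entity(
        MapEntity(
            id="pheno",
            name="apoptosis",
            entity_class=EntityClass.PHENOTYPE,
            position=(400, 250),
            size=(100, 40),
        )
    )
    smap.add_reaction(Reaction(id="rx", reactants=["c"], products=["p3"]))
    smap.add_reaction(
        Reaction(id="rp", reaction_class=ReactionClass.DEGRADATION, reactants=["pheno"], products=[])
    )
    smap.validate()
    return smap


@pytest.fixture
def two_reviews():
    return [
        Reference("1", ReferenceKind.REVIEW),
        Reference("2", ReferenceKind.REVIEW),
    ]


def annotated(entity, **sections):
    entity.annotation = Annotation(**sections)
    return entity
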