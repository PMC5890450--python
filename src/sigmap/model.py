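"""In-memory model of a process-description signalling map.

The map is a typed bipartite graph: molecular entities (proteins, genes,
RNAs, small molecules, complexes, phenotypes, ...) connected by reactions
(hyperedges with reactants, products and typed regulators), laid out on a
pixel canvas and optionally placed inside cell compartments.
"""

from __future__ import annotations

import enum
import math
from collections import deque
from dataclasses import dataclass, field, replace

from .annotation import Annotation
from .errors import EntityNotFoundError, IntegrityError


class EntityClass(enum.Enum):
    PROTEIN = "PROTEIN"
    GENE = "GENE"
    RNA = "RNA"
    ANTISENSE_RNA = "ANTISENSE_RNA"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    ION = "ION"
    DRUG = "DRUG"
    PHENOTYPE = "PHENOTYPE"
    COMPLEX = "COMPLEX"
    UNKNOWN = "UNKNOWN"


class ReactionClass(enum.Enum):
    STATE_TRANSITION = "STATE_TRANSITION"
    TRANSLATION = "TRANSLATION"
    TRANSCRIPTION = "TRANSCRIPTION"
    ASSOCIATION = "ASSOCIATION"
    DISSOCIATION = "DISSOCIATION"
    TRANSPORT = "TRANSPORT"
    DEGRADATION = "DEGRADATION"
    UNKNOWN = "UNKNOWN"


class RegulationClass(enum.Enum):
    CATALYSIS = "CATALYSIS"
    INHIBITION = "INHIBITION"
    MODULATION = "MODULATION"
    TRIGGER = "TRIGGER"
    PHYSICAL_STIMULATION = "PHYSICAL_STIMULATION"


@dataclass
class MapEntity:
    """A typed node of the map with layout box and structured annotation.

    ``position`` is the top-left corner of the bounding box, in pixels of
    the most detailed zoom level; x grows rightward, y downward.
    ``members`` is non-empty exactly for COMPLEX entities.
    """

    id: str
    name: str
    entity_class: EntityClass
    hugo_symbol: str | None = None
    modifications: list[str] = field(default_factory=list)
    compartment: str | None = None
    position: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (80.0, 40.0)
    members: list[str] = field(default_factory=list)
    annotation: Annotation = field(default_factory=Annotation)

    def __post_init__(self) -> None:
        if self.hugo_symbol is not None:
            self.hugo_symbol = self.hugo_symbol.strip().upper() or None
        # keep the HUGO identifier and the convenience field in lock-step so
        # that serialisation round-trips are exact
        if self.hugo_symbol and "HUGO" not in self.annotation.identifiers:
            self.annotation.identifiers["HUGO"] = self.hugo_symbol
        elif self.hugo_symbol is None and "HUGO" in self.annotation.identifiers:
            self.hugo_symbol = self.annotation.identifiers["HUGO"].strip().upper()
        for v in (*self.position, *self.size):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"entity {self.id}: position/size must be finite and >= 0")
        if bool(self.members) != (self.entity_class is EntityClass.COMPLEX):
            raise ValueError(
                f"entity {self.id}: members must be non-empty iff class is COMPLEX"
            )

    @property
    def centre(self) -> tuple[float, float]:
        return (self.position[0] + self.size[0] / 2, self.position[1] + self.size[1] / 2)


@dataclass
class Reaction:
    """A typed hyperedge linking reactant, product and regulator entities."""

    id: str
    reaction_class: ReactionClass = ReactionClass.STATE_TRANSITION
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    regulators: list[tuple[str, RegulationClass]] = field(default_factory=list)
    annotation: Annotation = field(default_factory=Annotation)

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ValueError(f"reaction {self.id}: reactants ∪ products must be non-empty")
        if not self.products and self.reaction_class is not ReactionClass.DEGRADATION:
            raise ValueError(
                f"reaction {self.id}: empty products only allowed for DEGRADATION"
            )

    def participant_ids(self) -> list[str]:
        """All entity ids touched by the reaction, in declaration order."""
        seen: dict[str, None] = {}
        for eid in (*self.reactants, *self.products, *(e for e, _ in self.regulators)):
            seen.setdefault(eid)
        return list(seen)


@dataclass
class Compartment:
    id: str
    name: str
    position: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (0.0, 0.0)


@dataclass
class SignallingMap:
    """A named map: entities + reactions + compartments on a pixel canvas."""

    name: str = "map"
    width: float = 1024.0
    height: float = 1024.0
    entities: dict[str, MapEntity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    module_set: "object | None" = None  # hierarchy.ModuleSet, set lazily

    # -- construction helpers ------------------------------------------------
    def add_entity(self, entity: MapEntity) -> MapEntity:
        if entity.id in self.entities:
            raise IntegrityError(f"duplicate entity id {entity.id!r}")
        self.entities[entity.id] = entity
        return entity

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if reaction.id in self.reactions:
            raise IntegrityError(f"duplicate reaction id {reaction.id!r}")
        self.reactions[reaction.id] = reaction
        return reaction

    def add_compartment(self, compartment: Compartment) -> Compartment:
        if compartment.id in self.compartments:
            raise IntegrityError(f"duplicate compartment id {compartment.id!r}")
        self.compartments[compartment.id] = compartment
        return compartment

    def entity(self, entity_id: str) -> MapEntity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise EntityNotFoundError(f"unknown entity id {entity_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[reaction_id]
        except KeyError:
            raise EntityNotFoundError(f"unknown reaction id {reaction_id!r}") from None

    # -- integrity -----------------------------------------------------------
    def validate(self) -> None:
        """Raise IntegrityError on any dangling reference or invariant breach."""
        for ent in self.entities.values():
            if ent.compartment is not None and ent.compartment not in self.compartments:
                raise IntegrityError(
                    f"entity {ent.id}: unknown compartment {ent.compartment!r}"
                )
            for mid in ent.members:
                if mid not in self.entities:
                    raise IntegrityError(f"complex {ent.id}: dangling member {mid!r}")
        self._check_member_acyclicity()
        for rxn in self.reactions.values():
            for eid in rxn.participant_ids():
                if eid not in self.entities:
                    raise IntegrityError(f"reaction {rxn.id}: dangling entity id {eid!r}")
        for ent in self.entities.values():
            x, y = ent.position
            w, h = ent.size
            if x + w > self.width + 1e-6 or y + h > self.height + 1e-6:
                raise IntegrityError(
                    f"entity {ent.id}: box ({x},{y},{w},{h}) outside canvas "
                    f"({self.width}x{self.height})"
                )

    def _check_member_acyclicity(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(eid: str, stack: list[str]) -> None:
            if state.get(eid) == 1:
                return
            if state.get(eid) == 0:
                raise IntegrityError(f"cyclic complex membership: {' -> '.join(stack + [eid])}")
            state[eid] = 0
            for mid in self.entities[eid].members:
                if mid in self.entities:
                    visit(mid, stack + [eid])
            state[eid] = 1

        for eid, ent in self.entities.items():
            if ent.members:
                visit(eid, [])

    # -- queries -------------------------------------------------------------
    def flatten_complex(self, entity_id: str) -> list[MapEntity]:
        """Leaf (non-COMPLEX) entities under a node, the node itself if a leaf."""
        ent = self.entity(entity_id)
        if not ent.members:
            return [ent]
        leaves: list[MapEntity] = []
        for mid in ent.members:
            if mid not in self.entities:
                raise IntegrityError(f"complex {entity_id}: dangling member {mid!r}")
            leaves.extend(self.flatten_complex(mid))
        return leaves

    def copy(self) -> "SignallingMap":
        out = SignallingMap(name=self.name, width=self.width, height=self.height)
        for ent in self.entities.values():
            out.entities[ent.id] = replace(
                ent,
                modifications=list(ent.modifications),
                members=list(ent.members),
                annotation=ent.annotation.copy(),
            )
        for rxn in self.reactions.values():
            out.reactions[rxn.id] = replace(
                rxn,
                reactants=list(rxn.reactants),
                products=list(rxn.products),
                regulators=list(rxn.regulators),
                annotation=rxn.annotation.copy(),
            )
        for comp in self.compartments.values():
            out.compartments[comp.id] = replace(comp)
        out.module_set = self.module_set
        return out


def participant_proteins(reaction: Reaction, smap: SignallingMap) -> set[str]:
    """HUGO symbols of every protein participating in a reaction.

    Complex participants are recursively decomposed into their protein
    members; participants of other classes, and proteins lacking a HUGO
    symbol, are omitted.
    """
    if reaction.id not in smap.reactions:
        raise IntegrityError(f"reaction {reaction.id!r} does not belong to map {smap.name!r}")
    symbols: set[str] = set()
    for eid in reaction.participant_ids():
        if eid not in smap.entities:
            raise IntegrityError(f"reaction {reaction.id}: dangling entity id {eid!r}")
        for leaf in smap.flatten_complex(eid):
            if leaf.entity_class is EntityClass.PROTEIN and leaf.hugo_symbol:
                symbols.add(leaf.hugo_symbol)
    return symbols


def entity_degree(smap: SignallingMap) -> dict[str, int]:
    """Participation degree: number of reactions each entity touches."""
    degree = {eid: 0 for eid in smap.entities}
    for rxn in smap.reactions.values():
        for eid in rxn.participant_ids():
            if eid in degree:
                degree[eid] += 1
    return degree


def neighbourhood(smap: SignallingMap, entity_id: str, radius: int) -> SignallingMap:
    """Induced sub-map of entities within ``radius`` reaction steps.

    A reaction links all of its participants (reactants, products and
    regulators alike); radius 0 returns the entity alone.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    smap.entity(entity_id)  # raises EntityNotFoundError when unknown
    # BFS on the bipartite entity-reaction incidence structure.
    incident: dict[str, list[Reaction]] = {}
    for rxn in smap.reactions.values():
        for eid in rxn.participant_ids():
            incident.setdefault(eid, []).append(rxn)
    kept_entities = {entity_id}
    kept_reactions: set[str] = set()
    frontier = deque([(entity_id, 0)])
    seen = {entity_id: 0}
    while frontier:
        eid, dist = frontier.popleft()
        if dist == radius:
            continue
        for rxn in incident.get(eid, ()):
            kept_reactions.add(rxn.id)
            for other in rxn.participant_ids():
                if other not in seen or seen[other] > dist + 1:
                    seen[other] = dist + 1
                    kept_entities.add(other)
                    frontier.append((other, dist + 1))
    return induced_submap(smap, kept_entities, kept_reactions, name=f"{smap.name}:{entity_id}+{radius}")


def induced_submap(
    smap: SignallingMap,
    entity_ids: set[str],
    reaction_ids: set[str] | None = None,
    name: str | None = None,
    include_members: bool = True,
) -> SignallingMap:
    """Sub-map induced by an entity set (closed over complex members).

    When ``reaction_ids`` is None, keeps every reaction all of whose
    participants survive.  Annotations are carried over by value.
    """
    closure = set()
    stack = [eid for eid in entity_ids if eid in smap.entities]
    while stack:
        eid = stack.pop()
        if eid in closure:
            continue
        closure.add(eid)
        if include_members:
            stack.extend(m for m in smap.entities[eid].members if m in smap.entities)
    sub = SignallingMap(name=name or smap.name, width=smap.width, height=smap.height)
    for eid, ent in smap.entities.items():
        if eid in closure:
            members = [m for m in ent.members if m in closure]
            # a complex whose members were all filtered away degrades to UNKNOWN
            cls = ent.entity_class
            if ent.members and not members:
                cls = EntityClass.UNKNOWN
            sub.entities[eid] = replace(
                ent,
                entity_class=cls,
                modifications=list(ent.modifications),
                members=members,
                annotation=ent.annotation.copy(),
            )
    for rid, rxn in smap.reactions.items():
        if reaction_ids is not None:
            keep = rid in reaction_ids
        else:
            keep = all(eid in closure for eid in rxn.participant_ids())
        if keep:
            sub.reactions[rid] = replace(
                rxn,
                reactants=list(rxn.reactants),
                products=list(rxn.products),
                regulators=list(rxn.regulators),
                annotation=rxn.annotation.copy(),
            )
    used_comps = {e.compartment for e in sub.entities.values() if e.compartment}
    for cid, comp in smap.compartments.items():
        if cid in used_comps:
            sub.compartments[cid] = replace(comp)
    return sub
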