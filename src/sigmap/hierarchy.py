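"""Layer/module hierarchy: decomposition from annotation tags, module
sub-map extraction with fresh layout, deterministic re-layout and
identifier-based map merging."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

from .annotation import Annotation, Reference
from .errors import EntityNotFoundError, IntegrityError, MergeConflictError
from .model import EntityClass, MapEntity, SignallingMap, induced_submap

#: module that collects entities carrying no module tag
UNTAGGED_MODULE = "_untagged"


@dataclass
class Module:
    name: str
    layer: str = "NA"
    entity_ids: set[str] = field(default_factory=set)
    reaction_ids: set[str] = field(default_factory=set)


@dataclass
class ModuleSet:
    layers: list[str] = field(default_factory=list)
    modules: list[Module] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.modules]
        if len(names) != len(set(names)):
            raise IntegrityError("module names must be unique")

    def module(self, name: str) -> Module:
        for m in self.modules:
            if m.name == name:
                return m
        raise EntityNotFoundError(f"unknown module {name!r}")

    def __len__(self) -> int:
        return len(self.modules)


def modules_from_tags(
    smap: SignallingMap, layer_of: dict[str, str] | None = None
) -> ModuleSet:
    """Build the module decomposition from ``MODULE:<map>:<module>`` tags.

    Entity membership comes from tags; a reaction belongs to every module
    that contains at least one of its participants.  Entities with no tag
    fall into the reserved ``_untagged`` module.
    """
    layer_of = layer_of or {}
    modules: dict[str, Module] = {}

    def get(name: str) -> Module:
        if name not in modules:
            modules[name] = Module(name=name, layer=layer_of.get(name, "NA"))
        return modules[name]

    for ent in smap.entities.values():
        tags = [mod for _map, mod in ent.annotation.module_tags]
        if tags:
            for mod in tags:
                get(mod).entity_ids.add(ent.id)
        else:
            get(UNTAGGED_MODULE).entity_ids.add(ent.id)
    for rxn in smap.reactions.values():
        for module in modules.values():
            if any(eid in module.entity_ids for eid in rxn.participant_ids()):
                module.reaction_ids.add(rxn.id)
    ordered = sorted(modules.values(), key=lambda m: m.name)
    layers = sorted({m.layer for m in ordered if m.layer != "NA"})
    if any(m.layer == "NA" for m in ordered):
        layers.append("NA")
    mset = ModuleSet(layers=layers, modules=ordered)
    smap.module_set = mset
    return mset


def extract_module_map(
    smap: SignallingMap,
    module_name: str,
    module_set: ModuleSet | None = None,
    strict: bool = True,
    seed: int = 0,
) -> SignallingMap:
    """Independent sub-map for one module, with a fresh compact layout.

    ``strict`` keeps only reactions whose participants all lie in the
    module closure (entities plus their complex members); the loose
    alternative keeps every reaction touching the module, pulling the
    missing participants in.
    """
    mset = module_set or smap.module_set or modules_from_tags(smap)
    module = mset.module(module_name)
    for eid in module.entity_ids:
        if eid not in smap.entities:
            raise IntegrityError(f"module {module_name!r}: missing entity {eid!r}")
    if strict:
        sub = induced_submap(smap, set(module.entity_ids), name=f"{smap.name}:{module_name}")
    else:
        entity_ids = set(module.entity_ids)
        for rid in module.reaction_ids:
            entity_ids.update(smap.reactions[rid].participant_ids())
        sub = induced_submap(
            smap, entity_ids, set(module.reaction_ids), name=f"{smap.name}:{module_name}"
        )
    return relayout(sub, seed=seed)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _interaction_graph(smap: SignallingMap) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(smap.entities)
    for rxn in smap.reactions.values():
        ids = rxn.participant_ids()
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if a != b:
                    g.add_edge(a, b)
    for ent in smap.entities.values():
        for mid in ent.members:
            g.add_edge(ent.id, mid)
    return g


def relayout(smap: SignallingMap, seed: int = 0) -> SignallingMap:
    """Deterministic force-directed layout with overlap removal.

    Same seed, same topology -> identical coordinates; entity bounding
    boxes never overlap (guaranteed by a grid fallback when the repulsion
    pass cannot separate them).
    """
    out = smap.copy()
    n = len(out.entities)
    if n == 0:
        return out
    order = sorted(out.entities)
    max_w = max(e.size[0] for e in out.entities.values())
    max_h = max(e.size[1] for e in out.entities.values())
    if n == 1:
        ent = out.entities[order[0]]
        ent.position = (
            max(0.0, (out.width - ent.size[0]) / 2),
            max(0.0, (out.height - ent.size[1]) / 2),
        )
        return out

    g = _interaction_graph(out)
    pos = nx.spring_layout(g, seed=seed, iterations=60)
    # scale unit layout onto a canvas roomy enough for the boxes
    cols = math.ceil(math.sqrt(n))
    width = max(cols * (max_w + 40.0) + 40.0, 400.0)
    height = max(cols * (max_h + 40.0) + 40.0, 400.0)
    xs = [pos[eid][0] for eid in order]
    ys = [pos[eid][1] for eid in order]
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    span_x = (x1 - x0) or 1.0
    span_y = (y1 - y0) or 1.0
    for eid in order:
        ent = out.entities[eid]
        ent.position = (
            20.0 + (pos[eid][0] - x0) / span_x * (width - ent.size[0] - 40.0),
            20.0 + (pos[eid][1] - y0) / span_y * (height - ent.size[1] - 40.0),
        )
    if not _separate_overlaps(out, order, width, height):
        _grid_layout(out, order, max_w, max_h)
        width = max(e.position[0] + e.size[0] for e in out.entities.values()) + 20.0
        height = max(e.position[1] + e.size[1] for e in out.entities.values()) + 20.0
    out.width = max(width, max(e.position[0] + e.size[0] for e in out.entities.values()) + 20.0)
    out.height = max(height, max(e.position[1] + e.size[1] for e in out.entities.values()) + 20.0)
    return out


def _boxes_overlap(a: MapEntity, b: MapEntity, pad: float = 2.0) -> bool:
    ax, ay = a.position
    aw, ah = a.size
    bx, by = b.position
    bw, bh = b.size
    return not (
        ax + aw + pad <= bx
        or bx + bw + pad <= ax
        or ay + ah + pad <= by
        or by + bh + pad <= ay
    )


def _separate_overlaps(smap, order, width, height, max_iter: int = 300) -> bool:
    for _ in range(max_iter):
        moved = False
        for i, aid in enumerate(order):
            for bid in order[i + 1 :]:
                a, b = smap.entities[aid], smap.entities[bid]
                if not _boxes_overlap(a, b):
                    continue
                moved = True
                ax, ay = a.centre
                bx, by = b.centre
                dx, dy = bx - ax, by - ay
                norm = math.hypot(dx, dy)
                if norm < 1e-9:
                    dx, dy, norm = 1.0, 0.5, math.hypot(1.0, 0.5)
                step = 6.0
                ux, uy = dx / norm * step, dy / norm * step
                a.position = (
                    min(max(0.0, a.position[0] - ux), width - a.size[0]),
                    min(max(0.0, a.position[1] - uy), height - a.size[1]),
                )
                b.position = (
                    min(max(0.0, b.position[0] + ux), width - b.size[0]),
                    min(max(0.0, b.position[1] + uy), height - b.size[1]),
                )
        if not moved:
            return True
    return False


def _grid_layout(smap, order, max_w, max_h) -> None:
    cols = math.ceil(math.sqrt(len(order)))
    for idx, eid in enumerate(order):
        ent = smap.entities[eid]
        ent.position = (
            20.0 + (idx % cols) * (max_w + 40.0),
            20.0 + (idx // cols) * (max_h + 40.0),
        )


def has_overlaps(smap: SignallingMap) -> bool:
    ents = sorted(smap.entities.values(), key=lambda e: e.id)
    member_ids = {m for e in ents for m in e.members}
    for i, a in enumerate(ents):
        for b in ents[i + 1 :]:
            # members drawn inside their complex are allowed to intersect it
            if a.id in member_ids or b.id in member_ids:
                continue
            if _boxes_overlap(a, b, pad=0.0):
                return True
    return False


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

_HUGO_CLASSES = {
    EntityClass.PROTEIN,
    EntityClass.GENE,
    EntityClass.RNA,
    EntityClass.ANTISENSE_RNA,
}
_CHEBI_CLASSES = {EntityClass.SIMPLE_MOLECULE, EntityClass.ION, EntityClass.DRUG}


def identity_key(ent: MapEntity) -> tuple:
    """Merge/scoring identity: standard identifiers, never display names.

    Proteins/genes/RNAs key on their HUGO symbol (plus class and drawn
    modification state); small molecules on their CHEBI id; everything
    else falls back to (class, name).
    """
    if ent.entity_class in _HUGO_CLASSES and ent.hugo_symbol:
        return ("HUGO", ent.hugo_symbol, tuple(sorted(ent.modifications)))
    chebi = ent.annotation.identifiers.get("CHEBI")
    if ent.entity_class in _CHEBI_CLASSES and chebi:
        return ("CHEBI", chebi)
    return ("NAME", ent.name, tuple(sorted(ent.modifications)))


def _merge_annotations(into: Annotation, other: Annotation) -> None:
    for ns, val in other.identifiers.items():
        into.identifiers.setdefault(ns, val)
    for tag in other.map_tags:
        if tag not in into.map_tags:
            into.map_tags.append(tag)
    for tag in other.module_tags:
        if tag not in into.module_tags:
            into.module_tags.append(tag)
    seen = {r.identifier for r in into.references}
    for ref in other.references:
        if ref.identifier not in seen:
            into.references.append(ref)
            seen.add(ref.identifier)
    for tag in other.tags:
        if tag not in into.tags:
            into.tags.append(tag)
    for note in other.notes:
        if note not in into.notes:
            into.notes.append(note)
    if into.confidence is None:
        into.confidence = other.confidence


def merge_maps(a: SignallingMap, b: SignallingMap, name: str | None = None) -> SignallingMap:
    """Union of two maps, unifying entities that share an identity key.

    Annotations are union-merged; reactions are de-duplicated by (class,
    reactant set, product set, regulator set) after identity mapping; the
    second map's layout is offset onto a free canvas region to the right.
    """
    a.validate()
    b.validate()
    out = SignallingMap(
        name=name or f"{a.name}+{b.name}",
        width=a.width,
        height=a.height,
    )
    key_to_id: dict[tuple, str] = {}
    id_map_a: dict[str, str] = {}
    id_map_b: dict[str, str] = {}
    offset_x = a.width + 40.0 if b.entities else 0.0

    for smap, id_map, dx in ((a, id_map_a, 0.0), (b, id_map_b, offset_x)):
        for eid in sorted(smap.entities):
            ent = smap.entities[eid]
            key = identity_key(ent)
            if key in key_to_id:
                target = out.entities[key_to_id[key]]
                if target.entity_class is not ent.entity_class:
                    raise MergeConflictError(
                        f"identity key {key} maps to classes "
                        f"{target.entity_class.value} and {ent.entity_class.value}"
                    )
                _merge_annotations(target.annotation, ent.annotation)
                id_map[eid] = target.id
            else:
                new = replace(
                    ent,
                    position=(ent.position[0] + dx, ent.position[1]),
                    modifications=list(ent.modifications),
                    members=list(ent.members),  # remapped below
                    annotation=ent.annotation.copy(),
                )
                if new.id in out.entities:
                    new.id = f"{smap.name}__{new.id}"
                out.entities[new.id] = new
                key_to_id[key] = new.id
                id_map[eid] = new.id

    for smap, id_map in ((a, id_map_a), (b, id_map_b)):
        for eid in sorted(smap.entities):
            new_id = id_map[eid]
            src = smap.entities[eid]
            if src.members and out.entities[new_id].members == src.members:
                out.entities[new_id].members = sorted(
                    {id_map[m] for m in src.members if m in id_map}
                )

    for cid in sorted({**a.compartments, **b.compartments}):
        comp = a.compartments.get(cid) or b.compartments[cid]
        out.compartments[cid] = replace(comp)

    seen_signatures: dict[tuple, str] = {}
    for smap, id_map in ((a, id_map_a), (b, id_map_b)):
        for rid in sorted(smap.reactions):
            rxn = smap.reactions[rid]
            reactants = [id_map[x] for x in rxn.reactants]
            products = [id_map[x] for x in rxn.products]
            regulators = [(id_map[x], rc) for x, rc in rxn.regulators]
            signature = (
                rxn.reaction_class.value,
                frozenset(reactants),
                frozenset(products),
                frozenset(regulators),
            )
            if signature in seen_signatures:
                existing = out.reactions[seen_signatures[signature]]
                _merge_annotations(existing.annotation, rxn.annotation)
                continue
            new_id = rid if rid not in out.reactions else f"{smap.name}__{rid}"
            out.reactions[new_id] = replace(
                rxn,
                id=new_id,
                reactants=reactants,
                products=products,
                regulators=regulators,
                annotation=rxn.annotation.copy(),
            )
            seen_signatures[signature] = new_id

    out.width = max(
        max((e.position[0] + e.size[0] for e in out.entities.values()), default=0.0)
        + 20.0,
        a.width,
    )
    out.height = max(
        max((e.position[1] + e.size[1] for e in out.entities.values()), default=a.height)
        + 20.0,
        a.height,
        b.height,
    )
    out.validate()
    return out
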