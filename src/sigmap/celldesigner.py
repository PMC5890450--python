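"""Read and write CellDesigner-flavoured SBML, plus SIF and GMT exports.

The reader targets the vendor extension subset actually used by
process-description maps: species classes, species aliases (layout
boxes), complex nesting via alias parentage, reaction types and typed
modification arcs.  Everything it does not understand is skipped — never
fatal — and recorded in a :class:`DialectReport`.

The writer emits a canonical form of the same dialect: UTF-8, two-space
indent, lexicographically sorted attributes and sorted element order, so
that output files are byte-stable and usable as golden files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree.ElementTree import ParseError as _ETParseError

from .annotation import parse_annotation, serialise_annotation
from .errors import IntegrityError, MapParseError
from .model import (
    Compartment,
    EntityClass,
    MapEntity,
    Reaction,
    ReactionClass,
    RegulationClass,
    SignallingMap,
)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"
XHTML_NS = "http://www.w3.org/1999/xhtml"


def _sbml(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _cd(tag: str) -> str:
    return f"{{{CD_NS}}}{tag}"


@dataclass
class SkippedConstruct:
    construct: str
    reason: str


@dataclass
class DialectReport:
    """Accounting of what the parser understood and what it skipped."""

    n_species: int = 0
    n_reactions: int = 0
    n_compartments: int = 0
    skipped: list[SkippedConstruct] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def skip(self, construct: str, reason: str) -> None:
        self.skipped.append(SkippedConstruct(construct, reason))


_REGULATION_NAMES = {rc.value: rc for rc in RegulationClass}
_ENTITY_CLASS_NAMES = {ec.value: ec for ec in EntityClass}
_REACTION_CLASS_NAMES = {rc.value: rc for rc in ReactionClass}


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_celldesigner(path: str | Path) -> tuple[SignallingMap, DialectReport]:
    """Parse a CellDesigner-dialect SBML file into a SignallingMap."""
    try:
        tree = ET.parse(str(path))
    except _ETParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise MapParseError(f"malformed XML in {path}: {exc.msg if hasattr(exc, 'msg') else exc}", line) from exc
    root = tree.getroot()
    if not root.tag.endswith("sbml"):
        raise MapParseError(f"{path}: root element is {root.tag!r}, expected sbml")
    report = DialectReport()
    model = root.find(_sbml("model"))
    if model is None:
        model = root.find("model")  # tolerate missing default namespace
    smap = SignallingMap(name="map")
    if model is None:
        report.warnings.append("no <model> element; returning empty map")
        return smap, report
    smap.name = model.get("id") or model.get("name") or "map"

    extension = model.find(f"{_sbml('annotation')}/{_cd('extension')}")
    if extension is None:
        report.warnings.append(
            "no CellDesigner extension on model; classes default to UNKNOWN"
        )

    alias_bounds, alias_parent, alias_species, complex_alias_species = _read_aliases(
        extension, report
    )
    _read_model_display(extension, smap)
    _read_compartments(model, extension, smap, report)
    _read_species(model, smap, report, alias_bounds, alias_species)
    _read_complex_membership(smap, alias_parent, alias_species, complex_alias_species, report)
    _read_reactions(model, smap, report)

    if smap.entities and (smap.width <= 1 or smap.height <= 1):
        _fit_canvas(smap)
    return smap, report


def _read_model_display(extension, smap: SignallingMap) -> None:
    if extension is None:
        return
    display = extension.find(_cd("modelDisplay"))
    if display is not None:
        try:
            smap.width = float(display.get("sizeX", smap.width))
            smap.height = float(display.get("sizeY", smap.height))
        except (TypeError, ValueError):
            pass


def _read_aliases(extension, report: DialectReport):
    alias_bounds: dict[str, tuple[float, float, float, float]] = {}
    alias_parent: dict[str, str] = {}  # speciesAlias id -> complexSpeciesAlias id
    alias_species: dict[str, str] = {}  # alias id -> species id
    complex_alias_species: dict[str, str] = {}
    if extension is None:
        return alias_bounds, alias_parent, alias_species, complex_alias_species
    for list_tag, is_complex in (
        ("listOfSpeciesAliases", False),
        ("listOfComplexSpeciesAliases", True),
    ):
        lst = extension.find(_cd(list_tag))
        if lst is None:
            continue
        for alias in lst:
            aid = alias.get("id")
            sid = alias.get("species")
            if not aid or not sid:
                report.skip(list_tag, "alias without id/species attributes")
                continue
            alias_species[aid] = sid
            if is_complex:
                complex_alias_species[aid] = sid
            parent = alias.get("complexSpeciesAlias")
            if parent:
                alias_parent[aid] = parent
            bounds = alias.find(_cd("bounds"))
            if bounds is not None:
                try:
                    alias_bounds[sid] = (
                        float(bounds.get("x", 0)),
                        float(bounds.get("y", 0)),
                        float(bounds.get("w", 80)),
                        float(bounds.get("h", 40)),
                    )
                except (TypeError, ValueError):
                    report.skip(list_tag, f"alias {aid}: non-numeric bounds")
    return alias_bounds, alias_parent, alias_species, complex_alias_species


def _read_compartments(model, extension, smap: SignallingMap, report: DialectReport) -> None:
    comp_bounds: dict[str, tuple[float, float, float, float]] = {}
    if extension is not None:
        lst = extension.find(_cd("listOfCompartmentAliases"))
        if lst is not None:
            for alias in lst:
                cid = alias.get("compartment")
                bounds = alias.find(_cd("bounds"))
                if cid and bounds is not None:
                    try:
                        comp_bounds[cid] = (
                            float(bounds.get("x", 0)),
                            float(bounds.get("y", 0)),
                            float(bounds.get("w", 0)),
                            float(bounds.get("h", 0)),
                        )
                    except (TypeError, ValueError):
                        report.skip("listOfCompartmentAliases", f"{cid}: non-numeric bounds")
    lst = model.find(_sbml("listOfCompartments"))
    if lst is None:
        return
    for comp in lst.findall(_sbml("compartment")):
        cid = comp.get("id")
        if not cid:
            report.skip("compartment", "missing id")
            continue
        x, y, w, h = comp_bounds.get(cid, (0.0, 0.0, 0.0, 0.0))
        smap.add_compartment(
            Compartment(id=cid, name=comp.get("name", cid), position=(x, y), size=(w, h))
        )
        report.n_compartments += 1


def _notes_text(element) -> str:
    notes = element.find(_sbml("notes"))
    if notes is None:
        return ""
    body = notes.find(f"{{{XHTML_NS}}}body")
    node = body if body is not None else notes
    return "".join(node.itertext()).strip()


def _read_species(model, smap, report, alias_bounds, alias_species) -> None:
    lst = model.find(_sbml("listOfSpecies"))
    if lst is None:
        return
    for sp in lst.findall(_sbml("species")):
        sid = sp.get("id")
        if not sid:
            report.skip("species", "missing id attribute")
            continue
        try:
            entity = _species_to_entity(sp, sid, report, alias_bounds)
        except Exception as exc:  # never fatal: record and move on
            report.skip("species", f"{sid}: {exc}")
            continue
        if entity.id in smap.entities:
            report.skip("species", f"duplicate id {sid}")
            continue
        smap.entities[entity.id] = entity
        report.n_species += 1


def _species_to_entity(sp, sid, report, alias_bounds) -> MapEntity:
    identity = sp.find(f"{_sbml('annotation')}/{_cd('extension')}/{_cd('speciesIdentity')}")
    cls = EntityClass.UNKNOWN
    modifications: list[str] = []
    if identity is not None:
        cls_el = identity.find(_cd("class"))
        raw = (cls_el.text or "").strip().upper() if cls_el is not None else ""
        if raw in _ENTITY_CLASS_NAMES:
            cls = _ENTITY_CLASS_NAMES[raw]
        elif raw:
            report.skip("speciesIdentity", f"{sid}: unsupported class {raw!r} -> UNKNOWN")
        mods = identity.find(_cd("listOfModifications"))
        if mods is not None:
            for mod in mods:
                state = mod.get("state")
                if state:
                    modifications.append(state)
    else:
        report.skip("species", f"{sid}: no speciesIdentity -> class UNKNOWN")
    annotation = parse_annotation(_notes_text(sp))
    hugo = annotation.identifiers.get("HUGO")
    x, y, w, h = alias_bounds.get(sid, (0.0, 0.0, 80.0, 40.0))
    if sid not in alias_bounds:
        report.warnings.append(f"species {sid}: no alias bounds; default box used")
    # members are attached later from alias parentage; pre-seed to satisfy the
    # COMPLEX invariant, then overwrite.
    members = ["__pending__"] if cls is EntityClass.COMPLEX else []
    return MapEntity(
        id=sid,
        name=sp.get("name", sid),
        entity_class=cls,
        hugo_symbol=hugo,
        modifications=modifications,
        compartment=sp.get("compartment") or None,
        position=(x, y),
        size=(w, h),
        members=members,
        annotation=annotation,
    )


def _read_complex_membership(smap, alias_parent, alias_species, complex_alias_species, report):
    members: dict[str, list[str]] = {}
    for aid, parent_aid in alias_parent.items():
        child_sid = alias_species.get(aid)
        parent_sid = complex_alias_species.get(parent_aid)
        if child_sid is None or parent_sid is None:
            report.skip("speciesAlias", f"{aid}: dangling complexSpeciesAlias ref")
            continue
        if child_sid in smap.entities and parent_sid in smap.entities:
            members.setdefault(parent_sid, []).append(child_sid)
        else:
            report.skip("speciesAlias", f"{aid}: member/complex species missing")
    for ent in smap.entities.values():
        if ent.entity_class is EntityClass.COMPLEX:
            got = sorted(members.get(ent.id, []))
            if got:
                ent.members = got
            else:
                report.warnings.append(f"complex {ent.id} has no members; class -> UNKNOWN")
                ent.members = []
                ent.entity_class = EntityClass.UNKNOWN


def _read_reactions(model, smap, report) -> None:
    lst = model.find(_sbml("listOfReactions"))
    if lst is None:
        return
    for rx in lst.findall(_sbml("reaction")):
        rid = rx.get("id")
        if not rid:
            report.skip("reaction", "missing id attribute")
            continue
        try:
            reaction = _reaction_from_xml(rx, rid, smap, report)
        except Exception as exc:
            report.skip("reaction", f"{rid}: {exc}")
            continue
        if reaction is None:
            continue
        smap.reactions[rid] = reaction
        report.n_reactions += 1


def _reaction_from_xml(rx, rid, smap, report) -> Reaction | None:
    ext = rx.find(f"{_sbml('annotation')}/{_cd('extension')}")
    rcls = ReactionClass.STATE_TRANSITION
    mod_types: dict[str, RegulationClass] = {}
    if ext is not None:
        type_el = ext.find(_cd("reactionType"))
        raw = (type_el.text or "").strip().upper() if type_el is not None else ""
        if raw in _REACTION_CLASS_NAMES:
            rcls = _REACTION_CLASS_NAMES[raw]
        elif raw:
            report.skip("reactionType", f"{rid}: unsupported type {raw!r} -> UNKNOWN")
            rcls = ReactionClass.UNKNOWN
        mods = ext.find(_cd("listOfModification"))
        if mods is not None:
            for mod in mods:
                mtype = (mod.get("type") or "").strip().upper().replace(" ", "_")
                for sid in (mod.get("modifiers") or "").split(","):
                    sid = sid.strip()
                    if not sid:
                        continue
                    if mtype in _REGULATION_NAMES:
                        mod_types[sid] = _REGULATION_NAMES[mtype]
                    else:
                        report.skip(
                            "modification", f"{rid}: type {mtype!r} -> MODULATION"
                        )
                        mod_types[sid] = RegulationClass.MODULATION

    def refs(tag: str) -> list[str]:
        parent = rx.find(_sbml(tag))
        if parent is None:
            return []
        out = []
        for child in parent:
            sid = child.get("species")
            if sid:
                out.append(sid)
        return out

    reactants = refs("listOfReactants")
    products = refs("listOfProducts")
    modifiers = refs("listOfModifiers")
    missing = [s for s in (*reactants, *products, *modifiers) if s not in smap.entities]
    if missing:
        report.skip("reaction", f"{rid}: references unknown species {missing}")
        return None
    if not reactants and not products:
        report.skip("reaction", f"{rid}: no reactants or products")
        return None
    if not products and rcls is not ReactionClass.DEGRADATION:
        report.skip("reaction", f"{rid}: empty products on non-degradation -> DEGRADATION")
        rcls = ReactionClass.DEGRADATION
    regulators = [
        (sid, mod_types.get(sid, RegulationClass.MODULATION)) for sid in modifiers
    ]
    for sid in modifiers:
        if sid not in mod_types:
            report.warnings.append(f"reaction {rid}: modifier {sid} untyped -> MODULATION")
    return Reaction(
        id=rid,
        reaction_class=rcls,
        reactants=reactants,
        products=products,
        regulators=regulators,
        annotation=parse_annotation(_notes_text(rx)),
    )


def _fit_canvas(smap: SignallingMap) -> None:
    smap.width = max(e.position[0] + e.size[0] for e in smap.entities.values()) + 20
    smap.height = max(e.position[1] + e.size[1] for e in smap.entities.values()) + 20


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _num(v: float) -> str:
    """Float formatting that round-trips exactly and prints ints bare."""
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_celldesigner(smap: SignallingMap, path: str | Path) -> None:
    """Serialise a map to the canonical CellDesigner-dialect XML form."""
    smap.validate()
    lines: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append(
        f'<sbml level="2" version="4" xmlns="{SBML_NS}" xmlns:celldesigner="{CD_NS}">'
    )
    lines.append(f'  <model id="{_esc(smap.name)}">')
    lines.append("    <annotation>")
    lines.append("      <celldesigner:extension>")
    lines.append(
        f'        <celldesigner:modelDisplay sizeX="{_num(smap.width)}" sizeY="{_num(smap.height)}"/>'
    )
    # aliases: one speciesAlias per non-complex entity, complexSpeciesAlias per complex;
    # membership encoded through the member alias' complexSpeciesAlias attribute.
    member_of = {
        mid: ent.id for ent in smap.entities.values() for mid in ent.members
    }
    lines.append("        <celldesigner:listOfSpeciesAliases>")
    for ent in _sorted_entities(smap):
        if ent.entity_class is EntityClass.COMPLEX:
            continue
        parent = member_of.get(ent.id)
        parent_attr = f' complexSpeciesAlias="csa_{_esc(parent)}"' if parent else ""
        lines.append(
            f'          <celldesigner:speciesAlias id="sa_{_esc(ent.id)}"'
            f' species="{_esc(ent.id)}"{parent_attr}>'
        )
        lines.append(_bounds_line(ent, indent=12))
        lines.append("          </celldesigner:speciesAlias>")
    lines.append("        </celldesigner:listOfSpeciesAliases>")
    lines.append("        <celldesigner:listOfComplexSpeciesAliases>")
    for ent in _sorted_entities(smap):
        if ent.entity_class is not EntityClass.COMPLEX:
            continue
        parent = member_of.get(ent.id)
        parent_attr = f' complexSpeciesAlias="csa_{_esc(parent)}"' if parent else ""
        lines.append(
            f'          <celldesigner:complexSpeciesAlias id="csa_{_esc(ent.id)}"'
            f' species="{_esc(ent.id)}"{parent_attr}>'
        )
        lines.append(_bounds_line(ent, indent=12))
        lines.append("          </celldesigner:complexSpeciesAlias>")
    lines.append("        </celldesigner:listOfComplexSpeciesAliases>")
    if smap.compartments:
        lines.append("        <celldesigner:listOfCompartmentAliases>")
        for comp in sorted(smap.compartments.values(), key=lambda c: c.id):
            lines.append(
                f'          <celldesigner:compartmentAlias compartment="{_esc(comp.id)}"'
                f' id="ca_{_esc(comp.id)}">'
            )
            lines.append(
                f'            <celldesigner:bounds h="{_num(comp.size[1])}" w="{_num(comp.size[0])}"'
                f' x="{_num(comp.position[0])}" y="{_num(comp.position[1])}"/>'
            )
            lines.append("          </celldesigner:compartmentAlias>")
        lines.append("        </celldesigner:listOfCompartmentAliases>")
    lines.append("      </celldesigner:extension>")
    lines.append("    </annotation>")

    if smap.compartments:
        lines.append("    <listOfCompartments>")
        for comp in sorted(smap.compartments.values(), key=lambda c: c.id):
            lines.append(
                f'      <compartment id="{_esc(comp.id)}" name="{_esc(comp.name)}"/>'
            )
        lines.append("    </listOfCompartments>")

    if smap.entities:
        lines.append("    <listOfSpecies>")
        for ent in _sorted_entities(smap):
            comp_attr = f' compartment="{_esc(ent.compartment)}"' if ent.compartment else ""
            lines.append(
                f'      <species{comp_attr} id="{_esc(ent.id)}" name="{_esc(ent.name)}">'
            )
            lines.append("        <annotation>")
            lines.append("          <celldesigner:extension>")
            lines.append("            <celldesigner:speciesIdentity>")
            lines.append(
                f"              <celldesigner:class>{ent.entity_class.value}</celldesigner:class>"
            )
            if ent.modifications:
                lines.append("              <celldesigner:listOfModifications>")
                for state in ent.modifications:
                    lines.append(
                        f'                <celldesigner:modification state="{_esc(state)}"/>'
                    )
                lines.append("              </celldesigner:listOfModifications>")
            lines.append("            </celldesigner:speciesIdentity>")
            lines.append("          </celldesigner:extension>")
            lines.append("        </annotation>")
            _append_notes(lines, _entity_annotation_text(ent), indent=8)
            lines.append("      </species>")
        lines.append("    </listOfSpecies>")

    if smap.reactions:
        lines.append("    <listOfReactions>")
        for rxn in sorted(smap.reactions.values(), key=lambda r: r.id):
            lines.append(f'      <reaction id="{_esc(rxn.id)}" reversible="false">')
            lines.append("        <annotation>")
            lines.append("          <celldesigner:extension>")
            lines.append(
                f"            <celldesigner:reactionType>{rxn.reaction_class.value}</celldesigner:reactionType>"
            )
            if rxn.regulators:
                lines.append("            <celldesigner:listOfModification>")
                for sid, rc in rxn.regulators:
                    lines.append(
                        f'              <celldesigner:modification modifiers="{_esc(sid)}"'
                        f' type="{rc.value}"/>'
                    )
                lines.append("            </celldesigner:listOfModification>")
            lines.append("          </celldesigner:extension>")
            lines.append("        </annotation>")
            _append_notes(lines, serialise_annotation(rxn.annotation), indent=8)
            if rxn.reactants:
                lines.append("        <listOfReactants>")
                for sid in rxn.reactants:
                    lines.append(f'          <speciesReference species="{_esc(sid)}"/>')
                lines.append("        </listOfReactants>")
            if rxn.products:
                lines.append("        <listOfProducts>")
                for sid in rxn.products:
                    lines.append(f'          <speciesReference species="{_esc(sid)}"/>')
                lines.append("        </listOfProducts>")
            if rxn.regulators:
                lines.append("        <listOfModifiers>")
                for sid, _ in rxn.regulators:
                    lines.append(
                        f'          <modifierSpeciesReference species="{_esc(sid)}"/>'
                    )
                lines.append("        </listOfModifiers>")
            lines.append("      </reaction>")
        lines.append("    </listOfReactions>")

    lines.append("  </model>")
    lines.append("</sbml>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _entity_annotation_text(ent: MapEntity) -> str:
    ann = ent.annotation.copy()
    if ent.hugo_symbol and ann.identifiers.get("HUGO") != ent.hugo_symbol:
        ann.identifiers["HUGO"] = ent.hugo_symbol
    return serialise_annotation(ann)


def _append_notes(lines: list[str], text: str, indent: int) -> None:
    if not text:
        return
    pad = " " * indent
    lines.append(f"{pad}<notes>")
    lines.append(f'{pad}  <body xmlns="{XHTML_NS}">')
    for ln in text.splitlines():
        lines.append(f"{pad}    {_esc(ln)}")
    lines.append(f"{pad}  </body>")
    lines.append(f"{pad}</notes>")


def _bounds_line(ent: MapEntity, indent: int) -> str:
    pad = " " * indent
    return (
        f'{pad}<celldesigner:bounds h="{_num(ent.size[1])}" w="{_num(ent.size[0])}"'
        f' x="{_num(ent.position[0])}" y="{_num(ent.position[1])}"/>'
    )


def _sorted_entities(smap: SignallingMap) -> list[MapEntity]:
    return sorted(smap.entities.values(), key=lambda e: e.id)


def _esc(text: str) -> str:
    return (
        str(text)
        .replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


# ---------------------------------------------------------------------------
# SIF / GMT exports
# ---------------------------------------------------------------------------

#: target used for degradation reactions, which have no product species
DEGRADATION_SINK = "__degraded__"


def sif_records(smap: SignallingMap) -> list[tuple[str, str, str]]:
    """Expand every reaction into directed binary (source, relation, target) rows.

    Reactants pair with every product under the reaction class; regulators
    pair with every product under their regulation class.  Degradation
    reactions (no products) target the reserved sink token.
    """
    records: list[tuple[str, str, str]] = []
    for rxn in smap.reactions.values():
        targets = [smap.entity(p).name for p in rxn.products] or [DEGRADATION_SINK]
        for rid_ in rxn.reactants:
            src = smap.entity(rid_).name
            for tgt in targets:
                records.append((src, rxn.reaction_class.value, tgt))
        for sid, rc in rxn.regulators:
            src = smap.entity(sid).name
            for tgt in targets:
                records.append((src, rc.value, tgt))
    records.sort()
    return records


def write_sif(smap: SignallingMap, path: str | Path) -> int:
    """Write the SIF expansion; returns the number of lines written."""
    smap.validate()
    records = sif_records(smap)
    with open(path, "w", encoding="utf-8") as fh:
        for src, rel, tgt in records:
            fh.write(f"{src}\t{rel}\t{tgt}\n")
    return len(records)


def write_gmt(module_set, smap: SignallingMap, path: str | Path) -> int:
    """Write the module decomposition as a GMT gene-set file.

    One line per module, sorted by module name: name, description (the
    module's layer or ``NA``), then the de-duplicated HUGO symbols of the
    module's entities with complexes flattened.
    """
    lines = []
    for module in sorted(module_set.modules, key=lambda m: m.name):
        genes: set[str] = set()
        for eid in sorted(module.entity_ids):
            if eid not in smap.entities:
                raise IntegrityError(
                    f"module {module.name!r} references missing entity {eid!r}"
                )
            for leaf in smap.flatten_complex(eid):
                if leaf.hugo_symbol:
                    genes.add(leaf.hugo_symbol)
        description = module.layer or "NA"
        lines.append("\t".join([module.name, description, *sorted(genes)]))
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
    return len(lines)
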