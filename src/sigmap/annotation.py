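"""Structured four-section entity annotations and their text dialect.

An annotation is organised in four sections — ``Identifiers``,
``Maps_Modules``, ``References`` and ``Confidence`` — stored inside the
notes block of a map entity or reaction.  The on-disk grammar is a plain
line-oriented dialect:

.. code-block:: text

    Identifiers:
    HUGO:BRCA1
    UNIPROT:P38398
    Maps_Modules:
    MAP:dna_repair
    MODULE:dna_repair:HR
    References:
    PMID:9103                     # an original publication (weight 1)
    PMID:12360 [review]           # a review article (weight 3)
    Confidence:
    REF:5
    FUNC:4

Section headers are case-insensitive and may appear in any order; lines
that match no known pattern are preserved verbatim as free-text notes.
``TAG:<flag>`` lines attach boolean flags (e.g. ``backbone``,
``canonical``) consumed by the semantic-zoom policies.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

from jinja2 import Template

log = logging.getLogger(__name__)


class ReferenceKind(enum.Enum):
    ORIGINAL = "original"
    REVIEW = "review"


@dataclass(frozen=True)
class Reference:
    """A literature reference; reviews carry more weight than originals."""

    identifier: str
    kind: ReferenceKind = ReferenceKind.ORIGINAL
    note: str | None = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("reference identifier must be non-empty")


@dataclass(frozen=True)
class Confidence:
    """The pair of integer confidence scores, each in [0, 5]."""

    ref_score: int
    func_score: int

    def __post_init__(self) -> None:
        for name in ("ref_score", "func_score"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 5:
                raise ValueError(f"{name} must be an integer in [0, 5], got {v!r}")


@dataclass
class Annotation:
    """The four-section structured annotation of an entity or reaction."""

    identifiers: dict[str, str] = field(default_factory=dict)
    map_tags: list[str] = field(default_factory=list)
    module_tags: list[tuple[str, str]] = field(default_factory=list)
    references: list[Reference] = field(default_factory=list)
    confidence: Confidence | None = None
    tags: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.identifiers
            or self.map_tags
            or self.module_tags
            or self.references
            or self.confidence
            or self.tags
            or self.notes
        )

    def copy(self) -> "Annotation":
        return Annotation(
            identifiers=dict(self.identifiers),
            map_tags=list(self.map_tags),
            module_tags=list(self.module_tags),
            references=list(self.references),
            confidence=self.confidence,
            tags=list(self.tags),
            notes=list(self.notes),
        )


_SECTIONS = ("identifiers", "maps_modules", "references", "confidence")
_HEADER_RE = re.compile(r"^\s*(identifiers|maps_modules|references|confidence)\s*:?\s*$", re.I)
_PMID_RE = re.compile(r"^PMID:(\S+)\s*(\[review\])?\s*(.*)$", re.I)
_KV_RE = re.compile(r"^([A-Za-z][\w.-]*):(\S.*)$")


def parse_annotation(text: str) -> Annotation:
    """Parse the body of a notes block into an :class:`Annotation`.

    Never raises on malformed content: unrecognised lines are kept as
    free-text notes (and logged) so no curator input is dropped silently.
    """
    ann = Annotation()
    section: str | None = None
    for raw in (text or "").splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _HEADER_RE.match(line)
        if m:
            section = m.group(1).lower()
            continue
        if _parse_line(ann, section, line):
            continue
        if section in (None, "identifiers", "maps_modules", "references", "confidence"):
            log.debug("annotation line kept as note: %r", line)
        ann.notes.append(line)
    return ann


def _parse_line(ann: Annotation, section: str | None, line: str) -> bool:
    """Try to interpret one line; return True when it was consumed."""
    upper = line.upper()
    if upper.startswith("TAG:"):
        flag = line.split(":", 1)[1].strip()
        if flag and flag not in ann.tags:
            ann.tags.append(flag)
        return True
    if upper.startswith("MAP:"):
        name = line.split(":", 1)[1].strip()
        if name and name not in ann.map_tags:
            ann.map_tags.append(name)
            return True
        return bool(name)
    if upper.startswith("MODULE:"):
        parts = line.split(":")
        if len(parts) == 3 and parts[1].strip() and parts[2].strip():
            tag = (parts[1].strip(), parts[2].strip())
            if tag not in ann.module_tags:
                ann.module_tags.append(tag)
            return True
        log.warning("malformed module tag: %r", line)
        return False
    if section == "references" or upper.startswith("PMID:"):
        m = _PMID_RE.match(line)
        if m:
            kind = ReferenceKind.REVIEW if m.group(2) else ReferenceKind.ORIGINAL
            note = m.group(3).strip() or None
            ann.references.append(Reference(m.group(1), kind, note))
            return True
        return False
    if section == "confidence":
        m = _KV_RE.match(line)
        if m and m.group(1).upper() in ("REF", "FUNC"):
            try:
                value = int(m.group(2).strip())
            except ValueError:
                log.warning("malformed confidence line: %r", line)
                return False
            ref = ann.confidence.ref_score if ann.confidence else 0
            func = ann.confidence.func_score if ann.confidence else 0
            if m.group(1).upper() == "REF":
                ref = value
            else:
                func = value
            try:
                ann.confidence = Confidence(ref, func)
            except ValueError:
                log.warning("confidence value out of range: %r", line)
                return False
            return True
        return False
    if section == "identifiers":
        m = _KV_RE.match(line)
        if m:
            ann.identifiers[m.group(1).upper()] = m.group(2).strip()
            return True
        return False
    return False


def serialise_annotation(ann: Annotation) -> str:
    """Render an Annotation back to its text dialect (inverse of parse)."""
    lines: list[str] = []
    if ann.identifiers:
        lines.append("Identifiers:")
        lines.extend(f"{ns}:{val}" for ns, val in sorted(ann.identifiers.items()))
    if ann.map_tags or ann.module_tags:
        lines.append("Maps_Modules:")
        lines.extend(f"MAP:{m}" for m in ann.map_tags)
        lines.extend(f"MODULE:{m}:{mod}" for m, mod in ann.module_tags)
    if ann.references:
        lines.append("References:")
        for ref in ann.references:
            suffix = " [review]" if ref.kind is ReferenceKind.REVIEW else ""
            note = f" {ref.note}" if ref.note else ""
            lines.append(f"PMID:{ref.identifier}{suffix}{note}")
    if ann.confidence is not None:
        lines.append("Confidence:")
        lines.append(f"REF:{ann.confidence.ref_score}")
        lines.append(f"FUNC:{ann.confidence.func_score}")
    lines.extend(f"TAG:{t}" for t in ann.tags)
    lines.extend(ann.notes)
    return "\n".join(lines)


#: printf-style URL templates per identifier namespace; overridable per call.
DEFAULT_URL_TEMPLATES: dict[str, str] = {
    "HUGO": "https://www.genenames.org/tools/search/#!/?query=%s",
    "UNIPROT": "https://www.uniprot.org/uniprotkb/%s",
    "ENTREZ": "https://www.ncbi.nlm.nih.gov/gene/%s",
    "CHEBI": "https://www.ebi.ac.uk/chebi/searchId.do?chebiId=%s",
    "PMID": "https://pubmed.ncbi.nlm.nih.gov/%s/",
}

_POST_TEMPLATE = Template(
    """\
<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{{ title }}</title></head>
<body>
<h1>{{ title }}</h1>
<h2>Identifiers</h2>
<ul>
{% for ns, val, url in identifiers %}{% if url %}<li>{{ ns }}: <a href="{{ url }}">{{ val }}</a></li>
{% else %}<li>{{ ns }}: {{ val }}</li>
{% endif %}{% endfor %}</ul>
<h2>Maps_Modules</h2>
<ul>
{% for label, anchor in modules %}<li><a href="#module-{{ anchor }}">{{ label }}</a></li>
{% endfor %}</ul>
<h2>References</h2>
<ul>
{% for ref in references %}<li><a href="{{ ref.url }}">PMID:{{ ref.id }}</a>{{ ref.suffix }}</li>
{% endfor %}</ul>
<h2>Confidence</h2>
{% if confidence %}<p>REF: <span class="stars">{{ confidence.ref_stars }}</span></p>
<p>FUNC: <span class="stars">{{ confidence.func_stars }}</span></p>
{% endif %}{% if notes %}<h2>Notes</h2>
<ul>
{% for note in notes %}<li>{{ note }}</li>
{% endfor %}</ul>
{% endif %}</body>
</html>
"""
)


def _stars(n: int) -> str:
    return "★" * n + "☆" * (5 - n)


def render_post(entity, url_templates: dict[str, str] | None = None) -> str:
    """Render an entity's annotation as a self-contained hypertext page.

    Pure function of the entity: identical input yields byte-identical
    output, so the pages can be golden-file tested.  Identifier namespaces
    absent from the template table are shown without a hyperlink.
    """
    templates = dict(DEFAULT_URL_TEMPLATES)
    if url_templates:
        templates.update(url_templates)
    ann: Annotation = entity.annotation
    identifiers = []
    for ns, val in sorted(ann.identifiers.items()):
        tpl = templates.get(ns)
        identifiers.append((ns, val, tpl % val if tpl else None))
    modules = [(f"MAP:{m}", m) for m in ann.map_tags]
    modules += [(f"{m}:{mod}", f"{m}-{mod}") for m, mod in ann.module_tags]
    references = []
    for ref in ann.references:
        suffix = " [review]" if ref.kind is ReferenceKind.REVIEW else ""
        if ref.note:
            suffix += f" — {ref.note}"
        references.append(
            {"id": ref.identifier, "url": templates["PMID"] % ref.identifier, "suffix": suffix}
        )
    confidence = None
    if ann.confidence is not None:
        confidence = {
            "ref_stars": _stars(ann.confidence.ref_score),
            "func_stars": _stars(ann.confidence.func_score),
        }
    return _POST_TEMPLATE.render(
        title=entity.name,
        identifiers=identifiers,
        modules=modules,
        references=references,
        confidence=confidence,
        notes=ann.notes,
    )
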