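"""Deterministic raster drawing of map views (Pillow, fixed palette/font).

Kept free of policy decisions: callers hand in a view plus optional
decorations (module background shapes, markers, overlay layers) and get a
PIL image back.  Determinism contract: identical inputs produce
byte-identical PNG output.
"""

from __future__ import annotations

from dataclasses import dataclass

from PIL import Image, ImageDraw, ImageFont

from .model import EntityClass, SignallingMap

CLASS_FILL: dict[EntityClass, str] = {
    EntityClass.PROTEIN: "#8ecae6",
    EntityClass.GENE: "#b7e4c7",
    EntityClass.RNA: "#d8f3dc",
    EntityClass.ANTISENSE_RNA: "#e9edc9",
    EntityClass.SIMPLE_MOLECULE: "#ffe5b4",
    EntityClass.ION: "#ffd6a5",
    EntityClass.DRUG: "#ffadad",
    EntityClass.PHENOTYPE: "#cdb4db",
    EntityClass.COMPLEX: "#a3c4f3",
    EntityClass.UNKNOWN: "#dddddd",
}

MODULE_PALETTE = [
    "#ffadad55", "#ffd6a555", "#fdffb655", "#caffbf55",
    "#9bf6ff55", "#a0c4ff55", "#bdb2ff55", "#ffc6ff55",
]

BACKGROUND = "#ffffff"
EDGE_COLOUR = "#555555"
MARKER_COLOUR = "#d00000"

_FONT = ImageFont.load_default()


@dataclass(frozen=True)
class Marker:
    entity_id: str
    label: str = ""


def draw_view(
    view: SignallingMap,
    scale: float = 1.0,
    module_backgrounds: list[tuple[str, tuple[float, float, float, float]]] | None = None,
    markers: list[Marker] | None = None,
    background_image: Image.Image | None = None,
) -> Image.Image:
    """Render one map view at a given pixel scale."""
    w = max(1, int(round(view.width * scale)))
    h = max(1, int(round(view.height * scale)))
    img = Image.new("RGB", (w, h), BACKGROUND)
    if background_image is not None:
        img.paste(
            background_image.resize((w, h), Image.NEAREST).convert("RGB"),
            (0, 0),
        )
    overlay = Image.new("RGBA", (w, h), (0, 0, 0, 0))
    odraw = ImageDraw.Draw(overlay)

    if module_backgrounds:
        for idx, (name, (x, y, bw, bh)) in enumerate(module_backgrounds):
            colour = MODULE_PALETTE[idx % len(MODULE_PALETTE)]
            box = _box(x, y, bw, bh, scale, w, h)
            odraw.rectangle(box, fill=colour, outline="#88888888")
            odraw.text((box[0] + 3, box[1] + 2), name, fill="#333333ff", font=_FONT)
    img = Image.alpha_composite(img.convert("RGBA"), overlay).convert("RGB")
    draw = ImageDraw.Draw(img)

    for comp in sorted(view.compartments.values(), key=lambda c: c.id):
        if comp.size[0] > 0 and comp.size[1] > 0:
            box = _box(*comp.position, *comp.size, scale, w, h)
            draw.rectangle(box, outline="#b08968", width=max(1, int(scale)))

    for rxn in sorted(view.reactions.values(), key=lambda r: r.id):
        pts = [
            view.entities[eid].centre
            for eid in rxn.participant_ids()
            if eid in view.entities
        ]
        if len(pts) < 2:
            continue
        cx = sum(p[0] for p in pts) / len(pts)
        cy = sum(p[1] for p in pts) / len(pts)
        for px, py in pts:
            draw.line(
                [(px * scale, py * scale), (cx * scale, cy * scale)],
                fill=EDGE_COLOUR,
                width=max(1, int(scale)),
            )

    for ent in sorted(view.entities.values(), key=lambda e: e.id):
        box = _box(*ent.position, *ent.size, scale, w, h)
        draw.rectangle(box, fill=CLASS_FILL[ent.entity_class], outline="#333333")
        if scale >= 0.5:
            draw.text((box[0] + 2, box[1] + 1), ent.name[:24], fill="#000000", font=_FONT)

    if markers:
        for marker in markers:
            ent = view.entities.get(marker.entity_id)
            if ent is None:
                continue
            mx, my = ent.centre
            mx *= scale
            my *= scale
            r = max(4, int(4 * scale))
            draw.polygon(
                [(mx, my), (mx - r, my - 2 * r), (mx + r, my - 2 * r)],
                fill=MARKER_COLOUR,
            )
            if marker.label:
                draw.text((mx + r, my - 2 * r), marker.label, fill=MARKER_COLOUR, font=_FONT)
    return img


def _box(x, y, bw, bh, scale, w, h):
    x0 = max(0, int(round(x * scale)))
    y0 = max(0, int(round(y * scale)))
    x1 = min(w - 1, int(round((x + bw) * scale)))
    y1 = min(h - 1, int(round((y + bh) * scale)))
    return (x0, y0, max(x0, x1), max(y0, y1))
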