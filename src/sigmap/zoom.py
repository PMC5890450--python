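"""Semantic zooming: per-level pruned map views and a raster tile pyramid.

Instead of pure geometric scaling, each zoom level shows a pruned view of
the map — a backbone-plus-module-backgrounds overview at the top, a
canonical-pathway view in the middle, full detail at the bottom — so the
amount of drawn detail stays readable at every level.  Views are rendered
into 256-px Google-Maps-style tiles: level ``L`` is drawn at ``2**L``
times the native canvas resolution and cut into a
``ceil(W*2^L/256) x ceil(H*2^L/256)`` grid.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from jinja2 import Template

from ._render import Marker, draw_view
from .model import SignallingMap, entity_degree, induced_submap

TILE_SIZE = 256

#: annotation flags consumed by the visibility rules
BACKBONE_TAG = "backbone"
CANONICAL_TAG = "canonical"


class VisibilityRule(enum.Enum):
    MODULE_BACKGROUNDS_AND_BACKBONE = "MODULE_BACKGROUNDS_AND_BACKBONE"
    CANONICAL_PATHWAYS = "CANONICAL_PATHWAYS"
    FULL_DETAIL = "FULL_DETAIL"


@dataclass(frozen=True)
class LevelSpec:
    name: str
    rule: VisibilityRule
    backbone_degree: int = 4
    canonical_tag: str = CANONICAL_TAG


@dataclass
class ZoomPolicy:
    levels: list[LevelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("a zoom policy needs at least 2 levels")
        if self.levels[-1].rule is not VisibilityRule.FULL_DETAIL:
            raise ValueError("the last zoom level must be FULL_DETAIL")


def default_policy(backbone_degree: int = 4, canonical_tag: str = CANONICAL_TAG) -> ZoomPolicy:
    """Three levels — backbone overview, canonical pathways, full detail."""
    return ZoomPolicy(
        levels=[
            LevelSpec("backbone", VisibilityRule.MODULE_BACKGROUNDS_AND_BACKBONE, backbone_degree, canonical_tag),
            LevelSpec("canonical", VisibilityRule.CANONICAL_PATHWAYS, backbone_degree, canonical_tag),
            LevelSpec("detail", VisibilityRule.FULL_DETAIL, backbone_degree, canonical_tag),
        ]
    )


def prune(smap: SignallingMap, level_spec: LevelSpec) -> SignallingMap:
    """One level's view.  Retained reactions keep all their participants or
    are dropped — pruning never reroutes edges."""
    if level_spec.rule is VisibilityRule.FULL_DETAIL:
        return smap.copy()
    if level_spec.rule is VisibilityRule.MODULE_BACKGROUNDS_AND_BACKBONE:
        degree = entity_degree(smap)
        keep = {
            eid
            for eid, ent in smap.entities.items()
            if degree[eid] >= level_spec.backbone_degree
            or BACKBONE_TAG in ent.annotation.tags
        }
    else:  # CANONICAL_PATHWAYS
        keep = {
            eid
            for eid, ent in smap.entities.items()
            if level_spec.canonical_tag in ent.annotation.tags
        }
        for rxn in smap.reactions.values():
            if level_spec.canonical_tag in rxn.annotation.tags:
                keep.update(rxn.participant_ids())
    view = induced_submap(smap, keep, name=f"{smap.name}@{level_spec.name}", include_members=False)
    view.width = smap.width
    view.height = smap.height
    return view


def build_views(smap: SignallingMap, policy: ZoomPolicy) -> list[SignallingMap]:
    """Views for every level, with monotone detail containment enforced:
    entities(level i) ⊆ entities(level i+1)."""
    views = [prune(smap, spec) for spec in policy.levels]
    for i in range(1, len(views)):
        missing = set(views[i - 1].entities) - set(views[i].entities)
        if missing:
            keep = set(views[i].entities) | set(views[i - 1].entities)
            views[i] = induced_submap(
                smap, keep, name=views[i].name, include_members=False
            )
            views[i].width = smap.width
            views[i].height = smap.height
    return views


def grid_shape(width: float, height: float, level: int, tile_size: int = TILE_SIZE) -> tuple[int, int]:
    scale = 2 ** level
    return (
        math.ceil(width * scale / tile_size),
        math.ceil(height * scale / tile_size),
    )


def tile_count(width: float, height: float, n_levels: int, tile_size: int = TILE_SIZE) -> int:
    """Closed-form total number of tiles over all levels."""
    total = 0
    for level in range(n_levels):
        nx, ny = grid_shape(width, height, level, tile_size)
        total += nx * ny
    return total


@dataclass
class TilePyramid:
    out_dir: Path
    tile_size: int
    canvas: tuple[float, float]
    levels: list[dict]

    @property
    def total_tiles(self) -> int:
        return sum(lv["nx"] * lv["ny"] for lv in self.levels)


_HTML_TEMPLATE = Template(
    """\
<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{{ name }}</title>
<style>
body { font-family: sans-serif; margin: 0; }
nav { padding: 6px; background: #eee; position: sticky; top: 0; }
nav a { margin-right: 8px; }
.level { display: none; line-height: 0; white-space: nowrap; overflow: auto; }
.level:target { display: block; }
.level:last-of-type { display: block; }
.level:target ~ .level:last-of-type { display: none; }
img { display: inline-block; }
</style>
</head>
<body>
<nav>Zoom:
{% for level in levels %}<a href="#level-{{ level.level }}">{{ level.level }} ({{ level.name }})</a>
{% endfor %}</nav>
{% for level in levels %}<div class="level" id="level-{{ level.level }}">
{% for row in level.rows %}<div>{% for tile in row %}<img src="{{ tile }}" width="{{ tile_size }}" height="{{ tile_size }}">{% endfor %}</div>
{% endfor %}</div>
{% endfor %}</body>
</html>
"""
)


def render_tiles(
    views: list[SignallingMap],
    policy: ZoomPolicy,
    out_dir: str | Path,
    markers: list[Marker] | None = None,
    module_backgrounds: list[tuple[str, tuple[float, float, float, float]]] | None = None,
    tile_size: int = TILE_SIZE,
) -> TilePyramid:
    """Render one view per level into PNG tiles plus index.json and map.html.

    Byte-identical across runs for identical inputs (fixed font, palette
    and PNG encoder settings).
    """
    if len(views) != len(policy.levels):
        raise ValueError(f"expected {len(policy.levels)} views, got {len(views)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(v.width for v in views)
    height = max(v.height for v in views)
    level_records = []
    html_levels = []
    for level, (view, spec) in enumerate(zip(views, policy.levels)):
        scale = 2 ** level
        backgrounds = None
        if spec.rule is VisibilityRule.MODULE_BACKGROUNDS_AND_BACKBONE:
            backgrounds = module_backgrounds
        img = draw_view(view, scale=scale, module_backgrounds=backgrounds, markers=markers)
        nx, ny = grid_shape(width, height, level, tile_size)
        level_dir = out_dir / "tiles" / str(level)
        level_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for ty in range(ny):
            row = []
            for tx in range(nx):
                tile = img.crop(
                    (tx * tile_size, ty * tile_size, (tx + 1) * tile_size, (ty + 1) * tile_size)
                )
                rel = f"tiles/{level}/{tx}_{ty}.png"
                tile.save(out_dir / "tiles" / str(level) / f"{tx}_{ty}.png", format="PNG")
                row.append(rel)
            rows.append(row)
        level_records.append(
            {"level": level, "name": spec.name, "rule": spec.rule.value,
             "scale": scale, "nx": nx, "ny": ny,
             "entities": len(view.entities), "reactions": len(view.reactions)}
        )
        html_levels.append({"level": level, "name": spec.name, "rows": rows})
    index = {
        "tile_size": tile_size,
        "canvas": [width, height],
        # dialect note: level 0 is the native canvas; each deeper level
        # doubles the resolution (no shrink-to-single-tile level exists)
        "coordinate_convention": "level0=native_canvas;scale=2**level",
        "levels": level_records,
    }
    (out_dir / "index.json").write_text(
        json.dumps(index, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out_dir / "map.html").write_text(
        _HTML_TEMPLATE.render(name=views[-1].name, levels=html_levels, tile_size=tile_size),
        encoding="utf-8",
    )
    return TilePyramid(out_dir=out_dir, tile_size=tile_size, canvas=(width, height), levels=level_records)


def module_background_boxes(smap: SignallingMap, module_set) -> list[tuple[str, tuple[float, float, float, float]]]:
    """Bounding box of each module's entities, for the overview level."""
    boxes = []
    for module in sorted(module_set.modules, key=lambda m: m.name):
        ents = [smap.entities[eid] for eid in module.entity_ids if eid in smap.entities]
        if not ents:
            continue
        x0 = min(e.position[0] for e in ents)
        y0 = min(e.position[1] for e in ents)
        x1 = max(e.position[0] + e.size[0] for e in ents)
        y1 = max(e.position[1] + e.size[1] for e in ents)
        boxes.append((module.name, (x0, y0, x1 - x0, y1 - y0)))
    return boxes


def read_markers_tsv(path: str | Path) -> list[Marker]:
    """Markers from a TSV of (entity id, label)."""
    markers = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        markers.append(Marker(cols[0], cols[1] if len(cols) > 1 else ""))
    return markers
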