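"""Omics overlay: import, group/family aggregation, map staining, glyphs
and per-entity mini charts.

All matching between data and map is done through upper-case HUGO
symbols; every rendering operation emits a reconciliation report counting
genes matched on the map versus ignored.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from ._render import draw_view
from .model import MapEntity, SignallingMap

log = logging.getLogger(__name__)


class AggregateBy(enum.Enum):
    GROUP = "GROUP"
    FAMILY = "FAMILY"
    GROUP_AND_FAMILY = "GROUP_AND_FAMILY"


class AggregateStat(enum.Enum):
    MEAN = "MEAN"
    MEDIAN = "MEDIAN"


@dataclass
class OverlayDataset:
    """gene x sample matrix plus optional sample groups and gene families."""

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    families: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [str(g).strip().upper() for g in self.values.index]
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene rows: {dupes}")
        self.families = {
            name: {str(g).strip().upper() for g in genes}
            for name, genes in self.families.items()
        }
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"groups reference unknown samples: {sorted(unknown)}")

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        groups_path: str | Path | None = None,
        families_path: str | Path | None = None,
    ) -> "OverlayDataset":
        """Load a TSV matrix (first column = HUGO symbol, header = samples),
        an optional (sample, group) TSV and an optional families GMT."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups: dict[str, str] = {}
        if groups_path is not None:
            for raw in Path(groups_path).read_text(encoding="utf-8").splitlines():
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) >= 2:
                    groups[cols[0]] = cols[1]
        families: dict[str, set[str]] = {}
        if families_path is not None:
            for raw in Path(families_path).read_text(encoding="utf-8").splitlines():
                cols = raw.rstrip("\n").split("\t")
                if len(cols) >= 3:
                    families[cols[0]] = set(cols[2:])
        return cls(values=values, groups=groups, families=families)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def aggregate(
    data: OverlayDataset,
    by: AggregateBy,
    stat: AggregateStat = AggregateStat.MEAN,
) -> OverlayDataset:
    """Aggregate over sample groups and/or gene families, skipping NAs.

    GROUP: one column per group (stat over member samples).  FAMILY: one
    extra row per family (stat over member genes present in the matrix).
    Row/column order is deterministic (sorted).  Groups or families that
    are empty after NA removal yield NA cells.
    """
    frame = data.values

    if by in (AggregateBy.GROUP, AggregateBy.GROUP_AND_FAMILY):
        if not data.groups:
            raise ValueError("GROUP aggregation requires sample groups")
        cols = {}
        for group in sorted(set(data.groups.values())):
            samples = [s for s, g in data.groups.items() if g == group and s in frame.columns]
            if not samples:
                log.warning("group %r has no samples in the matrix; NA column", group)
            sub = frame[samples]
            cols[group] = sub.mean(axis=1) if stat is AggregateStat.MEAN else sub.median(axis=1)
        frame = pd.DataFrame(cols)

    if by in (AggregateBy.FAMILY, AggregateBy.GROUP_AND_FAMILY):
        if not data.families:
            raise ValueError("FAMILY aggregation requires gene families")
        rows = {}
        for family in sorted(data.families):
            members = sorted(data.families[family] & set(frame.index))
            if not members:
                log.warning("family %r has no genes in the matrix; NA row", family)
            sub = frame.loc[members]
            rows[family] = sub.mean(axis=0) if stat is AggregateStat.MEAN else sub.median(axis=0)
        frame = pd.DataFrame(rows).T
        frame = frame.sort_index()

    return OverlayDataset(values=frame, groups={}, families=dict(data.families))


# ---------------------------------------------------------------------------
# colour scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorScale:
    """Diverging low-mid-high scale with an NA colour."""

    vmin: float
    vmax: float
    vmid: float = 0.0
    low: tuple[int, int, int] = (33, 102, 172)    # blue
    mid: tuple[int, int, int] = (247, 247, 247)   # near-white
    high: tuple[int, int, int] = (178, 24, 43)    # red
    na_colour: tuple[int, int, int] = (190, 190, 190)

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError("vmin must be < vmax")

    @classmethod
    def symmetric(cls, values) -> "ColorScale":
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        bound = float(np.max(np.abs(arr))) if arr.size else 1.0
        bound = bound or 1.0
        return cls(vmin=-bound, vmax=bound, vmid=0.0)

    def colour(self, value: float) -> tuple[int, int, int]:
        if value is None or not math.isfinite(value):
            return self.na_colour
        v = min(max(value, self.vmin), self.vmax)
        if v <= self.vmid:
            span = self.vmid - self.vmin or 1.0
            t = (v - self.vmin) / span
            a, b = self.low, self.mid
        else:
            span = self.vmax - self.vmid or 1.0
            t = (v - self.vmid) / span
            a, b = self.mid, self.high
        return tuple(int(round(a[i] + (b[i] - a[i]) * t)) for i in range(3))


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    """Bookkeeping of the gene-symbol match between a dataset and a view."""

    n_genes: int
    matched: list[str]
    ignored: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_ignored(self) -> int:
        return len(self.ignored)


def _symbol_anchors(view: SignallingMap) -> dict[str, list[MapEntity]]:
    """Map positions carrying each HUGO symbol (complex members included,
    anchored at the complex box)."""
    anchors: dict[str, list[MapEntity]] = {}
    member_ids = {m for e in view.entities.values() for m in e.members}
    for ent in sorted(view.entities.values(), key=lambda e: e.id):
        if ent.id in member_ids:
            continue  # members are drawn inside their complex
        for leaf in view.flatten_complex(ent.id):
            if leaf.hugo_symbol:
                anchors.setdefault(leaf.hugo_symbol, []).append(ent)
    return anchors


def _match(data: OverlayDataset, anchors: dict[str, list[MapEntity]]) -> MatchReport:
    matched = sorted(g for g in data.genes if g in anchors)
    ignored = sorted(g for g in data.genes if g not in anchors)
    return MatchReport(n_genes=len(data.genes), matched=matched, ignored=ignored)


# ---------------------------------------------------------------------------
# map staining
# ---------------------------------------------------------------------------

@dataclass
class StainLayer:
    """Smoothed background colour field: per-grid-cell value and kernel mass."""

    value_field: np.ndarray   # (ny, nx) kernel-weighted mean, NaN where empty
    weight_field: np.ndarray  # (ny, nx) total kernel mass
    grid_step: float
    scale: ColorScale
    bandwidth: float
    report: MatchReport

    def to_image(self, opacity: float = 0.55) -> Image.Image:
        ny, nx = self.value_field.shape
        img = Image.new("RGBA", (nx, ny))
        px = img.load()
        wmax = float(self.weight_field.max()) or 1.0
        for y in range(ny):
            for x in range(nx):
                v = self.value_field[y, x]
                colour = self.scale.colour(v if np.isfinite(v) else float("nan"))
                alpha = opacity * min(1.0, self.weight_field[y, x] / (0.05 * wmax + 1e-12))
                px[x, y] = (*colour, int(round(255 * alpha)))
        return img


def map_staining(
    view: SignallingMap,
    data: OverlayDataset,
    scale: ColorScale | None = None,
    bandwidth: float | None = None,
    grid_step: float = 16.0,
) -> StainLayer:
    """Gaussian-kernel background colour field from one column of values.

    Each gene's value is attached to every map position carrying that HUGO
    symbol; the field is the Nadaraya–Watson kernel-weighted average of
    attached values, with an isotropic Gaussian kernel whose default
    bandwidth is 5% of the canvas diagonal.  Invariant under permutation
    of entity enumeration order.
    """
    if data.values.shape[1] != 1:
        raise ValueError(
            f"map staining needs exactly one value column, got {data.values.shape[1]}"
        )
    report_warnings: list[str] = []
    anchors = _symbol_anchors(view)
    report = _match(data, anchors)
    report.warnings = report_warnings
    column = data.values.iloc[:, 0]
    xs, ys, vs = [], [], []
    for gene in report.matched:
        value = column.loc[gene]
        if not np.isfinite(value):
            continue
        for ent in anchors[gene]:
            cx, cy = ent.centre
            xs.append(cx)
            ys.append(cy)
            vs.append(float(value))
    if bandwidth is None:
        bandwidth = 0.05 * math.hypot(view.width, view.height)
    nx = max(1, int(math.ceil(view.width / grid_step)))
    ny = max(1, int(math.ceil(view.height / grid_step)))
    gx = (np.arange(nx) + 0.5) * grid_step
    gy = (np.arange(ny) + 0.5) * grid_step
    if not xs:
        report_warnings.append("no finite values matched the map; NA layer")
        value_field = np.full((ny, nx), np.nan)
        weight_field = np.zeros((ny, nx))
    else:
        px = np.asarray(xs)
        py = np.asarray(ys)
        pv = np.asarray(vs)
        dx2 = (gx[None, :, None] - px[None, None, :]) ** 2
        dy2 = (gy[:, None, None] - py[None, None, :]) ** 2
        w = np.exp(-(dx2 + dy2) / (2.0 * bandwidth**2))
        weight_field = w.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            value_field = (w * pv[None, None, :]).sum(axis=2) / weight_field
        value_field[weight_field <= 1e-300] = np.nan
    if scale is None:
        scale = ColorScale.symmetric(vs if vs else [1.0])
    return StainLayer(
        value_field=value_field,
        weight_field=weight_field,
        grid_step=grid_step,
        scale=scale,
        bandwidth=bandwidth,
        report=report,
    )


# ---------------------------------------------------------------------------
# glyphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlyphSpec:
    """Binding of data columns to glyph appearance."""

    shape: str = "triangle"  # triangle | square | circle
    size: int = 12
    colour: str = "#d00000"
    column: str | None = None  # None = flag set in any column


@dataclass(frozen=True)
class Glyph:
    entity_id: str
    gene: str
    x: float  # anchor, map pixels
    y: float
    shape: str
    size: int
    colour: str


@dataclass
class GlyphLayer:
    glyphs: list[Glyph]
    report: MatchReport

    def draw(self, img: Image.Image, scale: float = 1.0) -> None:
        draw = ImageDraw.Draw(img)
        for g in self.glyphs:
            x, y = g.x * scale, g.y * scale
            s = g.size * max(scale, 0.5)
            if g.shape == "triangle":
                draw.polygon([(x, y), (x + s, y), (x + s / 2, y - s)], fill=g.colour)
            elif g.shape == "square":
                draw.rectangle([x, y - s, x + s, y], fill=g.colour)
            else:
                draw.ellipse([x, y - s, x + s, y], fill=g.colour)


def place_glyphs(
    view: SignallingMap, data: OverlayDataset, glyph_spec: GlyphSpec = GlyphSpec()
) -> GlyphLayer:
    """One glyph per flagged gene per map location carrying its symbol.

    Anchored at the top-right corner of the entity box; multiple glyphs on
    one entity stack horizontally.  Deterministic placement (sorted by
    entity id, then gene).
    """
    anchors = _symbol_anchors(view)
    report = _match(data, anchors)
    if glyph_spec.column is not None:
        flags = data.values[glyph_spec.column].fillna(0) != 0
    else:
        flags = (data.values.fillna(0) != 0).any(axis=1)
    glyphs: list[Glyph] = []
    per_entity: dict[str, int] = {}
    placements = []
    for gene in report.matched:
        if not bool(flags.loc[gene]):
            continue
        for ent in anchors[gene]:
            placements.append((ent.id, gene, ent))
    placements.sort(key=lambda t: (t[0], t[1]))
    for eid, gene, ent in placements:
        slot = per_entity.get(eid, 0)
        per_entity[eid] = slot + 1
        x = ent.position[0] + ent.size[0] + slot * (glyph_spec.size + 2)
        y = ent.position[1]
        glyphs.append(
            Glyph(eid, gene, x, y, glyph_spec.shape, glyph_spec.size, glyph_spec.colour)
        )
    return GlyphLayer(glyphs=glyphs, report=report)


# ---------------------------------------------------------------------------
# entity charts
# ---------------------------------------------------------------------------

class ChartKind(enum.Enum):
    BARPLOT = "BARPLOT"
    HEATMAP = "HEATMAP"


@dataclass(frozen=True)
class EntityChart:
    entity_id: str
    gene: str
    x: float
    y: float
    values: tuple[float, ...]  # one per data column, NaN allowed


@dataclass
class ChartLayer:
    kind: ChartKind
    charts: list[EntityChart]
    columns: tuple[str, ...]
    vmin: float  # shared axis limits across every chart on the map
    vmax: float
    scale: ColorScale
    report: MatchReport

    def draw(self, img: Image.Image, scale: float = 1.0, bar_w: int = 6, height: int = 18) -> None:
        draw = ImageDraw.Draw(img)
        span = (self.vmax - self.vmin) or 1.0
        for chart in self.charts:
            x0 = chart.x * scale
            y0 = chart.y * scale
            for i, v in enumerate(chart.values):
                bx = x0 + i * (bar_w + 1)
                if self.kind is ChartKind.BARPLOT:
                    if not math.isfinite(v):
                        continue
                    h = (min(max(v, self.vmin), self.vmax) - self.vmin) / span * height
                    draw.rectangle([bx, y0 - h, bx + bar_w, y0], fill="#444444")
                else:
                    draw.rectangle(
                        [bx, y0 - height, bx + bar_w, y0],
                        fill=self.scale.colour(v if math.isfinite(v) else float("nan")),
                    )


def entity_charts(
    view: SignallingMap, data: OverlayDataset, kind: ChartKind = ChartKind.BARPLOT
) -> ChartLayer:
    """A miniature chart per matching entity, one bar/cell per column, with
    axis limits shared across the whole map for comparability."""
    if data.values.shape[1] < 1:
        raise ValueError("entity charts need at least one data column")
    anchors = _symbol_anchors(view)
    report = _match(data, anchors)
    arr = data.values.loc[report.matched].to_numpy(dtype=float) if report.matched else np.empty((0, 0))
    finite = arr[np.isfinite(arr)] if arr.size else np.array([])
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    if vmin == vmax:
        vmin, vmax = vmin - 0.5, vmax + 0.5
    charts = []
    for gene in report.matched:
        row = tuple(float(v) for v in data.values.loc[gene])
        for ent in anchors[gene]:
            charts.append(
                EntityChart(ent.id, gene, ent.position[0], ent.position[1], row)
            )
    charts.sort(key=lambda c: (c.entity_id, c.gene))
    return ChartLayer(
        kind=kind,
        charts=charts,
        columns=tuple(str(c) for c in data.values.columns),
        vmin=vmin,
        vmax=vmax,
        scale=ColorScale(vmin, vmax, (vmin + vmax) / 2),
        report=report,
    )


# ---------------------------------------------------------------------------
# composite rendering
# ---------------------------------------------------------------------------

def render_overlay(
    view: SignallingMap,
    stain: StainLayer | None = None,
    glyphs: GlyphLayer | None = None,
    charts: ChartLayer | None = None,
    scale: float = 1.0,
) -> Image.Image:
    """Composite base map + staining underlay + glyph/chart overlays."""
    background = stain.to_image() if stain is not None else None
    img = draw_view(view, scale=scale, background_image=background)
    if glyphs is not None:
        glyphs.draw(img, scale=scale)
    if charts is not None:
        charts.draw(img, scale=scale)
    return img
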