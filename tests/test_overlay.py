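import numpy as np
import pandas as pd
import pytest

from sigmap.overlay import (
    AggregateBy,
    AggregateStat,
    ChartKind,
    ColorScale,
    GlyphSpec,
    OverlayDataset,
    aggregate,
    entity_charts,
    map_staining,
    place_glyphs,
    render_overlay,
)
from sigmap.model import SignallingMap

from .conftest import protein


def dataset(values: dict, groups=None, families=None):
    frame = pd.DataFrame(values).T  # rows = genes
    return OverlayDataset(values=frame, groups=groups or {}, families=families or {})


class TestAggregate:
    def test_group_mean(self):
        data = dataset({"G": {"s1": 2.0, "s2": 4.0}}, groups={"s1": "A", "s2": "A"})
        out = aggregate(data, AggregateBy.GROUP, AggregateStat.MEAN)
        assert out.values.loc["G", "A"] == pytest.approx(3.0)

    def test_singleton_groups_are_identity(self):
        data = dataset(
            {"G": {"s1": 1.5, "s2": -2.0}}, groups={"s1": "s1", "s2": "s2"}
        )
        out = aggregate(data, AggregateBy.GROUP, AggregateStat.MEAN)
        assert out.values.loc["G", "s1"] == pytest.approx(1.5)
        assert out.values.loc["G", "s2"] == pytest.approx(-2.0)

    def test_family_median_skips_absent_genes(self):
        data = dataset(
            {"G1": {"s": 1.0}, "G2": {"s": 3.0}},
            families={"fam": {"G1", "G2", "G_ABSENT"}},
        )
        out = aggregate(data, AggregateBy.FAMILY, AggregateStat.MEDIAN)
        assert out.values.loc["FAM", "s"] == pytest.approx(2.0)

    def test_na_skipping_mean(self):
        data = dataset({"G": {"s1": 2.0, "s2": np.nan}}, groups={"s1": "A", "s2": "A"})
        out = aggregate(data, AggregateBy.GROUP, AggregateStat.MEAN)
        assert out.values.loc["G", "A"] == pytest.approx(2.0)

    def test_empty_group_yields_na(self):
        data = dataset({"G": {"s1": np.nan}}, groups={"s1": "A"})
        out = aggregate(data, AggregateBy.GROUP, AggregateStat.MEAN)
        assert np.isnan(out.values.loc["G", "A"])

    def test_group_and_family(self):
        data = dataset(
            {"G1": {"s1": 1.0, "s2": 3.0}, "G2": {"s1": 5.0, "s2": 7.0}},
            groups={"s1": "A", "s2": "A"},
            families={"fam": {"G1", "G2"}},
        )
        out = aggregate(data, AggregateBy.GROUP_AND_FAMILY, AggregateStat.MEAN)
        assert out.values.loc["FAM", "A"] == pytest.approx(4.0)

    def test_duplicate_gene_rows_rejected(self):
        frame = pd.DataFrame([[1.0], [2.0]], index=["G", "g"], columns=["s"])
        with pytest.raises(ValueError, match="duplicate"):
            OverlayDataset(values=frame)


def grid_map(genes, cols=4, spacing=150.0):
    smap = SignallingMap(name="grid", width=cols * spacing + 100, height=((len(genes) - 1) // cols + 1) * spacing + 100)
    for i, gene in enumerate(genes):
        smap.add_entity(
            protein(f"e_{gene.lower()}", hugo=gene, x=40 + (i % cols) * spacing, y=40 + (i // cols) * spacing)
        )
    smap.validate()
    return smap


class TestMapStaining:
    def test_uniform_value_constant_colour_field(self):
        genes = [f"G{i}" for i in range(8)]
        smap = grid_map(genes)
        data = dataset({g: {"v": 1.7} for g in genes})
        layer = map_staining(smap, data)
        finite = layer.value_field[np.isfinite(layer.value_field)]
        assert finite.size == layer.value_field.size
        assert np.allclose(finite, 1.7)

    def test_single_entity_intensity_decays_with_distance(self):
        smap = grid_map(["G0"])
        smap.width = smap.height = 600.0
        data = dataset({"G0": {"v": 2.0}})
        layer = map_staining(smap, data)
        cx, cy = smap.entities["e_g0"].centre
        gx = int(cx // layer.grid_step)
        gy = int(cy // layer.grid_step)
        w_at = [layer.weight_field[gy, min(gx + d, layer.weight_field.shape[1] - 1)] for d in (0, 5, 10, 20)]
        assert all(a > b for a, b in zip(w_at, w_at[1:]))

    def test_two_regions_opposite_signs(self):
        left = [f"L{i}" for i in range(4)]
        right = [f"R{i}" for i in range(4)]
        smap = SignallingMap(name="lr", width=1200, height=400)
        for i, g in enumerate(left):
            smap.add_entity(protein(f"e_{g}", hugo=g, x=40, y=40 + i * 80))
        for i, g in enumerate(right):
            smap.add_entity(protein(f"e_{g}", hugo=g, x=1000, y=40 + i * 80))
        data = dataset({**{g: {"v": +2.0} for g in left}, **{g: {"v": -2.0} for g in right}})
        layer = map_staining(smap, data, bandwidth=100.0)
        nx_ = layer.value_field.shape[1]
        left_mean = np.nanmean(layer.value_field[:, : nx_ // 4])
        right_mean = np.nanmean(layer.value_field[:, 3 * nx_ // 4 :])
        assert left_mean > 0 > right_mean

    def test_invariant_under_entity_enumeration_order(self):
        genes = [f"G{i}" for i in range(6)]
        smap = grid_map(genes)
        shuffled = SignallingMap(name="s", width=smap.width, height=smap.height)
        for eid in reversed(sorted(smap.entities)):
            shuffled.entities[eid] = smap.entities[eid]
        data = dataset({g: {"v": float(i)} for i, g in enumerate(genes)})
        a = map_staining(smap, data)
        b = map_staining(shuffled, data)
        np.testing.assert_allclose(a.value_field, b.value_field)

    def test_all_na_gives_na_layer_with_warning(self):
        smap = grid_map(["G0"])
        data = dataset({"G0": {"v": np.nan}})
        layer = map_staining(smap, data)
        assert np.all(~np.isfinite(layer.value_field))
        assert layer.report.warnings

    def test_reconciliation_report(self):
        smap = grid_map(["G0", "G1"])
        data = dataset({"G0": {"v": 1.0}, "NOT_ON_MAP": {"v": 2.0}})
        layer = map_staining(smap, data)
        rep = layer.report
        assert rep.n_genes == 2
        assert rep.n_matched + rep.n_ignored == rep.n_genes
        assert rep.ignored == ["NOT_ON_MAP"]

    def test_requires_single_column(self):
        smap = grid_map(["G0"])
        data = dataset({"G0": {"s1": 1.0, "s2": 2.0}})
        with pytest.raises(ValueError, match="one value column"):
            map_staining(smap, data)


class TestGlyphs:
    def test_single_mutated_gene_one_triangle(self):
        smap = grid_map(["G0", "G1"])
        data = dataset({"G0": {"s": 1}, "G1": {"s": 0}})
        layer = place_glyphs(smap, data)
        assert len(layer.glyphs) == 1
        assert layer.glyphs[0].shape == "triangle"
        assert layer.glyphs[0].gene == "G0"

    def test_empty_mutation_list_no_glyphs(self):
        smap = grid_map(["G0"])
        data = dataset({"G0": {"s": 0}})
        assert place_glyphs(smap, data).glyphs == []

    def test_gene_at_three_locations_three_glyphs(self):
        smap = SignallingMap(name="multi", width=800, height=300)
        for i in range(3):
            smap.add_entity(protein(f"e{i}", hugo="G0", x=50 + i * 200, y=40))
        data = dataset({"G0": {"s": 1}})
        layer = place_glyphs(smap, data)
        assert len(layer.glyphs) == 3

    def test_stacking_is_horizontal_and_deterministic(self):
        smap = grid_map(["G0"])
        data = dataset({"G0": {"s": 1}})
        # same entity carries two flagged genes via a complex? use two datasets instead:
        layer1 = place_glyphs(smap, data)
        layer2 = place_glyphs(smap, data)
        assert layer1.glyphs == layer2.glyphs


class TestEntityCharts:
    def test_two_columns_two_bars(self):
        smap = grid_map(["G0", "G1"])
        data = dataset({"G0": {"A": 1.0, "B": 2.0}, "G1": {"A": 0.5, "B": 1.5}})
        layer = entity_charts(smap, data, ChartKind.BARPLOT)
        assert all(len(c.values) == 2 for c in layer.charts)
        assert layer.columns == ("A", "B")

    def test_shared_axis_limits_across_charts(self):
        smap = grid_map(["G0", "G1"])
        data = dataset({"G0": {"A": -3.0, "B": 2.0}, "G1": {"A": 0.5, "B": 7.0}})
        layer = entity_charts(smap, data, ChartKind.HEATMAP)
        assert layer.vmin == -3.0 and layer.vmax == 7.0

    def test_all_equal_values_padded_axis(self):
        smap = grid_map(["G0"])
        data = dataset({"G0": {"A": 1.0, "B": 1.0}})
        layer = entity_charts(smap, data)
        assert layer.vmin < 1.0 < layer.vmax


class TestColorScale:
    def test_domain_validation(self):
        with pytest.raises(ValueError):
            ColorScale(vmin=1.0, vmax=1.0)

    def test_endpoints_and_na(self):
        scale = ColorScale(vmin=-1, vmax=1)
        assert scale.colour(-1) == scale.low
        assert scale.colour(1) == scale.high
        assert scale.colour(float("nan")) == scale.na_colour

    def test_clamping(self):
        scale = ColorScale(vmin=-1, vmax=1)
        assert scale.colour(-99) == scale.low
        assert scale.colour(99) == scale.high


def test_render_overlay_composites(tmp_path):
    smap = grid_map(["G0", "G1", "G2"])
    data = dataset({g: {"v": i - 1.0} for i, g in enumerate(["G0", "G1", "G2"])})
    stain = map_staining(smap, data)
    glyphs = place_glyphs(smap, dataset({"G0": {"v": 1}}))
    img = render_overlay(smap, stain=stain, glyphs=glyphs)
    assert img.size == (int(smap.width), int(smap.height))
    path = tmp_path / "o.png"
    img.save(path)
    assert path.stat().st_size > 0
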