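# sigmap

Toolkit for building and exploiting comprehensive process-description
signalling maps: a typed map model with CellDesigner-flavoured SBML I/O,
structured four-section entity annotations, two interaction-confidence
scores (REF from weighted literature counts, FUNC from shortest-path
proximity in an external protein–protein interaction network),
hierarchical layer/module decomposition with GMT export, semantic-zoom
view generation rendered as a Google-Maps-style raster tile pyramid, and
omics-data overlay (map staining, glyphs, barplots/heatmaps with
group/family aggregation).

All inputs can be generated synthetically by the built-in fixture module,
so the whole pipeline runs offline with known ground truth.

## CLI

One entry point, `sigmap`, with six subcommands:

```bash
# deterministic synthetic inputs (map + PPI + omics) with ground truth
sigmap fixture --seed 1 --out work/fx

# CellDesigner XML -> canonical XML + SIF + GMT + per-entity HTML posts
sigmap convert --map work/fx/map.xml --out work/conv

# REF / FUNC confidence scores against a PPI edge list
sigmap score --map work/fx/map.xml --ppi work/fx/ppi.sif \
             --out work/scored.xml --report work/scores.tsv

# module decomposition (GMT) and optional module-map extraction
sigmap modules --map work/fx/map.xml --out work/mods --extract HR

# semantic-zoom tile pyramid (tiles/, index.json, map.html)
sigmap zoom --map work/fx/map.xml --out work/zoom

# omics overlay: staining | glyph | barplot | heatmap
sigmap overlay --map work/fx/map.xml --data work/fx/expr.tsv \
               --groups work/fx/groups.tsv --mode staining --out work/ov
```

Each subcommand writes a `run_summary.json` with counts and any skipped
or unmatched items; logs go to stderr.

## Scoring rules

* **REF** = min(5, #originals + 3·#reviews); 0 (undefined) with no
  references. Two reviews therefore give the maximum REF = 5.
* **FUNC**: all protein participants of a reaction (complexes flattened to
  their members) are located in the PPI network; the score is
  `clamp(6 − round(mean pairwise shortest-path distance), 1, 5)`.
  Distance 1 → 5, 2 → 4, 3 → 3, 4 → 2; any disconnected or absent
  participant → 0 (undefined).

## Package layout

| module | purpose |
| --- | --- |
| `sigmap.model` | typed map model (entities, reactions, compartments), neighbourhoods |
| `sigmap.annotation` | four-section annotation dialect, HTML post rendering |
| `sigmap.celldesigner` | CellDesigner-dialect SBML reader/writer, SIF + GMT export |
| `sigmap.scoring` | REF / FUNC confidence scores, PPI network loading |
| `sigmap.hierarchy` | layer/module decomposition, module-map extraction, re-layout, map merging |
| `sigmap.zoom` | per-level pruned views, 256-px tile pyramid, static HTML shell |
| `sigmap.overlay` | omics import, aggregation, map staining, glyphs, entity charts |
| `sigmap.fixtures` | deterministic synthetic maps / PPI graphs / omics tables with truth records |
| `sigmap.cli` | click-based command line |

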