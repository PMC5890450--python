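"""Deterministic synthetic inputs with known ground truth.

Generates toy process-description maps (written as CellDesigner-dialect
XML), PPI edge lists with planted pairwise distances, and omics matrices
with planted group effects — everything the other modules need for
end-to-end testing without any download.  All outputs are reproducible
byte-for-byte from (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .annotation import Annotation, Reference, ReferenceKind
from .celldesigner import write_celldesigner
from .model import (
    EntityClass,
    MapEntity,
    Reaction,
    ReactionClass,
    RegulationClass,
    SignallingMap,
    entity_degree,
)

#: layer -> module names of the toy analogue of a 10+4+4 decomposition
#: (ten repair mechanisms, four cell-cycle phases, four checkpoints)
DNA_REPAIR_LAYERS: dict[str, list[str]] = {
    "repair_machinery": ["BER", "NER", "MMR", "HR", "NHEJ", "ALT_NHEJ", "FA", "TLS", "DR", "SSBR"],
    "checkpoints": ["G1_S_CHECKPOINT", "INTRA_S_CHECKPOINT", "G2_M_CHECKPOINT", "SPINDLE_CHECKPOINT"],
    "cell_cycle": ["G1", "S_PHASE", "G2", "M_PHASE"],
}


def dna_repair_module_names() -> list[str]:
    return [m for names in DNA_REPAIR_LAYERS.values() for m in names]


def dna_repair_layer_of() -> dict[str, str]:
    return {m: layer for layer, names in DNA_REPAIR_LAYERS.items() for m in names}


@dataclass
class FixtureSpec:
    """Knobs for the synthetic generators; every count must be >= 0."""

    seed: int = 0
    name: str = "toy"
    # map
    module_names: list[str] | None = None
    n_modules: int = 3
    entities_per_module: int = 4
    complex_fraction: float = 0.0
    n_hubs: int = 0
    hub_degree: int = 5
    layer_of: dict[str, str] = field(default_factory=dict)
    # ppi
    ppi_model: str = "path"  # path | ring | complete | er
    ppi_nodes: list[str] | None = None
    n_ppi_nodes: int = 6
    ppi_p: float = 0.3
    plant_disconnected_pair: bool = False
    # omics
    n_samples_per_group: int = 10
    effect_size: float = 0.0
    na_fraction: float = 0.0
    shift_genes: list[str] = field(default_factory=list)
    mutated_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for attr in ("n_modules", "entities_per_module", "n_hubs", "hub_degree",
                     "n_ppi_nodes", "n_samples_per_group"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        for attr in ("complex_fraction", "ppi_p", "na_fraction"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1]")


# ---------------------------------------------------------------------------
# map fixture
# ---------------------------------------------------------------------------

_MODULE_W = 320.0
_MODULE_H = 300.0
_ENTITY_W = 90.0
_ENTITY_H = 40.0


def build_map(spec: FixtureSpec) -> tuple[SignallingMap, dict]:
    """Assemble the toy map in memory; returns (map, truth record)."""
    modules = spec.module_names or [f"M{i + 1}" for i in range(spec.n_modules)]
    n_per = spec.entities_per_module
    cols = max(1, math.ceil(math.sqrt(len(modules)))) if modules else 1
    rows = math.ceil(len(modules) / cols) if modules else 0
    hub_band = 100.0 if spec.n_hubs else 0.0
    smap = SignallingMap(
        name=spec.name,
        width=max(400.0, cols * _MODULE_W + 40.0),
        height=max(400.0, rows * _MODULE_H + 60.0 + hub_band),
    )
    canonical_ids: list[str] = []
    complex_ids: list[str] = []
    module_entities: dict[str, list[str]] = {}

    for mi, module in enumerate(modules):
        mx = 20.0 + (mi % cols) * _MODULE_W
        my = 20.0 + hub_band + (mi // cols) * _MODULE_H
        ids = []
        for j in range(n_per):
            eid = f"{module.lower()}_p{j}"
            ent = MapEntity(
                id=eid,
                name=f"{module}_P{j}",
                entity_class=EntityClass.PROTEIN,
                hugo_symbol=f"{module}{j}".upper(),
                position=(mx + (j % 2) * (_ENTITY_W + 40.0), my + (j // 2) * (_ENTITY_H + 30.0)),
                size=(_ENTITY_W, _ENTITY_H),
                annotation=Annotation(module_tags=[(spec.name, module)]),
            )
            smap.add_entity(ent)
            ids.append(eid)
        module_entities[module] = ids
        if ids:
            smap.entities[ids[0]].annotation.tags.append("canonical")
            canonical_ids.append(ids[0])
        # chain of state transitions with a catalyst two steps ahead
        for j in range(n_per - 1):
            catalyst = ids[(j + 2) % n_per]
            regulators = []
            if catalyst not in (ids[j], ids[j + 1]):
                regulators = [(catalyst, RegulationClass.CATALYSIS)]
            smap.add_reaction(
                Reaction(
                    id=f"r_{module.lower()}_{j}",
                    reaction_class=ReactionClass.STATE_TRANSITION,
                    reactants=[ids[j]],
                    products=[ids[j + 1]],
                    regulators=regulators,
                    annotation=Annotation(
                        references=[Reference(f"{1000 + mi * 100 + j}", ReferenceKind.ORIGINAL)]
                    ),
                )
            )
        if spec.complex_fraction > 0 and n_per >= 2:
            cid = f"{module.lower()}_cplx"
            members = sorted(ids[:2])
            smap.add_entity(
                MapEntity(
                    id=cid,
                    name=f"{module}_COMPLEX",
                    entity_class=EntityClass.COMPLEX,
                    position=(mx, my + 2 * (_ENTITY_H + 30.0) + 10.0),
                    size=(_ENTITY_W + 30.0, _ENTITY_H + 10.0),
                    members=members,
                    annotation=Annotation(module_tags=[(spec.name, module)]),
                )
            )
            complex_ids.append(cid)
            smap.add_reaction(
                Reaction(
                    id=f"r_{module.lower()}_assoc",
                    reaction_class=ReactionClass.ASSOCIATION,
                    reactants=list(members),
                    products=[cid],
                )
            )

    # cross-module links so modules are interconnected
    for mi in range(len(modules) - 1):
        a = module_entities[modules[mi]]
        b = module_entities[modules[mi + 1]]
        if a and b:
            smap.add_reaction(
                Reaction(
                    id=f"r_cross_{mi}",
                    reaction_class=ReactionClass.STATE_TRANSITION,
                    reactants=[a[-1]],
                    products=[b[0]],
                )
            )

    # planted hubs: high participation degree, canonical + backbone tagged
    hub_ids = []
    for hi in range(spec.n_hubs):
        hid = f"hub{hi}"
        # hubs are filed under the module they feed first, so a fully
        # tagged map stays fully tagged
        hub_tags = [(spec.name, modules[hi % len(modules)])] if modules else []
        smap.add_entity(
            MapEntity(
                id=hid,
                name=f"HUB{hi}",
                entity_class=EntityClass.PROTEIN,
                hugo_symbol=f"HUB{hi}",
                position=(20.0 + hi * (_ENTITY_W + 50.0), 20.0),
                size=(_ENTITY_W, _ENTITY_H),
                annotation=Annotation(module_tags=hub_tags, tags=["canonical", "backbone"]),
            )
        )
        hub_ids.append(hid)
        for k in range(spec.hub_degree):
            target_module = modules[(hi + k) % len(modules)] if modules else None
            targets = module_entities.get(target_module, [])
            if not targets:
                continue
            smap.add_reaction(
                Reaction(
                    id=f"r_hub{hi}_{k}",
                    reaction_class=ReactionClass.STATE_TRANSITION,
                    reactants=[hid],
                    products=[targets[k % len(targets)]],
                )
            )

    smap.validate()
    degree = entity_degree(smap)
    truth = {
        "name": spec.name,
        "entity_count": len(smap.entities),
        "reaction_count": len(smap.reactions),
        "module_names": list(modules),
        "n_modules": len(modules),
        "layer_of": dict(spec.layer_of),
        "module_entities": module_entities,
        "complex_ids": complex_ids,
        "hub_ids": hub_ids,
        "canonical_ids": sorted(set(canonical_ids + hub_ids)),
        "degree": degree,
        "hugo_symbols": sorted(
            {e.hugo_symbol for e in smap.entities.values() if e.hugo_symbol}
        ),
    }
    return smap, truth


def make_map(spec: FixtureSpec, path: str | Path) -> tuple[Path, dict]:
    """Write the toy map as CellDesigner-dialect XML; returns (path, truth)."""
    smap, truth = build_map(spec)
    path = Path(path)
    write_celldesigner(smap, path)
    truth_path = path.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path, truth


def dna_repair_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """Spec for the 18-module toy analogue (10 repair + 4 phases + 4 checkpoints)."""
    kwargs = dict(
        seed=seed,
        name="dna_repair_toy",
        module_names=dna_repair_module_names(),
        layer_of=dna_repair_layer_of(),
        entities_per_module=4,
        complex_fraction=0.5,
        n_hubs=3,
        hub_degree=5,
    )
    kwargs.update(overrides)
    return FixtureSpec(**kwargs)


# ---------------------------------------------------------------------------
# PPI fixture
# ---------------------------------------------------------------------------

def build_ppi(spec: FixtureSpec) -> tuple[nx.Graph, dict]:
    nodes = spec.ppi_nodes or [f"N{i}" for i in range(spec.n_ppi_nodes)]
    nodes = [n.upper() for n in nodes]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if spec.ppi_model == "path":
        g.add_edges_from(zip(nodes, nodes[1:]))
    elif spec.ppi_model == "ring":
        g.add_edges_from(zip(nodes, nodes[1:]))
        if len(nodes) > 2:
            g.add_edge(nodes[-1], nodes[0])
    elif spec.ppi_model == "complete":
        g.add_edges_from(
            (a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]
        )
    elif spec.ppi_model == "er":
        rng = np.random.default_rng(spec.seed)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                if rng.random() < spec.ppi_p:
                    g.add_edge(a, b)
    else:
        raise ValueError(f"unknown ppi model {spec.ppi_model!r}")

    disconnected_pairs = []
    if spec.plant_disconnected_pair:
        g.add_edge("ISOLATE_A", "ISOLATE_B")  # its own component
        if nodes:
            disconnected_pairs = [(nodes[0], "ISOLATE_A"), (nodes[0], "ISOLATE_B")]

    distances: dict[str, int] = {}
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if src < dst:
                distances[f"{src}|{dst}"] = d
    truth = {
        "model": spec.ppi_model,
        "nodes": sorted(g.nodes),
        "n_edges": g.number_of_edges(),
        "distances": distances,
        "disconnected_pairs": disconnected_pairs,
    }
    return g, truth


def make_ppi(spec: FixtureSpec, path: str | Path) -> tuple[Path, dict]:
    """Write the PPI edge list as a 2-column SIF; returns (path, truth)."""
    g, truth = build_ppi(spec)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")
    path.with_suffix(".truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path, truth


# ---------------------------------------------------------------------------
# omics fixture
# ---------------------------------------------------------------------------

def build_omics(spec: FixtureSpec, genes: list[str]) -> tuple["pd.DataFrame", dict[str, str], "pd.DataFrame", dict]:
    """Gaussian gene x sample matrix with a planted group-B mean shift."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    genes = [g.upper() for g in genes]
    samples_a = [f"A_{i + 1}" for i in range(spec.n_samples_per_group)]
    samples_b = [f"B_{i + 1}" for i in range(spec.n_samples_per_group)]
    samples = samples_a + samples_b
    values = rng.standard_normal((len(genes), len(samples)))
    shift_set = {g.upper() for g in spec.shift_genes}
    for gi, gene in enumerate(genes):
        if gene in shift_set:
            values[gi, len(samples_a):] += spec.effect_size
    if spec.na_fraction > 0:
        mask = rng.random(values.shape) < spec.na_fraction
        values[mask] = np.nan
    frame = pd.DataFrame(values, index=genes, columns=samples)
    groups = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    mut_set = {g.upper() for g in spec.mutated_genes}
    mutations = pd.DataFrame(
        [[1 if gene in mut_set else 0 for _ in samples] for gene in genes],
        index=genes,
        columns=samples,
    )
    truth = {
        "shift_genes": sorted(shift_set & set(genes)),
        "effect_size": spec.effect_size,
        "n_samples_per_group": spec.n_samples_per_group,
        "na_fraction": spec.na_fraction,
        "mutated_genes": sorted(mut_set & set(genes)),
    }
    return frame, groups, mutations, truth


def make_omics(spec: FixtureSpec, genes: list[str], out_dir: str | Path) -> tuple[dict[str, Path], dict]:
    """Write expr.tsv / groups.tsv / mutations.tsv; returns (paths, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame, groups, mutations, truth = build_omics(spec, genes)
    paths = {
        "expression": out_dir / "expr.tsv",
        "groups": out_dir / "groups.tsv",
        "mutations": out_dir / "mutations.tsv",
        "truth": out_dir / "omics.truth.json",
    }
    frame.to_csv(paths["expression"], sep="\t", float_format="%.6f", index_label="gene")
    with open(paths["groups"], "w", encoding="utf-8") as fh:
        for sample in frame.columns:
            fh.write(f"{sample}\t{groups[sample]}\n")
    mutations.to_csv(paths["mutations"], sep="\t", index_label="gene")
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return paths, truth


def spec_from_json(path: str | Path) -> FixtureSpec:
    return FixtureSpec(**json.loads(Path(path).read_text(encoding="utf-8")))


def spec_to_json(spec: FixtureSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(spec), indent=2, sort_keys=True) + "\n", encoding="utf-8")
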