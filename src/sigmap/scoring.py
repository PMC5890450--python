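"""Reference (REF) and functional-proximity (FUNC) confidence scores.

Both scores are integers from 0 (undefined confidence) to 5 (high
confidence) attached to reactions and protein complexes.

REF weighs the literature behind an interaction: one point per original
publication, three per review article, capped at five.

FUNC measures how close the participants sit in an external
protein–protein interaction (PPI) network: participants that all
interact directly (average shortest-path distance 1) score 5, a pair
separated by 2 / 3 / 4 edges scores 4 / 3 / 2, and participants in
different components — or missing from the network — score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .annotation import Confidence, Reference, ReferenceKind
from .model import EntityClass, MapEntity, Reaction, SignallingMap, participant_proteins

#: sentinel distances returned by :func:`ppi_distance`
DISCONNECTED = "DISCONNECTED"
ABSENT = "ABSENT"

ORIGINAL_WEIGHT = 1
REVIEW_WEIGHT = 3
MAX_SCORE = 5


@dataclass
class PPINetwork:
    """Undirected simple graph over upper-case HUGO symbols."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: str = ""

    @classmethod
    def from_edges(cls, edges, provenance: str = "in-memory") -> "PPINetwork":
        g = nx.Graph()
        for a, b in edges:
            a = str(a).strip().upper()
            b = str(b).strip().upper()
            if a and b and a != b:
                g.add_edge(a, b)
        return cls(graph=g, provenance=provenance)

    @classmethod
    def from_sif(cls, path: str | Path) -> "PPINetwork":
        """Load a 2- or 3-column edge list (``A B`` or ``A relation B``)."""
        edges = []
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) == 2:
                edges.append((cols[0], cols[1]))
            elif len(cols) >= 3:
                edges.append((cols[0], cols[2]))
        return cls.from_edges(edges, provenance=str(path))

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ConfidenceResult:
    """Scores plus the evidence they were derived from."""

    ref_score: int
    func_score: int
    ref_breakdown: tuple[int, int, int]  # (n_original, n_review, raw_weight)
    func_breakdown: dict[tuple[str, str], object] = field(default_factory=dict)
    func_mean: object = "undefined"  # float, "disconnected" or "undefined"

    def to_confidence(self) -> Confidence:
        return Confidence(self.ref_score, self.func_score)


def ref_score(references: list[Reference]) -> int:
    """Capped weighted publication count; empty list scores 0 (undefined)."""
    if not references:
        return 0
    raw = sum(
        REVIEW_WEIGHT if r.kind is ReferenceKind.REVIEW else ORIGINAL_WEIGHT
        for r in references
    )
    return min(MAX_SCORE, raw)


def ref_result(references: list[Reference]) -> tuple[int, tuple[int, int, int]]:
    n_review = sum(1 for r in references if r.kind is ReferenceKind.REVIEW)
    n_original = len(references) - n_review
    raw = n_original * ORIGINAL_WEIGHT + n_review * REVIEW_WEIGHT
    return ref_score(references), (n_original, n_review, raw)


def ppi_distance(a: str, b: str, ppi: PPINetwork):
    """Unweighted shortest-path length between two symbols.

    Returns an integer >= 0 (0 iff a == b), or the sentinels ABSENT /
    DISCONNECTED.
    """
    a, b = a.strip().upper(), b.strip().upper()
    if a not in ppi.graph or b not in ppi.graph:
        return ABSENT
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(ppi.graph, a, b)
    except nx.NetworkXNoPath:
        return DISCONNECTED


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def func_score_from_symbols(symbols: set[str], ppi: PPINetwork) -> ConfidenceResult:
    """FUNC for an explicit protein set; REF fields are left at zero."""
    pairs: dict[tuple[str, str], object] = {}
    result = ConfidenceResult(0, 0, (0, 0, 0), pairs)
    ordered = sorted(symbols)
    if len(ordered) < 2:
        return result
    distances: list[int] = []
    status = "ok"
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            d = ppi_distance(a, b, ppi)
            pairs[(a, b)] = d
            if d == ABSENT:
                status = "undefined"
            elif d == DISCONNECTED and status != "undefined":
                status = "disconnected"
            elif isinstance(d, int):
                distances.append(d)
    if status != "ok":
        result.func_mean = status
        return result
    mean = sum(distances) / len(distances)
    result.func_mean = mean
    result.func_score = max(1, min(MAX_SCORE, 6 - _round_half_up(mean)))
    return result


def func_score(reaction: Reaction, smap: SignallingMap, ppi: PPINetwork) -> int:
    """FUNC for a reaction: pairwise proximity of its protein participants."""
    return func_score_from_symbols(participant_proteins(reaction, smap), ppi).func_score


def complex_proteins(entity: MapEntity, smap: SignallingMap) -> set[str]:
    return {
        leaf.hugo_symbol
        for leaf in smap.flatten_complex(entity.id)
        if leaf.entity_class is EntityClass.PROTEIN and leaf.hugo_symbol
    }


def score_reaction(reaction: Reaction, smap: SignallingMap, ppi: PPINetwork) -> ConfidenceResult:
    result = func_score_from_symbols(participant_proteins(reaction, smap), ppi)
    result.ref_score, result.ref_breakdown = ref_result(reaction.annotation.references)
    return result


def score_complex(entity: MapEntity, smap: SignallingMap, ppi: PPINetwork) -> ConfidenceResult:
    result = func_score_from_symbols(complex_proteins(entity, smap), ppi)
    result.ref_score, result.ref_breakdown = ref_result(entity.annotation.references)
    return result


def score_map(smap: SignallingMap, ppi: PPINetwork) -> dict[str, ConfidenceResult]:
    """Score every reaction and every complex; write scores into annotations.

    Returns the full results keyed by reaction/entity id.  Idempotent: a
    second run recomputes the same scores from the same evidence.
    """
    results: dict[str, ConfidenceResult] = {}
    for rxn in smap.reactions.values():
        res = score_reaction(rxn, smap, ppi)
        rxn.annotation.confidence = res.to_confidence()
        results[rxn.id] = res
    for ent in smap.entities.values():
        if ent.entity_class is EntityClass.COMPLEX:
            res = score_complex(ent, smap, ppi)
            ent.annotation.confidence = res.to_confidence()
            results[ent.id] = res
    return results


def write_score_report(
    results: dict[str, ConfidenceResult], path: str | Path
) -> int:
    """TSV report: id, REF, FUNC, n_original, n_review, raw_weight, mean distance."""
    rows = []
    for item_id in sorted(results):
        res = results[item_id]
        n_orig, n_rev, raw = res.ref_breakdown
        mean = res.func_mean
        mean_str = f"{mean:.4g}" if isinstance(mean, float) else str(mean)
        rows.append(
            "\t".join(
                [item_id, str(res.ref_score), str(res.func_score), str(n_orig), str(n_rev), str(raw), mean_str]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tREF\tFUNC\tn_original\tn_review\traw_weight\tmean_distance\n")
        for row in rows:
            fh.write(row + "\n")
    return len(rows)
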