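"""Gene-set intersection and degree-centrality hub ranking.

Upstream steps that depend on external services (co-expression module
discovery, target prediction, interaction-database retrieval, enrichment,
docking) are consumed through their *outputs*: plain gene lists and a
STRING-style TSV edge list. Symbol normalization is uppercase-trim only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import networkx as nx

logger = logging.getLogger(__name__)


class EdgeListError(ValueError):
    pass


def _norm_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    label: str
    symbols: frozenset

    @classmethod
    def from_symbols(cls, label: str, symbols: Sequence[str]) -> "GeneSet":
        return cls(label, frozenset(_norm_symbol(s) for s in symbols if s.strip()))

    @classmethod
    def from_file(cls, path: Path, label: Optional[str] = None) -> "GeneSet":
        """One symbol per line; blank lines and '#' comments ignored."""
        path = Path(path)
        lines = [
            line for line in path.read_text().splitlines()
            if line.strip() and not line.lstrip().startswith("#")
        ]
        return cls.from_symbols(label or path.stem, lines)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class InteractionGraph:
    """Undirected interaction network; no self-loops, duplicate edges collapsed."""

    graph: nx.Graph
    score_rescaled: bool = False  # True when a 0-1000 scale was divided by 1000

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def intersect_sets(drug_targets: GeneSet, disease_genes: GeneSet) -> GeneSet:
    """Exact set intersection after symbol normalization."""
    return GeneSet(
        label=f"{drug_targets.label} & {disease_genes.label}",
        symbols=drug_targets.symbols & disease_genes.symbols,
    )


def load_edges(path: Path, score_floor: float = 0.0) -> InteractionGraph:
    """Parse a STRING-style TSV (symbol, symbol[, combined_score]).

    A header row is skipped if its score column is not numeric. Scores on the
    0-1000 integer scale are auto-detected (any score > 1) and divided by
    1000 before the floor is applied; rows without a score count as 1.0.
    Malformed rows raise with their line number.
    """
    path = Path(path)
    rows: List[Tuple[str, str, Optional[float]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise EdgeListError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
        score: Optional[float] = None
        if len(parts) >= 3 and parts[2].strip():
            try:
                score = float(parts[2])
            except ValueError:
                if lineno == 1 or (not rows):
                    continue  # header row
                raise EdgeListError(
                    f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                ) from None
        rows.append((_norm_symbol(parts[0]), _norm_symbol(parts[1]), score))

    scores = [s for _, _, s in rows if s is not None]
    rescale = bool(scores) and max(scores) > 1.0
    if rescale:
        logger.info("edge scores look 0-1000 scaled; dividing by 1000")

    graph = nx.Graph()
    for u, v, score in rows:
        if u == v:
            continue
        value = 1.0 if score is None else (score / 1000.0 if rescale else score)
        if value < score_floor:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], value)
        else:
            graph.add_edge(u, v, score=value)
    return InteractionGraph(graph=graph, score_rescaled=rescale)


def degree_hubs(g: InteractionGraph, k: int) -> List[Tuple[str, int]]:
    """Top-k genes by degree centrality (edge count), ties lexicographic.

    Asking for more hubs than there are nodes returns them all with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    degrees = sorted(g.graph.degree(), key=lambda item: (-item[1], item[0]))
    if k > len(degrees):
        logger.warning("requested %d hubs but the graph has %d nodes", k, len(degrees))
        return degrees
    return degrees[:k]
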