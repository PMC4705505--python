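"""Readers, writers and canonical containers for PPI-network tool data.

File formats handled here are deliberately plain:

* edge lists — ``protA<TAB>protB[<TAB>weight]``, ``#`` comments, UTF-8;
  isolated nodes survive round-trips as single-column lines;
* complex sets — one complex per line, tab-separated members, optional
  trailing ``score=<float>`` field on predicted complexes;
* literature PPI lists — ``protA<TAB>protB<TAB>weight`` triples, where the
  weight is an extractor confidence and may be negative;
* GO annotations — either a two-column ``protein<TAB>term`` table or the
  needed subset of GAF 2.x (DB object symbol, qualifier, GO id);
* alias maps — two-column ``alias<TAB>systematic`` tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "ComplexSet",
    "LiteraturePPIList",
    "ParseError",
    "canonical_edge",
    "read_network",
    "write_network",
    "read_complexes",
    "write_complexes",
    "restrict_gold_standard",
    "read_literature_ppis",
    "write_literature_ppis",
    "read_annotation",
    "read_alias_map",
    "map_aliases",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Lexicographically sorted pair — the single canonical form of an edge."""
    return (a, b) if a <= b else (b, a)


class PPINetwork:
    """Undirected simple graph over protein identifiers.

    Thin wrapper around :class:`networkx.Graph` enforcing the container
    contract: no self-loops, canonical (sorted-pair) edges, and — when the
    network is weighted — a weight on every edge.
    """

    def __init__(self, weighted: bool = False) -> None:
        self.graph = nx.Graph()
        self.weighted = weighted

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple] = (),
        nodes: Iterable[str] = (),
        weighted: bool = False,
    ) -> "PPINetwork":
        """Build a network from ``(a, b)`` or ``(a, b, w)`` tuples.

        Self-loops are dropped; duplicate edges collapse keeping the
        maximum weight (weights are confidences — max is the optimistic
        merge).
        """
        net = cls(weighted=weighted)
        for n in nodes:
            net.add_node(n)
        for rec in edges:
            if weighted:
                a, b, w = rec
                net.add_edge(a, b, float(w))
            else:
                a, b = rec[0], rec[1]
                net.add_edge(a, b)
        return net

    def add_node(self, n: str) -> None:
        if not n:
            raise ValueError("protein identifiers must be non-empty strings")
        self.graph.add_node(n)

    def add_edge(self, a: str, b: str, weight: float | None = None) -> None:
        """Add a canonical edge; ignores self-loops, max-merges duplicates."""
        if not a or not b:
            raise ValueError("protein identifiers must be non-empty strings")
        if a == b:
            return
        u, v = canonical_edge(a, b)
        if self.weighted:
            if weight is None:
                raise ValueError(f"weighted network requires a weight for ({u},{v})")
            if self.graph.has_edge(u, v):
                weight = max(weight, self.graph[u][v]["weight"])
            self.graph.add_edge(u, v, weight=float(weight))
        else:
            self.graph.add_edge(u, v)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[tuple[str, str]]:
        return {canonical_edge(u, v) for u, v in self.graph.edges}

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges())

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        if not self.weighted:
            raise ValueError("network is unweighted")
        return self.graph[a][b]["weight"]

    def neighbors(self, n: str) -> set[str]:
        return set(self.graph[n]) if n in self.graph else set()

    def subgraph(self, members: Iterable[str]) -> nx.Graph:
        """Induced subgraph view on the backing graph."""
        return self.graph.subgraph(members)

    def copy(self) -> "PPINetwork":
        out = PPINetwork(weighted=self.weighted)
        out.graph = self.graph.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        if self.weighted != other.weighted or self.nodes != other.nodes:
            return False
        if self.edges() != other.edges():
            return False
        if self.weighted:
            return all(
                self.weight(u, v) == other.weight(u, v) for u, v in self.edges()
            )
        return True

    def __repr__(self) -> str:
        kind = "weighted" if self.weighted else "unweighted"
        return f"PPINetwork({kind}, {self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class ComplexSet:
    """Ordered collection of protein sets, with optional per-complex scores.

    Every complex has at least two distinct members (the gold-standard
    retention rule); scores, when present, align index-wise with complexes.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        for c in self.complexes:
            if len(c) < 2:
                raise ValueError(f"complex {sorted(c)} has fewer than 2 members")
            if any(not m for m in c):
                raise ValueError("member IDs must be non-empty strings")
        if self.scores is not None and len(self.scores) != len(self.complexes):
            raise ValueError("scores must align with complexes")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]


@dataclass
class LiteraturePPIList:
    """Literature-extracted PPIs with real-valued extractor confidences.

    Weights may be negative: the extractor's confidence scale spans below
    zero, and integrating thresholds are swept down to -1.2.
    """

    records: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon: list[tuple[str, str, float]] = []
        for a, b, w in self.records:
            if a == b:
                continue
            u, v = canonical_edge(a, b)
            canon.append((u, v, float(w)))
        self.records = canon

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.records)


# ---------------------------------------------------------------------------
# edge-list I/O


def _data_lines(path: str) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_network(path: str, weighted: bool = False) -> PPINetwork:
    """Read a TSV edge list into a canonical :class:`PPINetwork`.

    Single-column lines declare isolated nodes. Self-loops are dropped
    (count logged); duplicate edges collapse keeping the maximum weight.
    """
    net = PPINetwork(weighted=weighted)
    n_lines = 0
    n_selfloops = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = line.split("\t")
        if len(cols) == 1:
            net.add_node(cols[0])
            continue
        expected = 3 if weighted else 2
        if len(cols) != expected:
            raise ParseError(
                f"{path}:{lineno}: expected {expected} columns, got {len(cols)}"
            )
        a, b = cols[0], cols[1]
        if weighted:
            try:
                w = float(cols[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {cols[2]!r}")
        else:
            w = None
        if a == b:
            n_selfloops += 1
            net.add_node(a)
            continue
        net.add_edge(a, b, w)
    if n_lines == 0:
        raise ParseError(f"{path}: empty network file")
    if n_selfloops:
        logger.info("%s: dropped %d self-loop(s)", path, n_selfloops)
    return net


def write_network(net: PPINetwork, path: str) -> None:
    """Write a TSV edge list; isolated nodes become single-column lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in net.sorted_edges():
            if net.weighted:
                fh.write(f"{u}\t{v}\t{net.weight(u, v):g}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for n in sorted(net.nodes):
            if net.graph.degree(n) == 0:
                fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# complex-set I/O


def read_complexes(path: str, min_size: int = 2) -> ComplexSet:
    """Read one complex per line; drop complexes below ``min_size``.

    Duplicate members within a line collapse by set semantics; a trailing
    ``score=<float>`` field is read as the complex's score.
    """
    complexes: list[frozenset[str]] = []
    scores: list[float] = []
    any_score = False
    n_lines = 0
    n_dropped = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = [c for c in line.split("\t") if c]
        score = None
        if cols and cols[-1].startswith("score="):
            score = float(cols[-1][len("score="):])
            cols = cols[:-1]
        members = frozenset(cols)
        if len(members) < min_size:
            n_dropped += 1
            continue
        complexes.append(members)
        scores.append(score if score is not None else float("nan"))
        if score is not None:
            any_score = True
    if n_lines == 0:
        raise ParseError(f"{path}: empty complex file")
    if n_dropped:
        logger.info("%s: dropped %d complex(es) below size %d", path, n_dropped, min_size)
    return ComplexSet(complexes, scores if any_score else None)


def write_complexes(cset: ComplexSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, c in enumerate(cset):
            fields = sorted(c)
            if cset.scores is not None:
                fields.append(f"score={cset.scores[i]:.6g}")
            fh.write("\t".join(fields) + "\n")


def restrict_gold_standard(
    gold: ComplexSet, net: PPINetwork, min_size: int = 2
) -> ComplexSet:
    """Restrict a gold standard to the network's proteins.

    Members absent from ``net`` are filtered out of each complex; complexes
    falling below ``min_size`` distinct members are dropped.
    """
    nodes = net.nodes
    kept: list[frozenset[str]] = []
    for c in gold:
        r = c & nodes
        if len(r) >= min_size:
            kept.append(frozenset(r))
    return ComplexSet(kept)


# ---------------------------------------------------------------------------
# literature-PPI I/O


def read_literature_ppis(path: str) -> LiteraturePPIList:
    records: list[tuple[str, str, float]] = []
    n_lines = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
        try:
            w = float(cols[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric weight {cols[2]!r}")
        records.append((cols[0], cols[1], w))
    if n_lines == 0:
        raise ParseError(f"{path}: empty literature-PPI file")
    return LiteraturePPIList(records)


def write_literature_ppis(lit: LiteraturePPIList, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in lit:
            fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# GO annotation I/O (container type lives in slpc.reliability)


def read_annotation(path: str, format: str = "tsv", aspects: set[str] | None = None):
    """Read protein↔GO-term incidences from a 2-column TSV or a GAF 2.x file.

    GAF rows with a NOT qualifier are excluded; all three GO aspects are
    kept unless ``aspects`` restricts them (e.g. ``{"P"}`` for biological
    process only — GAF column 9).

    Returns a :class:`slpc.reliability.GOAnnotation`.
    """
    from .reliability import GOAnnotation

    pairs: set[tuple[str, str]] = set()
    if format == "tsv":
        for lineno, line in _data_lines(path):
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            pairs.add((cols[0], cols[1]))
    elif format == "gaf":
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    logger.warning("%s:%d: short GAF row skipped", path, lineno)
                    continue
                protein, qualifier, term, aspect = cols[2], cols[3], cols[4], cols[8]
                if "NOT" in qualifier.split("|"):
                    continue
                if aspects is not None and aspect not in aspects:
                    continue
                if protein and term:
                    pairs.add((protein, term))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GOAnnotation.from_pairs(pairs)


# ---------------------------------------------------------------------------
# alias mapping


def read_alias_map(path: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
        mapping[cols[0]] = cols[1]
    return mapping


def map_aliases(obj, aliases: Mapping[str, str]):
    """Replace alias protein names by systematic names and re-canonicalize.

    Works on :class:`PPINetwork`, :class:`ComplexSet` and
    :class:`LiteraturePPIList`. Edges whose endpoints collide onto the same
    systematic name become self-loops and are dropped with a warning.
    """
    def rename(n: str) -> str:
        return aliases.get(n, n)

    if isinstance(obj, PPINetwork):
        out = PPINetwork(weighted=obj.weighted)
        for n in obj.nodes:
            out.add_node(rename(n))
        n_collisions = 0
        for u, v in obj.sorted_edges():
            a, b = rename(u), rename(v)
            if a == b:
                n_collisions += 1
                continue
            out.add_edge(a, b, obj.weight(u, v) if obj.weighted else None)
        if n_collisions:
            logger.warning("alias mapping collapsed %d edge(s) to self-loops", n_collisions)
        return out
    if isinstance(obj, ComplexSet):
        return ComplexSet(
            [frozenset(rename(m) for m in c) for c in obj], obj.scores
        )
    if isinstance(obj, LiteraturePPIList):
        return LiteraturePPIList([(rename(a), rename(b), w) for a, b, w in obj])
    raise TypeError(f"cannot map aliases on {type(obj).__name__}")
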