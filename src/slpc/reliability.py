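"""Interaction-reliability scoring from GO annotation and shared neighbors.

An interaction's reliability combines two signals: how *specific* the GO
terms shared by the two proteins are, and how many network neighbors the
proteins share. For proteins m and n,

    rel(m, n) = -|C(m,n)| * log( min_i |T_i(m,n)| / T_max ) + NE(m,n)

where C(m,n) is the set of GO terms annotating both m and n, |T_i(m,n)| is
the number of proteins annotated to shared term g_i, T_max is the largest
annotation set over all terms, and NE(m,n) is the number of shared network
neighbors. A term annotating few proteins is more specific, so sharing it
drives the log argument down and the score up; unannotated specificity
contributes nothing and the score falls back to the neighbor count.

The score drives three operations: building a GO-weighted network,
removing low-reliability edges below a denoising threshold, and gating
literature-extracted PPIs on their way into a base network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .network_io import LiteraturePPIList, PPINetwork, canonical_edge

__all__ = [
    "GOAnnotation",
    "ReliabilityParams",
    "shared_terms",
    "shared_neighbors",
    "reliability_score",
    "weight_network",
    "denoise_network",
    "integrate_network",
]


@dataclass
class GOAnnotation:
    """Bidirectional protein↔GO-term incidence.

    ``term_to_proteins`` and ``protein_to_terms`` are transposes of each
    other; ``t_max`` caches the largest term size (the normalizer of the
    specificity ratio).
    """

    term_to_proteins: dict[str, frozenset[str]] = field(default_factory=dict)
    protein_to_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GOAnnotation":
        """Build from (protein, term) incidences; duplicates collapse."""
        t2p: dict[str, set[str]] = {}
        p2t: dict[str, set[str]] = {}
        for protein, term in pairs:
            t2p.setdefault(term, set()).add(protein)
            p2t.setdefault(protein, set()).add(term)
        return cls(
            {t: frozenset(ps) for t, ps in t2p.items()},
            {p: frozenset(ts) for p, ts in p2t.items()},
        )

    @property
    def t_max(self) -> int:
        """Largest annotation-set size over all terms (0 if no annotation)."""
        if not self.term_to_proteins:
            return 0
        return max(len(ps) for ps in self.term_to_proteins.values())

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.protein_to_terms.get(protein, frozenset())

    def term_size(self, term: str) -> int:
        return len(self.term_to_proteins.get(term, frozenset()))


@dataclass
class ReliabilityParams:
    """Scoring knobs.

    log_base
        "natural" (default) or "base10"; the base only rescales the
        semantic summand, so thresholds shift but orderings do not.
    no_shared_term_value
        Value of the semantic summand when the proteins share no term
        (the min over an empty set is undefined); 0 treats the absence of
        shared annotation as a maximally unspecific term.
    """

    log_base: str = "natural"
    no_shared_term_value: float = 0.0

    def _log(self, x: float) -> float:
        if self.log_base == "natural":
            return math.log(x)
        if self.log_base == "base10":
            return math.log10(x)
        raise ValueError(f"unknown log base {self.log_base!r}")


def shared_terms(m: str, n: str, ann: GOAnnotation) -> frozenset[str]:
    """GO terms annotating both m and n (C(m,n)); empty if either lacks annotation."""
    return ann.terms_of(m) & ann.terms_of(n)


def shared_neighbors(m: str, n: str, net: PPINetwork) -> int:
    """Number of common network neighbors of m and n, excluding m and n."""
    common = net.neighbors(m) & net.neighbors(n)
    common.discard(m)
    common.discard(n)
    return len(common)


def reliability_score(
    m: str,
    n: str,
    net: PPINetwork,
    ann: GOAnnotation,
    params: ReliabilityParams | None = None,
) -> float:
    """Reliability of the (m, n) interaction.

    The semantic summand is ``-|C| * log(min_i |T_i| / T_max)`` over the
    shared terms; since every |T_i| <= T_max the log argument is <= 1 and
    the summand is >= 0, so the score is bounded below by the shared
    neighbor count (plus ``no_shared_term_value``).
    """
    params = params or ReliabilityParams()
    ne = shared_neighbors(m, n, net)
    terms = shared_terms(m, n, ann)
    if not terms:
        return params.no_shared_term_value + ne
    t_max = ann.t_max
    if t_max < 1:
        raise ValueError("shared terms present but T_max < 1: inconsistent annotation")
    min_ti = min(ann.term_size(t) for t in terms)
    return -len(terms) * params._log(min_ti / t_max) + ne


def weight_network(
    net: PPINetwork, ann: GOAnnotation, params: ReliabilityParams | None = None
) -> PPINetwork:
    """GO-weighted copy of ``net``: same topology, reliability on every edge."""
    out = PPINetwork(weighted=True)
    for n in net.nodes:
        out.add_node(n)
    for u, v in net.sorted_edges():
        out.add_edge(u, v, reliability_score(u, v, net, ann, params))
    return out


def denoise_network(
    net: PPINetwork,
    ann: GOAnnotation,
    den_thred: float,
    params: ReliabilityParams | None = None,
) -> PPINetwork:
    """Remove low-reliability edges; drop nodes left isolated.

    Retains exactly the edges with ``reliability_score >= den_thred``
    (inclusive). Nodes stripped of all incident edges are removed, so node
    counts shrink as the threshold rises.
    """
    out = PPINetwork(weighted=net.weighted)
    for u, v in net.sorted_edges():
        if reliability_score(u, v, net, ann, params) >= den_thred:
            out.add_edge(u, v, net.weight(u, v) if net.weighted else None)
    return out


def integrate_network(
    base: PPINetwork,
    lit: LiteraturePPIList,
    int_thred: float,
    den_thred: float | None = None,
    ann: GOAnnotation | None = None,
    params: ReliabilityParams | None = None,
) -> PPINetwork:
    """Integrate literature-extracted PPIs into a base network.

    A literature record (a, b, w) becomes a candidate edge when
    ``w >= int_thred``, both a and b are already nodes of ``base``, and
    (a, b) is not already a base edge. When ``den_thred`` is given the
    candidate must additionally pass the reliability filter, evaluated
    against the *base* network's neighbor structure (so the outcome does
    not depend on the order in which candidates are added). The output
    keeps the base node set and adds the surviving candidates.
    """
    if den_thred is not None and ann is None:
        raise ValueError("den_thred requires a GO annotation")
    out = base.copy()
    nodes = base.nodes
    for a, b, w in lit:
        if w < int_thred:
            continue
        if a not in nodes or b not in nodes:
            continue
        u, v = canonical_edge(a, b)
        if base.has_edge(u, v):
            continue
        if den_thred is not None:
            if reliability_score(u, v, base, ann, params) < den_thred:
                continue
        out.add_edge(u, v, w if base.weighted else None)
    return out
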