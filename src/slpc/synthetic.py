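"""Seeded synthetic PPI fixtures with planted complexes.

The generator emulates the statistical shape of the toolkit's four inputs
so the whole pipeline is testable without external interaction databases:

* a background network with ``n_complexes`` planted node-disjoint dense
  groups (intra-group edge probability ``p_in``) over a sparse noise
  background (``p_out`` between all other pairs);
* a ground-truth complex set (the planted groups);
* a literature-PPI list made of a held-out fraction of the true
  intra-complex edges (removed from the network, re-offered with
  extractor-like confidences ~ Normal(w_true)) plus random non-edges with
  confidences ~ Normal(w_noise) — the true/noise weight distributions
  straddle the 0 … -1.2 integrating-threshold sweep range;
* a GO-like annotation: a few private terms per planted complex
  (occasionally leaking to an outside protein) under one broad term
  covering every protein, which pins T_max high so complex terms are the
  specific ones.

Everything is reproducible from ``SynthConfig.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .network_io import ComplexSet, LiteraturePPIList, PPINetwork, canonical_edge
from .reliability import GOAnnotation

__all__ = ["SynthConfig", "generate_network", "generate_annotation", "make_split"]


@dataclass
class SynthConfig:
    """Generator settings; defaults give the standard desk-scale benchmark.

    20 disjoint complexes of 4-8 proteins at p_in = 0.9 over 100
    background proteins at p_out = 0.02 — dense planted groups in a sparse
    background, the regime supervised complex detection targets. Weight
    defaults w_true = (0.2, 0.4) and w_noise = (-1.0, 0.4) make the
    0 … -1.2 integrating-threshold sweep meaningful: lowering the
    threshold first admits mostly held-out true pairs, then noise.
    """

    n_complexes: int = 20
    size_range: tuple[int, int] = (4, 8)
    p_in: float = 0.9
    n_background: int = 100
    p_out: float = 0.02
    holdout_frac: float = 0.0
    w_true: tuple[float, float] = (0.2, 0.4)
    w_noise: tuple[float, float] = (-1.0, 0.4)
    n_noise_pairs: int = 200
    terms_per_complex: int = 2
    term_leak: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        for p in (self.p_in, self.p_out, self.term_leak):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.holdout_frac <= 0.5:
            raise ValueError("holdout_frac must lie in [0, 0.5]")
        if self.n_complexes < 1:
            raise ValueError("need at least one planted complex")


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def generate_network(
    cfg: SynthConfig,
) -> tuple[PPINetwork, ComplexSet, LiteraturePPIList]:
    """Planted-complex network, ground truth, and literature-PPI list.

    Intra-complex edges appear with probability ``p_in``; all other pairs
    (cross-complex and background) with ``p_out``. A ``holdout_frac``
    sample of the realized intra-complex edges is then moved out of the
    network into the literature list with Normal(w_true) confidences,
    alongside ``n_noise_pairs`` random non-adjacent pairs with
    Normal(w_noise) confidences. Held-out true pairs are never edges of
    the returned network.
    """
    rng = np.random.default_rng(cfg.seed)

    sizes = rng.integers(cfg.size_range[0], cfg.size_range[1] + 1, cfg.n_complexes)
    complexes: list[frozenset[str]] = []
    next_id = 0
    for s in sizes:
        members = [_node_name(next_id + j) for j in range(int(s))]
        next_id += int(s)
        complexes.append(frozenset(members))
    background = [_node_name(next_id + j) for j in range(cfg.n_background)]
    all_nodes = [_node_name(i) for i in range(next_id)] + background

    membership = {m: i for i, c in enumerate(complexes) for m in c}

    net = PPINetwork(weighted=False)
    for n in all_nodes:
        net.add_node(n)

    intra_edges: list[tuple[str, str]] = []
    for c in complexes:
        for a, b in itertools.combinations(sorted(c), 2):
            if rng.random() < cfg.p_in:
                net.add_edge(a, b)
                intra_edges.append(canonical_edge(a, b))
    for a, b in itertools.combinations(all_nodes, 2):
        same = membership.get(a) is not None and membership.get(a) == membership.get(b)
        if same:
            continue
        if rng.random() < cfg.p_out:
            net.add_edge(a, b)

    records: list[tuple[str, str, float]] = []
    n_holdout = int(np.floor(cfg.holdout_frac * len(intra_edges)))
    if n_holdout > 0:
        idx = rng.choice(len(intra_edges), size=n_holdout, replace=False)
        for i in sorted(int(k) for k in idx):
            a, b = intra_edges[i]
            net.graph.remove_edge(a, b)
            records.append((a, b, float(rng.normal(*cfg.w_true))))

    existing = net.edges() | {canonical_edge(a, b) for a, b, _ in records}
    n_added = 0
    while n_added < cfg.n_noise_pairs:
        i, j = rng.integers(0, len(all_nodes), 2)
        if i == j:
            continue
        pair = canonical_edge(all_nodes[int(i)], all_nodes[int(j)])
        if pair in existing:
            continue
        existing.add(pair)
        records.append((pair[0], pair[1], float(rng.normal(*cfg.w_noise))))
        n_added += 1

    return net, ComplexSet(complexes), LiteraturePPIList(records)


def generate_annotation(
    truth: ComplexSet, net: PPINetwork, cfg: SynthConfig
) -> GOAnnotation:
    """GO-like annotation: private per-complex terms under one broad term.

    Each planted complex receives ``terms_per_complex`` terms annotating
    exactly its members; with probability ``term_leak`` a term also
    annotates one random outside protein. A broad term annotates every
    network protein, so T_max equals the proteome size and the complex
    terms are the specific (high-information) ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    nodes = sorted(net.nodes)
    pairs: set[tuple[str, str]] = {(n, "GO:BROAD") for n in nodes}
    for i, c in enumerate(truth):
        outside = [n for n in nodes if n not in c]
        for t in range(cfg.terms_per_complex):
            term = f"GO:C{i:03d}T{t}"
            for m in c:
                pairs.add((m, term))
            if outside and rng.random() < cfg.term_leak:
                leak = outside[int(rng.integers(0, len(outside)))]
                pairs.add((leak, term))
    return GOAnnotation.from_pairs(pairs)


def make_split(
    truth: ComplexSet, train_frac: float, seed: int
) -> tuple[ComplexSet, ComplexSet]:
    """Seeded disjoint train/test partition of a complex set."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(truth))
    n_train = int(round(train_frac * len(truth)))
    train_idx = sorted(int(i) for i in order[:n_train])
    test_idx = sorted(int(i) for i in order[n_train:])
    return (
        ComplexSet([truth[i] for i in train_idx]),
        ComplexSet([truth[i] for i in test_idx]),
    )
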