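"""Supervised clique-seeded protein-complex detection (SLPC).

The detector learns what a complex looks like from known examples and uses
the learned scorer to carve candidate complexes out of the network:

1. **Train** — feature vectors of the known (training) complexes, labeled
   1, plus size-matched random connected subgraphs labeled 0, fit a ridge
   linear regression scorer.
2. **Seed** — enumerate maximal cliques (size >= 3), score them, and scan
   the descending-score list removing any lower-scoring clique whose
   overlap with a survivor exceeds a threshold.
3. **Grow** — each surviving clique greedily absorbs the neighbor that
   most increases its model score, as long as some neighbor strictly
   increases it.
4. **Merge/filter** — scan candidates by descending score; a pair with
   neighborhood affinity above ``merg_thred`` is merged when the union
   scores strictly higher than the better member, otherwise the worse one
   is dropped.

Every stage breaks ties lexicographically on member tuples, so the whole
pipeline is deterministic given the network, model and configuration.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.linear_model import Ridge

from .features import FEATURE_NAMES, extract_features
from .metrics import na_score
from .network_io import ComplexSet, PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "RegressionModel",
    "CandidateComplex",
    "build_training_set",
    "train_model",
    "score_subgraph",
    "enumerate_maximal_cliques",
    "filter_cliques",
    "grow_clique",
    "merge_filter_candidates",
    "detect_complexes",
]

_MAX_NEGATIVE_RETRIES = 50


@dataclass
class DetectorConfig:
    """Detection hyper-parameters.

    min_clique_size
        Smallest clique used as a seed; size-2 cliques are bare edges and
        would swamp the candidate set.
    clique_overlap_thred
        Seed de-duplication threshold on the overlap ratio
        |A∩B| / min(|A|,|B|) (or on the raw intersection count when
        ``overlap_as_count`` is set).
    merg_thred
        Merge/filter threshold on the neighborhood-affinity score,
        mirroring the 0.25 complex-match threshold.
    negative_ratio
        Negative training subgraphs sampled per positive complex.
    ridge_alpha
        Small fixed L2 regularizer keeping the normal equations
        well-conditioned when features are degenerate.
    max_growth_steps
        Termination safeguard for the greedy growth stage. A scorer fit on
        very few examples can be monotone in subgraph size, in which case
        strict score improvement alone never stops a candidate from
        absorbing its whole connected component; 50 additions is far
        beyond any plausible complex size.
    """

    min_clique_size: int = 3
    clique_overlap_thred: float = 0.5
    merg_thred: float = 0.25
    negative_ratio: int = 1
    seed: int = 0
    overlap_as_count: bool = False
    ridge_alpha: float = 1e-6
    max_growth_steps: int = 50

    def __post_init__(self) -> None:
        if self.min_clique_size < 3:
            raise ValueError("min_clique_size must be >= 3")
        if not self.overlap_as_count and not 0 <= self.clique_overlap_thred <= 1:
            raise ValueError("clique_overlap_thred must lie in [0, 1]")
        if not 0 <= self.merg_thred <= 1:
            raise ValueError("merg_thred must lie in [0, 1]")


@dataclass
class RegressionModel:
    """Linear scorer over the feature registry."""

    coefficients: np.ndarray
    intercept: float
    feature_names: tuple[str, ...]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient vector does not align with feature names")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=tuple(d["feature_names"]),
            training_meta=d.get("training_meta", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str) -> "RegressionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CandidateComplex:
    members: frozenset
    score: float

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("candidate complexes have at least 3 members")

    def key(self) -> tuple:
        """Deterministic ordering key: score descending, members lexicographic."""
        return (-self.score, tuple(sorted(self.members)))


# ---------------------------------------------------------------------------
# training


def _sample_connected_subgraph(
    net: PPINetwork, size: int, rng: random.Random
) -> frozenset | None:
    """Seeded random-walk sample of a connected node set of the given size."""
    candidates = sorted(n for n in net.nodes if net.graph.degree(n) > 0)
    if not candidates:
        return None
    start = rng.choice(candidates)
    current = {start}
    frontier = set(net.neighbors(start))
    while len(current) < size:
        if not frontier:
            return None
        v = rng.choice(sorted(frontier))
        current.add(v)
        frontier |= net.neighbors(v)
        frontier -= current
    return frozenset(current)


def build_training_set(
    positives: ComplexSet,
    net: PPINetwork,
    wnet: PPINetwork,
    cfg: DetectorConfig,
) -> list[tuple[np.ndarray, float]]:
    """Labeled feature vectors: known complexes (1.0) and size-matched
    random connected subgraphs (0.0).

    Restrict the positives to the network first; every positive must have
    at least 2 members present. A sampled negative identical (as a set) to
    any positive is rejected and resampled; after bounded retries the
    negative is skipped with a warning.
    """
    positive_sets = {frozenset(c) for c in positives}
    rng = random.Random(cfg.seed)
    out: list[tuple[np.ndarray, float]] = []
    for c in positives:
        out.append((extract_features(c, net, wnet), 1.0))
    for c in positives:
        for _ in range(cfg.negative_ratio):
            neg = None
            for _ in range(_MAX_NEGATIVE_RETRIES):
                cand = _sample_connected_subgraph(net, len(c), rng)
                if cand is not None and len(cand) == len(c) and cand not in positive_sets:
                    neg = cand
                    break
            if neg is None:
                logger.warning(
                    "could not sample a size-%d negative subgraph; skipped", len(c)
                )
                continue
            out.append((extract_features(neg, net, wnet), 0.0))
    return out


def train_model(
    training: Sequence[tuple[np.ndarray, float]], cfg: DetectorConfig
) -> RegressionModel:
    """Fit the ridge linear scorer; requires both labels present."""
    if len(training) < 2:
        raise ValueError("training requires at least 2 examples")
    X = np.vstack([x for x, _ in training])
    y = np.array([label for _, label in training])
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both positive and negative examples")
    ridge = Ridge(alpha=cfg.ridge_alpha, fit_intercept=True)
    ridge.fit(X, y)
    return RegressionModel(
        coefficients=ridge.coef_,
        intercept=float(ridge.intercept_),
        feature_names=FEATURE_NAMES,
        training_meta={
            "seed": cfg.seed,
            "n_positive": int((y == 1.0).sum()),
            "n_negative": int((y == 0.0).sum()),
            "config": {k: v for k, v in vars(cfg).items()},
        },
    )


def score_subgraph(
    members, model: RegressionModel, net: PPINetwork, wnet: PPINetwork
) -> float:
    """Model score of a node set: intercept + coefficients · features."""
    if model.feature_names != FEATURE_NAMES:
        raise ValueError(
            "model feature registry does not match the current feature registry"
        )
    return float(model.intercept + model.coefficients @ extract_features(members, net, wnet))


# ---------------------------------------------------------------------------
# detection pipeline


def enumerate_maximal_cliques(net: PPINetwork, min_size: int = 3) -> list[frozenset]:
    """All maximal cliques of at least ``min_size`` nodes.

    Bron-Kerbosch with pivoting via networkx; output order is
    deterministic: size descending, then lexicographic member tuple.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(net.graph) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return cliques


def _overlap(a: frozenset, b: frozenset, cfg: DetectorConfig) -> float:
    inter = len(a & b)
    if cfg.overlap_as_count:
        return float(inter)
    return inter / min(len(a), len(b))


def filter_cliques(
    cliques: Sequence[frozenset],
    model: RegressionModel,
    cfg: DetectorConfig,
    net: PPINetwork,
    wnet: PPINetwork,
) -> list[CandidateComplex]:
    """Score, rank descending, and de-duplicate the clique seeds.

    Scanning in rank order, each surviving clique removes every
    lower-ranked clique whose overlap with it strictly exceeds
    ``clique_overlap_thred``.
    """
    scored = [
        CandidateComplex(c, score_subgraph(c, model, net, wnet)) for c in cliques
    ]
    scored.sort(key=CandidateComplex.key)
    survivors: list[CandidateComplex] = []
    removed = [False] * len(scored)
    for i, ci in enumerate(scored):
        if removed[i]:
            continue
        survivors.append(ci)
        for j in range(i + 1, len(scored)):
            if removed[j]:
                continue
            if _overlap(ci.members, scored[j].members, cfg) > cfg.clique_overlap_thred:
                removed[j] = True
    return survivors


def grow_clique(
    candidate: CandidateComplex,
    model: RegressionModel,
    net: PPINetwork,
    wnet: PPINetwork,
    max_steps: int = 50,
) -> CandidateComplex:
    """Greedily absorb neighbors while the model score strictly increases.

    At each step the neighbor whose addition maximizes the score is added
    (ties broken by smallest protein ID), provided the new score strictly
    exceeds the current one; the neighborhood is refreshed after every
    addition. The strict-increase rule bounds the loop for any sensible
    scorer; ``max_steps`` additionally caps the number of additions as a
    safeguard against scorers that are monotone in subgraph size.
    """
    members = candidate.members
    score = candidate.score
    for _ in range(max_steps):
        frontier = set()
        for v in members:
            frontier |= net.neighbors(v)
        frontier -= members
        best_v = None
        best_score = score
        for v in sorted(frontier):
            s = score_subgraph(members | {v}, model, net, wnet)
            if s > best_score:
                best_v, best_score = v, s
        if best_v is None:
            break
        members = members | {best_v}
        score = best_score
    return CandidateComplex(members, score)


def merge_filter_candidates(
    candidates: Sequence[CandidateComplex],
    model: RegressionModel,
    cfg: DetectorConfig,
    net: PPINetwork,
    wnet: PPINetwork,
) -> ComplexSet:
    """Merge or drop overlapping candidates, by descending score.

    For each surviving candidate, lower-ranked candidates with
    neighborhood affinity above ``merg_thred`` are merged in when the
    union scores strictly higher (the scan then restarts from the updated
    candidate) and removed otherwise. Exact duplicates collapse.
    """
    pool: list[CandidateComplex] = []
    seen: set[frozenset] = set()
    for c in sorted(candidates, key=CandidateComplex.key):
        if c.members not in seen:
            seen.add(c.members)
            pool.append(c)
    i = 0
    while i < len(pool):
        restart = True
        while restart:
            restart = False
            ci = pool[i]
            j = i + 1
            while j < len(pool):
                cj = pool[j]
                if na_score(ci.members, cj.members) > cfg.merg_thred:
                    union = ci.members | cj.members
                    union_score = score_subgraph(union, model, net, wnet)
                    if union_score > ci.score:
                        pool[i] = CandidateComplex(union, union_score)
                        del pool[j]
                        restart = True
                        break
                    del pool[j]
                else:
                    j += 1
        i += 1
    # merging can create exact duplicates across survivors; collapse them
    final: list[CandidateComplex] = []
    seen = set()
    for c in pool:
        if c.members not in seen:
            seen.add(c.members)
            final.append(c)
    return ComplexSet([c.members for c in final], [c.score for c in final])


def detect_complexes(
    net: PPINetwork,
    wnet: PPINetwork,
    model: RegressionModel,
    cfg: DetectorConfig | None = None,
) -> ComplexSet:
    """Full pipeline: seed with maximal cliques, de-duplicate, grow, merge.

    Deterministic given inputs and configuration; an edgeless (or
    triangle-free) network yields an empty prediction.
    """
    cfg = cfg or DetectorConfig()
    cliques = enumerate_maximal_cliques(net, cfg.min_clique_size)
    seeds = filter_cliques(cliques, model, cfg, net, wnet)
    grown = [grow_clique(c, model, net, wnet, cfg.max_growth_steps) for c in seeds]
    return merge_filter_candidates(grown, model, cfg, net, wnet)
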