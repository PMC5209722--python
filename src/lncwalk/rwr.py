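"""Random walk with restart over the composite network.

The walker starts from a mixed seed distribution built from the query
phenotype (S^P), its known disease genes (S^G) and known disease lncRNAs
(S^L), and iterates

    p^{t+1} = (1 - delta) * M^T p^t + delta * p^0

until the L1 difference between successive iterates falls below the
tolerance. Candidate lncRNAs are ranked by their stationary scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .network import GENE, LNCRNA, PHENOTYPE, CompositeNetwork
from .transition import TransitionModel


class ConvergenceError(RuntimeError):
    """Propagation failed to reach the tolerance within max_iter steps."""


class SeedError(ValueError):
    """No usable seed nodes after mapping onto the network."""


@dataclass(frozen=True)
class SeedSet:
    """Known disease phenotypes (S^P), genes (S^G) and lncRNAs (S^L)."""

    phenotypes: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()
    lncrnas: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "lncrnas", frozenset(self.lncrnas))


@dataclass(frozen=True)
class MixWeights:
    """Relative importance of the gene (alpha), phenotype (beta) and lncRNA
    (1 - alpha - beta) layers in the initial distribution."""

    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0 or not 0.0 <= self.beta <= 1.0:
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.alpha + self.beta > 1.0 + 1e-12:
            raise ValueError("alpha + beta must not exceed 1")

    @property
    def lncrna_weight(self) -> float:
        return max(0.0, 1.0 - self.alpha - self.beta)


@dataclass(eq=False)
class ProbabilityVector:
    """A distribution over the model's node order (sums to 1)."""

    values: np.ndarray
    node_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_order),):
            raise ValueError("probability vector length does not match node order")
        if (self.values < 0).any():
            raise ValueError("probability vector has negative entries")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise ValueError(f"probability vector sums to {self.values.sum()}, not 1")


@dataclass(eq=False)
class StationaryDistribution:
    """Converged propagation scores plus convergence diagnostics."""

    scores: np.ndarray
    iterations: int
    residual: float
    delta: float
    node_order: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {node: i for i, node in enumerate(self.node_order)}

    def score_of(self, node_id: str) -> float:
        return float(self.scores[self._index[node_id]])


@dataclass(frozen=True)
class RankedCandidate:
    lncrna_id: str
    score: float
    rank: int


@dataclass(eq=False)
class RankedList:
    """Candidate lncRNAs sorted by stationary score (descending)."""

    records: list[RankedCandidate]

    def rank_of(self, lncrna_id: str) -> int:
        for rec in self.records:
            if rec.lncrna_id == lncrna_id:
                return rec.rank
        raise KeyError(f"{lncrna_id!r} not among ranked candidates")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def build_seed_vector(
    seeds: SeedSet, mix: MixWeights, net: CompositeNetwork
) -> ProbabilityVector:
    """Mix per-layer uniform seed distributions into one initial vector.

    Within each layer the seed nodes share that layer's probability equally
    (u0, v0, w0 each sum to 1); the layers are then weighted by alpha, beta
    and 1-alpha-beta. The weight of a layer with no seeds is redistributed
    proportionally over the weights of the seeded layers (uniformly if those
    weights are all zero). Seed ids absent from the network are dropped with
    a warning; if nothing remains a :class:`SeedError` is raised.
    """
    layers = (GENE, PHENOTYPE, LNCRNA)
    requested = {GENE: seeds.genes, PHENOTYPE: seeds.phenotypes, LNCRNA: seeds.lncrnas}
    present: dict[str, list[str]] = {}
    dropped: list[str] = []
    for layer in layers:
        registry = set(net.layer_ids(layer))
        kept = sorted(requested[layer] & registry)
        dropped.extend(sorted(requested[layer] - registry))
        present[layer] = kept
    if dropped:
        if not any(present.values()):
            raise SeedError(f"no seed id maps onto the network (dropped: {dropped})")
        warnings.warn(f"dropping unknown seed id(s): {dropped}", stacklevel=2)
    if not any(present.values()):
        raise SeedError("empty seed set")

    raw = np.array([mix.alpha, mix.beta, mix.lncrna_weight])
    mask = np.array([bool(present[layer]) for layer in layers], dtype=float)
    effective = raw * mask
    if effective.sum() > 0:
        effective /= effective.sum()
    else:  # seeded layers all carry zero nominal weight: fall back to uniform
        effective = mask / mask.sum()

    values = np.zeros(net.n_nodes)
    for layer, weight in zip(layers, effective):
        for node in present[layer]:
            values[net.global_index(node)] = weight / len(present[layer])
    return ProbabilityVector(values, net.node_order)


def propagate(
    model: TransitionModel,
    p0: ProbabilityVector,
    delta: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> StationaryDistribution:
    """Iterate the restart walk to its stationary distribution.

    Dangling (edge-free) nodes have zero transition rows, so in their
    presence the stationary scores sum to slightly less than 1; rankings are
    unaffected.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0, 1]")
    if p0.node_order != model.node_order:
        raise ValueError("seed vector is not defined over the model's node order")
    MT = model.M.T.tocsr()
    p = p0.values.copy()
    for iteration in range(1, max_iter + 1):
        p_next = (1.0 - delta) * (MT @ p) + delta * p0.values
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return StationaryDistribution(p, iteration, residual, delta, model.node_order)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (last L1 residual {residual:.3e})"
    )


def closed_form_stationary(
    model: TransitionModel,
    p0: ProbabilityVector,
    delta: float = 0.7,
    max_nodes: int = 2000,
) -> StationaryDistribution:
    """Exact fixed point p = delta (I - (1-delta) M^T)^{-1} p0 by dense solve.

    Verification oracle for :func:`propagate`; guarded to small networks.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must lie in (0, 1]")
    n = model.n_nodes
    if n > max_nodes:
        raise ValueError(
            f"closed-form solve refused for {n} nodes (guard: {max_nodes}); use propagate"
        )
    if p0.node_order != model.node_order:
        raise ValueError("seed vector is not defined over the model's node order")
    A = np.eye(n) - (1.0 - delta) * model.M.toarray().T
    scores = delta * np.linalg.solve(A, p0.values)
    return StationaryDistribution(scores, 0, 0.0, delta, model.node_order)


def rank_candidates(
    stat: StationaryDistribution, candidates: Iterable[str]
) -> RankedList:
    """Sort candidate lncRNAs by stationary score, ties broken by id.

    Candidates must exist in the scored node order; seed lncRNAs are expected
    to be excluded by the caller. Isolated candidates carry score 0 and rank
    last.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("empty candidate set")
    unknown = [c for c in candidates if c not in stat._index]
    if unknown:
        raise KeyError(f"candidate id(s) not in the network: {unknown[:5]}")
    scored = sorted(candidates, key=lambda c: (-stat.score_of(c), c))
    records = [
        RankedCandidate(c, stat.score_of(c), rank)
        for rank, c in enumerate(scored, start=1)
    ]
    return RankedList(records)
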