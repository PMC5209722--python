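"""Row-stochastic transition matrix over the composite network.

Each node distributes one unit of per-step probability mass among the blocks
its edges touch. A cross-layer block with at least one edge at the node
receives exactly its jump parameter's mass (x for gene<->phenotype, y for
gene<->lncRNA, z for phenotype<->lncRNA), split proportionally to edge
weights; the intra-layer block, if the node has intra-layer edges, receives
whatever mass remains. When a node has bridge edges but no intra-layer edges
(or any combination leaving positive but sub-unit mass) the row is rescaled
to sum to exactly 1 so the walk stays a proper Markov kernel. Edge-free
nodes keep an all-zero (dangling) row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import CompositeNetwork


@dataclass(frozen=True)
class JumpParams:
    """Jump probabilities between layer pairs.

    x: gene <-> phenotype, y: gene <-> lncRNA, z: phenotype <-> lncRNA.
    Pairwise sums are capped at 1 so a node facing two bridge layers never
    owes more mass than it has.
    """

    x: float = 1.0 / 3.0
    y: float = 1.0 / 3.0
    z: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"jump parameter {name}={v} outside [0, 1]")
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            if getattr(self, a) + getattr(self, b) > 1.0 + 1e-12:
                raise ValueError(f"jump parameters {a}+{b} exceed 1")


@dataclass(eq=False)
class TransitionModel:
    """Sparse row-stochastic matrix M with M[i, j] = P(step i -> j)."""

    node_order: list[str]
    M: sp.csr_matrix
    dangling: frozenset[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {node: i for i, node in enumerate(self.node_order)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def index(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def row_mass(self, node_id: str) -> float:
        """Total outgoing probability: 1 for connected nodes, 0 for dangling."""
        return float(self.M[self.index(node_id)].sum())


def _safe_row_normalize(W: np.ndarray, row_sums: np.ndarray) -> np.ndarray:
    out = np.zeros_like(W, dtype=float)
    nz = row_sums > 0
    if nz.any():
        out[nz] = W[nz] / row_sums[nz, None]
    return out


def _layer_rows(
    W_intra: np.ndarray, bridges: list[tuple[np.ndarray, float]]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Assemble one layer's rows: [intra block, bridge blocks...], row totals."""
    n = W_intra.shape[0]
    bridge_mass = np.zeros(n)
    normalized = []
    for W, jump in bridges:
        s = W.sum(axis=1)
        mass = np.where(s > 0, jump, 0.0)
        bridge_mass += mass
        normalized.append(mass[:, None] * _safe_row_normalize(W, s))
    s_intra = W_intra.sum(axis=1)
    intra_mass = np.where(s_intra > 0, 1.0 - bridge_mass, 0.0)
    blocks = [intra_mass[:, None] * _safe_row_normalize(W_intra, s_intra)]
    blocks.extend(normalized)
    return blocks, intra_mass + bridge_mass


def build_transition(
    net: CompositeNetwork,
    params: JumpParams = JumpParams(),
    rescale_substochastic: bool = True,
) -> TransitionModel:
    """Build the composite transition matrix from the six adjacency blocks.

    ``rescale_substochastic=False`` leaves rows with positive sub-unit mass
    (bridges but no intra-layer edges) unrescaled, for sensitivity checks.
    """
    net.validate()
    ng, nph, nl = net.n_genes, net.n_phenotypes, net.n_lncrnas
    n = ng + nph + nl
    M = np.zeros((n, n))

    # gene rows: intra W_G, bridges to phenotypes (x) and lncRNAs (y)
    (g_intra, g_p, g_l), g_total = _layer_rows(
        net.W_G, [(net.W_GP, params.x), (net.W_GL, params.y)]
    )
    M[:ng, :ng] = g_intra
    M[:ng, ng:ng + nph] = g_p
    M[:ng, ng + nph:] = g_l

    # phenotype rows: intra W_P, bridges to genes (x) and lncRNAs (z)
    (p_intra, p_g, p_l), p_total = _layer_rows(
        net.W_P, [(net.W_GP.T, params.x), (net.W_PL, params.z)]
    )
    M[ng:ng + nph, ng:ng + nph] = p_intra
    M[ng:ng + nph, :ng] = p_g
    M[ng:ng + nph, ng + nph:] = p_l

    # lncRNA rows: intra W_L, bridges to genes (y) and phenotypes (z)
    (l_intra, l_g, l_p), l_total = _layer_rows(
        net.W_L, [(net.W_GL.T, params.y), (net.W_PL.T, params.z)]
    )
    M[ng + nph:, ng + nph:] = l_intra
    M[ng + nph:, :ng] = l_g
    M[ng + nph:, ng:ng + nph] = l_p

    totals = np.concatenate([g_total, p_total, l_total])
    if rescale_substochastic:
        fix = (totals > 0) & (np.abs(totals - 1.0) > 1e-15)
        if fix.any():
            M[fix] /= totals[fix, None]

    node_order = net.node_order
    dangling = frozenset(node_order[i] for i in np.flatnonzero(totals == 0))
    return TransitionModel(node_order, sp.csr_matrix(M), dangling)


def row_mass(model: TransitionModel, node_id: str) -> float:
    """Module-level alias for :meth:`TransitionModel.row_mass`."""
    return model.row_mass(node_id)
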