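"""Composite three-layer association network: construction, validation and I/O.

The network has three node layers (genes, disease phenotypes, lncRNAs) and six
weighted association blocks: three intra-layer (gene-gene protein interaction,
phenotype-phenotype textual similarity, lncRNA-lncRNA co-expression) and three
cross-layer (gene-phenotype, gene-lncRNA, phenotype-lncRNA). Edge weights are
1.0 for experimentally validated associations and correlation-valued in (0, 1)
for computationally predicted ones.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENE = "gene"
PHENOTYPE = "phenotype"
LNCRNA = "lncrna"
LAYERS = (GENE, PHENOTYPE, LNCRNA)

#: the six association blocks: name -> (source layer, target layer)
BLOCKS: dict[str, tuple[str, str]] = {
    "gene-gene": (GENE, GENE),
    "phenotype-phenotype": (PHENOTYPE, PHENOTYPE),
    "lncrna-lncrna": (LNCRNA, LNCRNA),
    "gene-phenotype": (GENE, PHENOTYPE),
    "gene-lncrna": (GENE, LNCRNA),
    "phenotype-lncrna": (PHENOTYPE, LNCRNA),
}
INTRA_BLOCKS = ("gene-gene", "phenotype-phenotype", "lncrna-lncrna")
CROSS_BLOCKS = ("gene-phenotype", "gene-lncrna", "phenotype-lncrna")
EVIDENCE_LEVELS = ("experimental", "predicted")

_EDGE_COLUMNS = ["source", "target", "weight", "evidence"]


class EdgeListError(ValueError):
    """Raised for malformed or invariant-violating edge-list input."""


class NetworkValidationError(ValueError):
    """Raised when a composite network violates a structural invariant."""


def block_for(layer_a: str, layer_b: str) -> str:
    """Canonical block name for an (unordered) pair of layers."""
    for name, (s, t) in BLOCKS.items():
        if {s, t} == {layer_a, layer_b} or (s == layer_a == layer_b == t):
            return name
    raise KeyError(f"no block for layer pair ({layer_a}, {layer_b})")


@dataclass(frozen=True)
class EdgeTable:
    """A validated table of weighted associations for one block.

    Records carry (source, target, weight, evidence). Intra-layer records are
    stored with the lexicographically smaller id as source so an unordered
    pair has one canonical orientation.
    """

    block: str
    frame: pd.DataFrame  # columns: source, target, weight, evidence

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise EdgeListError(f"unknown block {self.block!r}")
        if list(self.frame.columns) != _EDGE_COLUMNS:
            raise EdgeListError(f"edge frame must have columns {_EDGE_COLUMNS}")

    @classmethod
    def from_records(
        cls, block: str, records: Iterable[tuple[str, str, float, str]]
    ) -> "EdgeTable":
        frame = pd.DataFrame(list(records), columns=_EDGE_COLUMNS)
        frame["weight"] = frame["weight"].astype(float)
        table = cls(block, _canonicalize(block, frame))
        table.validate()
        return table

    def validate(self) -> None:
        f = self.frame
        bad = f.index[(f["weight"] <= 0) | (f["weight"] > 1)].tolist()
        if bad:
            raise EdgeListError(f"{self.block}: weights outside (0, 1] at rows {bad}")
        loops = f.index[f["source"] == f["target"]].tolist()
        if loops:
            raise EdgeListError(f"{self.block}: self-loops at rows {loops}")
        bad_ev = f.index[~f["evidence"].isin(EVIDENCE_LEVELS)].tolist()
        if bad_ev:
            raise EdgeListError(f"{self.block}: unknown evidence at rows {bad_ev}")

    def records(self) -> list[tuple[str, str, float, str]]:
        return list(self.frame.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.frame)


def _canonicalize(block: str, frame: pd.DataFrame) -> pd.DataFrame:
    """Orient intra-layer records so source <= target lexicographically."""
    frame = frame.copy()
    if block in INTRA_BLOCKS and len(frame):
        flip = frame["source"] > frame["target"]
        s = frame.loc[flip, "source"].copy()
        frame.loc[flip, "source"] = frame.loc[flip, "target"]
        frame.loc[flip, "target"] = s
    return frame.reset_index(drop=True)


def load_edge_list(path: str | Path, block: str) -> EdgeTable:
    """Parse one TSV edge list into a validated :class:`EdgeTable`.

    Rows have 2-4 tab-separated fields: source, target, optional weight
    (defaults to 1.0), optional evidence (defaults to ``experimental`` when
    the weight is 1.0 and ``predicted`` otherwise). Blank lines and lines
    starting with ``#`` are skipped. All malformed rows are reported together
    with their line numbers.
    """
    if block not in BLOCKS:
        raise EdgeListError(f"unknown block {block!r}")
    path = Path(path)
    records: list[tuple[str, str, float, str]] = []
    errors: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if not 2 <= len(fields) <= 4:
                errors.append(f"line {lineno}: expected 2-4 fields, got {len(fields)}")
                continue
            source, target = fields[0], fields[1]
            try:
                weight = float(fields[2]) if len(fields) >= 3 else 1.0
            except ValueError:
                errors.append(f"line {lineno}: unparseable weight {fields[2]!r}")
                continue
            if len(fields) == 4:
                evidence = fields[3]
            else:
                evidence = "experimental" if weight == 1.0 else "predicted"
            if not source or not target:
                errors.append(f"line {lineno}: empty node id")
            elif source == target:
                errors.append(f"line {lineno}: self-loop on {source!r}")
            elif not 0 < weight <= 1:
                errors.append(f"line {lineno}: weight {weight} outside (0, 1]")
            elif evidence not in EVIDENCE_LEVELS:
                errors.append(f"line {lineno}: unknown evidence {evidence!r}")
            else:
                records.append((source, target, weight, evidence))
    if errors:
        raise EdgeListError(f"{path}: " + "; ".join(errors))
    return EdgeTable.from_records(block, records)


def write_edge_list(table: EdgeTable, path: str | Path) -> None:
    """Write an EdgeTable as the canonical four-column TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\tweight\tevidence\n")
        for source, target, weight, evidence in table.records():
            fh.write(f"{source}\t{target}\t{weight:.10g}\t{evidence}\n")


def merge_edge_evidence(*tables: EdgeTable) -> EdgeTable:
    """Collapse duplicate node pairs across one or more tables for a block.

    Experimental evidence takes precedence over predicted; among duplicates of
    equal evidence the maximum weight is kept. Idempotent.
    """
    if not tables:
        raise EdgeListError("merge_edge_evidence needs at least one table")
    blocks = {t.block for t in tables}
    if len(blocks) != 1:
        raise EdgeListError(f"cannot merge tables of different blocks: {sorted(blocks)}")
    block = tables[0].block
    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    frame = _canonicalize(block, frame)
    # experimental sorts before predicted; then highest weight first
    frame["_ev_rank"] = frame["evidence"].map({"experimental": 0, "predicted": 1})
    frame = frame.sort_values(
        ["source", "target", "_ev_rank", "weight"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    frame = frame.drop_duplicates(["source", "target"], keep="first")
    frame = frame.drop(columns="_ev_rank").reset_index(drop=True)
    return EdgeTable(block, frame)


@dataclass(eq=False)
class ExpressionMatrix:
    """Entity-by-sample nonnegative expression values (FPKM-like).

    ``layers`` assigns each entity to the gene or lncRNA layer so that
    co-expression edges can be routed to the right block.
    """

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    layers: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValueError("expression values shape does not match id lists")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        unknown = [e for e in self.entity_ids if self.layers.get(e) not in (GENE, LNCRNA)]
        if unknown:
            raise ValueError(f"entities without gene/lncrna layer assignment: {unknown[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def load_expression(path: str | Path, layers_path: str | Path) -> ExpressionMatrix:
    """Load a TSV expression matrix plus a two-column entity->layer map."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    layer_map = pd.read_csv(
        layers_path, sep="\t", header=None, names=["entity", "layer"], comment="#"
    )
    layers = dict(zip(layer_map["entity"].astype(str), layer_map["layer"].astype(str)))
    return ExpressionMatrix(
        entity_ids=[str(i) for i in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=float),
        layers=layers,
    )


def coexpression_edges(
    expr: ExpressionMatrix,
    source_layer: str,
    target_layer: str,
    threshold: float = 0.6,
    policy: str = "absolute",
) -> EdgeTable:
    """Predicted-evidence edges between entities whose Pearson r passes a cutoff.

    policy ``absolute`` keeps pairs with |r| >= threshold at weight |r|;
    ``signed_positive`` keeps pairs with r >= threshold at weight r. Entities
    with constant profiles are skipped with a warning (correlation undefined).
    """
    if policy not in ("absolute", "signed_positive"):
        raise ValueError(f"unknown policy {policy!r}")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if expr.n_samples < 3:
        raise ValueError("at least 3 samples are required for correlation")

    block = block_for(source_layer, target_layer)
    values = expr.values
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        names = [expr.entity_ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"skipping {len(names)} constant expression profile(s): {names[:5]}",
            stacklevel=2,
        )
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]

    idx_a = [
        i
        for i, e in enumerate(expr.entity_ids)
        if expr.layers[e] == source_layer and not constant[i]
    ]
    idx_b = [
        i
        for i, e in enumerate(expr.entity_ids)
        if expr.layers[e] == target_layer and not constant[i]
    ]
    corr = np.clip(unit[idx_a] @ unit[idx_b].T, -1.0, 1.0)

    records: list[tuple[str, str, float, str]] = []
    intra = source_layer == target_layer
    for ai, i in enumerate(idx_a):
        for bj, j in enumerate(idx_b):
            if intra and j <= i:
                continue
            r = float(corr[ai, bj])
            w = abs(r) if policy == "absolute" else r
            if w >= threshold and w > 0:
                records.append(
                    (expr.entity_ids[i], expr.entity_ids[j], min(w, 1.0), "predicted")
                )
    return EdgeTable.from_records(block, records)


def top_k_phenotype_edges(similarity: EdgeTable, k: int) -> EdgeTable:
    """Keep each phenotype's k most similar neighbours, symmetrized by union.

    An edge survives if either endpoint lists the other among its k
    highest-weight neighbours; ties at the k-th weight break on lexicographic
    node id.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if similarity.block != "phenotype-phenotype":
        raise EdgeListError("top_k_phenotype_edges expects a phenotype-phenotype table")
    merged = merge_edge_evidence(similarity)
    neighbours: dict[str, list[tuple[float, str]]] = {}
    weights: dict[tuple[str, str], tuple[float, str]] = {}
    for source, target, weight, evidence in merged.records():
        neighbours.setdefault(source, []).append((weight, target))
        neighbours.setdefault(target, []).append((weight, source))
        weights[(source, target)] = (weight, evidence)
    keep: set[tuple[str, str]] = set()
    for node, nbrs in neighbours.items():
        nbrs.sort(key=lambda wt: (-wt[0], wt[1]))
        for _, other in nbrs[:k]:
            keep.add((min(node, other), max(node, other)))
    records = [
        (s, t, weights[(s, t)][0], weights[(s, t)][1]) for s, t in sorted(keep)
    ]
    return EdgeTable.from_records("phenotype-phenotype", records)


@dataclass(eq=False)
class CompositeNetwork:
    """The six weighted adjacency blocks over three ordered node registries.

    Intra-layer blocks (W_G, W_P, W_L) are symmetric with zero diagonal;
    cross-layer blocks are oriented gene x phenotype (W_GP), gene x lncRNA
    (W_GL) and phenotype x lncRNA (W_PL). All weights lie in [0, 1].
    """

    gene_ids: list[str]
    phenotype_ids: list[str]
    lncrna_ids: list[str]
    W_G: np.ndarray
    W_P: np.ndarray
    W_L: np.ndarray
    W_GP: np.ndarray
    W_GL: np.ndarray
    W_PL: np.ndarray
    _index: dict[str, tuple[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("W_G", "W_P", "W_L", "W_GP", "W_GL", "W_PL"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self._index = {}
        for layer, ids in zip(LAYERS, (self.gene_ids, self.phenotype_ids, self.lncrna_ids)):
            for local, node in enumerate(ids):
                if node in self._index:
                    raise NetworkValidationError(
                        f"id {node!r} appears in both {self._index[node][0]} and {layer} layers"
                    )
                self._index[node] = (layer, local)

    # -- registry helpers -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_genes + self.n_phenotypes + self.n_lncrnas

    @property
    def node_order(self) -> list[str]:
        """Global node ordering: genes ++ phenotypes ++ lncRNAs."""
        return list(self.gene_ids) + list(self.phenotype_ids) + list(self.lncrna_ids)

    def layer_of(self, node_id: str) -> str:
        try:
            return self._index[node_id][0]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def local_index(self, node_id: str) -> int:
        return self._index[node_id][1]

    def global_index(self, node_id: str) -> int:
        layer, local = self._index[node_id]
        offset = {GENE: 0, PHENOTYPE: self.n_genes, LNCRNA: self.n_genes + self.n_phenotypes}
        return offset[layer] + local

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def layer_ids(self, layer: str) -> list[str]:
        return {GENE: self.gene_ids, PHENOTYPE: self.phenotype_ids, LNCRNA: self.lncrna_ids}[layer]

    def copy(self) -> "CompositeNetwork":
        return CompositeNetwork(
            list(self.gene_ids),
            list(self.phenotype_ids),
            list(self.lncrna_ids),
            self.W_G.copy(),
            self.W_P.copy(),
            self.W_L.copy(),
            self.W_GP.copy(),
            self.W_GL.copy(),
            self.W_PL.copy(),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        shapes = {
            "W_G": (self.n_genes, self.n_genes),
            "W_P": (self.n_phenotypes, self.n_phenotypes),
            "W_L": (self.n_lncrnas, self.n_lncrnas),
            "W_GP": (self.n_genes, self.n_phenotypes),
            "W_GL": (self.n_genes, self.n_lncrnas),
            "W_PL": (self.n_phenotypes, self.n_lncrnas),
        }
        for name, shape in shapes.items():
            W = getattr(self, name)
            if W.shape != shape:
                raise NetworkValidationError(f"{name} has shape {W.shape}, expected {shape}")
            if (W < 0).any() or (W > 1).any():
                raise NetworkValidationError(f"{name} has entries outside [0, 1]")
        for name in ("W_G", "W_P", "W_L"):
            W = getattr(self, name)
            if W.size and not np.array_equal(W, W.T):
                raise NetworkValidationError(f"{name} is not symmetric")
            if W.size and np.diag(W).any():
                raise NetworkValidationError(f"{name} has nonzero diagonal")


def build_composite(
    tables: Mapping[str, EdgeTable],
    node_universes: Mapping[str, Sequence[str]] | None = None,
) -> CompositeNetwork:
    """Assemble the six blocks over the union of observed (plus universe) ids.

    Node id lists are sorted per layer, so the result is invariant to input
    record order. Intra-layer blocks are symmetrized; if a pair appears in
    both orientations with different weights the maximum is kept. An id used
    in two layers is rejected.
    """
    layer_sets: dict[str, set[str]] = {layer: set() for layer in LAYERS}
    for name, table in tables.items():
        if name not in BLOCKS:
            raise EdgeListError(f"unknown block {name!r}")
        if table.block != name:
            raise EdgeListError(f"table for {name!r} is labelled {table.block!r}")
        src_layer, tgt_layer = BLOCKS[name]
        layer_sets[src_layer].update(table.frame["source"])
        layer_sets[tgt_layer].update(table.frame["target"])
    if node_universes:
        for layer, ids in node_universes.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r} in node_universes")
            layer_sets[layer].update(ids)

    for la, lb in itertools.combinations(LAYERS, 2):
        shared = layer_sets[la] & layer_sets[lb]
        if shared:
            raise NetworkValidationError(
                f"id(s) assigned to both {la} and {lb} layers: {sorted(shared)[:5]}"
            )

    ids = {layer: sorted(layer_sets[layer]) for layer in LAYERS}
    pos = {layer: {node: i for i, node in enumerate(ids[layer])} for layer in LAYERS}

    mats = {
        "gene-gene": np.zeros((len(ids[GENE]), len(ids[GENE]))),
        "phenotype-phenotype": np.zeros((len(ids[PHENOTYPE]), len(ids[PHENOTYPE]))),
        "lncrna-lncrna": np.zeros((len(ids[LNCRNA]), len(ids[LNCRNA]))),
        "gene-phenotype": np.zeros((len(ids[GENE]), len(ids[PHENOTYPE]))),
        "gene-lncrna": np.zeros((len(ids[GENE]), len(ids[LNCRNA]))),
        "phenotype-lncrna": np.zeros((len(ids[PHENOTYPE]), len(ids[LNCRNA]))),
    }
    for name, table in tables.items():
        src_layer, tgt_layer = BLOCKS[name]
        W = mats[name]
        intra = name in INTRA_BLOCKS
        for source, target, weight, _ in table.records():
            i = pos[src_layer][source]
            j = pos[tgt_layer][target]
            if intra:
                w = max(weight, W[i, j])
                W[i, j] = w
                W[j, i] = w
            else:
                W[i, j] = max(weight, W[i, j])

    net = CompositeNetwork(
        ids[GENE], ids[PHENOTYPE], ids[LNCRNA],
        mats["gene-gene"], mats["phenotype-phenotype"], mats["lncrna-lncrna"],
        mats["gene-phenotype"], mats["gene-lncrna"], mats["phenotype-lncrna"],
    )
    net.validate()
    return net


def restrict_layers(net: CompositeNetwork, keep: Iterable[str]) -> CompositeNetwork:
    """Drop layers not in ``keep``, zeroing every block that touches them.

    Used for ablation baselines: a phenotype-lncRNA-only walk mimics
    heterogeneous two-layer methods, a lncRNA-only walk mimics single-layer
    similarity methods. ``keep`` must contain the lncRNA layer (otherwise
    there is nothing to rank).
    """
    keep = set(keep)
    unknown = keep - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layer(s) {sorted(unknown)}")
    if LNCRNA not in keep:
        raise ValueError("keep must include the lncrna layer")
    gene_ids = list(net.gene_ids) if GENE in keep else []
    phen_ids = list(net.phenotype_ids) if PHENOTYPE in keep else []
    lnc_ids = list(net.lncrna_ids)
    ng, np_, nl = len(gene_ids), len(phen_ids), len(lnc_ids)
    restricted = CompositeNetwork(
        gene_ids,
        phen_ids,
        lnc_ids,
        net.W_G.copy() if GENE in keep else np.zeros((0, 0)),
        net.W_P.copy() if PHENOTYPE in keep else np.zeros((0, 0)),
        net.W_L.copy(),
        net.W_GP.copy() if GENE in keep and PHENOTYPE in keep else np.zeros((ng, np_)),
        net.W_GL.copy() if GENE in keep else np.zeros((ng, nl)),
        net.W_PL.copy() if PHENOTYPE in keep else np.zeros((np_, nl)),
    )
    restricted.validate()
    return restricted


# -- serialization ---------------------------------------------------------

def _block_table(net: CompositeNetwork, name: str) -> EdgeTable:
    src_layer, tgt_layer = BLOCKS[name]
    W = {
        "gene-gene": net.W_G, "phenotype-phenotype": net.W_P,
        "lncrna-lncrna": net.W_L, "gene-phenotype": net.W_GP,
        "gene-lncrna": net.W_GL, "phenotype-lncrna": net.W_PL,
    }[name]
    src_ids = net.layer_ids(src_layer)
    tgt_ids = net.layer_ids(tgt_layer)
    records = []
    intra = name in INTRA_BLOCKS
    rows, cols = np.nonzero(W)
    for i, j in zip(rows, cols):
        if intra and j <= i:
            continue
        w = float(W[i, j])
        evidence = "experimental" if w == 1.0 else "predicted"
        records.append((src_ids[i], tgt_ids[j], w, evidence))
    return EdgeTable.from_records(name, records)


def write_network(net: CompositeNetwork, outdir: str | Path) -> None:
    """Serialize a network as six canonical TSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name in BLOCKS:
        path = outdir / f"{name}.tsv"
        write_edge_list(_block_table(net, name), path)
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "format": "lncwalk-network/1",
        "layers": {
            GENE: net.gene_ids,
            PHENOTYPE: net.phenotype_ids,
            LNCRNA: net.lncrna_ids,
        },
        "layer_sizes": {
            GENE: net.n_genes, PHENOTYPE: net.n_phenotypes, LNCRNA: net.n_lncrnas
        },
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_network(indir: str | Path) -> CompositeNetwork:
    """Load a network serialized by :func:`write_network`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    tables = {name: load_edge_list(indir / f"{name}.tsv", name) for name in BLOCKS}
    universes = {layer: manifest["layers"][layer] for layer in LAYERS}
    return build_composite(tables, node_universes=universes)
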