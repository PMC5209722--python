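"""LOOCV evaluation, ROC/AUC, parameter sweeps, landscape and hotspots.

Leave-one-out cross-validation removes each known phenotype-lncRNA link in
turn, re-runs the walk seeded by the phenotype plus its remaining known
lncRNAs and all its known genes, and records where the held-out lncRNA lands
in the candidate ranking. Folds have different candidate counts, so positives
are placed on a common [0, 1] rank-percentile axis, each fold's negatives
occupy the remaining rank positions on the same axis, and the pooled
empirical ROC/AUC is computed over those positions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import LAYERS, LNCRNA, CompositeNetwork, restrict_layers
from .rwr import (
    MixWeights,
    SeedSet,
    StationaryDistribution,
    build_seed_vector,
    propagate,
    rank_candidates,
)
from .transition import JumpParams, build_transition


@dataclass(eq=False)
class AssociationCatalog:
    """Known phenotype-lncRNA and phenotype-gene associations.

    ``classes`` optionally maps phenotypes to disease classes for per-class
    evaluation.
    """

    lncrnas: dict[str, frozenset[str]]
    genes: dict[str, frozenset[str]]
    classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.lncrnas = {p: frozenset(v) for p, v in self.lncrnas.items() if v}
        self.genes = {p: frozenset(v) for p, v in self.genes.items() if v}

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str]],
        classes: Mapping[str, str] | None = None,
    ) -> "AssociationCatalog":
        """Build from (phenotype, id, type) records, type in {gene, lncrna}."""
        lncs: dict[str, set[str]] = {}
        genes: dict[str, set[str]] = {}
        for phenotype, node, kind in records:
            if kind == "lncrna":
                lncs.setdefault(phenotype, set()).add(node)
            elif kind == "gene":
                genes.setdefault(phenotype, set()).add(node)
            else:
                raise ValueError(f"unknown association type {kind!r}")
        return cls(
            {p: frozenset(v) for p, v in lncs.items()},
            {p: frozenset(v) for p, v in genes.items()},
            dict(classes) if classes else None,
        )

    @classmethod
    def from_tsv(cls, path, classes_path=None) -> "AssociationCatalog":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["phenotype", "id", "type"], comment="#"
        )
        classes = None
        if classes_path is not None:
            cf = pd.read_csv(
                classes_path, sep="\t", header=None,
                names=["phenotype", "class"], comment="#",
            )
            classes = dict(zip(cf["phenotype"].astype(str), cf["class"].astype(str)))
        return cls.from_records(
            frame.astype(str).itertuples(index=False, name=None), classes
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# phenotype\tid\ttype\n")
            for p in sorted(self.lncrnas):
                for node in sorted(self.lncrnas[p]):
                    fh.write(f"{p}\t{node}\tlncrna\n")
            for p in sorted(self.genes):
                for node in sorted(self.genes[p]):
                    fh.write(f"{p}\t{node}\tgene\n")

    @property
    def n_lncrna_associations(self) -> int:
        return sum(len(v) for v in self.lncrnas.values())

    @property
    def n_gene_associations(self) -> int:
        return sum(len(v) for v in self.genes.values())


@dataclass(frozen=True)
class FoldRecord:
    phenotype: str
    held_out: str
    rank: int
    n_candidates: int
    percentile: float


@dataclass(eq=False)
class CVResult:
    """Per-fold ranks plus the pooled ROC curve and AUC."""

    folds: list[FoldRecord]
    roc: np.ndarray  # (k, 2) array of (FPR, TPR) points
    auc: float
    per_class_auc: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.__dict__ for f in self.folds])

    @property
    def mean_percentile(self) -> float:
        return float(np.mean([f.percentile for f in self.folds]))


def _pooled_roc(positives: np.ndarray, negatives: np.ndarray) -> np.ndarray:
    """Empirical step ROC over pooled percentile positions (lower = better).

    Ties between positives and negatives produce diagonal segments, so the
    trapezoidal area equals the Mann-Whitney statistic with half-credit ties.
    """
    if positives.size == 0:
        raise ValueError("no positives to build a ROC from")
    if negatives.size == 0:
        raise ValueError("no negatives to build a ROC from")
    values = np.unique(np.concatenate([positives, negatives]))
    points = [(0.0, 0.0)]
    tp = fp = 0
    for v in values:  # ascending percentile = descending score
        tp += int((positives == v).sum())
        fp += int((negatives == v).sum())
        points.append((fp / negatives.size, tp / positives.size))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.array(points)


def _fold_positions(percentile: float, n_candidates: int) -> np.ndarray:
    """Percentile positions of a fold's negatives (every rank but the positive's)."""
    if n_candidates < 2:
        return np.empty(0)
    grid = np.arange(n_candidates) / (n_candidates - 1)
    r = int(round(percentile * (n_candidates - 1)))
    return np.delete(grid, r)


def roc_points(
    positives: Sequence[float], n_candidates_per_fold: Sequence[int] | int
) -> np.ndarray:
    """Pooled ROC from held-out percentiles and per-fold candidate counts.

    Each fold contributes one positive at its percentile and n-1 negatives at
    the remaining rank percentiles of that fold.
    """
    positives = np.asarray(positives, dtype=float)
    if positives.size == 0:
        raise ValueError("no positives to build a ROC from")
    if (positives < 0).any() or (positives > 1).any():
        raise ValueError("percentiles must lie in [0, 1]")
    if np.isscalar(n_candidates_per_fold):
        counts = [int(n_candidates_per_fold)] * positives.size
    else:
        counts = [int(c) for c in n_candidates_per_fold]
        if len(counts) != positives.size:
            raise ValueError("one candidate count per positive required")
    negatives = np.concatenate(
        [_fold_positions(p, n) for p, n in zip(positives, counts)]
    )
    return _pooled_roc(positives, negatives)


def auc(roc: np.ndarray) -> float:
    """Trapezoidal area under a (FPR, TPR) point list."""
    roc = np.asarray(roc, dtype=float)
    if roc.ndim != 2 or roc.shape[1] != 2 or roc.shape[0] < 2:
        raise ValueError("ROC must be a (k, 2) array with k >= 2")
    if (np.diff(roc[:, 0]) < -1e-12).any() or (np.diff(roc[:, 1]) < -1e-12).any():
        raise ValueError("ROC points must be monotone nondecreasing")
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def _seed_for_fold(
    net: CompositeNetwork,
    phenotype: str,
    genes: Iterable[str],
    lncrnas: Iterable[str],
) -> SeedSet:
    """Intersect requested seeds with the network's registries."""
    reg_p = set(net.phenotype_ids)
    reg_g = set(net.gene_ids)
    reg_l = set(net.lncrna_ids)
    return SeedSet(
        phenotypes=frozenset({phenotype} & reg_p),
        genes=frozenset(set(genes) & reg_g),
        lncrnas=frozenset(set(lncrnas) & reg_l),
    )


def _run_fold(
    net: CompositeNetwork,
    seeds: SeedSet,
    jumps: JumpParams,
    mix: MixWeights,
    delta: float,
    tol: float,
    max_iter: int,
) -> StationaryDistribution:
    model = build_transition(net, jumps)
    p0 = build_seed_vector(seeds, mix, net)
    return propagate(model, p0, delta=delta, tol=tol, max_iter=max_iter)


def loocv(
    net: CompositeNetwork,
    catalog: AssociationCatalog,
    *,
    delta: float = 0.7,
    jumps: JumpParams = JumpParams(),
    mix: MixWeights = MixWeights(),
    min_known_lncrnas: int = 2,
    layer_ablation: Iterable[str] | None = None,
    seed_scenario: str = "full",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> CVResult:
    """Leave-one-out cross-validation over known phenotype-lncRNA links.

    For every association (p, l) of a phenotype with at least
    ``min_known_lncrnas`` known lncRNAs: remove the p-l edge (scenario
    ``full``) or all of p's known-lncRNA edges (scenario ``no_known_lncrnas``),
    seed with p, its remaining known lncRNAs (none in the second scenario) and
    all its known genes, propagate, and record the held-out lncRNA's rank
    among all non-seed lncRNAs. ``layer_ablation`` restricts the walk to a
    layer subset first (e.g. {"phenotype", "lncrna"}) for baseline
    comparisons.
    """
    if seed_scenario not in ("full", "no_known_lncrnas"):
        raise ValueError(f"unknown seed_scenario {seed_scenario!r}")
    if layer_ablation is not None:
        net = restrict_layers(net, layer_ablation)
    if not catalog.lncrnas:
        raise ValueError("association catalog has no phenotype-lncRNA records")

    lnc_registry = set(net.lncrna_ids)
    folds: list[FoldRecord] = []
    for phenotype in sorted(catalog.lncrnas):
        known_lncs = sorted(catalog.lncrnas[phenotype] & lnc_registry)
        if len(known_lncs) < min_known_lncrnas:
            continue
        known_genes = sorted(catalog.genes.get(phenotype, frozenset()))
        p_idx = (
            net.phenotype_ids.index(phenotype) if phenotype in net.phenotype_ids else None
        )

        shared_stat: StationaryDistribution | None = None
        if seed_scenario == "no_known_lncrnas":
            # one propagation serves every fold of this phenotype: the seed
            # set and the modified network do not depend on the held-out lncRNA
            fold_net = net.copy()
            if p_idx is not None:
                for l in known_lncs:
                    fold_net.W_PL[p_idx, fold_net.lncrna_ids.index(l)] = 0.0
            seeds = _seed_for_fold(fold_net, phenotype, known_genes, ())
            if not (seeds.phenotypes or seeds.genes or seeds.lncrnas):
                warnings.warn(f"skipping phenotype {phenotype!r}: no seeds", stacklevel=2)
                continue
            shared_stat = _run_fold(fold_net, seeds, jumps, mix, delta, tol, max_iter)

        for held_out in known_lncs:
            if shared_stat is not None:
                stat = shared_stat
                seed_lncs: list[str] = []
            else:
                fold_net = net.copy()
                if p_idx is not None:
                    fold_net.W_PL[p_idx, fold_net.lncrna_ids.index(held_out)] = 0.0
                seed_lncs = [l for l in known_lncs if l != held_out]
                seeds = _seed_for_fold(fold_net, phenotype, known_genes, seed_lncs)
                if not (seeds.phenotypes or seeds.genes or seeds.lncrnas):
                    warnings.warn(
                        f"skipping fold ({phenotype!r}, {held_out!r}): no seeds",
                        stacklevel=2,
                    )
                    continue
                stat = _run_fold(fold_net, seeds, jumps, mix, delta, tol, max_iter)
            candidates = sorted(lnc_registry - set(seed_lncs))
            ranking = rank_candidates(stat, candidates)
            rank = ranking.rank_of(held_out)
            n = len(candidates)
            percentile = (rank - 1) / (n - 1) if n > 1 else 0.0
            folds.append(FoldRecord(phenotype, held_out, rank, n, percentile))

    if not folds:
        raise ValueError("no usable folds (check min_known_lncrnas and the catalog)")
    roc = roc_points([f.percentile for f in folds], [f.n_candidates for f in folds])
    pooled_auc = auc(roc)
    per_class = None
    if catalog.classes:
        per_class = {}
        for cls in sorted(set(catalog.classes.values())):
            members = [f for f in folds if catalog.classes.get(f.phenotype) == cls]
            if members:
                per_class[cls] = auc(
                    roc_points(
                        [f.percentile for f in members],
                        [f.n_candidates for f in members],
                    )
                )
    return CVResult(folds, roc, pooled_auc, per_class)


def topk_recall(
    cv: CVResult, fraction: float | None = None, k: int | None = None
) -> float:
    """Share of folds whose held-out lncRNA ranks in the top fraction or top k."""
    if (fraction is None) == (k is None):
        raise ValueError("give exactly one of fraction or k")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        hits = sum(
            f.rank <= int(np.ceil(fraction * f.n_candidates)) for f in cv.folds
        )
    else:
        if k < 1:
            raise ValueError("k must be positive")
        hits = sum(f.rank <= k for f in cv.folds)
    return hits / len(cv.folds)


def parameter_sweep(
    net: CompositeNetwork,
    catalog: AssociationCatalog,
    grid: Mapping[str, Sequence[float]],
    **loocv_kwargs,
) -> pd.DataFrame:
    """Run one LOOCV per grid point over {delta, x, y, z, alpha, beta}.

    Grid points violating the jump/mix constraints are kept in the table with
    status ``skipped`` and the violation as reason.
    """
    allowed = ("delta", "x", "y", "z", "alpha", "beta")
    unknown = set(grid) - set(allowed)
    if unknown:
        raise ValueError(f"unknown sweep parameter(s): {sorted(unknown)}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty parameter grid")
    names = [n for n in allowed if n in grid]
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, combo))
        row = {n: point.get(n, np.nan) for n in allowed}
        try:
            jumps = JumpParams(
                x=point.get("x", 1 / 3), y=point.get("y", 1 / 3), z=point.get("z", 1 / 3)
            )
            mix = MixWeights(
                alpha=point.get("alpha", 1 / 3), beta=point.get("beta", 1 / 3)
            )
            delta = point.get("delta", 0.7)
            if not 0 < delta <= 1:
                raise ValueError(f"delta={delta} outside (0, 1]")
        except ValueError as exc:
            rows.append({**row, "auc": np.nan, "status": "skipped", "reason": str(exc)})
            continue
        result = loocv(net, catalog, delta=delta, jumps=jumps, mix=mix, **loocv_kwargs)
        rows.append({**row, "auc": result.auc, "status": "ok", "reason": ""})
    return pd.DataFrame(rows)


@dataclass(eq=False)
class ScoreMatrix:
    """Phenotype-by-lncRNA matrix of stationary scores."""

    values: np.ndarray
    phenotype_ids: list[str]
    lncrna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.phenotype_ids), len(self.lncrna_ids)):
            raise ValueError("score matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.phenotype_ids, columns=self.lncrna_ids
        )

    def row_ranking(self, phenotype: str) -> list[str]:
        """LncRNA ids in rank order for one phenotype (score desc, id ties)."""
        i = self.phenotype_ids.index(phenotype)
        row = self.values[i]
        return sorted(self.lncrna_ids, key=lambda l: (-row[self.lncrna_ids.index(l)], l))


def score_landscape(
    net: CompositeNetwork,
    catalog: AssociationCatalog,
    phenotypes: Sequence[str],
    *,
    delta: float = 0.7,
    jumps: JumpParams = JumpParams(),
    mix: MixWeights = MixWeights(),
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> ScoreMatrix:
    """Stationary lncRNA scores for each phenotype, seeded by its full
    known gene and lncRNA sets (nothing held out)."""
    model = build_transition(net, jumps)
    lnc_idx = [net.global_index(l) for l in net.lncrna_ids]
    values = np.zeros((len(phenotypes), net.n_lncrnas))
    for i, phenotype in enumerate(phenotypes):
        seeds = _seed_for_fold(
            net,
            phenotype,
            catalog.genes.get(phenotype, frozenset()),
            catalog.lncrnas.get(phenotype, frozenset()),
        )
        if not (seeds.phenotypes or seeds.genes or seeds.lncrnas):
            warnings.warn(
                f"phenotype {phenotype!r} has no seeds; emitting a zero row",
                stacklevel=2,
            )
            continue
        stat = propagate(
            model,
            build_seed_vector(seeds, mix, net),
            delta=delta,
            tol=tol,
            max_iter=max_iter,
        )
        values[i] = stat.scores[lnc_idx]
    return ScoreMatrix(values, list(phenotypes), list(net.lncrna_ids))


def hotspot_counts(sm: ScoreMatrix, cutoffs: Sequence[int]) -> pd.DataFrame:
    """Per-lncRNA count of phenotypes where it ranks within the top k.

    Highly counted lncRNAs are "hotspots" implicated across many diseases.
    Returns a table indexed by lncRNA with one column per cutoff.
    """
    cutoffs = [int(k) for k in cutoffs]
    if any(k < 1 for k in cutoffs):
        raise ValueError("cutoffs must be positive")
    counts = pd.DataFrame(0, index=sorted(sm.lncrna_ids), columns=cutoffs)
    order_idx = np.arange(len(sm.lncrna_ids))
    ids = np.array(sm.lncrna_ids)
    for row in sm.values:
        # rank by score descending, lexicographic id on ties
        order = sorted(order_idx, key=lambda j: (-row[j], ids[j]))
        for k in cutoffs:
            counts.loc[ids[order[:k]], k] += 1
    return counts
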