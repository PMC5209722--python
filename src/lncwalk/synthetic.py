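"""Synthetic composite networks with planted disease structure.

A layered stochastic-block-model generator: each planted disease owns one
phenotype, a gene module and a lncRNA module. Intra-module gene-gene and
lncRNA-lncRNA edges are dense (probability ``p_in``) with correlation-like
predicted weights, gene-lncRNA bridges inside a module are dense
(``q_bridge``), and background edges are sparse (``p_out`` / ``bg_bridge``).
A designated subset of each module carries experimental (weight 1)
phenotype-gene and phenotype-lncRNA associations — the "known" disease genes
and lncRNAs that cross-validation holds out. All randomness flows through a
single seeded generator, so a config maps deterministically to a network.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import AssociationCatalog
from .network import (
    GENE,
    LNCRNA,
    PHENOTYPE,
    CompositeNetwork,
    EdgeTable,
    ExpressionMatrix,
    build_composite,
    write_network,
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults define the standard benchmark fixture."""

    n_genes: int = 50
    n_phenotypes: int = 10
    n_lncrnas: int = 40
    n_diseases: int = 5
    module_size_genes: int = 6
    module_size_lncrnas: int = 5
    p_in: float = 0.6
    p_out: float = 0.02
    q_bridge: float = 0.5
    bg_bridge: float = 0.01
    predicted_weight_range: tuple[float, float] = (0.5, 0.9)
    known_genes_per_disease: int = 3
    known_lncrnas_per_disease: int = 3
    shared_module_pairs: tuple[tuple[int, int], ...] = ()
    n_samples: int = 50
    expression_noise: float = 0.3
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0 <= self.bg_bridge < self.q_bridge <= 1:
            raise ValueError("require 0 <= bg_bridge < q_bridge <= 1")
        lo, hi = self.predicted_weight_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("predicted_weight_range must be within (0, 1]")
        if self.n_diseases > self.n_phenotypes:
            raise ValueError("more diseases than phenotypes")
        if self.n_diseases * self.module_size_genes > self.n_genes:
            raise ValueError("gene modules do not fit in the gene layer")
        if self.n_diseases * self.module_size_lncrnas > self.n_lncrnas:
            raise ValueError("lncRNA modules do not fit in the lncRNA layer")
        if self.known_genes_per_disease > self.module_size_genes:
            raise ValueError("known genes per disease exceed the module size")
        if self.known_lncrnas_per_disease > self.module_size_lncrnas:
            raise ValueError("known lncRNAs per disease exceed the module size")
        for i, j in self.shared_module_pairs:
            if not (0 <= i < j < self.n_diseases):
                raise ValueError(
                    f"invalid shared module pair ({i}, {j}); require 0 <= i < j < n_diseases"
                )


@dataclass(frozen=True)
class PlantedDisease:
    phenotype_id: str
    gene_module: tuple[str, ...]
    lncrna_module: tuple[str, ...]
    known_genes: tuple[str, ...]
    known_lncrnas: tuple[str, ...]


@dataclass(eq=False)
class GroundTruth:
    """The planted structure behind a synthetic network."""

    diseases: list[PlantedDisease]
    config: SynthConfig

    def to_json(self) -> str:
        payload = {
            "diseases": [d.__dict__ for d in self.diseases],
            "config": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.config.__dict__.items()
            },
        }
        return json.dumps(payload, indent=2, default=list)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(max(n - 1, 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _draw_weight(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _plant_modules(cfg: SynthConfig, rng: np.random.Generator) -> list[PlantedDisease]:
    genes = _ids("g", cfg.n_genes)
    phens = _ids("p", cfg.n_phenotypes)
    lncs = _ids("l", cfg.n_lncrnas)
    gene_pool = list(rng.permutation(genes))
    lnc_pool = list(rng.permutation(lncs))
    shared_source = {j: i for i, j in cfg.shared_module_pairs}

    diseases: list[PlantedDisease] = []
    for d in range(cfg.n_diseases):
        if d in shared_source and shared_source[d] < d:
            src = diseases[shared_source[d]]
            gene_module = src.gene_module
            lnc_module = src.lncrna_module
        else:
            gene_module = tuple(
                sorted(gene_pool[d * cfg.module_size_genes:(d + 1) * cfg.module_size_genes])
            )
            lnc_module = tuple(
                sorted(lnc_pool[d * cfg.module_size_lncrnas:(d + 1) * cfg.module_size_lncrnas])
            )
        known_g = tuple(
            sorted(rng.choice(gene_module, cfg.known_genes_per_disease, replace=False))
        )
        known_l = tuple(
            sorted(rng.choice(lnc_module, cfg.known_lncrnas_per_disease, replace=False))
        )
        diseases.append(PlantedDisease(phens[d], gene_module, lnc_module, known_g, known_l))
    return diseases


def generate_network(
    cfg: SynthConfig,
) -> tuple[CompositeNetwork, AssociationCatalog, GroundTruth]:
    """Generate a composite network, its known-association catalog and the
    planted ground truth. Deterministic given ``cfg.rng_seed``."""
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _ids("g", cfg.n_genes)
    phens = _ids("p", cfg.n_phenotypes)
    lncs = _ids("l", cfg.n_lncrnas)
    diseases = _plant_modules(cfg, rng)

    same_gene_module: set[frozenset[str]] = set()
    same_lnc_module: set[frozenset[str]] = set()
    bridged: set[tuple[str, str]] = set()
    for d in diseases:
        for a, b in itertools.combinations(d.gene_module, 2):
            same_gene_module.add(frozenset((a, b)))
        for a, b in itertools.combinations(d.lncrna_module, 2):
            same_lnc_module.add(frozenset((a, b)))
        for g in d.gene_module:
            for l in d.lncrna_module:
                bridged.add((g, l))

    lo, hi = cfg.predicted_weight_range

    def intra_records(ids: list[str], module_pairs: set[frozenset[str]]):
        records = []
        for a, b in itertools.combinations(ids, 2):
            prob = cfg.p_in if frozenset((a, b)) in module_pairs else cfg.p_out
            if rng.random() < prob:
                records.append((a, b, _draw_weight(rng, lo, hi), "predicted"))
        return records

    gg = intra_records(genes, same_gene_module)
    ll = intra_records(lncs, same_lnc_module)

    gl = []
    for g in genes:
        for l in lncs:
            prob = cfg.q_bridge if (g, l) in bridged else cfg.bg_bridge
            if rng.random() < prob:
                gl.append((g, l, _draw_weight(rng, lo, hi), "predicted"))

    gp = []
    pl = []
    for d in diseases:
        for g in d.known_genes:
            gp.append((g, d.phenotype_id, 1.0, "experimental"))
        for l in d.known_lncrnas:
            pl.append((d.phenotype_id, l, 1.0, "experimental"))

    pp = []
    for i, j in cfg.shared_module_pairs:
        a, b = diseases[i].phenotype_id, diseases[j].phenotype_id
        pp.append((a, b, _draw_weight(rng, lo, hi), "predicted"))

    tables = {
        "gene-gene": EdgeTable.from_records("gene-gene", gg),
        "phenotype-phenotype": EdgeTable.from_records("phenotype-phenotype", pp),
        "lncrna-lncrna": EdgeTable.from_records("lncrna-lncrna", ll),
        "gene-phenotype": EdgeTable.from_records("gene-phenotype", gp),
        "gene-lncrna": EdgeTable.from_records("gene-lncrna", gl),
        "phenotype-lncrna": EdgeTable.from_records("phenotype-lncrna", pl),
    }
    net = build_composite(
        tables, node_universes={GENE: genes, PHENOTYPE: phens, LNCRNA: lncs}
    )
    catalog = AssociationCatalog(
        {d.phenotype_id: frozenset(d.known_lncrnas) for d in diseases},
        {d.phenotype_id: frozenset(d.known_genes) for d in diseases},
    )
    return net, catalog, GroundTruth(diseases, cfg)


def generate_expression(cfg: SynthConfig) -> ExpressionMatrix:
    """Module-correlated lognormal expression profiles for genes and lncRNAs.

    Members of the same planted module share a latent per-sample profile plus
    independent noise of scale ``expression_noise``; background entities are
    independent. With zero noise, within-module Pearson correlations are
    exactly 1.
    """
    if cfg.n_samples < 3:
        raise ValueError("at least 3 samples are required")
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _ids("g", cfg.n_genes)
    lncs = _ids("l", cfg.n_lncrnas)
    diseases = _plant_modules(cfg, rng)

    module_of: dict[str, int] = {}
    seen_modules: dict[tuple[str, ...], int] = {}
    for d in diseases:
        key = d.gene_module + d.lncrna_module
        idx = seen_modules.setdefault(key, len(seen_modules))
        for e in key:
            module_of[e] = idx
    latents = rng.standard_normal((len(seen_modules), cfg.n_samples))

    entity_ids = genes + lncs
    values = np.empty((len(entity_ids), cfg.n_samples))
    for i, e in enumerate(entity_ids):
        if e in module_of:
            base = latents[module_of[e]]
            signal = base + cfg.expression_noise * rng.standard_normal(cfg.n_samples)
        else:
            signal = rng.standard_normal(cfg.n_samples)
        baseline = rng.uniform(0.0, 2.0)
        values[i] = np.exp(baseline + signal)  # FPKM-like positive scale
    layers = {e: (GENE if e in set(genes) else LNCRNA) for e in entity_ids}
    return ExpressionMatrix(entity_ids, _ids("s", cfg.n_samples), values, layers)


def write_fixture(cfg: SynthConfig, outdir: str | Path) -> None:
    """Materialize a synthetic fixture: network TSVs, catalog and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, catalog, truth = generate_network(cfg)
    write_network(net, outdir)
    catalog.to_tsv(outdir / "associations.tsv")
    (outdir / "ground_truth.json").write_text(truth.to_json())
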