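# lncwalk

Prioritize disease candidate long non-coding RNAs (lncRNAs) by network
propagation on a three-layer composite network.

Most lncRNAs have no known disease role, and experimental validation is
expensive, so candidate lists from differential expression or GWAS need
ranking before follow-up. `lncwalk` ranks candidate lncRNAs for a disease
phenotype of interest under the guilt-by-association assumption that
functionally related lncRNAs and genes act in phenotypically similar
diseases. It integrates three node layers — genes, disease phenotypes and
lncRNAs — connected by six weighted association blocks (gene–gene
interaction, phenotype–phenotype similarity, lncRNA–lncRNA co-expression,
gene–phenotype, gene–lncRNA and phenotype–lncRNA links; weight 1 for
experimentally validated edges, correlation-valued weights for predicted
ones), and scores candidates by a random walk with restart over the whole
composite network.

## Model

Let W_G, W_P, W_L be the intra-layer adjacency blocks and W_GP, W_GL, W_PL
the cross-layer blocks. A row-stochastic transition matrix M is built per
node: a cross-layer block in which the node has edges receives exactly the
jump probability of that layer pair (x for gene↔phenotype, y for
gene↔lncRNA, z for phenotype↔lncRNA), split proportionally to edge weights,
and the intra-layer block receives the remaining mass; rows left with
positive but sub-unit mass are rescaled to sum to 1, and edge-free nodes
keep zero (dangling) rows.

The seed distribution p⁰ mixes the query phenotype (S^P), its known disease
genes (S^G) and known disease lncRNAs (S^L): each layer's seeds share that
layer's probability uniformly, and the layers are weighted α (genes),
β (phenotypes) and 1−α−β (lncRNAs). The walk iterates

    p^{t+1} = (1 − δ) Mᵀ p^t + δ p⁰

with restart probability δ until the L1 difference of successive iterates
falls below 10⁻¹⁰; candidates are ranked by their stationary lncRNA scores
w∞. Defaults: δ = 0.7 and x = y = z = α = β = 1/3.

Evaluation is leave-one-out cross-validation: each known phenotype–lncRNA
link is removed in turn and the held-out lncRNA must be re-ranked highly
among all non-seed lncRNAs; pooled ROC/AUC, top-k recall, layer-ablation
baselines, parameter sweeps, a phenotype × lncRNA score landscape and
hotspot counts are provided. A layered stochastic-block-model generator
produces benchmark networks with planted disease modules so everything is
testable without external downloads.

## Worked example

```python
import lncwalk as lw

# a planted benchmark: 50 genes, 10 phenotypes, 40 lncRNAs, 5 diseases
net, catalog, truth = lw.generate_network(lw.SynthConfig())

# rank candidates for one disease phenotype
d = truth.diseases[0]
seeds = lw.SeedSet(phenotypes={d.phenotype_id},
                   genes=set(d.known_genes), lncrnas=set(d.known_lncrnas))
model = lw.build_transition(net, lw.JumpParams())
stat = lw.propagate(model, lw.build_seed_vector(seeds, lw.MixWeights(), net))
candidates = [l for l in net.lncrna_ids if l not in seeds.lncrnas]
for rec in list(lw.rank_candidates(stat, candidates))[:3]:
    print(rec.rank, rec.lncrna_id, round(rec.score, 4))

# cross-validate the whole catalog
cv = lw.loocv(net, catalog)
print("AUC", round(cv.auc, 3), "mean percentile", round(cv.mean_percentile, 3))
```

prints

```
1 l18 0.0183
2 l32 0.0064
3 l24 0.0036
AUC 0.966 mean percentile 0.034
```

The two top-ranked candidates (l18, l32) are the first planted disease's
non-seed lncRNA module members — exactly the "unknown" disease lncRNAs the
walk is supposed to surface — and the pooled
cross-validation AUC of 0.966 means a held-out known lncRNA outranks a
random non-associated lncRNA about 97% of the time on this benchmark.

The same workflow is available from the shell:

```sh
lncwalk simulate --out net/
lncwalk rank --network net/ --seeds seeds.tsv --out ranks.tsv
lncwalk loocv --network net/ --associations net/associations.tsv --out cv.tsv
lncwalk landscape --network net/ --associations net/associations.tsv --out scores.tsv
lncwalk sweep --network net/ --associations net/associations.tsv \
        --grid '{"delta": [0.5, 0.7, 0.9]}' --out sweep.tsv
```

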