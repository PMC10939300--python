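# eabench

Balanced benchmarking of pathway enrichment analysis (EA) methods.

Given case/control gene expression datasets and a pathway collection, EA
methods report which pathways are affected. Benchmarks of such methods have
traditionally treated a single "target" pathway per dataset as the only true
positive and ignored specificity, which favours conservative methods.
`eabench` implements a generalized alternative built on two ideas:

1. **A disease pathway network (DPN).** Pathways related to a dataset's
   target pathway also count as true positives. Two pathways *A*, *B* are
   linked when both their gene overlap (Jaccard index
   *J(A,B) = |A∩B| / |A∪B|*) and their inter-pathway connectivity in a
   functional association network

   *IPC(A,B) = DL(A,B) + SN(A,B)*

   (direct links plus shared neighbours) are significant against a
   **degree-aware subsampling null**: one side is repeatedly replaced by a
   random gene set drawn bin-wise from genes of similar network degree.
   Directional empirical p-values are combined with Fisher's method, edges
   are gated at BH-FDR < 0.05 on *both* statistics, weighted by Wang
   graph-based semantic similarity, and pruned to each target's top-20
   neighbours.

2. **Independent positive and negative benchmarks.** Sensitivity
   (TPR = TP/(TP+FN)) comes from real (or simulated) datasets; specificity
   (TNR = TN/(TN+FP)) from gene-label-randomized copies of the same
   datasets, evaluated on the same positive pathway lists so the two sides
   are balanced. Methods are summarized by the geometric mean
   **G-mean = √(TPR·TNR)** and by tie-averaged relative ranks, and their
   null behaviour is profiled per pathway (false positive rate, p-value
   skew) and correlated with pathway network properties such as the
   intralink fraction — community-like pathways are where crosstalk tests
   with misspecified nulls break down.

The package is aimed at method developers and users who want to stress-test
an EA method (their own, or a published one supplied as a p-value matrix)
under controlled, fully synthetic conditions — no downloads required: the
`synthetic` module generates networks, pathway collections with planted
related pairs, expression data with planted differential expression, and
toy ontology DAGs.

## Worked example

```python
import numpy as np
import eabench as e

spec = e.SyntheticSpec(seed=0)              # 2000 genes, 20 pathways, 3 related pairs
net = e.make_network(spec)                  # heavy-tailed functional network
collection, truth = e.plant_pathways(net, spec)

table = e.pairwise_stats(collection, net, n_samples=400, seed=0, universe=net.nodes)
accepted = table[(table.q_conn < 0.05) & (table.q_olap < 0.05)]
print(accepted[["pathway_a", "pathway_b", "IPC", "J", "q_conn", "q_olap"]])
print("planted:", truth)
```

Output:

```
   pathway_a pathway_b  IPC         J    q_conn    q_olap
0       P000      P001  280  0.313253  0.007673  0.005115
37      P002      P003  307  0.214286  0.030443  0.005115
70      P004      P005  566  0.183673  0.007673  0.005115
planted: [('P000', 'P001'), ('P002', 'P003'), ('P004', 'P005')]
```

All three planted related pairs — and nothing else — pass both the
connectivity and the overlap gate (`q_conn`, `q_olap` are the BH-adjusted
Fisher-combined subsampling p-values; `IPC` counts direct links plus shared
neighbours; `J` is the gene-overlap Jaccard index). `e.assemble(...)` then
turns the accepted pairs into a DPN with semantic-similarity edge weights,
and `e.run_battery(...)` / the `eabench.benchmark` functions score
enrichment methods against it.

A command-line interface mirrors the stages:

```bash
eabench simulate --out study/ --seed 0 --n-datasets 2
eabench deg --matrix study/P000_d0.matrix.tsv --design study/P000_d0.design.tsv --out deg0
eabench similarity --gmt study/pathways.gmt --dag study/term_dag.tsv \
    --annotations study/annotations.tsv --out sim.tsv
eabench build-network --gmt study/pathways.gmt --network study/network.tsv \
    --targets P000 --similarity-matrix sim.tsv --seed 0 --out dpn
eabench run --methods fisher,ease --gmt study/pathways.gmt \
    --network study/network.tsv --datasets-dir study/ --out results/
```

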