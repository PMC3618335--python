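# coexnet

Partial-correlation gene co-expression networks: inference, structure
analysis, and phenotype association with network spatial statistics.

## The problem

Given a modest expression study — a few hundred genes measured on a few
dozen individuals, say 272 eQTL-controlled transcripts on 56 animals with a
quantitative phenotype such as muscle pH — how do you extract the direct
co-regulation structure, its functional modules, and the parts of that
structure tied to the phenotype?  Marginal correlations conflate direct and
indirect co-expression; `coexnet` instead works in the Gaussian graphical
model (GGM) framework, where the network is defined by *partial*
correlations

ρ<sub>ij</sub> = −Ω<sub>ij</sub> / √(Ω<sub>ii</sub> Ω<sub>jj</sub>),  Ω = Σ⁻¹,

the correlation between genes *i* and *j* given all other genes.  Because
n ≪ p makes Σ̂ singular, the estimator shrinks the covariance toward its
diagonal with an analytic variance-minimising intensity, aggregates over
bootstrap resamples (4,000 resamples of size 20 by default), and calls
significant edges with an empirical-null mixture: null density
f₀(r) ∝ (1−r²)^((κ−3)/2) plus a uniform alternative, retaining pairs whose
local false-discovery score is ≤ 0.2.

On the resulting graph the package computes hubs and betweenness, clusters
nodes by simulated-annealing modularity optimisation

Q = Σ<sub>c</sub> [ e<sub>c</sub>/m − (D<sub>c</sub>/2m)² ]

and by kernel k-means / batch kernel SOM on heat (e^(−βL)) and commute-time
(L⁺) kernels, selecting the best partition by Q.  The phenotype is brought
in through per-gene partial correlations with the trait, analysed as a node
attribute with spatial statistics: Moran's I with a permutation test, the
Moran scatterplot with Cook's-distance influential genes, and a per-cluster
Welch t-test on |ρ| at level 1%.

A synthetic-data module plants all of this structure (sparse block
precision matrix, phenotype driven by one module) so that every stage can
be validated against ground truth.

## Worked example

```python
import coexnet as cx

# study-shaped simulation: 272 genes, 7 modules, 56 samples,
# phenotype driven by module 4
truth, expr, pheno = cx.simulate_study(seed=1)

model = cx.CoexpressionGGM(expr, pheno)
res = model.fit(n_bootstrap=300, bootstrap_size=20, seed=5)
print(res.summary())
```

```
Co-expression Gaussian graphical model
================================================
genes:                 272
samples:               56
bootstrap replicates:  300 (size 20)
significance cutoff:   0.2 (local fdr)
null proportion eta0:  0.993
null kappa:            21572.1
edges retained:        27
density (ordered):     0.0%
phenotype attached:    True
```

At these sample sizes the estimator is deliberately conservative: 27 edges
are called, 26 of which are true planted conditional dependencies
(precision 0.96 against `truth.support()`).  The Moran stage then asks
whether phenotype correlations align with the network:

```python
G = res.network()
moran = cx.MoranTest(G, res.phenotype_pcor.to_series()).fit(seed=2)
print(moran.summary())
```

On the planted truth graph the per-cluster t-test flags module 4 — and only
module 4 — and about two thirds of the Cook's-distance influential genes
lie in that module.

The same analysis runs from the shell:

```sh
coexnet simulate --genes 272 --modules 7 --samples 56 --seed 1 --out-dir data/
coexnet run-all --out-dir results/ --seed 1
```

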