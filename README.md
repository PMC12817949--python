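# ecoassembly

Microbial community-assembly analysis for amplicon surveys: null-model
partitioning of assembly processes, dissimilarity-overlap curves, niche
breadth/overlap metrics, and thresholded co-occurrence networks — plus a
synthetic metacommunity generator with planted assembly processes so the
entire pipeline can be validated without any sequencing data.

## Who this is for

Microbial ecologists asking *why* communities differ between habitats —
for example, biofilms colonising different weathering states of a stone
surface. Given a taxon x sample count table, a rooted phylogeny, and a
sample -> group map, the package quantifies how much of the observed
turnover is attributable to deterministic selection versus stochastic
dispersal and drift, whether the communities share universal interspecific
dynamics, how specialised their members are, and how their putative
interaction networks differ between groups.

## The methods

**Assembly partitioning (betaNTI + RCbray).** For each sample pair the
beta mean nearest taxon distance

    betaMNTD(j,k) = 0.5 [ Σ_i f_ij · min_{i'∈k} d(i,i') + Σ_i f_ik · min_{i'∈j} d(i,i') ]

is standardised against a 999-fold tip-shuffling null to give betaNTI.
betaNTI > 2 ⇒ heterogeneous selection, betaNTI < −2 ⇒ homogeneous
selection. Remaining pairs are classified by the Bray-Curtis Raup-Crick
metric, which rebuilds both communities probabilistically (richness and
total reads preserved; entry ∝ occurrence frequency, abundance ∝ regional
relative abundance): RCbray > 0.95 ⇒ dispersal limitation, RCbray < −0.95
⇒ homogenizing dispersal, |RCbray| ≤ 0.95 ⇒ drift.

**Dissimilarity-overlap curve (DOC).** One point per sample pair: overlap
O = Σ_{shared} (x_i + y_i)/2 against the root Jensen-Shannon divergence of
the profiles renormalised over shared taxa. A LOWESS fit with a
sample-level bootstrap locates the change point xc beyond which the median
bootstrap slope is negative, the fraction Fns of pairs beyond it, and a
one-sided p-value for the negative slope.

**Niche metrics.** Samples are the habitat states: Levins breadth
B = 1/Σp², Shannon breadth H = −Σ p ln p, Schoener and Pianka overlap
between taxa, abundance-weighted community breadth Bcom per sample, and
specialist (B < 1.5) / middle / generalist (B > 5) classification.

**Co-occurrence networks.** Spearman correlations over the top-400 most
abundant taxa; edges need |r| > 0.75 and p < 0.001 (t-approximation).
Group subnetworks are extracted from the global network and summarised by
density, mean degree, transitivity, Freeman degree centralization, and the
proportion of negative edges.

**Beta-diversity tests.** Bray-Curtis distances with one-way ANOSIM and
PERMANOVA, permutation p-values with the (1+k)/(1+n) estimator.

## Worked example

Partition assembly processes for a synthetic metacommunity assembled under
heterogeneous selection (`examples/assembly_partition.py`):

```python
from ecoassembly import (NullModelConfig, SimulationScenario, bnti,
                         partition_processes, raup_crick_bray, simulate_scenario)

scenario = SimulationScenario("heterogeneous_selection", n_taxa=200,
                              n_samples=16, groups=("A", "B", "C", "D"),
                              reads_per_sample=1000, seed=3)
table, meta, tree, traits, _ = simulate_scenario(scenario)
config = NullModelConfig(n_randomizations=999, seed=0)
partition = partition_processes(bnti(table, tree, config),
                                raup_crick_bray(table, config))
```

Output:

```
heterogeneous selection    80.67 %
homogeneous selection      15.97 %
dispersal limitation        0.00 %
homogenizing dispersal      1.68 %
drift                       1.68 %
modal process: heterogeneous selection
deterministic share: 96.64 %
```

The planted process dominates: most pairs straddle contrasting
environmental filters, so their phylogenetic turnover exceeds the null
(betaNTI > 2); the within-group remainder shows the shared-filter
signature (betaNTI < −2). The other capabilities have one example each in
`examples/` (DOC, niche classification, networks, ANOSIM/PERMANOVA,
generator).

A shell entry point wraps the same library:

```sh
ecoassembly simulate --scenario dispersal_limitation --out sim/
ecoassembly all config.yaml      # or: betadiv / assembly / doc / niche / network
```

with a YAML config naming the table/tree/metadata paths and any threshold
overrides; every run writes per-stage TSVs, a consolidated `report.json`,
and a manifest that reproduces the run bit-for-bit.

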