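"""Synthetic metacommunities with planted assembly processes.

The generator emulates the sampling design of a small stone-surface
microbiome survey — 27 samples in 4 groups (CK, Black, Green, White), a few
hundred taxa, and amplicon-scale sequencing depth — while planting a known
assembly process so every downstream analysis can be validated end to end:

* ``heterogeneous_selection``: traits evolve on a Yule phylogeny under an
  early-burst Brownian model (variance concentrated at deep splits, so
  trait similarity tracks clade membership); Gaussian environmental
  filters with strongly contrasting optima between groups then produce
  excess phylogenetic turnover between groups (betaNTI > 2);
* ``homogeneous_selection``: the same filter with a single shared optimum
  anchored on a well-populated region of trait space, so all communities
  draw from one clade and phylogenetic turnover falls below the null
  (betaNTI < -2);
* ``dispersal_limitation`` / ``homogenizing_dispersal``: neutral
  (trait-blind) sampling from patch-specific pools coupled by a migration
  rate m; low m leaves patches compositionally isolated (RCbray > 0.95
  between patches), high m homogenises them (RCbray < -0.95);
* ``drift``: every sample drifts independently from one shared regional
  pool (Dirichlet-perturbed multinomial), leaving turnover within the null
  expectation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .core_io import CommunityTable, SampleMetadata

__all__ = [
    "SimulationScenario",
    "SCENARIOS",
    "simulate_tree",
    "simulate_traits",
    "simulate_communities",
    "simulate_scenario",
]

SCENARIOS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

#: planted process -> the assembly-process label the null models should infer
PLANTED_PROCESS = {
    "heterogeneous_selection": "heterogeneous selection",
    "homogeneous_selection": "homogeneous selection",
    "dispersal_limitation": "dispersal limitation",
    "homogenizing_dispersal": "homogenizing dispersal",
    "drift": "drift",
}


@dataclass
class SimulationScenario:
    """Knobs of one synthetic metacommunity.

    Defaults mirror the emulated survey: 27 samples in groups CK/Black/
    Green/White (CK keeps the smaller share), 500 taxa, and a sequencing
    depth at the lower end of the survey's rarefaction depths. Which knobs
    act depends on the scenario: ``trait_sigma`` and ``filter_width`` drive
    the selection scenarios, ``migration_rate`` and ``n_patches`` the
    dispersal scenarios, ``drift_concentration`` the drift scenario.
    """

    scenario: str
    n_taxa: int = 500
    n_samples: int = 27
    groups: tuple[str, ...] = ("CK", "Black", "Green", "White")
    reads_per_sample: int = 13622
    trait_sigma: float = 1.0  # Brownian-motion rate along the tree
    trait_acdc: float = -2.0  # early-burst rate for the filtering trait
    filter_width: float | None = None  # None -> 0.15 x realized trait sd
    richness_per_sample: int | None = None  # selection scenarios; None -> ~7.5% of taxa
    occupancy_evenness: float = 2.0  # Dirichlet mass per occupant (selection)
    migration_rate: float | None = None  # None -> 0.02 (limitation) / 0.98 (homogenizing)
    n_patches: int | None = None  # None -> one patch per group
    drift_concentration: float = 100.0  # Dirichlet mass for the drift scenario
    abundance_lognormal_sigma: float = 1.0  # regional abundance heterogeneity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if self.migration_rate is not None and not 0 <= self.migration_rate <= 1:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.n_samples < len(self.groups):
            raise ValueError("need at least one sample per group")

    @property
    def effective_migration(self) -> float:
        if self.migration_rate is not None:
            return self.migration_rate
        return 0.02 if self.scenario == "dispersal_limitation" else 0.98

    def group_sizes(self) -> dict[str, int]:
        k = len(self.groups)
        base = self.n_samples // k
        extra = self.n_samples % k
        # remainder goes to the later groups so the first (control) group
        # keeps the smaller share, as in the emulated survey (6 + 7 + 7 + 7)
        return {
            g: base + (1 if i >= k - extra else 0) for i, g in enumerate(self.groups)
        }


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit birth rate and tips T0001, T0002, ...

    Branch lengths are in expected substitutions under the unit-rate clock;
    all are strictly positive.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # the simulator stops at the instant of the n-th birth, leaving the two
    # newest tips with zero-length edges; run the clock on to just before
    # the next (uncounted) birth so every terminal branch is positive
    extra = rng.expovariate(n_taxa * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # time before the crown split carries no information about the tips
    tree.seed_node.edge.length = 0.0
    width = max(4, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:0{width}d}"
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def simulate_traits(
    tree: dendropy.Tree, sigma: float, seed: int, acdc: float = 0.0
) -> pd.Series:
    """Brownian-motion trait per tip: root value 0, increment variance
    sigma^2 x branch length along every edge.

    ``acdc`` applies an accelerating/decelerating-rate transform: the
    instantaneous rate at depth t from the root is sigma^2 exp(acdc * t),
    so a negative value gives an early burst in which most trait variance
    accumulates at deep splits and trait similarity tracks clade
    membership. ``acdc=0`` is plain Brownian motion.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    node_value: dict[int, float] = {}
    traits = {}
    for node in tree.preorder_node_iter():
        parent_value = node_value.get(id(node.parent_node), 0.0)
        if node.parent_node is None:
            value = 0.0
        else:
            t0 = depth[id(node.parent_node)]
            t1 = depth[id(node)]
            if acdc == 0.0:
                var = sigma**2 * (t1 - t0)
            else:
                var = sigma**2 * (np.exp(acdc * t1) - np.exp(acdc * t0)) / acdc
            value = parent_value + (rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0)
        node_value[id(node)] = value
        if node.is_leaf():
            traits[node.taxon.label] = value
    return pd.Series(traits, name="trait")


def simulate_communities(
    scenario: SimulationScenario,
    tree: dendropy.Tree,
    traits: pd.Series | None = None,
) -> tuple[CommunityTable, SampleMetadata, dict]:
    """Draw a counts table + metadata with the scenario's planted process.

    Returns the table (taxa x samples, every sample summing to
    ``reads_per_sample``), the sample -> group metadata, and a manifest
    echoing the generating parameters (sufficient to reproduce the draw).
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(taxa) != scenario.n_taxa:
        raise ValueError(
            f"tree has {len(taxa)} tips but scenario expects {scenario.n_taxa}"
        )
    needs_traits = scenario.scenario in (
        "heterogeneous_selection",
        "homogeneous_selection",
    )
    if needs_traits and traits is None:
        raise ValueError(f"scenario {scenario.scenario!r} requires traits")

    rng = np.random.default_rng(scenario.seed)
    n_taxa = scenario.n_taxa
    sizes = scenario.group_sizes()
    sample_groups: list[str] = []
    for g in scenario.groups:
        sample_groups.extend([g] * sizes[g])
    sample_ids = [f"S{i + 1:03d}" for i in range(scenario.n_samples)]

    # heavy-tailed regional abundance profile shared by all scenarios
    base = rng.lognormal(0.0, scenario.abundance_lognormal_sigma, size=n_taxa)
    base /= base.sum()

    if needs_traits:
        tr = traits.reindex(taxa).to_numpy(dtype=float)
        if np.any(np.isnan(tr)):
            raise ValueError("traits missing for some tree tips")
        sd = tr.std()
        width = scenario.filter_width if scenario.filter_width is not None else 0.15 * sd
        rich = scenario.richness_per_sample or max(10, round(0.1 * n_taxa))
        rich = min(rich, n_taxa)
        # optima are anchored on actual tip trait values so that each filter
        # sits on a clade (the early-burst trait makes trait neighbourhoods
        # clade-like); a homogeneous optimum is additionally drawn from a
        # trait region that is both well populated and phylogenetically
        # coherent — a filter selecting a sparse or convergent trait band
        # exerts no detectable phylogenetic selection at this tree size
        if scenario.scenario == "homogeneous_selection":
            from .assembly import patristic_matrix

            dist = patristic_matrix(tree, taxa)
            density = np.array([np.sum(np.abs(tr - t) < width) for t in tr])
            tightness = np.empty(n_taxa)
            for i in range(n_taxa):
                nb = np.argsort(np.abs(tr - tr[i]))[:rich]
                tightness[i] = dist[np.ix_(nb, nb)].mean()
            score = density / np.median(density) - tightness / np.median(tightness)
            candidates = np.flatnonzero(score >= np.quantile(score, 0.85))
            anchor = int(rng.choice(candidates))
            env_by_group = {g: float(tr[anchor]) for g in scenario.groups}
        else:
            order = np.argsort(tr)
            qs = np.linspace(0.05, 0.95, len(scenario.groups))
            env_by_group = {
                g: float(tr[order[int(q * (n_taxa - 1))]])
                for g, q in zip(scenario.groups, qs)
            }
        # community assembly under selection with drift: each sample is
        # colonised by `rich` taxa drawn without replacement in proportion
        # to their Gaussian filter weight, with Dirichlet abundance drift
        # among the occupants; deterministic weighting alone would make
        # same-optimum samples compositionally identical and the turnover
        # nulls degenerate
        alpha = scenario.occupancy_evenness
        cols = []
        for g in sample_groups:
            w = np.exp(-((tr - env_by_group[g]) ** 2) / (2.0 * width**2))
            keys = np.log(w + 1e-300) + rng.gumbel(size=n_taxa)
            occupants = np.argpartition(-keys, rich - 1)[:rich]
            p = np.zeros(n_taxa)
            p[occupants] = rng.dirichlet(np.full(rich, alpha))
            cols.append(p)
        probs = np.column_stack(cols)
        extra_manifest = {
            "env_by_group": env_by_group,
            "filter_width": float(width),
            "richness_per_sample": int(rich),
        }
    elif scenario.scenario in ("dispersal_limitation", "homogenizing_dispersal"):
        m = scenario.effective_migration
        n_patches = scenario.n_patches or len(scenario.groups)
        patch_of_group = {
            g: i % n_patches for i, g in enumerate(scenario.groups)
        }
        patch_pools = rng.lognormal(0.0, 1.5, size=(n_patches, n_taxa)) * base
        patch_pools /= patch_pools.sum(axis=1, keepdims=True)
        regional = patch_pools.mean(axis=0)
        mixed = (1.0 - m) * patch_pools + m * regional
        mixed /= mixed.sum(axis=1, keepdims=True)
        probs = np.column_stack(
            [mixed[patch_of_group[g]] for g in sample_groups]
        )
        extra_manifest = {
            "migration_rate": m,
            "n_patches": n_patches,
            "patch_of_group": patch_of_group,
        }
    else:  # drift
        alpha = scenario.drift_concentration * base
        probs = np.column_stack(
            [rng.dirichlet(alpha) for _ in range(scenario.n_samples)]
        )
        extra_manifest = {"drift_concentration": scenario.drift_concentration}

    counts = np.column_stack(
        [
            rng.multinomial(scenario.reads_per_sample, probs[:, j])
            for j in range(scenario.n_samples)
        ]
    )
    table = CommunityTable(
        pd.DataFrame(counts, index=taxa, columns=sample_ids), mode="counts"
    )
    meta = SampleMetadata(pd.Series(sample_groups, index=sample_ids, name="group"))
    manifest = {**asdict(scenario), **extra_manifest}
    return table, meta, manifest


def simulate_scenario(
    scenario: SimulationScenario,
) -> tuple[CommunityTable, SampleMetadata, dendropy.Tree, pd.Series, dict]:
    """Convenience wrapper: tree + traits + communities from one scenario.

    Child seeds for the tree, traits and community draw are derived from
    ``scenario.seed`` so one integer reproduces the whole dataset.
    """
    ss = np.random.SeedSequence(scenario.seed)
    tree_seed, trait_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    tree = simulate_tree(scenario.n_taxa, tree_seed)
    traits = simulate_traits(
        tree, scenario.trait_sigma, trait_seed, acdc=scenario.trait_acdc
    )
    table, meta, manifest = simulate_communities(scenario, tree, traits)
    return table, meta, tree, traits, manifest
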