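"""Synthetic interactomes, planted disease modules, and toy fixtures.

Real disease genes of one family tend to sit in densely interconnected
neighborhoods ("disease modules") of the interactome and therefore share
many graphlets. The generator emulates exactly that structure: a sparse
scale-free background network (preferential attachment, as protein-protein
interaction networks are commonly modeled) plus a number of planted modules
whose member genes receive extra mutual edges with a stated probability.
Each module becomes one disease family: the module members are the known
disease genes ``D`` and the candidate set ``C`` is ``D`` plus randomly
drawn decoy genes standing in for other genes in the disease loci.

All randomness flows from the single ``seed`` field of
:class:`SimulationConfig`; a fixed seed reproduces the benchmark exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .network import InteractionNetwork
from .scoring import DiseaseFamily
from .data_io import largest_component

__all__ = [
    "SimulationConfig",
    "generate_interactome",
    "plant_disease_modules",
    "generate_benchmark",
    "null_benchmark",
    "train_test_benchmark",
    "protocol_fixture",
    "schema_fixtures",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    Defaults are sized so that a full leave-one-out evaluation runs in about
    a minute while leaving enough leave-outs (80) for stable pooled curves:
    a 500-gene scale-free background with attachment 7 (mean degree about
    14, matching the density of curated integrated interactomes), ten
    8-gene modules whose members are additionally wired with probability
    0.8 (near-cliques, the strong-module regime), and 50 decoy candidates
    per family.
    """

    n_genes: int = 500
    attachment: int = 7           # edges per new node (preferential attachment)
    model: str = "ba"             # "ba" (scale-free) or "er" (uniform random)
    er_p: float = 0.01            # edge probability when model == "er"
    n_families: int = 10
    module_size: int = 8
    p_within: float = 0.8         # extra within-module edge probability
    n_decoys: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_within <= 1.0:
            raise ValueError("p_within must be in [0, 1]")
        if not 0.0 <= self.er_p <= 1.0:
            raise ValueError("er_p must be in [0, 1]")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if self.model not in ("ba", "er"):
            raise ValueError(f"unknown model {self.model!r}")


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


def generate_interactome(config: SimulationConfig) -> InteractionNetwork:
    """Seeded random interactome; the largest connected component is returned."""
    if config.model == "ba":
        if config.attachment >= config.n_genes:
            raise ValueError("attachment must be smaller than n_genes")
        g = nx.barabasi_albert_graph(config.n_genes, config.attachment,
                                     seed=config.seed)
    else:
        g = nx.gnp_random_graph(config.n_genes, config.er_p, seed=config.seed)
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})
    net = InteractionNetwork.from_networkx(g)
    if len(net) == 0 or net.number_of_edges() == 0:
        raise ValueError("generated network has no edges; "
                         "increase density parameters")
    return largest_component(net)


def plant_disease_modules(net: InteractionNetwork, config: SimulationConfig
                          ) -> tuple[InteractionNetwork, list[DiseaseFamily]]:
    """Plant disease modules and assemble their families.

    Module gene sets are disjoint across families. Within each module every
    absent gene pair receives an edge with probability ``p_within``; with
    ``p_within = 0`` the modules are indistinguishable from background (the
    null model). Returns the augmented network together with the families —
    planting adds edges, so a new network instance is produced rather than
    mutating the input.
    """
    rng = np.random.default_rng(config.seed + 1)
    nodes = sorted(net.nodes)
    need = config.n_families * config.module_size
    if need > len(nodes):
        raise ValueError(
            f"{config.n_families} disjoint modules of size "
            f"{config.module_size} need {need} genes; network has {len(nodes)}")
    chosen = rng.choice(len(nodes), size=need, replace=False)
    g = net.to_networkx()
    families: list[DiseaseFamily] = []
    for f in range(config.n_families):
        module = sorted(nodes[i] for i in
                        chosen[f * config.module_size:(f + 1) * config.module_size])
        for a_i, u in enumerate(module):
            for v in module[a_i + 1:]:
                if not g.has_edge(u, v) and rng.random() < config.p_within:
                    g.add_edge(u, v)
        decoy_pool = sorted(set(nodes) - set(module))
        n_decoys = min(config.n_decoys, len(decoy_pool))
        decoys = [decoy_pool[i] for i in
                  rng.choice(len(decoy_pool), size=n_decoys, replace=False)]
        families.append(DiseaseFamily(
            family_id=f"fam{f:02d}",
            known_genes=frozenset(module),
            candidates=frozenset(module) | frozenset(decoys),
        ))
    return InteractionNetwork.from_networkx(g), families


def generate_benchmark(config: SimulationConfig | None = None
                       ) -> tuple[InteractionNetwork, list[DiseaseFamily]]:
    """Background network plus planted disease families, in one call."""
    config = config if config is not None else SimulationConfig()
    net = generate_interactome(config)
    return plant_disease_modules(net, config)


def null_benchmark(config: SimulationConfig | None = None
                   ) -> tuple[InteractionNetwork, list[DiseaseFamily]]:
    """The same benchmark with no within-module wiring (p_within = 0)."""
    config = config if config is not None else SimulationConfig()
    return generate_benchmark(replace(config, p_within=0.0))


_TRAIN_SEED_OFFSET = 104729  # fixed prime: training split gets its own stream


def train_test_benchmark(config: SimulationConfig | None = None, *,
                         train_factor: int = 3) -> tuple[
    tuple[InteractionNetwork, list[DiseaseFamily]],
    tuple[InteractionNetwork, list[DiseaseFamily]],
]:
    """Independent training and test realizations of the benchmark.

    Isomer-weight regression is trained on disease families disjoint from
    those it is evaluated on, as in a held-out cross-validation split where
    the training portion is several times the test portion. Here the
    training split is an independent draw of the same generative conditions
    (seeded from the config's seed plus a fixed offset) with
    ``train_factor`` times as many families, so weights never see the
    evaluated network and are estimated from a comfortably larger sample.
    Returns ``((train_net, train_families), (test_net, test_families))``.
    """
    config = config if config is not None else SimulationConfig()
    train_cfg = replace(config, seed=config.seed + _TRAIN_SEED_OFFSET,
                        n_families=config.n_families * train_factor)
    return generate_benchmark(train_cfg), generate_benchmark(config)


# ---------------------------------------------------------------------------
# toy fixtures anchoring the printed worked-example values


def protocol_fixture() -> tuple[InteractionNetwork, DiseaseFamily]:
    """The 5-node toy network of the scoring protocol walk-through.

    Nodes 1 and 3 are the known disease genes; with the five 3-node-graphlet
    isomers, per-disease-gene normalization over all other nodes and unit
    weights, node 2's summed normalized vector is [0.83 0 0 1.67 1] and its
    score 0.83 + 0 + 0 + 1.67 + 1 = 3.5.

    The topology was transcribed by exhaustively searching all graphs on
    five nodes for those reproducing these printed values exactly
    (5/6, 0, 0, 5/3, 1). The solution is unique up to swapping the labels
    of nodes 4 and 5 and exchanging the two disease genes; the orientation
    below fixes disease gene 1 as the one with the extra neighbor 4.
    """
    net = InteractionNetwork([
        ("1", "2"), ("1", "3"), ("1", "4"),
        ("2", "3"), ("2", "4"), ("2", "5"),
    ])
    family = DiseaseFamily(
        family_id="protocol",
        known_genes=frozenset({"1", "3"}),
        candidates=frozenset({"1", "2", "3", "4", "5"}),
    )
    return net, family


def schema_fixtures() -> tuple[
    tuple[InteractionNetwork, DiseaseFamily],
    tuple[InteractionNetwork, DiseaseFamily],
]:
    """Two small schema networks contrasting graphlet-interaction scoring
    with purely neighborhood-based reasoning.

    First network — the high-degree candidate: disease gene A links to
    candidates B and C; B additionally has three private neighbors. A's
    interaction vectors over the five 3-node-graphlet isomers are
    [1 0 1 3 0] toward B and [1 0 1 0 0] toward C, and with unit weights
    B scores 2.0 versus C's 1.0, although both are single neighbors of A.

    Second network — the shared complex: disease gene A sits in a dense
    complex (a 5-clique minus the A-B edge) with candidate B, while
    candidate C is merely a pendant neighbor of A. B scores 1.0, above
    C's 0.75, although C is adjacent to A and B is not.

    The topologies are transcriptions of the described schemas; each is the
    minimal graph reproducing the printed vectors and scores exactly.
    """
    net_a = InteractionNetwork([
        ("A", "B"), ("A", "C"),
        ("B", "x1"), ("B", "x2"), ("B", "x3"),
    ])
    fam_a = DiseaseFamily("schema-high-degree", frozenset({"A"}),
                          frozenset({"A", "B", "C"}))

    net_b = InteractionNetwork([
        ("A", "C"),
        ("A", "x1"), ("A", "x2"), ("A", "x3"),
        ("x1", "x2"), ("x1", "x3"), ("x2", "x3"),
        ("B", "x1"), ("B", "x2"), ("B", "x3"),
    ])
    fam_b = DiseaseFamily("schema-complex", frozenset({"A"}),
                          frozenset({"A", "B", "C"}))
    return (net_a, fam_a), (net_b, fam_b)
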