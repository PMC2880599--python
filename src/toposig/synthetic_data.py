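"""Synthetic regulatory networks and paired two-platform DE datasets.

The generator emulates the study design the scoring pipeline assumes: a
layered signaling network (receptors -> kinases -> transcription factors ->
target genes) in which a handful of planted regulators are "active", driving
their downstream targets to differential expression.  Two noisy views of the
same signaling state are emitted: a transcript-level view (microarray-style
FDR-selected flags) and a protein-level view (iTRAQ-style ratios thresholded
at >=1.2 / <=0.83) that detects only a fraction of the transcript changes.
The two views therefore overlap weakly at the DE level even though they are
driven by the identical upstream state — the regime the topological scoring
method is designed to exploit.

Fixed fixtures reproduce the worked receptor->kinase->TF cascade example
(36 target genes, 10 of them over-expressed) and its competitive-regulation
extension, plus an androgen-receptor-style truncation scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .network_model import (
    DifferentialSet,
    Edge,
    Effect,
    GeneSetCollection,
    InteractionNetwork,
    InteractionType,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate",
    "worked_cascade_fixture",
    "competing_cascade_fixture",
    "ar_truncation_fixture",
    "supplementary_s1_synthetic",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic generator.

    Layer sizes default to a desk-scale stand-in for a curated interaction
    knowledgebase: 20 receptors, 50 kinases, 100 transcription factors and
    1000 measurable target genes, with on average 2 extra cross edges per
    signaling node.  ``activation_prob`` is the chance a planted regulator's
    downstream target is differentially expressed (true-signal rate);
    ``background_de_prob`` the chance an undriven target is flagged anyway;
    ``protein_detection_prob`` the chance a transcript-level change is also
    seen at the protein level.
    """

    n_receptors: int = 20
    n_kinases: int = 50
    n_tfs: int = 100
    n_targets: int = 1000
    cross_edges_per_node: float = 2.0
    n_planted: int = 5
    activation_prob: float = 0.8
    background_de_prob: float = 0.02
    protein_detection_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_receptors", "n_kinases", "n_tfs", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("activation_prob", "background_de_prob",
                     "protein_detection_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cross_edges_per_node < 0:
            raise ValueError("cross_edges_per_node must be non-negative")
        n_heads = self.n_receptors + self.n_kinases
        if not 1 <= self.n_planted <= n_heads:
            raise ValueError(
                f"n_planted must lie in [1, {n_heads}] for these layers"
            )


@dataclass
class SyntheticTruth:
    """A generated network together with everything the generator knows."""

    network: InteractionNetwork
    planted: set[str]
    driven_targets: dict[str, set[str]]
    gene_view: DifferentialSet
    protein_view: DifferentialSet
    process_sets: GeneSetCollection
    target_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.planted <= self.network.nodes:
            raise ValueError("planted regulators must be network nodes")


# --- ratio generation --------------------------------------------------------
# DE-up ratios Uniform(1.2, 3.0), DE-down Uniform(0.4, 0.83), unchanged
# Uniform(0.84, 1.19): the threshold rule (>=1.2 up, <=0.83 down) recovers the
# flags exactly, making the iTRAQ filter a pure, testable function.

def _draw_ratios(
    rng: np.random.Generator, up: set[str], down: set[str], universe: set[str]
) -> dict[str, float]:
    ratios: dict[str, float] = {}
    for ident in sorted(universe):
        if ident in up:
            ratios[ident] = float(rng.uniform(1.2, 3.0))
        elif ident in down:
            ratios[ident] = float(rng.uniform(0.4, 0.83))
        else:
            ratios[ident] = float(rng.uniform(0.84, 1.19))
    return ratios


def _collapse(edges: list[Edge]) -> list[Edge]:
    best: dict[tuple[str, str, InteractionType], Edge] = {}
    for e in edges:
        key = (e.source, e.target, e.interaction_type)
        prev = best.get(key)
        if prev is None or e.trust > prev.trust:
            best[key] = e
    return list(best.values())


def generate(config: SimulationConfig) -> SyntheticTruth:
    """Generate one synthetic signaling state; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)

    receptors = [f"R{i:03d}" for i in range(config.n_receptors)]
    kinases = [f"K{i:03d}" for i in range(config.n_kinases)]
    tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
    targets = [f"T{i:04d}" for i in range(config.n_targets)]

    edges: list[Edge] = []

    def effect() -> Effect:
        return Effect.activation if rng.random() < 0.8 else Effect.inhibition

    # backbone: every node has one upstream parent in the previous layer
    for k in kinases:
        parent = receptors[int(rng.integers(len(receptors)))]
        etype = (InteractionType.binding if rng.random() < 0.5
                 else InteractionType.phosphorylation)
        edges.append(Edge(parent, k, etype, effect()))
    for f in tfs:
        parent = kinases[int(rng.integers(len(kinases)))]
        edges.append(Edge(parent, f, InteractionType.phosphorylation, effect()))
    for t in targets:
        parent = tfs[int(rng.integers(len(tfs)))]
        edges.append(
            Edge(parent, t, InteractionType.transcriptional_regulation, effect())
        )

    # seeded random cross edges into the next layer
    lam = config.cross_edges_per_node
    for src_layer, dst_layer, etype in (
        (receptors, kinases, InteractionType.binding),
        (kinases, tfs, InteractionType.other),
        (tfs, targets, InteractionType.transcriptional_regulation),
    ):
        for src in src_layer:
            for _ in range(int(rng.poisson(lam))):
                dst = dst_layer[int(rng.integers(len(dst_layer)))]
                edges.append(Edge(src, dst, etype, effect()))

    edges = _collapse(edges)
    nodes = set(receptors) | set(kinases) | set(tfs) | set(targets)
    network = InteractionNetwork(nodes=nodes, edges=edges)

    signaling = receptors + kinases + tfs
    # planted activity enters at cascade heads (receptors/kinases), the way a
    # ligand or constitutively active kinase would; transcription factors are
    # recovered as mediators, not planted directly
    heads = receptors + kinases
    planted = set(
        rng.choice(np.array(heads), size=config.n_planted, replace=False)
        .tolist()
    )

    # planted regulators drive their downstream targets to DE
    g = network.digraph()
    target_set = set(targets)
    driven_targets: dict[str, set[str]] = {}
    gene_up: set[str] = set()
    for p in sorted(planted):
        reachable = sorted(nx.descendants(g, p) & target_set)
        hit = {t for t in reachable if rng.random() < config.activation_prob}
        driven_targets[p] = hit
        gene_up |= hit

    gene_down: set[str] = set()
    for t in targets:
        if t in gene_up:
            continue
        if rng.random() < config.background_de_prob:
            (gene_up if rng.random() < 0.5 else gene_down).add(t)

    gene_view = DifferentialSet(
        universe=target_set,
        de_up=gene_up,
        de_down=gene_down,
        label="microarray",
    )

    # protein view: thinning of the transcript changes plus background noise
    prot_up: set[str] = set()
    prot_down: set[str] = set()
    for t in targets:
        if t in gene_up:
            if rng.random() < config.protein_detection_prob:
                prot_up.add(t)
        elif t in gene_down:
            if rng.random() < config.protein_detection_prob:
                prot_down.add(t)
        elif rng.random() < config.background_de_prob:
            (prot_up if rng.random() < 0.5 else prot_down).add(t)
    protein_view = DifferentialSet(
        universe=target_set,
        de_up=prot_up,
        de_down=prot_down,
        ratios=_draw_ratios(rng, prot_up, prot_down, target_set),
        label="itraq",
    )

    # one functional "process" set per planted cascade: the planted head and
    # its full downstream closure (mediators and target genes), the shape of
    # a curated process network containing both regulators and their targets
    process: dict[str, tuple[str, frozenset[str]]] = {}
    for p in sorted(planted):
        members = {p} | nx.descendants(g, p)
        process[f"CASCADE_{p}"] = (
            f"signaling cascade headed by planted regulator {p}",
            frozenset(members),
        )

    return SyntheticTruth(
        network=network,
        planted=planted,
        driven_targets=driven_targets,
        gene_view=gene_view,
        protein_view=protein_view,
        process_sets=GeneSetCollection(sets=process),
        target_ids=target_set,
    )


# ---------------------------------------------------------------------------
# Fixed fixtures
# ---------------------------------------------------------------------------

#: number of measured background genes embedded in the cascade fixtures so
#: that target-set enrichment is computed against a realistic universe
_N_BACKGROUND = 264


def worked_cascade_fixture() -> SyntheticTruth:
    """The worked single-cascade example, fixed and seedless.

    A receptor (FGFR3) binds a kinase (P90RSK2) which phosphorylates a
    transcription factor (ATF4) regulating 36 target genes T01..T36; ten of
    the targets (T01..T10) and the TF itself are over-expressed, while the
    receptor and kinase show no expression change — they are "hidden"
    regulators detectable only through their network position.  The measured
    universe embeds the cascade among 264 unchanged background genes.
    """
    targets = [f"T{i:02d}" for i in range(1, 37)]
    background = [f"B{i:03d}" for i in range(1, _N_BACKGROUND + 1)]
    edges = [
        Edge("FGFR3", "P90RSK2", InteractionType.binding, Effect.activation),
        Edge("P90RSK2", "ATF4", InteractionType.phosphorylation, Effect.activation),
    ]
    edges += [
        Edge("ATF4", t, InteractionType.transcriptional_regulation,
             Effect.activation)
        for t in targets
    ]
    nodes = {"FGFR3", "P90RSK2", "ATF4"} | set(targets) | set(background)
    network = InteractionNetwork(nodes=nodes, edges=edges)

    universe = set(targets) | {"FGFR3", "P90RSK2", "ATF4"} | set(background)
    de_up = set(targets[:10]) | {"ATF4"}
    gene_view = DifferentialSet(
        universe=universe, de_up=de_up, de_down=set(), label="microarray"
    )
    protein_view = DifferentialSet(
        universe=set(universe),
        de_up=set(de_up),
        de_down=set(),
        ratios={i: (1.5 if i in de_up else 1.0) for i in sorted(universe)},
        label="itraq",
    )
    return SyntheticTruth(
        network=network,
        planted={"FGFR3", "P90RSK2", "ATF4"},
        driven_targets={r: set(targets[:10]) for r in ("FGFR3", "P90RSK2", "ATF4")},
        gene_view=gene_view,
        protein_view=protein_view,
        process_sets=GeneSetCollection(
            sets={
                "FGFR3_CASCADE": (
                    "receptor-kinase-TF cascade",
                    frozenset({"FGFR3", "P90RSK2", "ATF4"}),
                )
            }
        ),
        target_ids=set(targets),
    )


def competing_cascade_fixture() -> SyntheticTruth:
    """Competitive-regulation extension of the single-cascade fixture.

    The kinase additionally signals through a second transcription factor
    (YB1) whose 12 target genes U01..U12 are not differentially expressed,
    diluting the kinase's full remote-target set.  A competing kinase (AKT1)
    sits one step from the YB1 block, so competitor exclusion removes that
    block and restores the kinase's specific enrichment.
    """
    base = worked_cascade_fixture()
    u_targets = [f"U{i:02d}" for i in range(1, 13)]
    edges = list(base.network.edges)
    edges.append(
        Edge("P90RSK2", "YB1", InteractionType.phosphorylation, Effect.activation)
    )
    edges += [
        Edge("YB1", u, InteractionType.transcriptional_regulation,
             Effect.activation)
        for u in u_targets
    ]
    edges += [Edge("AKT1", u, InteractionType.other) for u in u_targets]
    nodes = base.network.nodes | {"YB1", "AKT1"} | set(u_targets)
    network = InteractionNetwork(nodes=nodes, edges=edges)

    extra = set(u_targets) | {"YB1", "AKT1"}
    gene_view = DifferentialSet(
        universe=base.gene_view.universe | extra,
        de_up=set(base.gene_view.de_up),
        de_down=set(),
        label="microarray",
    )
    protein_view = DifferentialSet(
        universe=base.protein_view.universe | extra,
        de_up=set(base.protein_view.de_up),
        de_down=set(),
        label="itraq",
    )
    return SyntheticTruth(
        network=network,
        planted=set(base.planted),
        driven_targets=dict(base.driven_targets),
        gene_view=gene_view,
        protein_view=protein_view,
        process_sets=base.process_sets,
        target_ids=base.target_ids | set(u_targets),
    )


def ar_truncation_fixture() -> SyntheticTruth:
    """Receptor-dependence scenario for the truncation analysis.

    An androgen-receptor-like transcription factor (AR) directly drives 45
    over-expressed genes, while an independent growth-factor cascade
    (EGFR -> MEK1 -> MYC) drives a separate block of 30 over-expressed genes
    out of 40 targets.  Removing AR's direct transcriptional targets from the
    DE list should silence AR but leave the growth-factor cascade heads
    significant — the receptor-independence signature.
    """
    a_block = [f"A{i:02d}" for i in range(1, 46)]
    b_block = [f"G{i:02d}" for i in range(1, 41)]
    background = [f"B{i:03d}" for i in range(1, 501)]
    edges = [
        Edge("AR", a, InteractionType.transcriptional_regulation,
             Effect.activation)
        for a in a_block
    ]
    edges += [
        Edge("EGFR", "MEK1", InteractionType.binding, Effect.activation),
        Edge("MEK1", "MYC", InteractionType.phosphorylation, Effect.activation),
    ]
    edges += [
        Edge("MYC", b, InteractionType.transcriptional_regulation,
             Effect.activation)
        for b in b_block
    ]
    nodes = (
        {"AR", "EGFR", "MEK1", "MYC"}
        | set(a_block) | set(b_block) | set(background)
    )
    network = InteractionNetwork(nodes=nodes, edges=edges)

    universe = set(a_block) | set(b_block) | set(background)
    de_up = set(a_block) | set(b_block[:30])
    gene_view = DifferentialSet(
        universe=universe, de_up=de_up, de_down=set(), label="microarray"
    )
    protein_view = DifferentialSet(
        universe=set(universe), de_up=set(de_up), de_down=set(), label="itraq"
    )
    return SyntheticTruth(
        network=network,
        planted={"AR", "EGFR", "MEK1", "MYC"},
        driven_targets={
            "AR": set(a_block),
            "EGFR": set(b_block[:30]),
            "MEK1": set(b_block[:30]),
            "MYC": set(b_block[:30]),
        },
        gene_view=gene_view,
        protein_view=protein_view,
        process_sets=GeneSetCollection(
            sets={
                "ANDROGEN_CASCADE": ("AR direct regulation", frozenset({"AR"})),
                "GROWTH_FACTOR_CASCADE": (
                    "growth-factor cascade to cell-cycle TF",
                    frozenset({"EGFR", "MEK1", "MYC"}),
                ),
            }
        ),
        target_ids=set(a_block) | set(b_block),
    )


def supplementary_s1_synthetic() -> dict[str, frozenset[str]]:
    """Synthetic stand-in for the study's published up/down gene and protein
    lists, reproducing their set arithmetic (not their identities).

    The real supplementary lists are not redistributable here; this fixture
    carries the same cardinalities and overlaps: 347 up-regulated genes and
    70 up-regulated proteins sharing 13 members, 257 down-regulated genes and
    39 down-regulated proteins sharing 3 members (about 8% of the smaller
    set).  All identifiers are synthetic.
    """
    shared_up = [f"SHUP{i:02d}" for i in range(1, 14)]
    shared_down = [f"SHDN{i:02d}" for i in range(1, 4)]
    up_genes = frozenset(shared_up) | {f"GUP{i:03d}" for i in range(1, 335)}
    up_proteins = frozenset(shared_up) | {f"PUP{i:03d}" for i in range(1, 58)}
    down_genes = frozenset(shared_down) | {f"GDN{i:03d}" for i in range(1, 255)}
    down_proteins = frozenset(shared_down) | {f"PDN{i:03d}" for i in range(1, 37)}
    return {
        "up_genes": frozenset(up_genes),
        "up_proteins": frozenset(up_proteins),
        "down_genes": frozenset(down_genes),
        "down_proteins": frozenset(down_proteins),
    }
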