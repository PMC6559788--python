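"""End-to-end build: input tables -> scored, queryable property graph."""

from __future__ import annotations

import logging
from pathlib import Path

from . import dominance, graph, network, toxicity
from .enzyme_model import read_enzyme_map
from .fingerprints import pairwise_similarity, read_compounds
from .synthetic import read_uses

logger = logging.getLogger(__name__)


def build_graph_from_files(
    compounds_path,
    side_effects_path=None,
    enzyme_map_path=None,
    abundance_path=None,
    uses_path=None,
    min_similarity: float = network.DEFAULT_MIN_SIMILARITY,
    z_threshold: float = network.DEFAULT_Z_THRESHOLD,
    walk_length: int = network.DEFAULT_WALK_LENGTH,
    seed: int = 0,
) -> tuple[graph.PropertyGraph, network.SimilarityNetwork]:
    """Run the full construction pipeline from TSV inputs.

    Optional inputs that are omitted simply leave their relationship
    type (or the enzyme ``ecsd`` property) out of the graph.
    """
    compounds = read_compounds(compounds_path)
    logger.info(
        "build: %d compounds, min_similarity=%s z_threshold=%s "
        "walk_length=%s seed=%s",
        len(compounds), min_similarity, z_threshold, walk_length, seed,
    )
    sims = pairwise_similarity(compounds)
    node_attrs = {
        c.compound_id: {"category": c.category, "superclass": c.superclass}
        for c in compounds
    }
    net = network.build_network(
        sims,
        min_similarity=min_similarity,
        nodes=[c.compound_id for c in compounds],
        node_attrs=node_attrs,
    )
    net = network.detect_communities(net, walk_length=walk_length, seed=seed)
    net = network.flag_significant_edges(net, z_threshold=z_threshold)

    tox_edges = None
    if side_effects_path is not None:
        profiles = toxicity.read_side_effects(side_effects_path)
        if len(profiles) >= 2:
            tox_edges = toxicity.all_pairs_toxicity(profiles)
    enzyme_map = (
        read_enzyme_map(enzyme_map_path) if enzyme_map_path is not None else None
    )
    ecsd_scores = None
    if abundance_path is not None:
        scores = dominance.ecsd_table(dominance.read_abundance(abundance_path))
        ecsd_scores = dict(
            zip(scores["ec_number"], scores["ecsd"].astype(float))
        )
    uses = read_uses(uses_path) if uses_path is not None else None

    pg = graph.assemble_graph(
        net,
        tox_edges=tox_edges,
        enzyme_map=enzyme_map,
        uses=uses,
        ecsd_scores=ecsd_scores,
    )
    return pg, net
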