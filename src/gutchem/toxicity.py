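"""Drug toxicity similarity from side-effect concept profiles.

Two drugs are toxicologically similar when they share side-effect
concepts, with each shared concept contributing according to how
informative it is:

* a rarity weight, -ln(frequency across all drug side-effect lists) —
  ubiquitous concepts (nausea, headache) carry no information;
* a redundancy weight from the Gerstein–Sonnhammer–Chothia (GSC)
  procedure run on a UPGMA tree of concept co-occurrence, which
  down-weights concepts that always travel together (a cluster of
  near-duplicate concepts shares one concept's worth of weight).

The pair score is the sum of combined weights over shared concepts,
cosine-normalised by the drugs' self-scores so that identical profiles
score 1 and disjoint profiles score 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .fingerprints import canonical_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SideEffectProfile:
    compound_id: str
    concepts: frozenset[str]


@dataclass(frozen=True)
class ConceptWeight:
    concept_id: str
    frequency: float
    rarity_weight: float
    gsc_weight: float

    @property
    def combined_weight(self) -> float:
        return self.rarity_weight * self.gsc_weight


@dataclass(frozen=True)
class ToxicityEdge:
    pair: tuple[str, str]
    raw_score: float
    normalized_score: float


class ConceptTree:
    """Ultrametric concept dendrogram from average-linkage agglomeration.

    Stored as the leaf list plus a merge list ``(left, right, height)``
    using the scipy cluster-id convention (leaf i < n; merge k creates
    cluster n + k). Leaves sit at height 0; branch length of a child
    edge is the parent's merge height minus the child's height.
    """

    def __init__(
        self, leaves: Sequence[str], merges: Sequence[tuple[int, int, float]]
    ) -> None:
        self.leaves = list(leaves)
        self.merges = [(int(a), int(b), float(h)) for a, b, h in merges]
        n = len(self.leaves)
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError("a binary tree on n leaves needs n-1 merges")
        self._heights: dict[int, float] = {i: 0.0 for i in range(n)}
        self._cluster_leaves: dict[int, list[int]] = {
            i: [i] for i in range(n)
        }
        for k, (a, b, h) in enumerate(self.merges):
            cid = n + k
            self._heights[cid] = h
            self._cluster_leaves[cid] = (
                self._cluster_leaves[a] + self._cluster_leaves[b]
            )

    def height(self, cluster: int) -> float:
        return self._heights[cluster]

    def cluster_leaf_indices(self, cluster: int) -> list[int]:
        return list(self._cluster_leaves[cluster])

    def total_branch_length(self) -> float:
        total = 0.0
        for k, (a, b, h) in enumerate(self.merges):
            for child in (a, b):
                total += h - self._heights[child]
        return total


def concept_frequency(
    profiles: Sequence[SideEffectProfile],
) -> dict[str, float]:
    """Fraction of drugs listing each concept, in (0, 1]."""
    if not profiles:
        raise ValueError("need at least one side-effect profile")
    n = len(profiles)
    counts: dict[str, int] = {}
    for prof in profiles:
        for c in prof.concepts:
            counts[c] = counts.get(c, 0) + 1
    return {c: k / n for c, k in counts.items()}


def rarity_weights(frequencies: Mapping[str, float]) -> dict[str, float]:
    """Information-content rarity weight -ln(frequency) per concept."""
    out: dict[str, float] = {}
    for c, f in frequencies.items():
        if not 0.0 < f <= 1.0:
            raise ValueError(f"frequency for {c!r} must be in (0,1], got {f}")
        out[c] = -math.log(f)
    return out


def concept_cooccurrence(
    profiles: Sequence[SideEffectProfile],
) -> dict[tuple[str, str], float]:
    """Tanimoto correlation between concepts over the drugs listing them:
    |drugs(c1) ∩ drugs(c2)| / |drugs(c1) ∪ drugs(c2)|."""
    drugs_of: dict[str, set[str]] = {}
    for prof in profiles:
        for c in prof.concepts:
            drugs_of.setdefault(c, set()).add(prof.compound_id)
    concepts = sorted(drugs_of)
    if len(concepts) < 2:
        raise ValueError("need at least 2 concepts")
    out: dict[tuple[str, str], float] = {}
    for i, c1 in enumerate(concepts):
        for c2 in concepts[i + 1 :]:
            inter = len(drugs_of[c1] & drugs_of[c2])
            union = len(drugs_of[c1] | drugs_of[c2])
            out[(c1, c2)] = inter / union if union else 0.0
    return out


def build_concept_tree(
    cooccurrence: Mapping[tuple[str, str], float],
) -> ConceptTree:
    """UPGMA tree on distance 1 - co-occurrence; node height = merge
    distance / 2 (ultrametric). Concepts are sorted lexicographically
    before agglomeration so equal-distance merges break ties the same
    way on every run."""
    concepts = sorted({c for pair in cooccurrence for c in pair})
    if len(concepts) < 2:
        return ConceptTree(concepts, [])
    index = {c: i for i, c in enumerate(concepts)}
    n = len(concepts)
    dist = np.zeros((n, n))
    for (c1, c2), corr in cooccurrence.items():
        if not 0.0 <= corr <= 1.0:
            raise ValueError(f"co-occurrence for ({c1},{c2}) outside [0,1]")
        i, j = index[c1], index[c2]
        dist[i, j] = dist[j, i] = 1.0 - corr
    z = linkage(squareform(dist, checks=False), method="average")
    merges = [(int(row[0]), int(row[1]), float(row[2]) / 2.0) for row in z]
    return ConceptTree(concepts, merges)


def gsc_weights(tree: ConceptTree, rescale: bool = True) -> dict[str, float]:
    """GSC redundancy weights: distribute branch lengths leaf-upward.

    Edges are processed from the leaves toward the root; each edge's
    length is shared among the leaves below it in proportion to their
    weight accumulated so far (equally while all are still zero). Before
    rescaling the weights sum to the tree's total branch length, which
    is what makes a pair of duplicated concepts split one concept's
    weight between them. With ``rescale`` the weights are scaled to
    mean 1 (all-1 on a zero-length tree, where every leaf is redundant
    with every other to the same degree).
    """
    n = len(tree.leaves)
    if n == 0:
        return {}
    weights = np.zeros(n)
    for k, (a, b, h) in enumerate(tree.merges):
        for child in (a, b):
            length = h - tree.height(child)
            if length < -1e-12:
                raise ValueError(
                    f"negative branch length {length} at merge {k}"
                )
            length = max(length, 0.0)
            idx = tree.cluster_leaf_indices(child)
            sub = weights[idx]
            total = sub.sum()
            if total == 0.0:
                weights[idx] = sub + length / len(idx)
            else:
                weights[idx] = sub + length * sub / total
    if rescale:
        total = weights.sum()
        weights = weights * (n / total) if total > 0 else np.ones(n)
    return {leaf: float(w) for leaf, w in zip(tree.leaves, weights)}


def compute_concept_weights(
    profiles: Sequence[SideEffectProfile],
) -> dict[str, ConceptWeight]:
    """Full weight table: frequency -> rarity, co-occurrence -> UPGMA ->
    GSC, combined = rarity x GSC."""
    freqs = concept_frequency(profiles)
    rarity = rarity_weights(freqs)
    if len(freqs) >= 2:
        gsc = gsc_weights(build_concept_tree(concept_cooccurrence(profiles)))
    else:
        gsc = {c: 1.0 for c in freqs}
    return {
        c: ConceptWeight(
            concept_id=c,
            frequency=freqs[c],
            rarity_weight=rarity[c],
            gsc_weight=gsc[c],
        )
        for c in sorted(freqs)
    }


def _self_score(
    profile: SideEffectProfile, weights: Mapping[str, ConceptWeight]
) -> float:
    missing = profile.concepts - weights.keys()
    if missing:
        raise KeyError(
            f"profile {profile.compound_id} has unweighted concepts: "
            f"{sorted(missing)[:5]}"
        )
    return sum(weights[c].combined_weight for c in profile.concepts)


def toxicity_similarity(
    a: SideEffectProfile,
    b: SideEffectProfile,
    weights: Mapping[str, ConceptWeight],
) -> ToxicityEdge:
    """Weighted shared-concept score for one drug pair.

    raw = sum of combined weights over shared concepts; normalised by
    sqrt(self(a) * self(b)) so the score is 1 for identical profiles
    and bounded in [0, 1].
    """
    sa = _self_score(a, weights)
    sb = _self_score(b, weights)
    if sa == 0.0 or sb == 0.0:
        raise ValueError(
            "profile with zero total concept weight cannot be compared "
            f"({a.compound_id if sa == 0 else b.compound_id})"
        )
    shared = a.concepts & b.concepts
    raw = sum(weights[c].combined_weight for c in shared)
    return ToxicityEdge(
        pair=canonical_pair(a.compound_id, b.compound_id),
        raw_score=raw,
        normalized_score=raw / math.sqrt(sa * sb),
    )


def all_pairs_toxicity(
    profiles: Sequence[SideEffectProfile],
    weights: Mapping[str, ConceptWeight] | None = None,
) -> dict[tuple[str, str], ToxicityEdge]:
    """Toxicity edges for every unordered pair of profiled drugs.

    Profiles whose every concept has zero combined weight (all concepts
    ubiquitous) cannot be scored and are dropped with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if weights is None:
        weights = compute_concept_weights(profiles)
    usable = []
    for prof in profiles:
        if _self_score(prof, weights) > 0:
            usable.append(prof)
        else:
            logger.warning(
                "profile %s has zero total concept weight; skipped",
                prof.compound_id,
            )
    out: dict[tuple[str, str], ToxicityEdge] = {}
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            edge = toxicity_similarity(a, b, weights)
            out[edge.pair] = edge
    return out


def read_side_effects(path) -> list[SideEffectProfile]:
    """Read a side-effect TSV: ``compound_id concept_id concept_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"compound_id", "concept_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"side-effect table missing columns: {sorted(missing)}")
    grouped = df.groupby("compound_id")["concept_id"].apply(set)
    return [
        SideEffectProfile(compound_id=cid, concepts=frozenset(concepts))
        for cid, concepts in sorted(grouped.items())
    ]


def write_weight_table(weights: Mapping[str, ConceptWeight], path) -> None:
    rows = [
        {
            "concept_id": w.concept_id,
            "frequency": w.frequency,
            "rarity_weight": w.rarity_weight,
            "gsc_weight": w.gsc_weight,
            "combined_weight": w.combined_weight,
        }
        for w in sorted(weights.values(), key=lambda w: w.concept_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_toxicity_edges(
    edges: Mapping[tuple[str, str], ToxicityEdge], path
) -> None:
    rows = [
        {
            "source": e.pair[0],
            "target": e.pair[1],
            "raw_score": e.raw_score,
            "normalized_score": e.normalized_score,
        }
        for _, e in sorted(edges.items())
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "raw_score", "normalized_score"]
    ).to_csv(path, sep="\t", index=False)
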