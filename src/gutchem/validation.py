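"""Network validation: randomisation, superclass agreement, regressions.

Three checks that the substructure network captures real chemistry:

* superclass agreement — edges between compounds of the same ClassyFire
  superclass should concentrate at high similarity, and do so more than
  in a randomised network with the same nodes, edge count and labels
  (Wilcoxon rank-sum);
* structure–toxicity regression — OLS of pairwise toxicity similarity on
  substructure similarity over drug pairs present in both edge sets;
* category self-similarity — two-sample Kolmogorov–Smirnov comparison
  of within-category Tanimoto distributions (e.g. food vs drug).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb, isqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fingerprints import Compound, pairwise_similarity
from .network import SimilarityEdge, SimilarityNetwork

DEFAULT_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    conclusive: bool = True


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    pvalue: float
    stderr: float
    ci95: tuple[float, float]
    n: int


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    # unrank k into the lexicographic unordered pair (i, j), i < j < n
    i = n - 2 - int((isqrt(4 * (comb(n, 2) - 1 - k) * 2 + 1) - 1) // 2)
    # fall back to a robust scan near the analytic guess
    while comb(n, 2) - comb(n - i, 2) > k:
        i -= 1
    while comb(n, 2) - comb(n - i - 1, 2) <= k:
        i += 1
    j = i + 1 + (k - (comb(n, 2) - comb(n - i, 2)))
    return i, j


def randomize_network(
    net: SimilarityNetwork,
    seed: int,
    method: str = "uniform",
) -> SimilarityNetwork:
    """Randomised network with the same nodes, edge count and labels.

    ``uniform`` draws the edge set uniformly among unordered node pairs
    without replacement (an Erdős–Rényi G(n, m) draw); node attributes
    are untouched. The source network's score multiset is permuted onto
    the random edges so score-binned comparisons remain defined.
    ``rewire`` is a degree-preserving double-edge-swap variant for
    sensitivity analysis.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    m = len(net.edges)
    if m > comb(n, 2):
        raise ValueError("edge count exceeds number of unordered pairs")
    rng = np.random.default_rng(seed)
    scores = np.array([e.score for _, e in sorted(net.edges.items())])
    rng.shuffle(scores)
    if method == "uniform":
        picks = rng.choice(comb(n, 2), size=m, replace=False)
        pairs = []
        for k in sorted(int(p) for p in picks):
            i, j = _pair_from_index(k, n)
            pairs.append((nodes[i], nodes[j]))
    elif method == "rewire":
        import networkx as nx

        g = nx.Graph(list(net.edges))
        nswap = max(1, 10 * m)
        if m >= 2:
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=100 * nswap, seed=int(seed)
            )
        pairs = [tuple(sorted(e)) for e in g.edges]
    else:
        raise ValueError(f"unknown randomisation method {method!r}")
    edges = {
        pair: SimilarityEdge(pair=pair, score=float(s))
        for pair, s in zip(sorted(pairs), scores)
    }
    return SimilarityNetwork(
        nodes=list(nodes),
        edges=edges,
        node_attrs=dict(net.node_attrs),
        parameters=dict(net.parameters, randomized=method, random_seed=seed),
    )


def edge_match_table(
    net: SimilarityNetwork,
    superclass: Mapping[str, str | None] | None = None,
) -> pd.DataFrame:
    """Per-edge (score, matched) rows over edges with both endpoints
    superclass-annotated; unannotated endpoints exclude the edge."""
    if superclass is None:
        superclass = {
            n: net.node_attrs.get(n, {}).get("superclass") for n in net.nodes
        }
    rows = []
    for (a, b), edge in sorted(net.edges.items()):
        sa, sb = superclass.get(a), superclass.get(b)
        if not sa or not sb:
            continue
        rows.append({"score": edge.score, "matched": sa == sb})
    return pd.DataFrame(rows, columns=["score", "matched"])


def superclass_agreement(
    net: SimilarityNetwork,
    superclass: Mapping[str, str | None] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> pd.DataFrame:
    """Matched/unmatched superclass counts per similarity bin.

    Reports the matched fraction alongside the matched:unmatched ratio;
    the ratio is NaN when a bin has no unmatched pair, the fraction is
    always defined on occupied bins.
    """
    table = edge_match_table(net, superclass)
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    rows = []
    if len(table):
        idx = np.clip(
            np.digitize(table["score"].to_numpy(), edges[1:-1]), 0, nbins - 1
        )
    else:
        idx = np.array([], dtype=int)
    matched_arr = table["matched"].to_numpy() if len(table) else np.array([])
    for b in range(nbins):
        mask = idx == b
        matched = int(matched_arr[mask].sum()) if mask.any() else 0
        total = int(mask.sum())
        unmatched = total - matched
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "matched": matched,
                "unmatched": unmatched,
                "matched_fraction": matched / total if total else np.nan,
                "ratio": matched / unmatched if unmatched else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_to_random(
    real: pd.DataFrame, random: pd.DataFrame
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum on similarity scores of superclass-
    matched edges, real vs randomised.

    A significant result with higher real ranks means matched pairs
    concentrate at higher similarity in the real network than label
    chance alone produces. All-tied degenerate samples are reported as
    inconclusive rather than as a p-value.
    """
    a = real.loc[real["matched"], "score"].to_numpy(dtype=float)
    b = random.loc[random["matched"], "score"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankSumResult(statistic=0.0, pvalue=np.nan, conclusive=False)
    stat, p = stats.ranksums(a, b)
    return RankSumResult(statistic=float(stat), pvalue=float(p))


def structure_toxicity_regression(
    struct_edges: Mapping[tuple[str, str], float],
    tox_edges: Mapping[tuple[str, str], float],
) -> RegressionResult:
    """OLS of toxicity similarity on substructure similarity over the
    drug pairs present in both edge sets."""
    pairs = sorted(set(struct_edges) & set(tox_edges))
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs present in both edge sets")
    x = np.array([struct_edges[p] for p in pairs], dtype=float)
    y = np.array([tox_edges[p] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in substructure similarity")
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(pairs) - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        pvalue=float(fit.pvalue),
        stderr=float(fit.stderr),
        ci95=ci,
        n=len(pairs),
    )


def within_category_similarities(
    compounds: Sequence[Compound], category: str
) -> np.ndarray:
    members = [c for c in compounds if c.category == category]
    if len(members) < 2:
        raise ValueError(f"category {category!r} has fewer than 2 compounds")
    sims = pairwise_similarity(members)
    return np.array([sims[p] for p in sorted(sims)], dtype=float)


def category_self_similarity(
    compounds: Sequence[Compound], category_a: str, category_b: str
):
    """Two-sample KS test between the within-category pairwise Tanimoto
    distributions of two compound categories."""
    a = within_category_similarities(compounds, category_a)
    b = within_category_similarities(compounds, category_b)
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def write_report(
    path,
    agreement: pd.DataFrame,
    regression: RegressionResult | None = None,
    ranksum: RankSumResult | None = None,
    parameters: Mapping | None = None,
) -> None:
    """Validation report TSV with the run parameters in header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in sorted((parameters or {}).items()):
            fh.write(f"# {key} = {value}\n")
        if regression is not None:
            fh.write(
                f"# regression slope={regression.slope:.6g} "
                f"r={regression.r:.6g} p={regression.pvalue:.3g} "
                f"n={regression.n}\n"
            )
        if ranksum is not None:
            fh.write(
                f"# ranksum statistic={ranksum.statistic:.6g} "
                f"p={ranksum.pvalue:.3g} conclusive={ranksum.conclusive}\n"
            )
        agreement.to_csv(fh, sep="\t", index=False)
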