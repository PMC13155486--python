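"""Query the regulatory network for short regulatory paths and rank targets.

A query is an ordered list of node-class constraints (optionally with
attribute predicates, e.g. membership of a supplied cell-cycle gene list)
ending at a Gene or ParalogGroup.  Matching is exhaustive subgraph-path
search, implemented as a depth-first traversal against the direction of the
edges starting from candidate terminal nodes.

Each matched target is scored by the product, over edge types (ChIP cell
lines or GWAS traits), of the smallest incoming scored-edge value of that
type; targets are ranked ascending (small product = strong convergent
evidence from many independent types).  Significance is assessed by
permuting, independently per type, the assignment between that type's score
contributions and the target labels, recomputing combined scores, and
reporting the fraction of rounds with a permuted score at most the observed
one (with the plus-one convention so p >= 1/(rounds+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .regnet import NODE_GENE, NODE_GROUP, RegNetwork

SCORED_EDGE_KINDS = {"peak_gene", "snp_gene"}


@dataclass
class QueryNode:
    node_class: str
    predicate: Callable[[dict], bool] | None = None

    def matches(self, attrs: dict) -> bool:
        if attrs.get("node_class") != self.node_class:
            return False
        return self.predicate is None or bool(self.predicate(attrs))


@dataclass
class QueryPath:
    """Ordered constraints along the edge direction; terminal last."""

    nodes: list[QueryNode]

    def __post_init__(self):
        if not self.nodes:
            raise ValueError("empty query")
        if self.nodes[-1].node_class not in (NODE_GENE, NODE_GROUP):
            raise ValueError("query must end at a Gene or ParalogGroup")


@dataclass
class MatchSubnetwork:
    """Per-target matched paths (node-id tuples ordered along the edges)."""

    paths_by_target: dict = field(default_factory=dict)

    def targets(self):
        return list(self.paths_by_target)


def match_paths(network: RegNetwork, query: QueryPath) -> MatchSubnetwork:
    """All network paths matching the query: reverse depth-first search from
    each matching terminal node, pruning on class/attribute mismatch."""
    g = network.graph
    terminals = [n for n in g.nodes if query.nodes[-1].matches(g.nodes[n])]
    out: dict = {}
    L = len(query.nodes)
    for t in terminals:
        found: list[tuple] = []
        stack = [(t, (t,))]
        while stack:
            node, path = stack.pop()
            depth = len(path)  # constraints consumed, counting from the end
            if depth == L:
                found.append(path)
                continue
            constraint = query.nodes[L - depth - 1]
            for pred in g.predecessors(node):
                if pred not in path and constraint.matches(g.nodes[pred]):
                    stack.append((pred, (pred,) + path))
        if found:
            out[t] = found
    return MatchSubnetwork(paths_by_target=out)


def _target_type_minima(network: RegNetwork, match: MatchSubnetwork) -> pd.DataFrame:
    """Per (target, type) minimum scored-edge value over the matched paths.

    For ParalogGroup targets the incoming scored edges of all member genes
    pool into the shared type groups.
    """
    g = network.graph
    rows = []
    for target, paths in match.paths_by_target.items():
        for path in paths:
            for u, v in zip(path[:-1], path[1:]):
                attrs = g.edges[u, v]
                if attrs.get("edge_kind") in SCORED_EDGE_KINDS:
                    rows.append((target, attrs["type"], attrs.get("edge_score")))
    df = pd.DataFrame(rows, columns=["target", "type", "edge_score"])
    if df.empty:
        return df
    if df["edge_score"].isna().any():
        raise ValueError("matched scored edges lack edge_score; run score_edges first")
    return (
        df.groupby(["target", "type"], sort=False)["edge_score"].min().reset_index()
    )


def combined_scores(network: RegNetwork, match: MatchSubnetwork) -> pd.Series:
    """Product over types of the per-type minimum edge score, per target.
    Targets with no scored incoming edge are excluded (undefined score)."""
    minima = _target_type_minima(network, match)
    if minima.empty:
        return pd.Series(dtype=float)
    return minima.groupby("target", sort=False)["edge_score"].prod()


def rank_targets(scores: pd.Series) -> pd.DataFrame:
    """Ascending stable ranking with competition ranks for ties."""
    df = scores.rename("combined_score").reset_index().rename(columns={"index": "target"})
    df = df.sort_values("combined_score", kind="stable").reset_index(drop=True)
    df["rank"] = df["combined_score"].rank(method="min").astype(int)
    return df


def permutation_test(
    network: RegNetwork,
    match: MatchSubnetwork,
    rounds: int = 100_000,
    seed: int = 0,
    target_universe: list | None = None,
    batch: int = 2_000,
) -> pd.DataFrame:
    """Permutation empirical p-values for the observed combined scores.

    Per round, independently for each type, the target labels of the whole
    universe are permuted, so the type's per-target minimum-score
    contributions land on a random subset of targets; combined scores are the
    product of the contributions a target receives (no contribution -> no
    score that round).  empirical_p = (1 + #{rounds with permuted score <=
    observed}) / (1 + rounds).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    minima = _target_type_minima(network, match)
    observed = combined_scores(network, match)
    if observed.empty:
        return pd.DataFrame(columns=["target", "combined_score", "empirical_p"])

    if target_universe is None:
        g = network.graph
        classes = {g.nodes[t]["node_class"] for t in observed.index}
        target_universe = [
            n for n in g.nodes if g.nodes[n]["node_class"] in classes
        ]
    universe = list(target_universe)
    n_univ = len(universe)
    pos = {t: i for i, t in enumerate(universe)}

    types = sorted(minima["type"].unique())
    # per type: contribution values and the universe positions they sit on
    contrib = []
    for typ in types:
        sub = minima.loc[minima["type"] == typ]
        vals = np.log(sub["edge_score"].to_numpy())
        contrib.append(vals)

    obs_targets = [t for t in observed.index]
    obs_idx = np.array([pos[t] for t in obs_targets])
    log_obs = np.log(observed.to_numpy())

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(obs_targets), dtype=np.int64)
    done = 0
    while done < rounds:
        b = min(batch, rounds - done)
        logsum = np.zeros((b, n_univ))
        npresent = np.zeros((b, n_univ), dtype=np.int16)
        for vals in contrib:
            k = len(vals)
            # permute labels: contributions land on the first k slots of a
            # fresh permutation of the universe, with shuffled assignment
            perm = np.argsort(rng.random((b, n_univ)), axis=1)[:, :k]
            rowix = np.repeat(np.arange(b), k)
            order = np.argsort(rng.random((b, k)), axis=1)
            np.add.at(logsum, (rowix, perm.ravel()), vals[order].ravel())
            np.add.at(npresent, (rowix, perm.ravel()), 1)
        perm_log = np.where(npresent > 0, logsum, np.inf)
        hits += (perm_log[:, obs_idx] <= log_obs + 1e-12).sum(axis=0)
        done += b

    p = (1 + hits) / (1 + rounds)
    return pd.DataFrame(
        {
            "target": obs_targets,
            "combined_score": observed.to_numpy(),
            "empirical_p": p,
        }
    )


def run_query(
    network: RegNetwork,
    query: QueryPath,
    rounds: int = 100_000,
    seed: int = 0,
    target_universe: list | None = None,
) -> pd.DataFrame:
    """Match, score, rank and test in one call; the full query result table."""
    match = match_paths(network, query)
    scores = combined_scores(network, match)
    if scores.empty:
        return pd.DataFrame(columns=["target", "combined_score", "rank", "empirical_p"])
    ranking = rank_targets(scores)
    pvals = permutation_test(
        network, match, rounds=rounds, seed=seed, target_universe=target_universe
    )
    return ranking.merge(pvals[["target", "empirical_p"]], on="target")
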