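"""Five-class regulatory network construction and two-rank edge scoring.

The network has node classes TF, Peak, SNP, Gene and ParalogGroup, with edges
TF->Peak, Peak->Gene, SNP->Gene (drawn when the feature lies within a window
of the gene TSS) and Gene->ParalogGroup.  Peak->Gene and SNP->Gene edges are
scored against all regulatory relationships of the same type (peaks in the
same cell line, SNPs of the same cancer trait) by two criteria — the rank of
the regulatory feature (peak height, association p-value) and the rank of its
distance from the gene, measured as the number of genes whose TSS lies closer
to the feature.  The edge score is the fraction of same-type relationships
ranking at least as highly on both criteria, so a small score marks a strong,
proximal feature.

A minimal peak caller from extended-read coverage is included: candidate
regions are maximal runs of coverage >= 4 containing a position of height
>= 8, retained when the ChIP-vs-IgG read-count contrast is significant under
the Audic-Claverie comparative count probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

NODE_TF = "TF"
NODE_PEAK = "Peak"
NODE_SNP = "SNP"
NODE_GENE = "Gene"
NODE_GROUP = "ParalogGroup"


# ---------------------------------------------------------------------------
# paralog groups
# ---------------------------------------------------------------------------

def merge_paralogs(pairs) -> dict[str, frozenset[str]]:
    """Merge paralog pairs into groups (connected components; union-find).

    Returns a map group_id -> member set; the group id is derived from the
    sorted member list so regeneration is deterministic.  Self-pairs are
    ignored with a warning.
    """
    parent: dict[str, str] = {}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        if a == b:
            logger.warning("ignoring self-pair (%s, %s)", a, b)
            continue
        for g in (a, b):
            parent.setdefault(g, g)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    members: dict[str, set[str]] = {}
    for g in parent:
        members.setdefault(find(g), set()).add(g)
    return {
        "grp:" + "|".join(sorted(m)): frozenset(m) for m in members.values()
    }


def group_of_gene(groups: dict[str, frozenset[str]]) -> dict[str, str]:
    out = {}
    for gid, members in groups.items():
        for g in members:
            out[g] = gid
    return out


# ---------------------------------------------------------------------------
# ranked distance
# ---------------------------------------------------------------------------

def ranked_distance(
    feature_position: tuple[str, int], genes: pd.DataFrame, target: str
) -> int:
    """Number of genes (excluding the target) whose TSS is strictly closer to
    the feature than the target's TSS; equidistant ties do not count."""
    chrom, pos = feature_position
    row = genes.loc[genes["gene_id"] == target]
    if row.empty:
        raise ValueError(f"target {target!r} not in gene table")
    if row["chrom"].iloc[0] != chrom:
        raise ValueError("feature and target gene on different chromosomes")
    r = abs(int(row["tss"].iloc[0]) - pos)
    same = genes.loc[(genes["chrom"] == chrom) & (genes["gene_id"] != target)]
    return int((np.abs(same["tss"].to_numpy() - pos) < r).sum())


def _ranked_distances_bulk(tss_sorted: np.ndarray, pos: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorised strictly-closer counts: #{tss : |tss - pos| < r}, the target
    itself excluded by its zero-distance contribution (|t-p| = r exactly)."""
    lo = np.searchsorted(tss_sorted, pos - r, side="right")
    hi = np.searchsorted(tss_sorted, pos + r, side="left")
    return hi - lo


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class RegNetwork:
    """Directed regulatory graph plus its scored feature->gene edge table."""

    graph: nx.DiGraph
    edges: pd.DataFrame  # source, target, edge_kind, type, feature_rank, distance_rank, edge_score

    def targets(self, node_class: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["node_class"] == node_class]


def _competition_rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    s = pd.Series(values if ascending else -values)
    return s.rank(method="min").to_numpy().astype(int)


def build_network(
    peaks: pd.DataFrame | None,
    snps: pd.DataFrame | None,
    genes: pd.DataFrame,
    groups: dict[str, frozenset[str]] | None = None,
    window: int = 500_000,
    include_singleton_groups: bool = False,
) -> RegNetwork:
    """Assemble the five-class network and rank its feature->gene edges.

    Peak->Gene and SNP->Gene edges exist iff |feature midpoint - TSS| <=
    ``window`` on the same chromosome.  Within each type (cell line / trait),
    feature_rank orders peaks by descending height or SNPs by ascending
    p-value, and distance_rank orders edges by ascending ranked distance,
    both with competition ("min") ranking.  ``include_singleton_groups``
    additionally gives every ungrouped gene its own paralog-group node so a
    group-terminal query ranks the whole gene universe.
    """
    if snps is not None and len(snps) and (snps["p_value"] <= 0).any():
        raise ValueError("SNPs with p <= 0 rejected")

    g = nx.DiGraph()
    for _, row in genes.iterrows():
        g.add_node(("gene", row["gene_id"]), node_class=NODE_GENE,
                   gene_id=row["gene_id"])

    groups = dict(groups or {})
    if include_singleton_groups:
        grouped = {m for mem in groups.values() for m in mem}
        for gid in genes["gene_id"]:
            if gid not in grouped:
                groups[f"grp:{gid}"] = frozenset([gid])
    gene_universe = set(genes["gene_id"])
    for grp_id, members in groups.items():
        g.add_node(("group", grp_id), node_class=NODE_GROUP, group_id=grp_id)
        for m in members:
            if m in gene_universe:
                g.add_edge(("gene", m), ("group", grp_id), edge_kind="gene_group")

    # per-chromosome sorted TSS for window joins and ranked distances
    by_chrom = {
        chrom: sub.sort_values("tss").reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom")
    }

    edge_rows = []

    def feature_edges(chrom, pos, radius):
        sub = by_chrom.get(chrom)
        if sub is None:
            return sub, np.empty(0, dtype=int)
        tss = sub["tss"].to_numpy()
        lo = np.searchsorted(tss, pos - radius, side="left")
        hi = np.searchsorted(tss, pos + radius, side="right")
        return sub, np.arange(lo, hi)

    if peaks is not None and len(peaks):
        for i, row in peaks.reset_index(drop=True).iterrows():
            peak_node = ("peak", i)
            g.add_node(peak_node, node_class=NODE_PEAK, height=row["height"],
                       cell_line=row["cell_line"], tf=row["tf"],
                       chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]))
            tf_node = ("tf", row["tf"], row["cell_line"])
            if tf_node not in g:
                g.add_node(tf_node, node_class=NODE_TF, tf=row["tf"],
                           cell_line=row["cell_line"])
            g.add_edge(tf_node, peak_node, edge_kind="tf_peak")
            mid = (int(row["start"]) + int(row["end"])) // 2
            sub, idx = feature_edges(row["chrom"], mid, window)
            if len(idx) == 0:
                continue
            tss_sorted = sub["tss"].to_numpy()
            tss_hit = tss_sorted[idx]
            rd = _ranked_distances_bulk(
                tss_sorted, np.full(len(idx), mid), np.abs(tss_hit - mid)
            )
            for j, d in zip(idx, rd):
                edge_rows.append(
                    ("peak", i, sub["gene_id"].iloc[j], row["cell_line"],
                     float(row["height"]), int(d))
                )

    if snps is not None and len(snps):
        for i, row in snps.reset_index(drop=True).iterrows():
            snp_node = ("snp", row["snp_id"])
            g.add_node(snp_node, node_class=NODE_SNP, trait=row["trait"],
                       p_value=row["p_value"], chrom=row["chrom"], pos=int(row["pos"]))
            sub, idx = feature_edges(row["chrom"], int(row["pos"]), window)
            if len(idx) == 0:
                continue
            tss_sorted = sub["tss"].to_numpy()
            tss_hit = tss_sorted[idx]
            rd = _ranked_distances_bulk(
                tss_sorted, np.full(len(idx), int(row["pos"])),
                np.abs(tss_hit - int(row["pos"])),
            )
            for j, d in zip(idx, rd):
                edge_rows.append(
                    ("snp", row["snp_id"], sub["gene_id"].iloc[j], row["trait"],
                     float(row["p_value"]), int(d))
                )

    edges = pd.DataFrame(
        edge_rows,
        columns=["edge_kind", "source_id", "gene_id", "type", "feature_value",
                 "ranked_distance"],
    )
    # within-type ranks
    edges["feature_rank"] = 0
    edges["distance_rank"] = 0
    for (kind, typ), idx in edges.groupby(["edge_kind", "type"]).groups.items():
        sub = edges.loc[idx]
        asc = kind == "snp"  # SNPs: ascending p-value; peaks: descending height
        edges.loc[idx, "feature_rank"] = _competition_rank(
            sub["feature_value"].to_numpy(), ascending=asc
        )
        edges.loc[idx, "distance_rank"] = _competition_rank(
            sub["ranked_distance"].to_numpy(), ascending=True
        )
    edges["edge_score"] = np.nan

    for _, row in edges.iterrows():
        src = ("peak", row["source_id"]) if row["edge_kind"] == "peak" else ("snp", row["source_id"])
        g.add_edge(
            src, ("gene", row["gene_id"]), edge_kind=f"{row['edge_kind']}_gene",
            type=row["type"], feature_rank=int(row["feature_rank"]),
            distance_rank=int(row["distance_rank"]),
        )
    return RegNetwork(graph=g, edges=edges)


def _dominance_fraction(fr: np.ndarray, dr: np.ndarray) -> np.ndarray:
    """fraction of pairs with fr' <= fr and dr' <= dr (inclusive of self)."""
    n = len(fr)
    order = np.lexsort((dr, fr))
    fr_s, dr_s = fr[order], dr[order]
    counts = np.zeros(n, dtype=np.int64)
    # Fenwick tree over compressed distance ranks
    uniq = np.unique(dr_s)
    comp = np.searchsorted(uniq, dr_s) + 1
    tree = np.zeros(len(uniq) + 1, dtype=np.int64)

    def update(i):
        while i <= len(uniq):
            tree[i] += 1
            i += i & (-i)

    def query(i):
        s = 0
        while i > 0:
            s += tree[i]
            i -= i & (-i)
        return s

    i = 0
    while i < n:
        j = i
        while j < n and fr_s[j] == fr_s[i]:
            j += 1
        for k in range(i, j):  # insert the whole equal-feature-rank block
            update(comp[k])
        for k in range(i, j):
            counts[order[k]] = query(comp[k])
        i = j
    return counts / n


def score_edges(network: RegNetwork) -> RegNetwork:
    """Set edge_score = fraction of same-type relationships with feature_rank
    and distance_rank both at least as high (<=); the edge counts itself, so
    scores lie in [1/N, 1]."""
    edges = network.edges
    for (kind, typ), idx in edges.groupby(["edge_kind", "type"]).groups.items():
        sub = edges.loc[idx]
        frac = _dominance_fraction(
            sub["feature_rank"].to_numpy(), sub["distance_rank"].to_numpy()
        )
        edges.loc[idx, "edge_score"] = frac
    # push scores onto the graph edges
    for _, row in edges.iterrows():
        src = ("peak", row["source_id"]) if row["edge_kind"] == "peak" else ("snp", row["source_id"])
        network.graph.edges[src, ("gene", row["gene_id"])]["edge_score"] = row["edge_score"]
    return network


# ---------------------------------------------------------------------------
# peak calling from extended-read coverage
# ---------------------------------------------------------------------------

def audic_claverie_p(chip: int, igg: int, depth_ratio: float = 1.0) -> float:
    """One-sided Audic-Claverie comparative count probability
    P(Y >= chip | igg) with Y the null ChIP count given the IgG count and
    ``depth_ratio`` = ChIP library depth / IgG depth.  Exact summation of
    p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) over the upper tail via
    log-factorials (summing the complementary lower tail)."""
    x, y_obs, r = int(igg), int(chip), float(depth_ratio)
    ys = np.arange(0, y_obs)
    if len(ys) == 0:
        return 1.0
    logp = (
        ys * np.log(r)
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * np.log1p(r)
    )
    lower = np.exp(logp).sum()
    return float(max(1.0 - lower, 0.0))


def call_peaks(
    chip_starts: np.ndarray,
    igg_starts: np.ndarray,
    genome_length: int,
    fragment_length: int = 200,
    min_height: int = 8,
    min_overlap: int = 4,
    alpha: float = 0.05,
    tf: str = "TF",
    cell_line: str = "cell",
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Call peaks from extended-read start positions.

    Reads are extended to ``fragment_length``; coverage at a position is the
    number of overlapping extended reads.  Candidate regions are maximal runs
    with coverage >= ``min_overlap`` that contain a position with coverage >=
    ``min_height``; each region's ChIP read count is tested against the IgG
    count in the same region with the Audic-Claverie probability and regions
    with p < ``alpha`` (uncorrected) are reported with height = max coverage.
    """
    chip_starts = np.asarray(chip_starts, dtype=int)
    igg_starts = np.asarray(igg_starts, dtype=int)
    if len(chip_starts) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "tf", "cell_line", "height", "p_value"])

    def coverage(starts):
        cov = np.zeros(genome_length + fragment_length + 1, dtype=np.int64)
        np.add.at(cov, starts, 1)
        np.add.at(cov, starts + fragment_length, -1)
        return np.cumsum(cov)[:genome_length]

    cov = coverage(chip_starts)
    above = cov >= min_overlap
    # maximal runs of `above`
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[0::2], edges[1::2]
    depth_ratio = len(chip_starts) / max(len(igg_starts), 1)

    rows = []
    for s, e in zip(starts, ends):
        height = int(cov[s:e].max())
        if height < min_height:
            continue
        n_chip = int(((chip_starts + fragment_length > s) & (chip_starts < e)).sum())
        n_igg = int(((igg_starts + fragment_length > s) & (igg_starts < e)).sum())
        p = audic_claverie_p(n_chip, n_igg, depth_ratio)
        if p < alpha:
            rows.append((chrom, int(s), int(e), tf, cell_line, height, p))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tf", "cell_line", "height", "p_value"]
    )
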