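import numpy as np
import pandas as pd
import pytest

import masterreg as mr
from masterreg import netquery, regnet


@pytest.fixture
def small_genes():
    return pd.DataFrame(
        {
            "gene_id": ["A", "B", "C"],
            "chrom": ["chr1", "chr1", "chr1"],
            "tss": [100_000, 600_000, 2_000_000],
            "strand": ["+", "+", "-"],
        }
    )


def random_instance(rng, n_genes=None, n_peaks=None, n_snps=None, span=2_000_000):
    """Small random genes/peaks/snps tables for oracle-equivalence checks."""
    n_genes = n_genes or int(rng.integers(2, 12))
    n_peaks = n_peaks if n_peaks is not None else int(rng.integers(0, 15))
    n_snps = n_snps if n_snps is not None else int(rng.integers(0, 15))
    chroms = ["chr1", "chr2"]
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": rng.choice(chroms, n_genes),
            "tss": rng.choice(span, n_genes, replace=False),
            "strand": rng.choice(["+", "-"], n_genes),
        }
    )
    starts = rng.integers(0, span, n_peaks)
    peaks = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n_peaks),
            "start": starts,
            "end": starts + 200,
            "tf": rng.choice(["TFa", "TFb"], n_peaks),
            "cell_line": rng.choice(["cl1", "cl2"], n_peaks),
            "height": rng.integers(1, 40, n_peaks),
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chrom": rng.choice(chroms, n_snps),
            "pos": rng.integers(0, span, n_snps),
            "trait": rng.choice(["t1", "t2"], n_snps),
            "p_value": rng.uniform(1e-12, 1e-4, n_snps),
        }
    )
    return genes, peaks, snps


def toy_network(type_scores: dict[str, dict[str, float]]) -> tuple:
    """Build a scored RegNetwork directly from {cell_line: {gene: min_score}}.

    One peak per (cell line, gene) carrying the given edge score; returns the
    network and the TF->Peak->Gene query for it.
    """
    import networkx as nx

    g = nx.DiGraph()
    genes = sorted({t for d in type_scores.values() for t in d})
    for gid in genes:
        g.add_node(("gene", gid), node_class=regnet.NODE_GENE, gene_id=gid)
    rows = []
    k = 0
    for cl, per_gene in type_scores.items():
        tf_node = ("tf", cl)
        g.add_node(tf_node, node_class=regnet.NODE_TF, cell_line=cl)
        for gid, score in per_gene.items():
            pk = ("peak", k)
            k += 1
            g.add_node(pk, node_class=regnet.NODE_PEAK, cell_line=cl)
            g.add_edge(tf_node, pk, edge_kind="tf_peak")
            g.add_edge(pk, ("gene", gid), edge_kind="peak_gene", type=cl,
                       edge_score=score, feature_rank=1, distance_rank=1)
            rows.append(("peak", k, gid, cl, score))
    edges = pd.DataFrame(
        rows, columns=["edge_kind", "source_id", "gene_id", "type", "edge_score"]
    )
    net = regnet.RegNetwork(graph=g, edges=edges)
    query = netquery.QueryPath(
        [netquery.QueryNode("TF"), netquery.QueryNode("Peak"), netquery.QueryNode("Gene")]
    )
    return net, query


def match_phases(true_labels, inferred_labels) -> float:
    """Best-bipartite-matching phase agreement (labels are exchangeable)."""
    from scipy.optimize import linear_sum_assignment

    conf = pd.crosstab(pd.Series(true_labels), pd.Series(inferred_labels))
    r, c = linear_sum_assignment(-conf.to_numpy())
    return conf.to_numpy()[r, c].sum() / len(true_labels)


@pytest.fixture
def phase_match():
    return match_phases
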