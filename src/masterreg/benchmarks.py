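"""End-to-end recovery simulations on the synthetic generators.

Each function sets up the study-scale synthetic scenario for one pipeline
stage — convergent-network target ranking, permutation-null calibration,
single-cell drug-gene recovery with joint phase inference, CGE fitness
closed form, and set-level FDR control — runs the stage, and reports how
well the planted ground truth is recovered.  They are used by the test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from . import cge, netquery, regnet, scdrug, setstats, synth
from .netquery import QueryNode, QueryPath
from .synth import GroundTruth


def _chip_query() -> QueryPath:
    return QueryPath(
        [QueryNode("TF"), QueryNode("Peak"), QueryNode("Gene"), QueryNode("ParalogGroup")]
    )


def network_recovery(
    seed: int,
    n_genes: int = 500,
    n_paralog_pairs: int = 60,
    n_planted_groups: int = 3,
    n_cancers: int = 5,
    tfs_per_cancer: int = 3,
    rounds: int = 10_000,
) -> dict:
    """Convergent ChIP signal from several cancer types onto a few paralog
    groups: how highly do the planted groups rank, and do they attain the
    smallest permutation p-value?"""
    rng = np.random.default_rng(seed)
    genes, pairs = synth.gen_annotation(n_genes, n_paralog_pairs, seed=seed)
    groups = regnet.merge_paralogs(pairs)
    group_ids = sorted(groups)
    chosen = rng.choice(len(group_ids), size=n_planted_groups, replace=False)
    planted_groups = [group_ids[i] for i in chosen]
    planted_genes = [sorted(groups[g])[0] for g in planted_groups]
    truth = GroundTruth(planted_master_genes=planted_genes)

    tf_map = {
        f"cancer{i + 1}": [f"TF{i + 1}_{j + 1}" for j in range(tfs_per_cancer)]
        for i in range(n_cancers)
    }
    peaks = synth.gen_peaks(genes, tf_map, truth, seed=seed + 1)
    net = regnet.build_network(
        peaks, None, genes, groups, include_singleton_groups=True
    )
    regnet.score_edges(net)

    result = netquery.run_query(net, _chip_query(), rounds=rounds, seed=seed + 2)
    result = result.set_index("target")
    planted_nodes = [("group", g) for g in planted_groups]
    planted_ranks = [int(result.loc[[n], "rank"].iloc[0]) for n in planted_nodes]
    planted_p = [float(result.loc[[n], "empirical_p"].iloc[0]) for n in planted_nodes]
    return {
        "n_targets": len(result),
        "planted_groups": planted_groups,
        "planted_ranks": planted_ranks,
        "planted_p": planted_p,
        "min_p_overall": float(result["empirical_p"].min()),
        "in_top_2m": sum(r <= 2 * n_planted_groups for r in planted_ranks),
        "result": result.reset_index(),
    }


def _null_network(rng, n_targets: int, n_types: int):
    """A label-randomized network: every type covers every target with an
    i.i.d. uniform edge score, so targets are exchangeable under the null."""
    g = nx.DiGraph()
    targets = [f"g{i}" for i in range(n_targets)]
    for t in targets:
        g.add_node(("gene", t), node_class=regnet.NODE_GENE, gene_id=t)
    k = 0
    for j in range(n_types):
        cl = f"cl{j}"
        g.add_node(("tf", cl), node_class=regnet.NODE_TF, cell_line=cl)
        for t in targets:
            pk = ("peak", k)
            k += 1
            g.add_node(pk, node_class=regnet.NODE_PEAK, cell_line=cl)
            g.add_edge(("tf", cl), pk, edge_kind="tf_peak")
            g.add_edge(pk, ("gene", t), edge_kind="peak_gene", type=cl,
                       edge_score=float(rng.uniform(0, 1)))
    net = regnet.RegNetwork(graph=g, edges=pd.DataFrame())
    query = QueryPath([QueryNode("TF"), QueryNode("Peak"), QueryNode("Gene")])
    return net, query


def permutation_calibration(
    seed: int,
    n_networks: int = 1_000,
    rounds: int = 1_000,
    n_targets: int = 20,
    n_types: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Empirical p-values on null networks must be super-uniform: the ECDF
    at ``alpha`` may not exceed alpha by more than Monte Carlo error."""
    rng = np.random.default_rng(seed)
    pvals = []
    for i in range(n_networks):
        net, query = _null_network(rng, n_targets, n_types)
        match = netquery.match_paths(net, query)
        res = netquery.permutation_test(
            net, match, rounds=rounds, seed=int(rng.integers(2**31))
        )
        # one designated target per network keeps the p-values independent
        pvals.append(float(res.set_index("target").loc[[("gene", "g0")], "empirical_p"].iloc[0]))
    pvals = np.asarray(pvals)
    ecdf = float(np.mean(pvals <= alpha))
    mc_error = float(np.sqrt(alpha * (1 - alpha) / n_networks))
    return {"ecdf_at_alpha": ecdf, "alpha": alpha, "mc_error": mc_error,
            "n_networks": n_networks, "pvals": pvals}


def drug_gene_recovery(
    seed: int,
    n_cells: int = 200,
    n_genes: int = 500,
    n_planted: int = 20,
    effect: float = 1.5,
    pairs: tuple[str, ...] = ("pairA", "pairB"),
    restarts: int = 10,
    iters: int = 100,
) -> dict:
    """Planted sensitive-only monotone drug genes: fraction recovered in the
    top 2x|planted| of the sensitive-minus-resistant drug-EP ranking, and
    phase-assignment agreement, per cell-line pair."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    markers = {
        ph: [gene_ids[3 * k + j] for j in range(3)]
        for k, ph in enumerate(synth.DEFAULT_PHASES)
    }
    free = gene_ids[9:]
    chosen = rng.choice(len(free), size=n_planted, replace=False)
    planted = {
        free[i]: (int(rng.choice([-1, 1])), int(rng.choice([-1, 1])), effect)
        for i in chosen
    }
    truth = GroundTruth(planted_drug_genes=planted)
    counts, meta = synth.gen_sc_counts(
        n_cells, n_genes, markers, truth, pairs=pairs, seed=seed + 1
    )

    from scipy.optimize import linear_sum_assignment

    per_pair = {}
    for pair in pairs:
        sel = (meta["pair_id"] == pair).to_numpy()
        counts_p = counts.iloc[:, sel]
        meta_p = meta.loc[sel].reset_index(drop=True)
        X = scdrug.rank_normalize(counts_p)
        ph = scdrug.infer_phases(
            X, meta_p, markers, iters=iters, restarts=restarts, seed=seed + 2
        )
        conf = pd.crosstab(meta_p["true_phase"], ph.phases.to_numpy())
        r, c = linear_sum_assignment(-conf.to_numpy())
        agreement = conf.to_numpy()[r, c].sum() / len(meta_p)

        phases = ph.phases.to_numpy()
        ep_s = scdrug.drug_explanatory_power(X, meta_p, phases, "sensitive")
        ep_r = scdrug.drug_explanatory_power(X, meta_p, phases, "resistant")
        ranked = scdrug.rank_drug_genes(ep_s, ep_r)
        top = set(ranked.head(2 * n_planted)["gene_id"])
        recovery = len(top & set(planted)) / n_planted
        per_pair[pair] = {"recovery": recovery, "phase_agreement": float(agreement)}
    return {"per_pair": per_pair, "planted": sorted(planted)}


def cge_closed_form(seed: int, n_tags: int = 200, depth: float = 10_000.0) -> dict:
    """Planted s = -0.5 over 2 doublings: the median per-tag log2 ratio has
    closed form -1; ten all-negative distinct ratios give exact two-sided
    signed-rank p = 2/1024."""
    truth = GroundTruth(tag_fitness={f"tag{i:04d}": -0.5 for i in range(n_tags)})
    t = synth.gen_cge_counts(n_tags, depth=depth, truth=truth, n_doublings=2, seed=seed)
    ratios = cge.fitness_ratios(cge.filter_tags(t, 5))
    res = cge.test_fitness(ratios["log2_ratio"])
    ten = ratios["log2_ratio"].iloc[:10]
    exact = cge.test_fitness(ten) if (ten < 0).all() else None
    return {
        "median_log2_ratio": res.median,
        "n_tags": res.n_tags,
        "all_negative_10tag_p": None if exact is None else exact.wilcoxon_p,
    }


def set_fdr_simulation(
    seed: int,
    n_sims: int = 100,
    n_sets: int = 50,
    set_size: int = 10,
    n_planted: int = 5,
    shift: float = 0.5,
    noise_sd: float = 0.2,
    n_pairs: int = 8,
) -> dict:
    """Planted regulated sets at 1% BH FDR: per-simulation recovery of every
    planted set, and the aggregate realized false-discovery proportion."""
    rng = np.random.default_rng(seed)
    sets = {
        f"S{i}": [f"f{set_size * i + j}" for j in range(set_size)]
        for i in range(n_sets)
    }
    n_recovered_all = 0
    false_pos = 0
    total_pos = 0
    for i in range(n_sims):
        names = [f"S{k}" for k in rng.choice(n_sets, size=n_planted, replace=False)]
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        truth = GroundTruth(
            regulated_sets={n: float(s * shift) for n, s in zip(names, signs)}
        )
        fc = synth.gen_foldchanges(
            sets, truth, n_pairs=n_pairs, noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        res = setstats.run(fc, sets, fdr_level=0.01)
        flagged = set(res.loc[res["significant"], "set_id"])
        if set(names) <= flagged:
            n_recovered_all += 1
        false_pos += len(flagged - set(names))
        total_pos += len(flagged)
    return {
        "recovery_rate": n_recovered_all / n_sims,
        "realized_fdp": false_pos / max(total_pos, 1),
        "n_sims": n_sims,
    }
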