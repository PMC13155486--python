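"""Synthetic-data generators: planted structure, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest

import masterreg as mr
from masterreg import io, regnet, synth
from masterreg.synth import ConfigError, GroundTruth


# ------------------------------------------------------------- annotation

def test_gen_annotation_counts_and_determinism():
    genes, pairs = synth.gen_annotation(100, 10, seed=1)
    assert len(genes) == 100
    assert len(pairs) == 10
    genes2, pairs2 = synth.gen_annotation(100, 10, seed=1)
    assert genes.to_csv() == genes2.to_csv()  # byte-for-byte
    assert pairs == pairs2
    # unique TSS per chromosome
    assert not genes.duplicated(subset=["chrom", "tss"]).any()


def test_gen_annotation_pairs_chain_into_merged_groups():
    _, pairs = synth.gen_annotation(40, 25, chain_fraction=0.9, seed=3)
    groups = regnet.merge_paralogs(pairs)
    # chaining must produce at least one group larger than a bare pair
    assert max(len(m) for m in groups.values()) >= 3


def test_gen_annotation_rejects_impossible_requests():
    with pytest.raises(ConfigError):
        synth.gen_annotation(3, 10, seed=0)
    with pytest.raises(ConfigError):
        synth.gen_annotation(100, 5, genome_length=50, seed=0)


# ------------------------------------------------------------------ peaks

@pytest.fixture
def planted_setup():
    genes, pairs = synth.gen_annotation(80, 8, seed=11)
    truth = GroundTruth(planted_master_genes=list(genes["gene_id"].iloc[:3]))
    tfs = {f"cancer{i}": [f"TF{i}a", f"TF{i}b"] for i in range(5)}
    return genes, truth, tfs


def test_gen_peaks_planted_convergence(planted_setup):
    genes, truth, tfs = planted_setup
    peaks = synth.gen_peaks(genes, tfs, truth, background_rate=2.0, seed=4)
    gi = genes.set_index("gene_id")
    for g in truth.planted_master_genes:
        tss, chrom = gi.loc[g, "tss"], gi.loc[g, "chrom"]
        mid = (peaks["start"] + peaks["end"]) // 2
        near = peaks[(peaks["chrom"] == chrom) & ((mid - tss).abs() <= 6_000)]
        assert near["cell_line"].nunique() >= 5  # every cancer type's line


def test_gen_peaks_zero_background_emits_only_planted(planted_setup):
    genes, truth, tfs = planted_setup
    peaks = synth.gen_peaks(genes, tfs, truth, background_rate=0.0, seed=4)
    n_tracks = sum(len(v) for v in tfs.values())
    assert len(peaks) == n_tracks * len(truth.planted_master_genes)


def test_gen_peaks_planted_heights_exceed_background(planted_setup):
    genes, truth, tfs = planted_setup
    peaks = synth.gen_peaks(genes, tfs, truth, background_rate=5.0, seed=9)
    bg_only = synth.gen_peaks(
        genes, tfs, GroundTruth(), background_rate=5.0, seed=9
    )
    planted_min = synth.gen_peaks(
        genes, tfs, truth, background_rate=0.0, seed=9
    )["height"].min()
    assert planted_min > bg_only["height"].median()
    assert len(peaks) > len(bg_only)


def test_gen_peaks_errors(planted_setup):
    genes, truth, _ = planted_setup
    with pytest.raises(ConfigError):
        synth.gen_peaks(genes, {}, truth)
    bad = GroundTruth(planted_master_genes=["NOPE"])
    with pytest.raises(ConfigError):
        synth.gen_peaks(genes, {"c": ["TF"]}, bad)


# ------------------------------------------------------------------- snps

def test_gen_snps_planted_below_background(planted_setup):
    genes, truth, _ = planted_setup
    snps = synth.gen_snps(genes, truth, n_background=50, seed=2)
    snps_b = synth.gen_snps(genes, truth, n_background=50, seed=2)
    assert snps.to_csv() == snps_b.to_csv()
    only_planted = synth.gen_snps(genes, truth, n_background=0, seed=2)
    assert len(only_planted) == 3 * len(truth.planted_master_genes)
    bg = snps.loc[~snps["snp_id"].isin(only_planted["snp_id"])]
    # disjoint p-value ranges by construction
    assert only_planted["p_value"].max() < 1e-9 <= bg["p_value"].min() + 1


# ------------------------------------------------------------- sc counts

def sc_setup(effect=1.5, n_cells=120, seed=0):
    gene_ids = [f"G{i:05d}" for i in range(30)]
    markers = {
        ph: [gene_ids[3 * k + j] for j in range(3)]
        for k, ph in enumerate(synth.DEFAULT_PHASES)
    }
    planted = {gene_ids[20]: (-1, -1, effect), gene_ids[21]: (1, 1, effect)}
    truth = GroundTruth(planted_drug_genes=planted)
    counts, meta = synth.gen_sc_counts(
        n_cells, 30, markers, truth, pairs=("p1",), seed=seed
    )
    return counts, meta, truth, markers


def test_gen_sc_counts_monotone_group_means_in_sensitive_cells():
    counts, meta, truth, _ = sc_setup(n_cells=250, seed=6)
    down_gene = next(g for g, v in truth.planted_drug_genes.items() if v[0] == -1)
    sens = (meta["status"] == "sensitive").to_numpy()
    vals = counts.loc[down_gene].to_numpy()
    means = [
        vals[sens & (meta["conc_level"] == d).to_numpy()].mean() for d in range(3)
    ]
    assert means[0] > means[-1]  # planted "down" direction
    # resistant cells show no systematic dose trend
    res = ~sens
    rmeans = [
        vals[res & (meta["conc_level"] == d).to_numpy()].mean() for d in range(3)
    ]
    assert abs(rmeans[0] - rmeans[-1]) < 0.5 * abs(means[0] - means[-1])


def test_gen_sc_counts_zero_effect_matches_between_statuses():
    gene_ids = [f"G{i:05d}" for i in range(30)]
    truth = GroundTruth(planted_drug_genes={gene_ids[20]: (-1, -1, 0.0)})
    counts, meta = synth.gen_sc_counts(
        200, 30, {"G1": [gene_ids[0]], "S": [gene_ids[1]]}, truth,
        pairs=("p1",), n_conc=2, n_time=1, seed=7,
    )
    v = counts.loc[gene_ids[20]]
    sens = v[(meta["status"] == "sensitive").to_numpy()]
    res = v[(meta["status"] == "resistant").to_numpy()]
    # equal in expectation: means within a few standard errors
    se = np.sqrt(sens.var() / len(sens) + res.var() / len(res))
    assert abs(sens.mean() - res.mean()) < 4 * se


def test_gen_sc_counts_markers_elevated_and_truth_recorded():
    counts, meta, truth, markers = sc_setup(seed=8)
    phase = pd.Series([truth.phase_of_cell[c] for c in counts.columns])
    g1_marker = markers["G1"][0]
    v = counts.loc[g1_marker].to_numpy()
    inside = v[(phase == "G1").to_numpy()].mean()
    outside = v[(phase != "G1").to_numpy()].mean()
    assert inside > 2 * outside


def test_gen_sc_counts_determinism_and_errors():
    c1, m1 = sc_setup(seed=9)[:2]
    c2, m2 = sc_setup(seed=9)[:2]
    assert c1.to_csv() == c2.to_csv()
    assert m1.to_csv() == m2.to_csv()
    with pytest.raises(ConfigError):
        synth.gen_sc_counts(
            10, 30, {"G1": ["G00000"], "S": ["G00000"]}, GroundTruth(), seed=0
        )


# ------------------------------------------------------------- cge counts

def test_gen_cge_counts_neutral_and_selected_expectations():
    tags = {f"tag{i:04d}": 0.0 for i in range(200)}
    truth = GroundTruth(tag_fitness=tags)
    t = synth.gen_cge_counts(200, depth=5_000, truth=truth, n_doublings=2, seed=1)
    ratio = np.log2(
        (t["mutated_day8"] / t["restored_day8"])
        / (t["mutated_day2"] / t["restored_day2"])
    )
    assert abs(np.median(ratio)) < 0.05

    truth_sel = GroundTruth(tag_fitness={k: -0.5 for k in tags})
    t2 = synth.gen_cge_counts(200, depth=5_000, truth=truth_sel, n_doublings=2, seed=1)
    ratio2 = np.log2(
        (t2["mutated_day8"] / t2["restored_day8"])
        / (t2["mutated_day2"] / t2["restored_day2"])
    )
    # closed form: 2^(s * n) -> log2 ratio = -1
    assert np.median(ratio2) == pytest.approx(-1.0, abs=0.1)
    assert t2.to_csv() == synth.gen_cge_counts(
        200, depth=5_000, truth=truth_sel, n_doublings=2, seed=1
    ).to_csv()


# ------------------------------------------------------------ fold changes

def test_gen_foldchanges_exact_shift_and_missingness():
    sets = {"S1": ["f1", "f2"], "S2": ["f3", "f4", "f5"]}
    truth = GroundTruth(regulated_sets={"S1": 0.5})
    fc = synth.gen_foldchanges(sets, truth, n_pairs=4, noise_sd=0.0, seed=0)
    assert np.allclose(fc.loc[["f1", "f2"]], 0.5)
    assert np.allclose(fc.loc[["f3", "f4", "f5"]], 0.0)

    fc_miss = synth.gen_foldchanges(
        sets, truth, n_pairs=200, noise_sd=0.1, missing_frac=0.2, seed=1
    )
    frac = fc_miss.isna().to_numpy().mean()
    assert frac == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / fc_miss.size))


# ------------------------------------------------------------- round trips

def test_tables_round_trip_through_writers(tmp_path, planted_setup):
    genes, truth, tfs = planted_setup
    peaks = synth.gen_peaks(genes, tfs, truth, background_rate=1.0, seed=5)
    io.write_peaks_bed(peaks, tmp_path / "p.bed")
    back = io.read_peaks_bed(tmp_path / "p.bed")
    pd.testing.assert_frame_equal(
        peaks.reset_index(drop=True), back, check_dtype=False
    )

    snps = synth.gen_snps(genes, truth, n_background=20, seed=5)
    io.write_tsv(snps, tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(snps, io.read_tsv(tmp_path / "s.tsv"))

    io.write_ground_truth(truth, tmp_path / "t.json")
    assert io.read_ground_truth(tmp_path / "t.json") == truth

    counts, meta = sc_setup(seed=2)[:2]
    io.write_counts(counts, meta, tmp_path / "cnt")
    c2, m2 = io.read_counts(tmp_path / "cnt")
    np.testing.assert_array_equal(counts.to_numpy(), c2.to_numpy())
    pd.testing.assert_frame_equal(meta, m2)

    sets = {"A": ["x", "y"], "B": ["z"]}
    io.write_gmt(sets, tmp_path / "s.gmt")
    assert io.read_gmt(tmp_path / "s.gmt") == sets
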