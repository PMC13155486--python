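"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (network target scoring, the monotone
single-cell drug-response model, CGE fitness statistics, set-level contrasts)
is exercised on data drawn here, with the planted structure recorded in a
:class:`GroundTruth` so that recovery can be quantified.

The generators emulate the statistical shape of the real inputs — multi-cell
line ChIP peak sets converging on a few target genes, GWAS-style SNP lists,
negative-binomial single-cell counts with monotone drug effects confined to
drug-sensitive lines and phase-specific marker genes, lineage-tag read counts
under selection, and set-structured log-fold-change tables — not their raw
sequencing substrate.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PHASES = ("G1", "S", "G2M")


class ConfigError(ValueError):
    """Impossible generator parameter combination."""


@dataclass
class GroundTruth:
    """Planted structure carried alongside every generated table."""

    planted_master_genes: list[str] = field(default_factory=list)
    #: gene id -> (direction in concentration, direction in time, log2 effect)
    planted_drug_genes: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    phase_of_cell: dict[str, str] = field(default_factory=dict)
    #: tag id -> per-doubling selection coefficient s
    tag_fitness: dict[str, float] = field(default_factory=dict)
    #: set name -> planted mean log-fold-change shift
    regulated_sets: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_master_genes": list(self.planted_master_genes),
            "planted_drug_genes": {
                g: list(v) for g, v in self.planted_drug_genes.items()
            },
            "phase_of_cell": dict(self.phase_of_cell),
            "tag_fitness": dict(self.tag_fitness),
            "regulated_sets": dict(self.regulated_sets),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            planted_master_genes=list(d.get("planted_master_genes", [])),
            planted_drug_genes={
                g: tuple(v) for g, v in d.get("planted_drug_genes", {}).items()
            },
            phase_of_cell=dict(d.get("phase_of_cell", {})),
            tag_fitness=dict(d.get("tag_fitness", {})),
            regulated_sets=dict(d.get("regulated_sets", {})),
        )


# ---------------------------------------------------------------------------
# gene annotation + paralogy
# ---------------------------------------------------------------------------

def gen_annotation(
    n_genes: int,
    n_paralog_pairs: int,
    genome_length: int = 100_000_000,
    n_chroms: int = 5,
    chain_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Gene table (gene_id, chrom, tss, strand) plus a paralog pair list.

    A ``chain_fraction`` of the pairs reuse a gene already in a pair so that
    transitive merging (A-B, B-C -> {A, B, C}) is exercised.
    """
    if n_genes < 2:
        raise ConfigError("need at least 2 genes")
    if genome_length < n_genes:
        raise ConfigError("genome_length must be >= n_genes")
    if n_paralog_pairs > n_genes * (n_genes - 1) // 2:
        raise ConfigError("more paralog pairs than distinct gene pairs")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    chroms = np.sort(rng.integers(0, n_chroms, size=n_genes))
    chrom_len = genome_length // n_chroms
    tss = np.zeros(n_genes, dtype=int)
    for c in range(n_chroms):
        idx = np.where(chroms == c)[0]
        pos = rng.choice(chrom_len, size=len(idx), replace=False)
        tss[idx] = np.sort(pos)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c + 1}" for c in chroms],
            "tss": tss,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    used: list[str] = []
    while len(pairs) < n_paralog_pairs:
        if used and rng.uniform() < chain_fraction:
            a = used[rng.integers(len(used))]
        else:
            a = gene_ids[rng.integers(n_genes)]
        b = gene_ids[rng.integers(n_genes)]
        key = (min(a, b), max(a, b))
        if a == b or key in seen:
            continue
        seen.add(key)
        pairs.append((a, b))
        used.extend([a, b])
    return genes, pairs


# ---------------------------------------------------------------------------
# ChIP peaks and GWAS SNPs
# ---------------------------------------------------------------------------

def gen_peaks(
    genes: pd.DataFrame,
    tfs_per_cancer: dict[str, list[str]],
    truth: GroundTruth,
    background_rate: float = 5.0,
    near_tss: int = 5_000,
    peak_width: int = 200,
    planted_height_boost: int = 20,
    background_height_p: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak table: background peaks uniform on the genome with geometric
    heights, plus high planted peaks near the TSS of every planted master
    gene from every cancer type's TF set (one cell line per cancer type).

    ``background_rate`` is peaks per Mb per (TF, cell line) track.
    """
    if not tfs_per_cancer:
        raise ConfigError("empty TF map")
    missing = set(truth.planted_master_genes) - set(genes["gene_id"])
    if missing:
        raise ConfigError(f"planted genes not in gene table: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    gene_idx = genes.set_index("gene_id")
    chrom_span = genes.groupby("chrom")["tss"].max() + 1_000_000

    rows = []
    for cancer in sorted(tfs_per_cancer):
        cell_line = f"{cancer}_line"
        for tf in tfs_per_cancer[cancer]:
            # background
            for chrom, span in chrom_span.items():
                n_bg = rng.poisson(background_rate * span / 1e6)
                starts = rng.integers(0, max(span - peak_width, 1), size=n_bg)
                heights = rng.geometric(background_height_p, size=n_bg)
                for s, h in zip(starts, heights):
                    rows.append((chrom, s, s + peak_width, tf, cell_line, int(h)))
            # planted convergence
            for g in truth.planted_master_genes:
                chrom = gene_idx.loc[g, "chrom"]
                offset = rng.integers(-near_tss, near_tss + 1)
                start = max(int(gene_idx.loc[g, "tss"]) + offset - peak_width // 2, 0)
                height = planted_height_boost + rng.geometric(background_height_p)
                rows.append((chrom, start, start + peak_width, tf, cell_line, int(height)))
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tf", "cell_line", "height"]
    )
    return peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def gen_snps(
    genes: pd.DataFrame,
    truth: GroundTruth,
    n_background: int = 500,
    traits: tuple[str, ...] = ("breast", "prostate", "colorectal"),
    near_tss: int = 5_000,
    background_log10p: tuple[float, float] = (-8.0, -5.0),
    planted_log10p: tuple[float, float] = (-12.0, -9.0),
    seed: int = 0,
) -> pd.DataFrame:
    """GWAS-style SNP table; planted loci sit near planted master genes with
    p-values drawn strictly below the background range, for every trait."""
    rng = np.random.default_rng(seed)
    gene_idx = genes.set_index("gene_id")
    chrom_span = genes.groupby("chrom")["tss"].max() + 1_000_000
    chrom_names = list(chrom_span.index)
    rows = []
    k = 0
    for trait in traits:
        for _ in range(n_background):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            pos = int(rng.integers(0, chrom_span[chrom]))
            logp = rng.uniform(*background_log10p)
            rows.append((f"rs{k:07d}", chrom, pos, trait, 10.0 ** logp))
            k += 1
        for g in truth.planted_master_genes:
            chrom = gene_idx.loc[g, "chrom"]
            pos = int(gene_idx.loc[g, "tss"]) + int(rng.integers(-near_tss, near_tss + 1))
            logp = rng.uniform(*planted_log10p)
            rows.append((f"rs{k:07d}", chrom, max(pos, 0), trait, 10.0 ** logp))
            k += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "trait", "p_value"])


# ---------------------------------------------------------------------------
# single-cell counts with monotone drug effects
# ---------------------------------------------------------------------------

def _dose_curve(levels: np.ndarray, n_levels: int, steepness: float = 2.0) -> np.ndarray:
    """Scaled logistic in the ordinal level, normalised to [0, 1]: a smooth,
    saturating, direction-controllable dose/time response."""
    if n_levels == 1:
        return np.zeros_like(levels, dtype=float)
    mid = (n_levels - 1) / 2.0
    s = 1.0 / (1.0 + np.exp(-steepness * (levels - mid)))
    s0 = 1.0 / (1.0 + np.exp(-steepness * (0 - mid)))
    s1 = 1.0 / (1.0 + np.exp(-steepness * (n_levels - 1 - mid)))
    return (s - s0) / (s1 - s0)


def gen_sc_counts(
    n_cells: int,
    n_genes: int,
    markers: dict[str, list[str]],
    truth: GroundTruth,
    pairs: tuple[str, ...] = ("pairA", "pairB"),
    n_conc: int = 3,
    n_time: int = 3,
    phases: tuple[str, ...] = DEFAULT_PHASES,
    marker_fold: float = 4.0,
    dispersion: float = 0.2,
    mean_depth: float = 5_000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts (genes x cells) plus per-cell metadata.

    ``n_cells`` cells are drawn for every (pair, status, concentration, time)
    condition.  Planted drug genes respond monotonically in concentration and
    time — in sensitive (parental) cells only — following a scaled logistic
    with log2 amplitude given by the planted effect size.  Marker genes are
    elevated ``marker_fold``-fold in their own phase; sampled phases are
    recorded in ``truth.phase_of_cell``.
    """
    flat = [g for gs in markers.values() for g in gs]
    if len(flat) != len(set(flat)):
        raise ConfigError("marker sets overlap across phases")
    if n_cells < 1:
        raise ConfigError("need >= 1 cell per design condition")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    unknown = (set(flat) | set(truth.planted_drug_genes)) - set(gene_ids)
    if unknown:
        raise ConfigError(f"marker/planted genes outside gene universe: {sorted(unknown)}")

    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))  # relative abundance

    meta_rows = []
    for pair in pairs:
        for status in ("sensitive", "resistant"):
            for d in range(n_conc):
                for t in range(n_time):
                    for _ in range(n_cells):
                        meta_rows.append((pair, status, d, t))
    meta = pd.DataFrame(meta_rows, columns=["pair_id", "status", "conc_level", "time_level"])
    meta.insert(0, "cell_id", [f"cell{i:06d}" for i in range(len(meta))])
    ncell = len(meta)

    phase_idx = rng.integers(0, len(phases), size=ncell)
    meta["true_phase"] = [phases[i] for i in phase_idx]
    truth.phase_of_cell.update(dict(zip(meta["cell_id"], meta["true_phase"])))

    # log2 mean offsets
    log2mu = np.tile(np.log2(base)[:, None], (1, ncell))
    gpos = {g: i for i, g in enumerate(gene_ids)}
    dcurve = _dose_curve(meta["conc_level"].to_numpy(), n_conc)
    tcurve = _dose_curve(meta["time_level"].to_numpy(), n_time)
    sens = (meta["status"] == "sensitive").to_numpy()
    for g, (dir_d, dir_t, eff) in truth.planted_drug_genes.items():
        i = gpos[g]
        log2mu[i] += sens * eff * (dir_d * dcurve + dir_t * tcurve) / 2.0
    for phase, gs in markers.items():
        pidx = phases.index(phase)
        in_phase = phase_idx == pidx
        for g in gs:
            log2mu[gpos[g]] += in_phase * np.log2(marker_fold)

    mu = 2.0 ** log2mu
    mu *= mean_depth / mu.sum(axis=0, keepdims=True)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=meta["cell_id"])
    return counts_df, meta


# ---------------------------------------------------------------------------
# CGE tag counts
# ---------------------------------------------------------------------------

def gen_cge_counts(
    n_tags: int,
    depth: float,
    truth: GroundTruth,
    n_doublings: float = 2.0,
    site_id: str = "site1",
    allele_class: str = "nonphospho",
    abundance_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Lineage-tag read counts at day 2 and day 8 for mutated vs restored
    alleles.  The day-8 mutant/restored expectation equals the day-2 ratio
    times ``2**(s * n_doublings)`` for selection coefficient ``s``; counts are
    multinomial at total depth ``depth * 2 * n_tags`` per time point.
    """
    if n_tags < 1:
        raise ConfigError("need >= 1 tag")
    rng = np.random.default_rng(seed)
    tag_ids = [f"tag{i:04d}" for i in range(n_tags)]
    s = np.array([truth.tag_fitness.get(t, 0.0) for t in tag_ids])

    mut_w = np.exp(rng.normal(0, abundance_sd, size=n_tags))
    res_w = np.exp(rng.normal(0, abundance_sd, size=n_tags))
    total = int(round(depth * 2 * n_tags))

    day2_w = np.concatenate([mut_w, res_w])
    day2 = rng.multinomial(total, day2_w / day2_w.sum())
    day8_w = np.concatenate([mut_w * 2.0 ** (s * n_doublings), res_w])
    day8 = rng.multinomial(total, day8_w / day8_w.sum())

    return pd.DataFrame(
        {
            "tag_id": tag_ids,
            "site_id": site_id,
            "allele_class": allele_class,
            "mutated_day2": day2[:n_tags],
            "restored_day2": day2[n_tags:],
            "mutated_day8": day8[:n_tags],
            "restored_day8": day8[n_tags:],
        }
    )


# ---------------------------------------------------------------------------
# set-structured fold changes
# ---------------------------------------------------------------------------

def gen_foldchanges(
    sets: dict[str, list[str]],
    truth: GroundTruth,
    n_pairs: int = 8,
    noise_sd: float = 0.2,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature x cell-line-pair log-fold-change table.

    Members of sets named in ``truth.regulated_sets`` receive the planted
    Gaussian mean shift in every pair; all other features have mean 0.
    Optional uniform missingness mimics data-dependent acquisition.
    """
    rng = np.random.default_rng(seed)
    features = sorted({f for members in sets.values() for f in members})
    pair_ids = [f"pair{i + 1}" for i in range(n_pairs)]
    shift = np.zeros(len(features))
    fpos = {f: i for i, f in enumerate(features)}
    for name, delta in truth.regulated_sets.items():
        if name not in sets:
            raise ConfigError(f"regulated set {name!r} not in set definitions")
        for f in sets[name]:
            shift[fpos[f]] = delta
    vals = shift[:, None] + rng.normal(0, noise_sd, size=(len(features), n_pairs))
    if missing_frac > 0:
        mask = rng.uniform(size=vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(vals, index=pd.Index(features, name="feature_id"), columns=pair_ids)
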