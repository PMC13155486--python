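"""Competitive genome editing (CGE) fitness statistics.

Each edited lineage is traced by a sequence tag pair carrying either the
mutated allele or the restored wild-type sequence.  The fitness readout per
tag is log2[(mutated_day8/restored_day8) / (mutated_day2/restored_day2)]:
sequencing depth cancels in the double ratio, and under exponential growth
its expectation is s * n_doublings for selection coefficient s.  The set of
per-tag ratios of an experiment is summarised by its median and a two-sided
Wilcoxon signed-rank test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COUNT_COLS = ["mutated_day2", "restored_day2", "mutated_day8", "restored_day8"]


def filter_tags(table: pd.DataFrame, day2_min: int = 5) -> pd.DataFrame:
    """Keep tags with both day-2 counts >= ``day2_min`` (range 5..50 is the
    intended operating band; values outside it warn but are honoured)."""
    if not (5 <= day2_min <= 50):
        import warnings

        warnings.warn(
            f"day2_min={day2_min} outside the usual 5..50 range", stacklevel=2
        )
    keep = (table["mutated_day2"] >= day2_min) & (table["restored_day2"] >= day2_min)
    return table.loc[keep].reset_index(drop=True)


def fitness_ratios(
    table: pd.DataFrame, zero_policy: str = "pseudocount"
) -> pd.DataFrame:
    """Per-tag log2 double ratios, with a flag for pseudocounted tags.

    Zero day-8 counts are handled by ``zero_policy``: "pseudocount" adds 0.5
    to all four counts of the affected tag (Haldane correction); "drop"
    removes the tag.
    """
    if len(table) == 0:
        raise ValueError("no tags after filtering; nothing to compute")
    t = table.copy()
    zero8 = (t["mutated_day8"] == 0) | (t["restored_day8"] == 0)
    if zero_policy == "drop":
        t = t.loc[~zero8].reset_index(drop=True)
        zero8 = pd.Series(False, index=t.index)
    elif zero_policy != "pseudocount":
        raise ValueError("zero_policy must be 'pseudocount' or 'drop'")
    c = t[COUNT_COLS].to_numpy(dtype=float)
    c[zero8.to_numpy()] += 0.5
    ratio = np.log2((c[:, 2] / c[:, 3]) / (c[:, 0] / c[:, 1]))
    out = t[[col for col in ("tag_id", "site_id", "allele_class") if col in t]].copy()
    out["log2_ratio"] = ratio
    out["pseudocounted"] = zero8.to_numpy()
    return out


@dataclass
class FitnessResult:
    median: float
    wilcoxon_p: float
    n_tags: int
    degenerate: bool = False


def test_fitness(ratios: np.ndarray | pd.Series, exact_max_n: int = 25) -> FitnessResult:
    """Two-sided Wilcoxon signed-rank test of the per-tag ratios against 0.

    Exact null distribution for n <= ``exact_max_n`` (when free of zeros and
    ties), else the normal approximation with continuity correction and
    tie-corrected variance.  All ratios exactly zero is degenerate: p = 1.
    """
    r = np.asarray(ratios, dtype=float)
    n = len(r)
    if n < 5:
        raise ValueError("need >= 5 tags for the signed-rank test")
    if np.all(r == 0):
        return FitnessResult(median=0.0, wilcoxon_p=1.0, n_tags=n, degenerate=True)
    nonzero = r[r != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    if n <= exact_max_n and not has_ties and len(nonzero) == n:
        method = "exact"
        res = stats.wilcoxon(r, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            r, alternative="two-sided", method="approx", correction=True
        )
    return FitnessResult(
        median=float(np.median(r)), wilcoxon_p=float(res.pvalue), n_tags=n
    )


def run(
    table: pd.DataFrame, day2_min: int = 5, zero_policy: str = "pseudocount"
) -> pd.DataFrame:
    """Per-site fitness summary: filter, ratio, median and signed-rank p."""
    kept = filter_tags(table, day2_min=day2_min)
    if len(kept) == 0:
        raise ValueError("no tags pass the day-2 read cutoff")
    ratios = fitness_ratios(kept, zero_policy=zero_policy)
    rows = []
    for (site, allele), sub in ratios.groupby(["site_id", "allele_class"], sort=False):
        res = test_fitness(sub["log2_ratio"])
        rows.append(
            (site, allele, res.n_tags, res.median, res.wilcoxon_p, res.degenerate)
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "allele_class", "n_tags", "median_log2_ratio",
                 "wilcoxon_p", "degenerate"],
    )
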