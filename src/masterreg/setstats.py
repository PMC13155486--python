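"""Set-level contrasts of feature fold changes across cell-line pairs.

Shared by the phosphoproteomics and thermal-stability (PISA) analyses: per
feature and cell-line pair, replicate measurements are collapsed by median
into a contrast (single-condition difference, or the sensitive-minus-
resistant difference of drug-induced differences); contrasts are averaged
over the observed members of each KEGG-pathway / CORUM-complex style set per
pair; each set's per-pair means are tested against zero with a two-sided
one-sample t-test across pairs; and p-values are Benjamini-Hochberg adjusted
(1% FDR by default).  The unit of replication is the cell-line pair, and
missing features (data-dependent acquisition) are handled by available-case
means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def pair_contrast(
    replicates: pd.DataFrame, mode: str = "single"
) -> pd.DataFrame:
    """Collapse replicate-level measurements into per-(feature, pair) contrasts.

    ``replicates`` columns: feature_id, pair_id, arm (``sensitive`` /
    ``resistant``; ignored for mode="single"), condition (``treated`` /
    ``control``), value; one row per replicate.  Per feature/pair/arm/
    condition the replicate median is taken, then:

    - mode="single": median(treated) - median(control) (sensitive arm);
    - mode="difference": the sensitive delta minus the resistant delta.

    Features absent in a required condition come out missing, not zero.
    Returns a feature x pair table of contrasts.
    """
    med = (
        replicates.groupby(["feature_id", "pair_id", "arm", "condition"])["value"]
        .median()
        .unstack("condition")
        .reindex(columns=["treated", "control"])
    )
    delta = (med["treated"] - med["control"]).unstack("arm")
    if mode == "single":
        contrast = delta.reindex(columns=["sensitive"])["sensitive"]
    elif mode == "difference":
        delta = delta.reindex(columns=["sensitive", "resistant"])
        contrast = delta["sensitive"] - delta["resistant"]
    else:
        raise ValueError("mode must be 'single' or 'difference'")
    return contrast.unstack("pair_id")


def set_mean_logfc(
    contrasts: pd.DataFrame, sets: dict[str, list[str]], min_size: int = 3
) -> tuple[pd.DataFrame, pd.Series]:
    """Unweighted available-case mean of member contrasts, per set and pair.

    Duplicate GMT entries count once.  Sets whose median per-pair observed
    size falls below ``min_size`` are excluded (logged).  Returns the set x
    pair mean table and the per-set median observed feature count.
    """
    means = {}
    sizes = {}
    for name, members in sets.items():
        mem = contrasts.loc[contrasts.index.intersection(set(members))]
        if mem.empty:
            logger.info("set %s: no observed members, excluded", name)
            continue
        n_obs = mem.notna().sum(axis=0)
        if float(n_obs.median()) < min_size:
            logger.info("set %s: median observed size %.1f < %d, excluded",
                        name, float(n_obs.median()), min_size)
            continue
        means[name] = mem.mean(axis=0, skipna=True)
        sizes[name] = float(n_obs.median())
    if not means:
        return pd.DataFrame(columns=contrasts.columns), pd.Series(dtype=float)
    return pd.DataFrame(means).T, pd.Series(sizes, name="n_features")


def set_ttest(set_means: pd.DataFrame) -> pd.DataFrame:
    """Two-sided one-sample t-test of each set's per-pair means against 0.

    Requires >= 2 pairs with a value; zero variance across pairs flags the
    set with p = NaN rather than claiming significance.
    """
    rows = []
    for name, vals in set_means.iterrows():
        v = vals.dropna().to_numpy(dtype=float)
        if len(v) < 2:
            continue
        if np.allclose(v, v[0]):
            rows.append((name, len(v), float(v.mean()), np.nan, np.nan, True))
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        rows.append((name, len(v), float(v.mean()), float(t), float(p), False))
    return pd.DataFrame(
        rows, columns=["set_id", "n_pairs", "mean_logfc", "t_stat", "p", "zero_variance"]
    )


def bh_adjust(pvals, fdr_level: float = 0.01):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return q, q <= fdr_level


def run(
    contrasts: pd.DataFrame,
    sets: dict[str, list[str]],
    min_size: int = 3,
    fdr_level: float = 0.01,
) -> pd.DataFrame:
    """Full set-level analysis: means, t-tests, BH adjustment; volcano-ready."""
    means, sizes = set_mean_logfc(contrasts, sets, min_size=min_size)
    res = set_ttest(means)
    if res.empty:
        res["q"] = []
        res["significant"] = []
        return res
    tested = res["p"].notna()
    q = np.full(len(res), np.nan)
    sig = np.zeros(len(res), dtype=bool)
    if tested.any():
        q_t, sig_t = bh_adjust(res.loc[tested, "p"].to_numpy(), fdr_level=fdr_level)
        q[tested.to_numpy()] = q_t
        sig[tested.to_numpy()] = sig_t
    res["q"] = q
    res["significant"] = sig
    res.insert(1, "n_features", res["set_id"].map(sizes).to_numpy())
    return res
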