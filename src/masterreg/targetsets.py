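"""Stepwise calling of putative MYC target genes and cross-species overlap.

A gene is called a target when it (i) is expressed in control cells (FPKM
above a floor), (ii) has a binding peak within a small window of its TSS, and
(iii) responds to perturbation — either passing the FDR/fold-change gate in
enough conditions, or showing a large absolute FPKM difference in enough
conditions; the two response lists are merged by union.  Conserved targets
are the genes of one species' call with an ortholog in the other's.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def call_targets(
    evidence: pd.DataFrame,
    de: pd.DataFrame,
    expressed_min_fpkm: float = 2.0,
    tss_window: int = 1_000,
    fdr_max: float = 0.1,
    fc_min: float = 1.3,
    delta_fpkm_min: float = 50.0,
    min_conditions_fc: int = 1,
    min_conditions_delta: int = 1,
    signed_linear_fc: bool = True,
) -> set[str]:
    """Call target genes through the stepwise gates.

    Parameters
    ----------
    evidence : per-gene table with columns ``gene_id``, ``expression_control``
        (FPKM in control cells) and ``nearest_peak_distance`` (bp to TSS).
    de : differential-expression records, one row per (gene, condition), with
        columns ``gene_id``, ``condition``, ``fold_change``, ``fdr``,
        ``delta_fpkm``.
    signed_linear_fc : with True (cuffdiff-style), the fold-change gate is
        fold_change > fc_min or < -fc_min; with False, fold_change is an
        unsigned ratio and the gate is fc > fc_min or fc < 1/fc_min.
    min_conditions_fc, min_conditions_delta : number of conditions in which
        the FDR/FC gate (resp. the delta-FPKM gate) must hold.

    Returns the called gene set; intermediate gate counts are logged.
    """
    n_cond = de.groupby("gene_id")["condition"].nunique().max() if len(de) else 0
    if min_conditions_fc > max(n_cond, 1) or min_conditions_delta > max(n_cond, 1):
        raise ValueError("min_conditions exceeds the number of available conditions")

    expressed = set(
        evidence.loc[evidence["expression_control"] > expressed_min_fpkm, "gene_id"]
    )
    proximal = set(
        evidence.loc[
            evidence["nearest_peak_distance"].abs() <= tss_window, "gene_id"
        ]
    )
    base = expressed & proximal

    if signed_linear_fc:
        fc_pass = (de["fold_change"] > fc_min) | (de["fold_change"] < -fc_min)
    else:
        fc_pass = (de["fold_change"] > fc_min) | (de["fold_change"] < 1.0 / fc_min)
    fdr_fc = de.loc[fc_pass & (de["fdr"] < fdr_max)]
    fc_genes = set(
        fdr_fc.groupby("gene_id")["condition"]
        .nunique()
        .loc[lambda s: s >= min_conditions_fc]
        .index
    )
    delta = de.loc[de["delta_fpkm"].abs() > delta_fpkm_min]
    delta_genes = set(
        delta.groupby("gene_id")["condition"]
        .nunique()
        .loc[lambda s: s >= min_conditions_delta]
        .index
    )

    called = base & (fc_genes | delta_genes)
    logger.info(
        "target calling: expressed=%d proximal=%d expressed&proximal=%d "
        "fdr_fc=%d delta_fpkm=%d union=%d called=%d",
        len(expressed), len(proximal), len(base),
        len(fc_genes & base), len(delta_genes & base),
        len((fc_genes | delta_genes) & base), len(called),
    )
    return called


def conserved_overlap(
    set_a: set[str], set_b: set[str], ortholog_map: pd.DataFrame
) -> set[str]:
    """Genes of ``set_a`` with at least one ortholog in ``set_b``.

    ``ortholog_map`` has columns ``gene_a``, ``gene_b`` and may be
    many-to-many.  An empty map yields an empty overlap with a warning.
    """
    if len(ortholog_map) == 0:
        logger.warning("empty ortholog map: overlap is empty")
        return set()
    hits = ortholog_map.loc[
        ortholog_map["gene_a"].isin(set_a) & ortholog_map["gene_b"].isin(set_b)
    ]
    return set(hits["gene_a"])
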