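"""Readers and writers for the plain-text formats the pipeline exchanges.

Peaks travel as BED (0-based half-open, score column = peak height, name
column = ``tf:cell_line``); genes, SNPs, CGE counts and fold changes as TSV;
single-cell counts as Matrix Market plus a metadata TSV; gene sets as GMT;
planted ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

PEAK_COLUMNS = ["chrom", "start", "end", "tf", "cell_line", "height"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "trait", "p_value"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6-style: chrom, start, end, name(tf:cell_line), score(height), strand."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": peaks["tf"].astype(str) + ":" + peaks["cell_line"].astype(str),
            "score": peaks["height"].astype(int),
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    tf_cl = bed["name"].str.split(":", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "tf": tf_cl[0],
            "cell_line": tf_cl[1],
            "height": bed["score"],
        }
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_counts(counts: pd.DataFrame, meta: pd.DataFrame, prefix) -> None:
    """Matrix Market (genes x cells) + genes.tsv + cell metadata TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(prefix) + ".mtx", scipy.sparse.csr_matrix(counts.to_numpy())
    )
    pd.Series(counts.index, name="gene_id").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    meta.to_csv(str(prefix) + ".meta.tsv", sep="\t", index=False)


def read_counts(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t")["gene_id"]
    meta = pd.read_csv(str(prefix) + ".meta.tsv", sep="\t")
    counts = pd.DataFrame(mat, index=genes.to_numpy(), columns=meta["cell_id"])
    return counts, meta


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_ground_truth(path):
    from .synth import GroundTruth

    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
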