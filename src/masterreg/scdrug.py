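"""Monotone factorial modelling of single-cell drug responses.

Expression of each gene is modelled as a full-factorial function of cell line
(parental/resistant), drug concentration, treatment time and cell-cycle
phase, on a per-gene rank-normalised scale in [0, 1].  The cell-mean array
beta[i, p, d, t, c] is fitted by least squares under the constraint that it
is monotone along the ordered concentration and time axes — the direction
free per gene, chosen by refitting under all four (+-d, +-t) combinations and
keeping the smallest residual.  Cell-cycle phases are inferred jointly on
phase-specific marker genes by alternating (i) the constrained fit with the
additional requirement that each marker's fitted level is maximal in its own
phase and (ii) reassignment of every cell to its best-fitting phase; the
objective is non-increasing, and the best of several random restarts is kept.

The contribution of a design variable is quantified by rank variance
analysis: refit with the variable's levels collapsed and report the lost
fraction of rank variance, EP_v = (RSS_reduced - RSS_full) / TSS.  Genes are
ranked for drug response by the drug's explanatory power in sensitive minus
resistant cells of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._isotonic import project_grid_monotone

FACTORS = ("cellline", "drug", "time", "phase")
_EMPTY_WEIGHT = 1e-8  # imputed cells: constraint-interpolated, zero influence


# ---------------------------------------------------------------------------
# rank normalisation
# ---------------------------------------------------------------------------

def rank_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum-normalise each cell, then map each gene's values to [0, 1] ranks.

    Per cell, values are divided by the cell's total count; per gene, values
    are replaced by (rank - 1) / (n - 1) with average ranks for ties, so the
    lowest expression maps to 0 and the highest to 1 (a constant gene maps
    to 0.5 everywhere).
    """
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("all-zero cell in counts")
    X = X / totals
    n = X.shape[1]
    if n < 2:
        raise ValueError("need >= 2 cells")
    ranks = pd.DataFrame(X).rank(axis=1, method="average").to_numpy()
    return pd.DataFrame(
        (ranks - 1) / (n - 1), index=counts.index, columns=counts.columns
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _codes(meta: pd.DataFrame, col: str) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(meta[col])
    if col in ("conc_level", "time_level"):
        levels = sorted(cat.categories)
        cat = pd.Categorical(meta[col], categories=levels, ordered=True)
    return cat.codes.astype(int), list(cat.categories)


@dataclass
class MonotoneFactorialResults:
    """Fitted cell means, per-gene directions and residuals.

    Attributes
    ----------
    beta : (G, P, D, T, C) array of fitted expression levels.
    directions : (G, 2) int array, sign of monotonicity in (drug, time).
    rss, tss : per-gene residual and total sums of squares.
    """

    model: "MonotoneFactorialModel"
    beta: np.ndarray
    directions: np.ndarray
    rss: np.ndarray
    tss: np.ndarray

    @property
    def genes(self):
        return self.model.genes

    def explanatory_power(self, variable: str) -> pd.Series:
        """Rank variance analysis: EP_v = (RSS_reduced - RSS_full)/TSS >= 0.

        The reduced model collapses the variable's levels to one; constant
        genes (TSS = 0) get NaN.
        """
        reduced = self.model.drop_variable(variable).fit()
        with np.errstate(invalid="ignore", divide="ignore"):
            ep = (reduced.rss - self.rss) / self.tss
        ep = np.where(self.tss > 0, np.clip(ep, 0.0, None), np.nan)
        return pd.Series(ep, index=self.genes, name=f"EP_{variable}")

    def summary(self) -> pd.DataFrame:
        frac = np.where(self.tss > 0, 1.0 - self.rss / self.tss, np.nan)
        return pd.DataFrame(
            {
                "gene_id": self.genes,
                "dir_drug": self.directions[:, 0],
                "dir_time": self.directions[:, 1],
                "rss": self.rss,
                "tss": self.tss,
                "frac_explained": frac,
            }
        ).set_index("gene_id")


class MonotoneFactorialModel:
    """Monotonicity-constrained full-factorial least-squares model.

    Parameters
    ----------
    X : DataFrame, genes x cells, rank-normalised expression.
    meta : DataFrame with per-cell columns ``cell_id``, ``status`` (cell
        line: sensitive/resistant), ``conc_level`` and ``time_level``
        (ordered integers) aligned to the columns of ``X``.
    phases : per-cell phase labels (array-like), or None for a model without
        the phase factor.
    marker_phase_of_gene : optional map gene -> phase label imposing the
        phase-marker constraint (fitted level maximal in the marker's own
        phase) on that gene.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        meta: pd.DataFrame,
        phases=None,
        marker_phase_of_gene: dict | None = None,
        collapsed: tuple[str, ...] = (),
    ):
        if list(X.columns) != list(meta["cell_id"]):
            raise ValueError("X columns and meta cell_id must align")
        self.X = X
        self.meta = meta.reset_index(drop=True)
        self.genes = list(X.index)
        self.collapsed = tuple(collapsed)
        self.marker_phase_of_gene = marker_phase_of_gene or {}

        n = len(self.meta)
        zero = np.zeros(n, dtype=int)
        if "cellline" in collapsed:
            self.p_codes, self.p_levels = zero, ["all"]
        else:
            self.p_codes, self.p_levels = _codes(self.meta, "status")
        if "drug" in collapsed:
            self.d_codes, self.d_levels = zero, [0]
        else:
            self.d_codes, self.d_levels = _codes(self.meta, "conc_level")
        if "time" in collapsed:
            self.t_codes, self.t_levels = zero, [0]
        else:
            self.t_codes, self.t_levels = _codes(self.meta, "time_level")
        if phases is None or "phase" in collapsed:
            self.c_codes, self.c_levels = zero, ["all"]
        else:
            cat = pd.Categorical(phases)
            self.c_codes, self.c_levels = cat.codes.astype(int), list(cat.categories)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, meta: pd.DataFrame, **kw):
        return cls(rank_normalize(counts), meta, **kw)

    # -- grid bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return (
            len(self.p_levels),
            len(self.d_levels),
            len(self.t_levels),
            len(self.c_levels),
        )

    def _group_index(self) -> np.ndarray:
        return np.ravel_multi_index(
            (self.p_codes, self.d_codes, self.t_codes, self.c_codes), self.shape
        )

    def drop_variable(self, variable: str) -> "MonotoneFactorialModel":
        if variable not in FACTORS:
            raise ValueError(f"variable must be one of {FACTORS}")
        phases = None
        if len(self.c_levels) > 1:
            phases = np.asarray(self.c_levels)[self.c_codes]
        return MonotoneFactorialModel(
            self.X,
            self.meta,
            phases=phases,
            marker_phase_of_gene=self.marker_phase_of_gene,
            collapsed=self.collapsed + (variable,),
        )

    # -- fitting ------------------------------------------------------------

    def _group_stats(self, group_idx=None):
        gi = self._group_index() if group_idx is None else group_idx
        n_groups = int(np.prod(self.shape))
        Xv = self.X.to_numpy(dtype=float)
        G = Xv.shape[0]
        ind = np.zeros((len(gi), n_groups))
        ind[np.arange(len(gi)), gi] = 1.0
        counts = ind.sum(axis=0)
        sums = Xv @ ind
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        within = (Xv**2).sum(axis=1) - np.nansum(
            counts * np.where(counts > 0, means, 0.0) ** 2, axis=1
        )
        grand = Xv.mean(axis=1)
        tss = ((Xv - grand[:, None]) ** 2).sum(axis=1)
        # impute empty cells at the gene grand mean with negligible weight
        weights = np.where(counts > 0, counts, _EMPTY_WEIGHT)
        means = np.where(np.isnan(means), grand[:, None], means)
        return (
            means.reshape((G,) + self.shape),
            weights.reshape(self.shape),
            counts.reshape(self.shape),
            within,
            tss,
        )

    def fit(self, tol: float = 1e-10, max_iter: int = 500) -> MonotoneFactorialResults:
        """Fit beta under all four direction combinations per gene and keep
        the best; ties prefer nondecreasing.  Single-constraint fits reduce to
        exact isotonic regression; joint constraints use Dykstra projections.
        """
        means, weights, counts, within, tss = self._group_stats()
        G = means.shape[0]
        P, D, T, C = self.shape

        marker_phase = None
        if self.marker_phase_of_gene and C > 1:
            phase_pos = {ph: i for i, ph in enumerate(self.c_levels)}
            marker_phase = np.full(G, -1, dtype=int)
            for gi, g in enumerate(self.genes):
                ph = self.marker_phase_of_gene.get(g)
                if ph is not None and ph in phase_pos:
                    marker_phase[gi] = phase_pos[ph]

        combos = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
        best_beta = None
        best_sse = None
        best_dir = np.zeros((G, 2), dtype=int)
        for sd, st in combos:
            axes = []
            if D > 1:
                axes.append((2, sd))
            if T > 1:
                axes.append((3, st))
            beta = self._project(means, weights, axes, marker_phase, tol, max_iter)
            sse = within + (counts[None] * (means - beta) ** 2).sum(axis=(1, 2, 3, 4))
            if best_sse is None:
                best_beta, best_sse = beta, sse
                best_dir[:, 0], best_dir[:, 1] = sd, st
            else:
                better = sse < best_sse - 1e-12
                best_sse = np.where(better, sse, best_sse)
                best_beta = np.where(better[:, None, None, None, None], beta, best_beta)
                best_dir[better, 0] = sd
                best_dir[better, 1] = st
        return MonotoneFactorialResults(
            model=self,
            beta=best_beta,
            directions=best_dir,
            rss=best_sse,
            tss=tss,
        )

    def _project(self, means, weights, axes, marker_phase, tol, max_iter):
        if not axes and marker_phase is None:
            return means.copy()
        if marker_phase is None:
            return project_grid_monotone(means, weights, axes, tol=tol, max_iter=max_iter)
        # genes without a marker constraint are projected separately
        has = marker_phase >= 0
        beta = np.empty_like(means)
        if np.any(~has):
            beta[~has] = project_grid_monotone(
                means[~has], weights, axes, tol=tol, max_iter=max_iter
            )
        if np.any(has):
            beta[has] = project_grid_monotone(
                means[has], weights, axes,
                marker_phase=marker_phase[has], phase_axis=4,
                tol=tol, max_iter=max_iter,
            )
        return beta


# ---------------------------------------------------------------------------
# joint phase inference
# ---------------------------------------------------------------------------

@dataclass
class PhaseInferenceResult:
    phases: pd.Series  # per cell
    results: MonotoneFactorialResults  # marker-gene fit at the optimum
    objective: float
    objective_trace: list


def infer_phases(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    markers: dict[str, list[str]],
    iters: int = 100,
    restarts: int = 10,
    seed: int = 0,
) -> PhaseInferenceResult:
    """Jointly infer cell-cycle phases on marker genes.

    Alternates (i) the monotone factorial fit on the marker genes with the
    phase-marker maximality constraint and (ii) reassignment of each cell to
    the phase minimising its squared residual over the markers.  Initial
    phases are drawn uniformly; the best of ``restarts`` restarts after at
    most ``iters`` iterations (stopping early at a fixed point) is returned.
    """
    phase_names = sorted(markers)
    if len(phase_names) < 2:
        raise ValueError("need >= 2 phases in the marker set")
    flat = [g for ph in phase_names for g in markers[ph]]
    if len(flat) != len(set(flat)):
        raise ValueError("marker sets overlap across phases")
    missing = set(flat) - set(X.index)
    if missing:
        raise ValueError(f"markers missing from X: {sorted(missing)}")

    Xm = X.loc[flat]
    marker_phase_of_gene = {g: ph for ph in phase_names for g in markers[ph]}
    rng = np.random.default_rng(seed)
    ncell = Xm.shape[1]

    best: PhaseInferenceResult | None = None
    for _ in range(restarts):
        codes = rng.integers(0, len(phase_names), size=ncell)
        trace: list[float] = []
        prev_obj = np.inf
        res = None
        for _ in range(iters):
            phases = np.asarray(phase_names)[codes]
            model = MonotoneFactorialModel(
                Xm, meta, phases=pd.Categorical(phases, categories=phase_names),
                marker_phase_of_gene=marker_phase_of_gene,
            )
            res = model.fit()
            new_codes, obj = _reassign(Xm, model, res.beta)
            trace.append(obj)
            assert obj <= prev_obj + 1e-6, "phase objective increased"
            if np.array_equal(new_codes, codes):
                codes = new_codes
                break
            codes, prev_obj = new_codes, obj
        result = PhaseInferenceResult(
            phases=pd.Series(
                np.asarray(phase_names)[codes], index=Xm.columns, name="phase"
            ),
            results=res,
            objective=trace[-1],
            objective_trace=trace,
        )
        if best is None or result.objective < best.objective:
            best = result
    return best


def _reassign(Xm: pd.DataFrame, model: MonotoneFactorialModel, beta: np.ndarray):
    """Per-cell best phase under the current beta, plus the new objective."""
    Xv = Xm.to_numpy(dtype=float)  # (G, n)
    # beta per cell and candidate phase: (G, n, C)
    bc = beta[:, model.p_codes, model.d_codes, model.t_codes, :]
    cost = ((Xv[:, :, None] - bc) ** 2).sum(axis=0)  # (n, C)
    codes = np.argmin(cost, axis=1)
    obj = float(cost[np.arange(len(codes)), codes].sum())
    return codes, obj


# ---------------------------------------------------------------------------
# drug-gene ranking
# ---------------------------------------------------------------------------

def drug_explanatory_power(
    X: pd.DataFrame, meta: pd.DataFrame, phases, status: str
) -> pd.Series:
    """EP of the drug variable fitted on the cells of one status subset."""
    mask = (meta["status"] == status).to_numpy()
    sub_meta = meta.loc[mask].reset_index(drop=True)
    sub_X = X.iloc[:, mask]
    sub_phases = np.asarray(phases)[mask] if phases is not None else None
    model = MonotoneFactorialModel(sub_X, sub_meta, phases=sub_phases)
    return model.fit().explanatory_power("drug")


def rank_drug_genes(
    ep_sensitive: pd.Series, ep_resistant: pd.Series
) -> pd.DataFrame:
    """Rank genes by drug explanatory power in sensitive minus resistant
    cells, descending; genes absent from either side are excluded."""
    common = ep_sensitive.index.intersection(ep_resistant.index)
    score = (ep_sensitive.loc[common] - ep_resistant.loc[common]).rename("score")
    df = score.reset_index()
    df.columns = ["gene_id", "score"]
    df["ep_sensitive"] = ep_sensitive.loc[common].to_numpy()
    df["ep_resistant"] = ep_resistant.loc[common].to_numpy()
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
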