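"""Dynamic-gene detection along a pseudotime ordering of cells.

Given a cells x genes expression matrix whose rows are totally ordered
(for instance by diffusion pseudotime computed upstream), a gene is called
*dynamic* when its expression differs between the stretch of the ordering
where it is highest and the stretch where it is lowest.  Concretely, for
each gene all contiguous windows of ``w`` cells (stride 1) are scanned for
the windows with maximum and minimum mean expression; a two-sample t-test
between those two sets of ``w`` measurements gives a p-value, and
Benjamini-Hochberg adjustment across genes controls the FDR.

Note that picking the extreme windows *before* testing makes the procedure
anti-conservative: under a pure-noise null the realized false-positive
rate exceeds the nominal t-test level.  The realized rate is an empirical
property of (n_cells, w, n_genes) and should be measured by simulation;
this module reports, it does not correct.

Significant genes can then be z-scaled, smoothed with a centred moving
average of the same width, and ranked by the position of their smoothed
peak to produce a heatmap-ready matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionOrdering",
    "extreme_windows",
    "dynamic_gene_test",
    "smooth_and_rank",
]

DEFAULT_WINDOW = 100


@dataclass
class ExpressionOrdering:
    """A cells x genes matrix with a total ordering of cells (pseudotime rank).

    ``matrix[i, j]`` is the expression of gene ``gene_names[j]`` in the cell
    of pseudotime rank ``i`` (``cell_ids[i]``).  Values are expected on a
    log-normalized scale; no missing values are allowed.
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        if self.matrix.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length must match matrix columns")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.matrix.shape[0])]
        if len(self.cell_ids) != self.matrix.shape[0]:
            raise ValueError("cell_ids length must match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cell_ids, columns=self.gene_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionOrdering":
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index.astype(str)))


def _window_means(values: np.ndarray, w: int) -> np.ndarray:
    """Means of all contiguous windows of length w, stride 1."""
    c = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    return (c[w:] - c[:-w]) / w


def extreme_windows(values: np.ndarray, w: int = DEFAULT_WINDOW) -> tuple[int, int]:
    """Start indices of the max-mean and min-mean windows of length ``w``.

    All contiguous windows with stride 1 are considered; ties resolve to
    the earliest start.  Raises if the vector is shorter than ``w``.
    """
    values = np.asarray(values, dtype=float)
    if w < 1:
        raise ValueError("window size must be >= 1")
    if values.size < w:
        raise ValueError(f"need >= {w} values, got {values.size}")
    means = _window_means(values, w)
    return int(np.argmax(means)), int(np.argmin(means))


def dynamic_gene_test(
    data: ExpressionOrdering,
    w: int = DEFAULT_WINDOW,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Sliding-window extreme-versus-extreme t-test for every gene.

    For each gene the max-mean and min-mean windows of ``w`` cells are
    located along the ordering and their two sets of ``w`` expression
    values compared by a t-test (Welch by default; set ``equal_var`` for
    the pooled-variance variant).  P-values are Benjamini-Hochberg
    adjusted across genes; a gene is significant when its adjusted p is
    strictly below ``alpha``.

    Returns a DataFrame with one row per gene: ``gene, window_max_start,
    window_min_start, t_statistic, p_value, fdr_adjusted_p, significant,
    degenerate`` (degenerate marks zero variance in both windows, where p
    is set to 1).
    """
    if data.n_cells < w:
        raise ValueError("ordering shorter than the window")
    rows = []
    for j, gene in enumerate(data.gene_names):
        v = data.matrix[:, j]
        i_max, i_min = extreme_windows(v, w)
        hi = v[i_max : i_max + w]
        lo = v[i_min : i_min + w]
        degenerate = hi.std() == 0.0 and lo.std() == 0.0
        if degenerate:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(hi, lo, equal_var=equal_var)
        rows.append((gene, i_max, i_min, float(t_stat), float(p), degenerate))
    res = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "window_max_start",
            "window_min_start",
            "t_statistic",
            "p_value",
            "degenerate",
        ],
    )
    _, q, _, _ = multipletests(res["p_value"].to_numpy(), method="fdr_bh")
    res["fdr_adjusted_p"] = q
    res["significant"] = res["fdr_adjusted_p"] < alpha
    return res[
        [
            "gene",
            "window_max_start",
            "window_min_start",
            "t_statistic",
            "p_value",
            "fdr_adjusted_p",
            "significant",
            "degenerate",
        ]
    ]


def smooth_and_rank(
    data: ExpressionOrdering,
    results: pd.DataFrame,
    w: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, pd.Series]:
    """Z-scale, smooth and peak-rank the significant genes.

    Each significant gene's expression vector is standardized to zero mean
    and unit variance, then smoothed with a centred moving average of
    width ``w`` whose window shrinks at the edges (no padding).  Genes are
    ordered by the position of the smoothed maximum (the peak), earliest
    first.

    Returns ``(heatmap, peaks)``: a genes x cells DataFrame of smoothed
    z-scores with rows in peak order, and the per-gene peak positions.
    Constant genes (zero variance overall) are excluded defensively; with
    no significant genes both outputs are empty.
    """
    sig = results.loc[results["significant"], "gene"].tolist()
    name_to_col = {g: j for j, g in enumerate(data.gene_names)}
    rows, peaks = {}, {}
    for gene in sig:
        v = data.matrix[:, name_to_col[gene]]
        sd = v.std()
        if sd == 0.0:
            continue
        z = (v - v.mean()) / sd
        smooth = (
            pd.Series(z).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
        )
        rows[gene] = smooth
        peaks[gene] = int(np.argmax(smooth))
    if not rows:
        return (
            pd.DataFrame(columns=data.cell_ids),
            pd.Series(dtype=int, name="peak_position"),
        )
    order = sorted(rows, key=lambda g: (peaks[g], sig.index(g)))
    heat = pd.DataFrame([rows[g] for g in order], index=order, columns=data.cell_ids)
    return heat, pd.Series({g: peaks[g] for g in order}, name="peak_position")
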