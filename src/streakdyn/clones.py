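"""Clone identification from barcodes and multispectral color codes.

Two labeling strategies define clones:

* retroviral barcodes — descendants share an integrated random sequence,
  so exact string identity defines the clone;
* combinatorial three-fluorophore nuclear labels — descendants inherit a
  stable color hue, retrieved by normalizing the three channel
  intensities per cell and clustering cells in hue space (K-means),
  keeping only confidently assigned cells (silhouette > 0.4).

Either way, each clone is then classified by potency from the tissues its
members occupy — neural only (N), mesoderm only (M), or bipotent
neuromesodermal (NM) — and by its axial composition relative to an
anteroposterior boundary (in the embryo, the somite-27 level separating
primary from secondary neurulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "CloneCall",
    "normalize_colors",
    "cluster_colors",
    "silhouette_filter",
    "triplot_coordinates",
    "triplot_to_fractions",
    "classify_clones",
    "group_barcodes",
    "potency_summary",
]

SILHOUETTE_THRESHOLD = 0.4
FRACTION_COLS = ["f1", "f2", "f3"]


@dataclass
class CloneCall:
    """One called clone with its potency and axial composition."""

    clone_id: int | str
    member_cell_ids: list = field(default_factory=list)
    n_neural: int = 0
    n_mesoderm: int = 0
    n_anterior: int = 0
    n_posterior: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.member_cell_ids)

    @property
    def potency(self) -> str:
        if self.n_neural > 0 and self.n_mesoderm > 0:
            return "NM"
        return "N" if self.n_neural > 0 else "M"


def normalize_colors(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per-cell channel intensities to percentage fractions.

    ``raw`` must carry columns ``c1, c2, c3`` (non-negative intensities).
    Adds ``f1, f2, f3`` with ``f_i = 100 * c_i / (c1 + c2 + c3)``.  Cells
    whose intensities sum to zero cannot be normalized and are returned
    separately.  Returns ``(normalized, rejected)``.
    """
    for col in ("c1", "c2", "c3"):
        if col not in raw.columns:
            raise ValueError(f"missing intensity column {col!r}")
        if (raw[col] < 0).any():
            raise ValueError(f"negative intensities in {col!r}")
    total = raw[["c1", "c2", "c3"]].sum(axis=1)
    bad = total == 0
    rejected = raw[bad].copy()
    rejected["reason"] = "all channel intensities zero"
    out = raw[~bad].copy()
    tot = total[~bad]
    for i, col in enumerate(("c1", "c2", "c3"), start=1):
        out[f"f{i}"] = 100.0 * out[col] / tot
    return out, rejected


def cluster_colors(
    cells: pd.DataFrame,
    k: int | str = "auto",
    seed: int | None = 0,
    k_range: tuple[int, int] = (2, 15),
    n_init: int = 25,
) -> pd.DataFrame:
    """K-means clustering of cells in normalized hue space.

    Clusters on the fraction triples (Euclidean metric; the simplex
    constraint leaves two effective dimensions) and attaches per-cell
    silhouette scores.  ``k="auto"`` sweeps ``k_range`` inclusive and
    keeps the k maximizing the mean silhouette — the same statistic used
    downstream as the per-cell quality filter.  Multiple restarts
    (``n_init``) under one seed keep the result deterministic.

    Returns a copy of ``cells`` with ``cluster_id`` and ``silhouette``
    columns plus a ``degenerate`` flag in ``.attrs`` (set when all cells
    share one color and silhouettes are undefined).
    """
    X = cells[FRACTION_COLS].to_numpy(dtype=float)
    n = X.shape[0]
    out = cells.copy()
    if np.allclose(X, X[0], atol=1e-12):
        out["cluster_id"] = 0
        out["silhouette"] = np.nan
        out.attrs["degenerate"] = True
        out.attrs["k"] = 1
        return out

    def _fit(kk: int) -> tuple[np.ndarray, np.ndarray]:
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        sil = silhouette_samples(X, labels)
        return labels, sil

    if k == "auto":
        lo, hi = k_range
        hi = min(hi, n - 1)
        if lo > hi:
            raise ValueError("k_range empty after capping at n - 1")
        best = None
        for kk in range(lo, hi + 1):
            labels, sil = _fit(kk)
            score = float(sil.mean())
            if best is None or score > best[0]:
                best = (score, kk, labels, sil)
        _, chosen, labels, sil = best
    else:
        k = int(k)
        if not 2 <= k <= n:
            raise ValueError(f"need n >= k >= 2, got k={k}, n={n}")
        chosen = k
        labels, sil = _fit(k)
    out["cluster_id"] = labels
    out["silhouette"] = sil
    out.attrs["degenerate"] = False
    out.attrs["k"] = chosen
    return out


def silhouette_filter(
    cells: pd.DataFrame, threshold: float = SILHOUETTE_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cells into (kept, discarded) by silhouette strictly > threshold.

    Only set membership changes; cluster assignments are untouched.
    """
    if "silhouette" not in cells.columns:
        raise ValueError("silhouettes not computed; run cluster_colors first")
    keep = cells["silhouette"] > threshold
    return cells[keep].copy(), cells[~keep].copy()


_SQRT3_2 = np.sqrt(3.0) / 2.0


def triplot_coordinates(f1, f2, f3):
    """Map percentage fractions to planar ternary-diagram coordinates.

    The equilateral triangle has vertices channel1 -> (0, 0),
    channel2 -> (1, 0), channel3 -> (0.5, sqrt(3)/2); the balanced color
    (33.3, 33.3, 33.3) maps to the centroid.  Vectorized; returns (u, v).
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    f3 = np.asarray(f3, dtype=float)
    u = (f2 + 0.5 * f3) / 100.0
    v = _SQRT3_2 * f3 / 100.0
    return u, v


def triplot_to_fractions(u, v):
    """Inverse of :func:`triplot_coordinates`; returns (f1, f2, f3) percentages."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    f3 = 100.0 * v / _SQRT3_2
    f2 = 100.0 * u - 0.5 * f3
    f1 = 100.0 - f2 - f3
    return f1, f2, f3


def _call_from_group(
    clone_id, grp: pd.DataFrame, ap_boundary: float, axial_col: str
) -> CloneCall:
    neural = int((grp["tissue"] == "neural").sum())
    meso = int((grp["tissue"] == "mesoderm").sum())
    anterior = int((grp[axial_col] < ap_boundary).sum())
    return CloneCall(
        clone_id=clone_id,
        member_cell_ids=grp["cell_id"].tolist(),
        n_neural=neural,
        n_mesoderm=meso,
        n_anterior=anterior,
        n_posterior=len(grp) - anterior,
    )


def classify_clones(
    cells: pd.DataFrame,
    ap_boundary: float,
    group_col: str = "cluster_id",
    axial_col: str = "y_um",
) -> list[CloneCall]:
    """One CloneCall per cluster: potency and anterior/posterior counts.

    ``ap_boundary`` is the axial coordinate of the anterior/posterior
    split (posterior = axial position >= boundary, axial coordinates
    increasing posteriorly).  Empty groups after filtering are simply
    absent from the output.
    """
    if group_col not in cells.columns:
        raise ValueError(f"missing group column {group_col!r}")
    calls = [
        _call_from_group(cid, grp, ap_boundary, axial_col)
        for cid, grp in cells.groupby(group_col, sort=True)
        if len(grp) > 0
    ]
    return calls


def group_barcodes(
    table: pd.DataFrame, ap_boundary: float, axial_col: str = "axial_pos"
) -> tuple[list[CloneCall], pd.DataFrame]:
    """Clone calls from exact barcode-string grouping.

    Rows whose barcode contains an ambiguous base (``N``) cannot be
    grouped reliably and are excluded; they are returned alongside the
    calls.  Classification then mirrors :func:`classify_clones`.
    Returns ``(calls, excluded_rows)``.
    """
    if "barcode" not in table.columns:
        raise ValueError("missing 'barcode' column")
    ambiguous = table["barcode"].str.contains("N", na=True)
    excluded = table[ambiguous].copy()
    kept = table[~ambiguous]
    calls = [
        _call_from_group(bc, grp, ap_boundary, axial_col)
        for bc, grp in kept.groupby("barcode", sort=True)
    ]
    return calls, excluded


def potency_summary(calls: list[CloneCall]) -> pd.DataFrame:
    """Frequency table of clone potencies (N / M / NM) with cell totals."""
    rows = []
    for p in ("N", "M", "NM"):
        sub = [c for c in calls if c.potency == p]
        rows.append((p, len(sub), sum(c.n_cells for c in sub)))
    return pd.DataFrame(rows, columns=["potency", "n_clones", "n_cells"])
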