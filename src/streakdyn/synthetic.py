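"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here with its
ground truth retained, so that each stage can be scored (clone ARI,
ingression-time recovery, count accuracy, dynamic-gene confusion matrix)
without re-deriving labels:

* 2D+t nuclear tracks in a gastrulating epiblast, with a posteriorly
  regressing node, anteroposterior (AP) gradients of convergence speed,
  ingression hazard and division rate;
* per-cell three-channel color intensities drawn around clone-specific
  hues (multispectral combinatorial labeling), with tissue labels;
* per-cell retroviral barcode strings with tissue and axial labels;
* two-channel immunostain-like images of Gaussian nuclear blobs with a
  known number of double-positive nuclei;
* a cells x genes expression matrix ordered by a latent pseudotime with
  known dynamic and null genes.

The generators are phenomenological: they reproduce the statistical
structure the estimators see (gradients, hazards, hue noise, blob
overlap), not tissue mechanics.  All are bitwise reproducible for a
fixed seed.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ExpressionOrdering
from .tracks import Track, TrackSet

__all__ = [
    "TrackGenParams",
    "TrackGroundTruth",
    "generate_tracks",
    "CloneGenParams",
    "generate_clone_colors",
    "generate_barcodes",
    "ImageGenParams",
    "generate_two_channel_image",
    "generate_graded_nuclei_image",
    "ExpressionGenParams",
    "generate_expression",
]


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

Profile = Callable[[np.ndarray], np.ndarray]


def _as_profile(p: float | Profile) -> Profile:
    if callable(p):
        return p
    const = float(p)
    return lambda y: np.full_like(np.asarray(y, dtype=float), const)


@dataclass
class TrackGenParams:
    """Parameters of the epiblast track simulator.

    Cells drift posteriorly following the node (``node_speed``, µm/min),
    converge toward the midline at an AP-position-dependent speed
    (``convergence_profile``, µm/min as a function of y), ingress with an
    AP-dependent per-frame hazard, and divide with an AP-dependent rate
    (events per cell per hour).  Positions get isotropic Gaussian noise of
    ``position_noise_sd`` µm per frame.  Initial cells are uniform over
    ``ml_range`` x ``ap_range``; with ``two_sided`` each cell's
    mediolateral side is drawn at random (ml_range then gives |x|).

    The default frame interval is 4 min, a typical wide-field time-lapse
    acquisition rate for gastrula-stage avian embryos.
    """

    n_cells: int = 500
    duration: float = 180.0          # minutes
    frame_interval: float = 4.0      # minutes
    midline_x: float = 0.0           # µm, fixed by convention
    node_speed: float = 1.0          # µm/min, posterior-directed
    convergence_profile: float | Profile = 0.5   # µm/min toward midline
    ingression_hazard_profile: float | Profile = 0.0  # probability per frame
    division_rate_profile: float | Profile = 0.0      # events/cell/hour
    position_noise_sd: float = 0.0   # µm per frame
    ml_range: tuple[float, float] = (80.0, 400.0)   # µm, |x| span of seeds
    ap_range: tuple[float, float] = (0.0, 1000.0)   # µm, AP span of seeds
    two_sided: bool = True
    node_start: tuple[float, float] = (0.0, 0.0)    # (x, y) µm at t = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.midline_x != 0.0:
            raise ValueError("the coordinate convention fixes midline_x = 0")


@dataclass
class TrackGroundTruth:
    """Programmed truth accompanying a generated TrackSet."""

    events: pd.DataFrame          # track_id, frame, t_min, kind, x_um, y_um
    node: Track                   # the regressing node trajectory
    params: TrackGenParams

    def n_events(self, kind: str) -> int:
        return int((self.events["kind"] == kind).sum())


class _Cell:
    __slots__ = ("track_id", "parent_id", "frames", "t", "x", "y", "status")

    def __init__(self, track_id, parent_id, frame, t, x, y):
        self.track_id = track_id
        self.parent_id = parent_id
        self.frames = [frame]
        self.t = [t]
        self.x = [x]
        self.y = [y]
        self.status = "live"


def generate_tracks(params: TrackGenParams) -> tuple[TrackSet, TrackGroundTruth]:
    """Simulate nuclear tracks frame by frame.

    Per frame each live cell (in order): may ingress with its local
    per-frame hazard (the track is censored), may divide with probability
    ``rate(y)/60 * dt`` (the mother track ends with status ``divided`` and
    two daughter tracks start at her position), otherwise advances by the
    node-following AP drift plus convergence toward the midline plus
    noise.  Convergence never overshoots the midline.  The node trajectory
    and every ingression/division event are returned as ground truth.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    n_frames = int(round(params.duration / dt)) + 1  # samples, incl. t = 0
    conv = _as_profile(params.convergence_profile)
    hazard = _as_profile(params.ingression_hazard_profile)
    div_rate = _as_profile(params.division_rate_profile)

    x0 = rng.uniform(params.ml_range[0], params.ml_range[1], params.n_cells)
    if params.two_sided:
        x0 = x0 * rng.choice([-1.0, 1.0], size=params.n_cells)
    y0 = rng.uniform(params.ap_range[0], params.ap_range[1], params.n_cells)

    cells = [_Cell(i, None, 0, 0.0, float(x0[i]), float(y0[i])) for i in range(params.n_cells)]
    next_id = params.n_cells
    done: list[_Cell] = []
    events: list[tuple] = []

    for f in range(n_frames - 1):
        t_next = (f + 1) * dt
        n_live = len(cells)
        ys = np.array([c.y[-1] for c in cells])
        xs = np.array([c.x[-1] for c in cells])
        h = np.clip(hazard(ys), 0.0, 1.0)
        ingress = rng.random(n_live) < h
        p_div = np.clip(div_rate(ys) / 60.0 * dt, 0.0, 1.0)
        divide = (~ingress) & (rng.random(n_live) < p_div)
        move = ~(ingress | divide)
        # kinematics: AP drift with the node + convergence toward midline,
        # never overshooting it
        step = np.minimum(conv(ys) * dt, np.abs(xs))
        nx = xs - np.sign(xs) * step
        ny = ys + params.node_speed * dt
        if params.position_noise_sd > 0:
            nx = nx + rng.normal(0.0, params.position_noise_sd, n_live)
            ny = ny + rng.normal(0.0, params.position_noise_sd, n_live)
        new_cells: list[_Cell] = []
        still = []
        for i, c in enumerate(cells):
            if ingress[i]:
                c.status = "ingressed"
                events.append((c.track_id, f + 1, t_next, "ingression", c.x[-1], c.y[-1]))
                done.append(c)
            elif divide[i]:
                c.status = "divided"
                events.append((c.track_id, f + 1, t_next, "division", c.x[-1], c.y[-1]))
                done.append(c)
                for _ in range(2):
                    new_cells.append(
                        _Cell(next_id, c.track_id, f + 1, t_next, c.x[-1], c.y[-1])
                    )
                    next_id += 1
            else:
                c.frames.append(f + 1)
                c.t.append(t_next)
                c.x.append(float(nx[i]))
                c.y.append(float(ny[i]))
                still.append(c)
        cells = still + new_cells

    done.extend(cells)  # survivors keep status "live"
    done.sort(key=lambda c: c.track_id)
    tracks = TrackSet(
        [
            Track(
                track_id=c.track_id,
                parent_id=c.parent_id,
                t=np.asarray(c.t),
                x=np.asarray(c.x),
                y=np.asarray(c.y),
                status=c.status,
                frame=np.asarray(c.frames),
            )
            for c in done
        ]
    )
    t_node = np.arange(n_frames) * dt
    node = Track(
        track_id=-1,
        parent_id=None,
        t=t_node,
        x=np.full(n_frames, params.node_start[0]),
        y=params.node_start[1] + params.node_speed * t_node,
        status="live",
        frame=np.arange(n_frames),
    )
    ev = pd.DataFrame(
        events, columns=["track_id", "frame", "t_min", "kind", "x_um", "y_um"]
    )
    return tracks, TrackGroundTruth(events=ev, node=node, params=params)


# ---------------------------------------------------------------------------
# Clone colors (combinatorial multispectral labels)
# ---------------------------------------------------------------------------

POTENCIES = ("N", "M", "NM")


@dataclass
class CloneGenParams:
    """Parameters for three-channel clone color generation.

    Each clone has a hue center on the 2-simplex (fractions of the three
    fluorescence channels summing to 1).  Per cell, raw channel
    intensities are the center scaled by ``total_intensity`` plus Gaussian
    noise of sd ``hue_noise_sd * total_intensity`` (noise enters on raw
    intensities, before normalization, as detector noise does), clipped at
    zero and renormalized.  ``n_ambiguous`` extra cells with uniform
    random hues model cells whose color code cannot be trusted.
    """

    n_clones: int = 5
    cells_per_clone: int | Sequence[int] = 40
    hue_centers: Sequence[tuple[float, float, float]] | None = None
    hue_noise_sd: float = 0.03       # fraction of total intensity
    potency_assignment: Sequence[str] | None = None   # per clone: N, M or NM
    ap_span: float = 1000.0          # µm
    total_intensity: float = 1000.0  # arbitrary units
    n_ambiguous: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hue_centers is not None:
            for c in self.hue_centers:
                if len(c) != 3 or any(v < 0 for v in c) or abs(sum(c) - 1.0) > 1e-9:
                    raise ValueError(f"hue center {c} is not on the 2-simplex")
            if len(self.hue_centers) != self.n_clones:
                raise ValueError("need one hue center per clone")
        if self.potency_assignment is not None:
            if len(self.potency_assignment) != self.n_clones:
                raise ValueError("need one potency per clone")
            for p in self.potency_assignment:
                if p not in POTENCIES:
                    raise ValueError(f"unknown potency {p!r}")


def _default_hue_centers(n: int, rng: np.random.Generator) -> np.ndarray:
    """Well-spread simplex points: corners, edge midpoints, centroid, then random."""
    base = [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5),
        (1 / 3, 1 / 3, 1 / 3),
    ]
    pts = [np.array(p, dtype=float) for p in base[:n]]
    while len(pts) < n:
        pts.append(rng.dirichlet([1.0, 1.0, 1.0]))
    return np.vstack(pts)


def _tissue_labels(n: int, potency: str, rng: np.random.Generator) -> np.ndarray:
    if potency == "N":
        return np.full(n, "neural")
    if potency == "M":
        return np.full(n, "mesoderm")
    if n == 1:
        # a single cell cannot exhibit bipotency; give it one tissue at random
        return np.asarray([rng.choice(["neural", "mesoderm"])])
    lab = np.where(rng.random(n) < 0.5, "neural", "mesoderm")
    # bipotent clones must show both tissues
    if (lab == "neural").all():
        lab[rng.integers(n)] = "mesoderm"
    elif (lab == "mesoderm").all():
        lab[rng.integers(n)] = "neural"
    return lab


def generate_clone_colors(params: CloneGenParams) -> pd.DataFrame:
    """Generate a per-cell color table with ground-truth clone ids.

    Returns a DataFrame with columns ``cell_id, clone_id, c1, c2, c3,
    tissue, y_um``; ``clone_id`` is -1 for injected ambiguous cells.  Raw
    intensities feed :func:`streakdyn.clones.normalize_colors`.
    """
    rng = np.random.default_rng(params.seed)
    centers = (
        np.asarray(params.hue_centers, dtype=float)
        if params.hue_centers is not None
        else _default_hue_centers(params.n_clones, rng)
    )
    sizes = (
        np.full(params.n_clones, params.cells_per_clone, dtype=int)
        if np.isscalar(params.cells_per_clone)
        else np.asarray(params.cells_per_clone, dtype=int)
    )
    if len(sizes) != params.n_clones:
        raise ValueError("cells_per_clone length must match n_clones")
    potency = (
        list(params.potency_assignment)
        if params.potency_assignment is not None
        else [rng.choice(POTENCIES) for _ in range(params.n_clones)]
    )

    rows = []
    cell_id = 0
    for k in range(params.n_clones):
        n = int(sizes[k])
        raw = centers[k] * params.total_intensity + rng.normal(
            0.0, params.hue_noise_sd * params.total_intensity, size=(n, 3)
        )
        raw = np.clip(raw, 0.0, None)
        # a draw that clips to all-zero is unusable; resample it
        bad = raw.sum(axis=1) == 0
        while bad.any():
            raw[bad] = np.clip(
                centers[k] * params.total_intensity
                + rng.normal(0.0, params.hue_noise_sd * params.total_intensity, (int(bad.sum()), 3)),
                0.0,
                None,
            )
            bad = raw.sum(axis=1) == 0
        tissues = _tissue_labels(n, potency[k], rng)
        ys = rng.uniform(0.0, params.ap_span, n)
        for i in range(n):
            rows.append((cell_id, k, raw[i, 0], raw[i, 1], raw[i, 2], tissues[i], ys[i]))
            cell_id += 1
    for _ in range(params.n_ambiguous):
        frac = rng.dirichlet([1.0, 1.0, 1.0])
        raw = frac * params.total_intensity
        rows.append(
            (
                cell_id,
                -1,
                raw[0],
                raw[1],
                raw[2],
                rng.choice(["neural", "mesoderm"]),
                rng.uniform(0.0, params.ap_span),
            )
        )
        cell_id += 1
    return pd.DataFrame(
        rows, columns=["cell_id", "clone_id", "c1", "c2", "c3", "tissue", "y_um"]
    )


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------

BARCODE_LENGTH = 24
_BASES = np.array(list("ACGT"))


def generate_barcodes(
    n_clones: int,
    cells_per_clone: int | Sequence[int],
    potency_assignment: Sequence[str] | None = None,
    somite27_coordinate: float = 500.0,
    ap_span: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a retroviral-barcode cell table with ground truth.

    Each clone receives a distinct random 24-mer over {A, C, G, T}
    (collisions are redrawn).  Each cell row carries the barcode, a tissue
    label honoring the clone's potency (N, M, or NM — bipotent clones show
    both tissues), and an axial position uniform on ``[0, ap_span]`` µm;
    ``somite27_coordinate`` is the anterior/posterior boundary downstream
    classification will use.  Columns: ``cell_id, clone_id, barcode,
    tissue, axial_pos``.
    """
    rng = np.random.default_rng(seed)
    sizes = (
        np.full(n_clones, cells_per_clone, dtype=int)
        if np.isscalar(cells_per_clone)
        else np.asarray(cells_per_clone, dtype=int)
    )
    if len(sizes) != n_clones:
        raise ValueError("cells_per_clone length must match n_clones")
    if potency_assignment is None:
        potency_assignment = [rng.choice(POTENCIES) for _ in range(n_clones)]
    if len(potency_assignment) != n_clones:
        raise ValueError("need one potency per clone")

    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_clones:
        bc = "".join(rng.choice(_BASES, BARCODE_LENGTH))
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)

    rows = []
    cell_id = 0
    for k in range(n_clones):
        n = int(sizes[k])
        tissues = _tissue_labels(n, potency_assignment[k], rng)
        axial = rng.uniform(0.0, ap_span, n)
        for i in range(n):
            rows.append((cell_id, k, barcodes[k], tissues[i], axial[i]))
            cell_id += 1
    df = pd.DataFrame(rows, columns=["cell_id", "clone_id", "barcode", "tissue", "axial_pos"])
    df.attrs["somite27_coordinate"] = somite27_coordinate
    return df


# ---------------------------------------------------------------------------
# Two-channel immunostain-like images
# ---------------------------------------------------------------------------


@dataclass
class ImageGenParams:
    """Parameters for synthetic two-channel nuclear images.

    Nuclei are isotropic Gaussian blobs of width ``blob_sigma`` px and
    peak ``intensity``.  Double-positive nuclei share the same center in
    both channels; all other centers keep a minimum separation of
    ``4 * blob_sigma`` so particles stay resolvable.  Additive Gaussian
    background noise is clipped at zero (intensities are non-negative).
    """

    shape: tuple[int, int] = (256, 256)
    n_cells_channel1: int = 10
    n_cells_channel2: int = 10
    n_double_positive: int = 5
    blob_sigma: float = 3.0
    intensity: float = 1000.0
    background_noise_sd: float = 0.0
    pixel_size: float = 1.0   # µm per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_double_positive > min(self.n_cells_channel1, self.n_cells_channel2):
            raise ValueError("n_double_positive exceeds a per-channel count")
        margin = 4 * self.blob_sigma
        if 2 * margin >= min(self.shape):
            raise ValueError("blobs do not fit inside the frame")


def _place_centers(
    n: int, shape: tuple[int, int], min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    margin = min_sep
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10 * n if n else 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} centers at separation {min_sep} "
                f"in {shape} within {max_attempts} attempts"
            )
        attempts += 1
        # integer-pixel centers so a blob's peak pixel equals its amplitude
        c = np.array(
            [
                np.round(rng.uniform(margin, shape[0] - margin)),
                np.round(rng.uniform(margin, shape[1] - margin)),
            ]
        )
        if all(np.hypot(*(c - p)) >= min_sep for p in centers):
            centers.append(c)
    return np.asarray(centers).reshape(n, 2)


def _render_blobs(
    shape: tuple[int, int], centers: np.ndarray, sigma: float, amp: float
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma))
    for cy, cx in centers:
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return img


def generate_two_channel_image(
    params: ImageGenParams,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a registered two-channel image pair with known counts.

    Returns ``(img1, img2, truth)`` where ``truth`` holds the per-channel
    and double-positive counts and all centers (row, col pixel
    coordinates).
    """
    rng = np.random.default_rng(params.seed)
    n1, n2, nd = params.n_cells_channel1, params.n_cells_channel2, params.n_double_positive
    total = nd + (n1 - nd) + (n2 - nd)
    centers = _place_centers(total, params.shape, 4 * params.blob_sigma, rng)
    shared = centers[:nd]
    only1 = centers[nd : nd + (n1 - nd)]
    only2 = centers[nd + (n1 - nd) :]
    c1 = np.vstack([shared, only1]) if n1 else np.empty((0, 2))
    c2 = np.vstack([shared, only2]) if n2 else np.empty((0, 2))
    img1 = _render_blobs(params.shape, c1, params.blob_sigma, params.intensity)
    img2 = _render_blobs(params.shape, c2, params.blob_sigma, params.intensity)
    if params.background_noise_sd > 0:
        img1 = np.clip(img1 + rng.normal(0, params.background_noise_sd, params.shape), 0, None)
        img2 = np.clip(img2 + rng.normal(0, params.background_noise_sd, params.shape), 0, None)
    truth = {
        "n_channel1": n1,
        "n_channel2": n2,
        "n_double_positive": nd,
        "centers_channel1": c1,
        "centers_channel2": c2,
        "centers_shared": shared,
        "pixel_size": params.pixel_size,
    }
    return img1, img2, truth


def generate_graded_nuclei_image(
    shape: tuple[int, int] = (256, 256),
    n_dim: int = 30,
    n_bright: int = 8,
    bright_factor: float = 3.0,
    blob_sigma: float = 3.0,
    intensity: float = 1000.0,
    background_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Single-channel image with two nuclear brightness classes.

    Emulates a live nuclear marker in which mitotic cells appear brighter
    than interphase cells (chromatin condensation): ``n_bright`` nuclei at
    peak ``bright_factor * intensity`` among ``n_dim`` at ``intensity``.
    Returns ``(image, truth)`` with truth counts and centers.
    """
    rng = np.random.default_rng(seed)
    total = n_dim + n_bright
    centers = _place_centers(total, shape, 4 * blob_sigma, rng)
    bright_centers = centers[:n_bright]
    dim_centers = centers[n_bright:]
    img = _render_blobs(shape, dim_centers, blob_sigma, intensity)
    img += _render_blobs(shape, bright_centers, blob_sigma, bright_factor * intensity)
    if background_noise_sd > 0:
        img = np.clip(img + rng.normal(0, background_noise_sd, shape), 0, None)
    truth = {
        "n_total": total,
        "n_bright": n_bright,
        "centers_bright": bright_centers,
        "centers_dim": dim_centers,
    }
    return img, truth


# ---------------------------------------------------------------------------
# Expression along a latent pseudotime
# ---------------------------------------------------------------------------

TREND_SHAPES = ("ramp", "sigmoid", "pulse")


@dataclass
class ExpressionGenParams:
    """Parameters for pseudotime-ordered expression matrices.

    Dynamic genes follow a trend shape (``ramp``: linear increase;
    ``sigmoid``: switch at a random point; ``pulse``: Gaussian bump at a
    random position) with amplitude ``effect_size * noise_sd``; null genes
    are pure Gaussian noise.  ``n_cells`` must be at least three windows
    of the downstream default (100 cells) so sliding-window statistics are
    meaningful.
    """

    n_cells: int = 1000
    n_dynamic_genes: int = 50
    n_null_genes: int = 200
    trend_shapes: Sequence[str] = ("ramp", "sigmoid", "pulse")
    effect_size: float = 5.0     # mean shift in noise-SD units
    noise_sd: float = 1.0        # expression units
    seed: int = 0
    min_cells: int = field(default=300, repr=False)

    def __post_init__(self) -> None:
        if self.n_cells < self.min_cells:
            raise ValueError(f"n_cells must be >= {self.min_cells}")
        if self.n_dynamic_genes < 0 or self.n_null_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for s in self.trend_shapes:
            if s not in TREND_SHAPES:
                raise ValueError(f"unknown trend shape {s!r}")


def _trend(shape: str, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude trend over s in [0, 1]."""
    if shape == "ramp":
        return s
    if shape == "sigmoid":
        center = rng.uniform(0.3, 0.7)
        return 1.0 / (1.0 + np.exp(-(s - center) / 0.05))
    if shape == "pulse":
        center = rng.uniform(0.2, 0.8)
        return np.exp(-((s - center) ** 2) / (2 * 0.1**2))
    raise ValueError(shape)


def generate_expression(
    params: ExpressionGenParams,
) -> tuple[ExpressionOrdering, pd.DataFrame]:
    """Generate an ordered expression matrix plus a gene truth table.

    Returns ``(ordering, truth)``; truth has one row per gene with columns
    ``gene, dynamic, shape`` (shape is None for null genes).  Dynamic
    genes come first in the column order, named ``dyn_<shape>_<i>``; null
    genes are ``null_<i>``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    s = np.linspace(0.0, 1.0, n)
    cols, names, truth_rows = [], [], []
    # amplitude in noise-SD units; with zero noise the unit scale is kept so
    # noiseless trends remain non-degenerate
    amp = params.effect_size * (params.noise_sd if params.noise_sd > 0 else 1.0)
    for i in range(params.n_dynamic_genes):
        shape = params.trend_shapes[i % len(params.trend_shapes)]
        signal = amp * _trend(shape, s, rng)
        noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
        cols.append(signal + noise)
        name = f"dyn_{shape}_{i}"
        names.append(name)
        truth_rows.append((name, True, shape))
    for i in range(params.n_null_genes):
        cols.append(rng.normal(0.0, params.noise_sd, n))
        name = f"null_{i}"
        names.append(name)
        truth_rows.append((name, False, None))
    matrix = np.column_stack(cols) if cols else np.empty((n, 0))
    truth = pd.DataFrame(truth_rows, columns=["gene", "dynamic", "shape"])
    return ExpressionOrdering(matrix, names), truth
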