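"""Epiblast cell-behavior quantification from nuclear tracks.

Quantifies the measurements used to characterize primitive-streak (PS)
epiblast dynamics: registration of tracks to the regressing node,
instantaneous lateral-to-medial (convergence, v_LM) and anteroposterior
(v_AP) velocities, track angles with the midline, binned speed profiles
along the AP axis, track longevity (survival of a t0 cohort after 1 and
2 hours), ingression-intensity gradients from ventral image stacks, and
inter-division times.

Sign conventions (see :mod:`streakdyn.tracks`): the midline is x = 0;
v_LM is positive for motion toward the midline; v_AP is positive
posteriorly.  The angle with the midline folds convergence and divergence
together, theta = arctan(|v_LM| / |v_AP|) in [0, 90] degrees: 0 means
motion parallel to the midline, 90 pure convergence/divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Region, Track, TrackSet

__all__ = [
    "register_to_node",
    "velocities",
    "midline_angle",
    "angle_fraction_report",
    "speed_profile",
    "LongevityReport",
    "track_longevity",
    "IngressionCurve",
    "ingression_intensity",
    "interdivision_times",
]


def register_to_node(tracks: TrackSet, node_track: Track, invert: bool = False) -> TrackSet:
    """Subtract the node's contemporaneous position from every sample.

    Puts tracks in the frame comoving with the regressing node (the node
    maps to the origin at all times).  The node position is linearly
    interpolated inside its time span; samples outside the span raise (no
    extrapolation).  ``invert=True`` adds the node position back, undoing
    a previous registration.
    """
    sign = 1.0 if invert else -1.0
    t0, t1 = node_track.t[0], node_track.t[-1]
    out = []
    for tr in tracks:
        if tr.t[0] < t0 - 1e-9 or tr.t[-1] > t1 + 1e-9:
            raise ValueError(
                f"track {tr.track_id} spans [{tr.t[0]}, {tr.t[-1]}] min, outside "
                f"the node span [{t0}, {t1}]"
            )
        nx = np.interp(tr.t, node_track.t, node_track.x)
        ny = np.interp(tr.t, node_track.t, node_track.y)
        out.append(
            Track(
                track_id=tr.track_id,
                parent_id=tr.parent_id,
                t=tr.t.copy(),
                x=tr.x + sign * nx,
                y=tr.y + sign * ny,
                status=tr.status,
                frame=tr.frame.copy(),
            )
        )
    return TrackSet(out)


def velocities(track: Track) -> pd.DataFrame:
    """Discrete-displacement velocities between consecutive samples.

    One row per consecutive sample pair, attached to the midpoint time and
    position: ``v_ap = dy/dt`` (posterior positive) and
    ``v_lm = -sign(x_mid) * dx/dt`` so motion toward the midline is
    positive.  Columns: ``t, v_lm, v_ap, ap_position, x_mid``.
    """
    if len(track) < 2:
        raise ValueError("need >= 2 samples to compute velocities")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("non-positive time step")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    x_mid = 0.5 * (track.x[:-1] + track.x[1:])
    return pd.DataFrame(
        {
            "t": 0.5 * (track.t[:-1] + track.t[1:]),
            "v_lm": -np.sign(x_mid) * dx / dt,
            "v_ap": dy / dt,
            "ap_position": 0.5 * (track.y[:-1] + track.y[1:]),
            "x_mid": x_mid,
        }
    )


def midline_angle(v_lm, v_ap):
    """Angle with the midline in degrees, arctan(|v_LM| / |v_AP|) in [0, 90].

    Vectorized; a sample with zero displacement in both components is
    undefined and returns NaN (callers skip and count such samples).
    """
    v_lm = np.asarray(v_lm, dtype=float)
    v_ap = np.asarray(v_ap, dtype=float)
    ang = np.degrees(np.arctan2(np.abs(v_lm), np.abs(v_ap)))
    ang = np.where((v_lm == 0) & (v_ap == 0), np.nan, ang)
    return ang if ang.ndim else float(ang)


def angle_fraction_report(
    tracks: TrackSet,
    region: Region | None = None,
    boundary: float = 45.0,
    per_track: bool = True,
) -> dict:
    """Fractions of tracks with mean midline angle below/above ``boundary``.

    Each track's angle is the mean over its velocity samples whose
    midpoint lies in ``region`` (all samples if region is None); fractions
    are then taken over tracks, which avoids overweighting long tracks.
    ``per_track=False`` pools all step angles instead.  The boundary angle
    itself goes to the upper bin.  Returns ``{"frac_0_45", "frac_45_90",
    "n", "n_skipped"}`` where ``n_skipped`` counts zero-displacement
    samples.
    """
    units = []  # one angle per track (or per step when pooled)
    n_skipped = 0
    for tr in tracks:
        if len(tr) < 2:
            continue
        v = velocities(tr)
        if region is not None:
            v = v[region.contains(v["x_mid"], v["ap_position"])]
        if v.empty:
            continue
        ang = midline_angle(v["v_lm"].to_numpy(), v["v_ap"].to_numpy())
        n_skipped += int(np.isnan(ang).sum())
        ang = ang[~np.isnan(ang)]
        if ang.size == 0:
            continue
        if per_track:
            units.append(float(np.mean(ang)))
        else:
            units.extend(ang.tolist())
    if not units:
        raise ValueError("no valid angles in the region")
    arr = np.asarray(units)
    frac_hi = float(np.mean(arr >= boundary))  # boundary goes to the upper bin
    return {
        "frac_0_45": 1.0 - frac_hi,
        "frac_45_90": frac_hi,
        "n": len(units),
        "n_skipped": n_skipped,
    }


def speed_profile(
    tracks: TrackSet,
    ap_bin_width: float = 50.0,
    time_bin_width: float = 30.0,
) -> pd.DataFrame:
    """Binned mean v_LM and v_AP versus AP position, per time bin.

    All velocity samples of all tracks are pooled and binned by
    (AP position, time).  Returns one row per populated bin with columns
    ``ap_bin_center, t_bin_center, v_lm_mean, v_lm_sd, v_ap_mean,
    v_ap_sd, n``; SD is NaN for single-sample bins, and empty bins are
    simply absent (never imputed as zero).
    """
    if ap_bin_width <= 0 or time_bin_width <= 0:
        raise ValueError("bin widths must be positive")
    frames = [velocities(tr) for tr in tracks if len(tr) >= 2]
    if not frames:
        raise ValueError("no track has >= 2 samples")
    v = pd.concat(frames, ignore_index=True)
    v["ap_bin"] = np.floor(v["ap_position"] / ap_bin_width).astype(int)
    v["t_bin"] = np.floor(v["t"] / time_bin_width).astype(int)
    grouped = v.groupby(["ap_bin", "t_bin"])
    out = grouped.agg(
        v_lm_mean=("v_lm", "mean"),
        v_lm_sd=("v_lm", lambda s: s.std(ddof=1)),
        v_ap_mean=("v_ap", "mean"),
        v_ap_sd=("v_ap", lambda s: s.std(ddof=1)),
        n=("v_lm", "size"),
    ).reset_index()
    out["ap_bin_center"] = (out["ap_bin"] + 0.5) * ap_bin_width
    out["t_bin_center"] = (out["t_bin"] + 0.5) * time_bin_width
    return out[
        ["ap_bin_center", "t_bin_center", "v_lm_mean", "v_lm_sd",
         "v_ap_mean", "v_ap_sd", "n"]
    ]


@dataclass
class LongevityReport:
    """Survival of a t0 track cohort in one region after 1 and 2 hours."""

    region: str
    n_t0: int
    ratio_1h: float
    ratio_2h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_2h <= self.ratio_1h <= 1.0:
            raise ValueError("ratios must satisfy 0 <= ratio_2h <= ratio_1h <= 1")


def _alive_at(tr: Track, t: float, children: dict, index: dict, lineage: bool) -> bool:
    """Is this track (or, with lineage=True, any descendant) present at time t?"""
    if tr.t[0] > t:
        return False
    if tr.t[-1] >= t:
        return True
    if tr.status == "divided" and lineage:
        return any(
            _alive_at(index[cid], t, children, index, lineage)
            for cid in children.get(tr.track_id, [])
        )
    return False


def track_longevity(
    tracks: TrackSet,
    regions: list[Region],
    t0: float = 0.0,
    lineage_survival: bool = True,
) -> list[LongevityReport]:
    """Fraction of the t0 cohort still present after 1 and 2 hours.

    The cohort of a region is every track alive at ``t0`` whose position
    at ``t0`` falls inside it.  A track counts as surviving at horizon
    ``t0 + k*60`` when it is still uncensored there; with
    ``lineage_survival`` (the default) a track that divided survives
    through its daughters.
    """
    children = tracks.children()
    index = {tr.track_id: tr for tr in tracks}
    reports = []
    for region in regions:
        cohort = []
        for tr in tracks:
            pos = tr.position_at(t0)
            if pos is not None and bool(region.contains(*pos)):
                cohort.append(tr)
        if not cohort:
            raise ValueError(f"region {region.label!r} is empty at t0 = {t0}")
        n0 = len(cohort)
        n1 = sum(_alive_at(tr, t0 + 60.0, children, index, lineage_survival) for tr in cohort)
        n2 = sum(_alive_at(tr, t0 + 120.0, children, index, lineage_survival) for tr in cohort)
        reports.append(LongevityReport(region.label, n0, n1 / n0, n2 / n0))
    return reports


@dataclass
class IngressionCurve:
    """Mean intensity along the PS axis per timepoint, with linear fits.

    ``profile`` has one row per (timepoint, AP bin) with the mean pixel
    intensity of labeled nuclei that have ingressed under the streak;
    ``fits`` has one row per timepoint with the OLS slope (units/µm),
    intercept and R² of intensity against bin center.  A positive slope
    means intensity (hence ingression) increases posteriorly.  Timepoints
    with fewer than three populated bins carry no fit (``fitted`` False).
    """

    profile: pd.DataFrame
    fits: pd.DataFrame
    ap_bin_width: float


def ingression_intensity(
    stack: np.ndarray,
    ps_axis: np.ndarray,
    ap_bin_width: float = 50.0,
    band_halfwidth: float = 50.0,
    pixel_size: float = 1.0,
) -> IngressionCurve:
    """Intensity gradient along the primitive streak from a ventral stack.

    ``stack`` is (T, H, W); ``ps_axis`` a polyline of (row, col) pixel
    vertices running anterior to posterior along the streak.  Pixels
    within ``band_halfwidth`` µm of the polyline are assigned an arclength
    coordinate (µm, via the nearest projection) and binned at
    ``ap_bin_width``; each timepoint's binned means are fit by ordinary
    least squares against bin centers.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    axis = np.asarray(ps_axis, dtype=float)
    if axis.ndim != 2 or axis.shape[0] < 2 or axis.shape[1] != 2:
        raise ValueError("ps_axis must be an (N >= 2, 2) polyline of pixel coords")
    _, H, W = stack.shape
    if (axis[:, 0].min() < 0 or axis[:, 0].max() >= H
            or axis[:, 1].min() < 0 or axis[:, 1].max() >= W):
        raise ValueError("ps_axis must lie within the frame")

    yy, xx = np.mgrid[0:H, 0:W]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    best_d2 = np.full(pts.shape[0], np.inf)
    best_arc = np.zeros(pts.shape[0])
    arc0 = 0.0
    for a, b in zip(axis[:-1], axis[1:]):
        seg = b - a
        seg_len = float(np.hypot(*seg))
        if seg_len == 0:
            continue
        t = np.clip(((pts - a) @ seg) / seg_len**2, 0.0, 1.0)
        proj = a + t[:, None] * seg
        d2 = ((pts - proj) ** 2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = (arc0 + t[closer] * seg_len)
        arc0 += seg_len
    dist_um = np.sqrt(best_d2) * pixel_size
    arc_um = best_arc * pixel_size
    in_band = dist_um <= band_halfwidth
    bins = np.floor(arc_um[in_band] / ap_bin_width).astype(int)

    prof_rows, fit_rows = [], []
    for ti in range(stack.shape[0]):
        vals = stack[ti].ravel()[in_band]
        df = pd.DataFrame({"bin": bins, "v": vals}).groupby("bin")["v"].mean()
        centers = (df.index.to_numpy() + 0.5) * ap_bin_width
        for c, m in zip(centers, df.to_numpy()):
            prof_rows.append((ti, c, m))
        if len(df) >= 3:
            res = stats.linregress(centers, df.to_numpy())
            fit_rows.append(
                (ti, res.slope, res.intercept, res.rvalue**2, True)
            )
        else:
            fit_rows.append((ti, np.nan, np.nan, np.nan, False))
    profile = pd.DataFrame(prof_rows, columns=["timepoint", "ap_bin_center", "mean_intensity"])
    fits = pd.DataFrame(fit_rows, columns=["timepoint", "slope", "intercept", "r2", "fitted"])
    return IngressionCurve(profile=profile, fits=fits, ap_bin_width=ap_bin_width)


def interdivision_times(tracks: TrackSet) -> tuple[list[float], int]:
    """Observed inter-division intervals, in minutes.

    A track contributes an interval only when both its birth (it has a
    recorded parent) and its own division (status ``divided``) were
    observed; the interval is the time between its first and last sample.
    Returns ``(intervals, n_censored)`` where censored tracks are those
    with observed birth but no observed division.
    """
    intervals = []
    n_censored = 0
    for tr in tracks:
        if tr.parent_id is None:
            continue  # birth not observed
        if tr.status == "divided":
            intervals.append(tr.t_end - tr.t_start)
        else:
            n_censored += 1
    return intervals, n_censored
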