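"""Spindle-frame reference geometry and per-bivalent chromosome metrics.

The spindle reference frame is rebuilt at every frame from the two pole
positions: unit long-axis vector ``u`` from pole A to pole B, equator center
``m`` at the pole midpoint.  All chromosome metrics are expressed in this
frame:

- ``theta_labeled`` — angle (degrees, 0..180) between the inter-homolog
  vector (with fixed homolog labels) and the long axis;
- ``theta_folded = min(theta, 180 - theta)`` — the label-free angle used for
  orientation classification;
- ``d_eq`` — unsigned distance of the bivalent center from the equator plane;
- ``d_ax`` — distance of the bivalent center from the long axis;
- ``osc(t) = |d_eq(t + dt) - d_eq(t)|`` — the oscillation measure;
- stretching metrics from the four endpoint markers: homolog lengths,
  inter-homolog distance, and bivalent length (maximum pairwise endpoint
  distance, i.e. the outermost extent).

The bivalent center is the mean of the two homolog centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpindleFrame",
    "spindle_frame",
    "orientation_angle",
    "equator_distance",
    "axis_distance",
    "oscillation",
    "stretch_metrics",
    "detect_reversion",
    "compute_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "oocyte_id", "condition", "bivalent_id", "time_s",
    "theta_labeled_deg", "theta_folded_deg",
    "d_eq_um", "d_ax_um", "osc_um",
    "l_hom1_um", "l_hom2_um", "d_ih_um", "l_biv_um",
]


@dataclass(frozen=True)
class SpindleFrame:
    """Per-timepoint spindle reference frame (all positions in um)."""

    t: float
    pole_a: np.ndarray
    pole_b: np.ndarray
    u: np.ndarray          # unit long-axis vector, A -> B
    midpoint: np.ndarray   # equator center
    length: float          # pole-pole distance


def spindle_frame(pole_a, pole_b, t: float = 0.0) -> SpindleFrame:
    """Build the spindle frame from the two pole positions.

    Raises ``ValueError`` for coincident poles ("degenerate spindle").
    """
    pole_a = np.asarray(pole_a, dtype=float)
    pole_b = np.asarray(pole_b, dtype=float)
    d = pole_b - pole_a
    length = float(np.linalg.norm(d))
    if length == 0.0:
        raise ValueError("degenerate spindle: coincident poles")
    return SpindleFrame(t=float(t), pole_a=pole_a, pole_b=pole_b,
                        u=d / length, midpoint=(pole_a + pole_b) / 2.0,
                        length=length)


def orientation_angle(homolog1, homolog2, frame: SpindleFrame):
    """Angle of the labeled inter-homolog vector against the long axis.

    Returns ``(theta_labeled, theta_folded)`` in degrees; ``(nan, nan)``
    for coincident homologs (undefined angle, to be excluded from
    proportion denominators).
    """
    v = np.asarray(homolog2, dtype=float) - np.asarray(homolog1, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        return float("nan"), float("nan")
    cos = np.clip(v @ frame.u / n, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos)))
    return theta, min(theta, 180.0 - theta)


def equator_distance(centroid, frame: SpindleFrame) -> float:
    """Unsigned distance of a point from the equator plane."""
    d = np.asarray(centroid, dtype=float) - frame.midpoint
    return float(abs(d @ frame.u))


def axis_distance(centroid, frame: SpindleFrame) -> float:
    """Distance of a point from the spindle long axis."""
    d = np.asarray(centroid, dtype=float) - frame.midpoint
    return float(np.linalg.norm(d - (d @ frame.u) * frame.u))


def oscillation(d_eq, dt: float = 10.0) -> np.ndarray:
    """``|d_eq(t + dt) - d_eq(t)|`` for a series sampled at ``dt``.

    One element shorter than the input (undefined at the last frame);
    a single-frame series yields an empty array.
    """
    d_eq = np.asarray(d_eq, dtype=float)
    if d_eq.size < 2:
        return np.empty(0)
    return np.abs(np.diff(d_eq))


def stretch_metrics(end1a, end1b, end2a, end2b):
    """Stretching metrics from the four endpoint markers of one bivalent.

    Parameters are the two endpoints of homolog 1 then of homolog 2.
    Returns ``(l_hom1, l_hom2, d_ih, l_biv)``: homolog lengths (endpoint
    separation), inter-homolog distance (between homolog midpoints), and
    bivalent length (maximum pairwise distance among all four endpoints).
    """
    pts = np.asarray([end1a, end1b, end2a, end2b], dtype=float)
    l1 = float(np.linalg.norm(pts[1] - pts[0]))
    l2 = float(np.linalg.norm(pts[3] - pts[2]))
    c1 = (pts[0] + pts[1]) / 2.0
    c2 = (pts[2] + pts[3]) / 2.0
    d_ih = float(np.linalg.norm(c2 - c1))
    diff = pts[:, None, :] - pts[None, :, :]
    l_biv = float(np.sqrt((diff**2).sum(-1)).max())
    return l1, l2, d_ih, l_biv


def detect_reversion(theta_labeled, persistence: int = 3):
    """Orientation-reversion events in a labeled angle series.

    A reversion is a crossing of the labeled angle from below 90 degrees to
    above 90 degrees that persists for at least ``persistence`` consecutive
    frames.  NaN frames break persistence.  Returns the list of event start
    indices.
    """
    th = np.asarray(theta_labeled, dtype=float)
    above = th > 90.0
    events = []
    i = 0
    n = len(th)
    prev_below = False
    while i < n:
        if np.isnan(th[i]):
            i += 1
            continue
        if above[i] and prev_below:
            run = 0
            j = i
            while j < n and not np.isnan(th[j]) and above[j]:
                run += 1
                j += 1
            if run >= persistence:
                events.append(i)
            i = j
            prev_below = False
        else:
            prev_below = not above[i]
            i += 1
    return events


def _pole_arrays(odf: pd.DataFrame):
    poles = odf[odf["object_class"] == "pole"]
    pa = poles[poles["pole_id"] == "A"].sort_values("time_s")
    pb = poles[poles["pole_id"] == "B"].sort_values("time_s")
    times = pa["time_s"].to_numpy()
    if not np.array_equal(times, pb["time_s"].to_numpy()):
        raise ValueError("pole A and pole B sampled at different times")
    return times, pa[["x_um", "y_um", "z_um"]].to_numpy(), \
        pb[["x_um", "y_um", "z_um"]].to_numpy()


def compute_metrics(tracks: pd.DataFrame, dt: float | None = None) -> pd.DataFrame:
    """Compute the full per-bivalent metric table from a track table.

    For every oocyte the spindle frame is rebuilt at each frame from the
    current pole positions.  Homolog labels are fixed per bivalent so that
    homolog 1 is the homolog nearer pole A at the first tracked frame.
    Stretching metrics are emitted only where endpoint markers exist
    (NaN otherwise).

    Returns a tidy table with one row per bivalent per frame
    (``METRIC_COLUMNS`` schema).
    """
    out = []
    for oid, odf in tracks.groupby("oocyte_id", sort=True):
        times, pa, pb = _pole_arrays(odf)
        if dt is None:
            dt_o = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        else:
            dt_o = dt
        axis = pb - pa
        lengths = np.linalg.norm(axis, axis=1)
        if np.any(lengths == 0):
            raise ValueError("degenerate spindle: coincident poles")
        u = axis / lengths[:, None]
        m = (pa + pb) / 2.0
        condition = odf["condition"].iloc[0] if "condition" in odf else ""

        homs = odf[odf["object_class"] == "homolog"]
        endpoints = odf[odf["object_class"] == "endpoint"]
        for bid, bdf in homs.groupby("bivalent_id", sort=True):
            h1 = bdf[bdf["homolog_id"] == 1].sort_values("time_s")
            h2 = bdf[bdf["homolog_id"] == 2].sort_values("time_s")
            # metrics exist only where both homologs are sampled
            bt = np.intersect1d(h1["time_s"].to_numpy(),
                                h2["time_s"].to_numpy())
            if bt.size == 0:
                continue
            h1 = h1[h1["time_s"].isin(bt)]
            h2 = h2[h2["time_s"].isin(bt)]
            tidx = np.searchsorted(times, bt)
            if not np.allclose(times[tidx], bt):
                raise ValueError("homolog frames missing pole positions")
            p1 = h1[["x_um", "y_um", "z_um"]].to_numpy()
            p2 = h2[["x_um", "y_um", "z_um"]].to_numpy()
            ub, mb = u[tidx], m[tidx]
            # fix labels: homolog 1 = nearer pole A at the first tracked frame
            swap = (np.linalg.norm(p2[0] - pa[tidx[0]])
                    < np.linalg.norm(p1[0] - pa[tidx[0]]))
            if swap:
                p1, p2 = p2, p1
            v = p2 - p1
            vn = np.linalg.norm(v, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = np.clip(np.einsum("ij,ij->i", v, ub) / vn, -1, 1)
            theta = np.degrees(np.arccos(cos))
            theta[vn == 0] = np.nan
            theta_f = np.minimum(theta, 180.0 - theta)
            c = (p1 + p2) / 2.0
            dvec = c - mb
            proj = np.einsum("ij,ij->i", dvec, ub)
            d_eq = np.abs(proj)
            d_ax = np.linalg.norm(dvec - proj[:, None] * ub, axis=1)
            osc = np.full(len(bt), np.nan)
            if len(bt) > 1:
                osc[:-1] = oscillation(d_eq, dt_o)

            l1 = np.full(len(bt), np.nan)
            l2 = np.full(len(bt), np.nan)
            d_ih = np.linalg.norm(p2 - p1, axis=1)
            l_biv = np.full(len(bt), np.nan)
            eb = endpoints[endpoints["bivalent_id"] == bid]
            if len(eb):
                epos = {}
                ok = True
                for h in (1, 2):
                    for e in (1, 2):
                        sel = eb[(eb["homolog_id"] == h)
                                 & (eb["endpoint_id"] == e)].sort_values("time_s")
                        if not np.array_equal(sel["time_s"].to_numpy(), bt):
                            ok = False
                            break
                        epos[(h, e)] = sel[["x_um", "y_um", "z_um"]].to_numpy()
                if ok:
                    hh = (2, 1) if swap else (1, 2)
                    a1, b1 = epos[(hh[0], 1)], epos[(hh[0], 2)]
                    a2, b2 = epos[(hh[1], 1)], epos[(hh[1], 2)]
                    l1 = np.linalg.norm(b1 - a1, axis=1)
                    l2 = np.linalg.norm(b2 - a2, axis=1)
                    pts = np.stack([a1, b1, a2, b2], axis=1)  # (n, 4, 3)
                    diff = pts[:, :, None, :] - pts[:, None, :, :]
                    l_biv = np.sqrt((diff**2).sum(-1)).max(axis=(1, 2))

            out.append(pd.DataFrame({
                "oocyte_id": oid, "condition": condition, "bivalent_id": bid,
                "time_s": bt, "theta_labeled_deg": theta,
                "theta_folded_deg": theta_f, "d_eq_um": d_eq, "d_ax_um": d_ax,
                "osc_um": osc, "l_hom1_um": l1, "l_hom2_um": l2,
                "d_ih_um": d_ih, "l_biv_um": l_biv,
            }))
    if not out:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    return pd.concat(out, ignore_index=True)[METRIC_COLUMNS]
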