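"""Spot detection, pole localization, track linking and homolog pairing.

Recovers point tracks from rendered (or real) two-channel stacks:

- chromatin spots by scale-normalized Laplacian-of-Gaussian detection on
  anisotropic voxels, refined by intensity-weighted centroids;
- spindle poles either passed through from user coordinates (with A/B labels
  kept consistent by nearest-previous-position matching) or estimated from
  the tubulin intensity distribution (intensity-weighted PCA; poles at the
  2nd/98th weighted percentiles along the principal axis);
- frame-to-frame linking by greedy mutual-nearest-neighbor assignment with
  gap closing and linear position prediction;
- homolog-to-bivalent pairing by minimum-total-distance perfect matching at
  a user-chosen pre-anaphase pairing time.

All coordinates are physical micrometres; voxel centers sit at
``(i + 0.5) * spacing`` relative to the volume origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

__all__ = [
    "detect_spots",
    "identify_poles",
    "link_tracks",
    "pair_homologs",
    "apply_edits",
    "recover_tracks",
    "match_points",
]


def detect_spots(frame: np.ndarray, spacing, *, min_diameter: float = 0.8,
                 intensity_threshold: float = 0.1, max_diameter: float = 2.5,
                 n_scales: int = 4, origin=(0.0, 0.0, 0.0)) -> pd.DataFrame:
    """Detect blob-like spots in one 3D frame (Z, Y, X).

    Scale-normalized LoG responses are computed at ``n_scales`` diameters
    between ``min_diameter`` and ``max_diameter`` with per-axis sigmas scaled
    by the voxel spacing, local maxima are kept where the response is at
    least ``intensity_threshold`` of the strongest response in the frame, and
    positions are refined by an intensity-weighted centroid in a
    diameter-sized neighborhood.

    Returns a data frame with physical coordinates ``x_um, y_um, z_um``,
    peak ``intensity`` and estimated ``diameter_um``.  A blank frame yields
    an empty table; unknown voxel spacing is an error (anisotropy must be
    accounted for).
    """
    if spacing is None:
        raise ValueError("voxel spacing unknown: anisotropy unaccounted "
                         "(supply (dz, dy, dx))")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive values (dz, dy, dx)")
    if min_diameter < 2 * spacing[1:].max():
        raise ValueError("min_diameter must be at least two pixels")
    img = frame.astype(float)
    rng_val = img.max() - img.min()
    if rng_val == 0:
        return _empty_spots()
    img = (img - np.median(img)) / rng_val

    diameters = np.geomspace(min_diameter, max_diameter, n_scales)
    sigmas_um = diameters / (2.0 * np.sqrt(3.0))
    responses = np.stack([
        -ndimage.gaussian_laplace(img, sigma=s / spacing) * s**2
        for s in sigmas_um
    ])
    rmax = responses.max()
    if rmax <= 0:
        return _empty_spots()

    # peaks per scale with a minimal footprint (peaks at fine scales resolve
    # near-touching spots that merge in coarser responses), then greedy
    # pruning of spatial duplicates across scales, strongest response first
    candidates = []
    for s_i in range(n_scales):
        resp = responses[s_i]
        # noise gate: fine scales amplify shot noise, so each scale must
        # clear a robust floor of its own response map as well as the
        # relative threshold
        mad = np.median(np.abs(resp - np.median(resp)))
        floor = max(intensity_threshold * rmax, 15.0 * mad)
        pks = peak_local_max(resp, footprint=np.ones((3, 3, 3)),
                             threshold_abs=floor,
                             exclude_border=False)
        for pk in pks:
            candidates.append((float(responses[s_i][tuple(pk)]), s_i, pk))
    candidates.sort(key=lambda c: -c[0])
    kept = []
    kept_pos = []
    min_sep = min_diameter / 2.0
    for resp_val, s_i, pk in candidates:
        pos_um = (pk + 0.5) * spacing
        if all(np.linalg.norm(pos_um - q) >= min_sep for q in kept_pos):
            kept.append((resp_val, s_i, pk))
            kept_pos.append(pos_um)
    # drop "parent" blobs: a coarse response whose radius encloses two or
    # more finer detections is the unresolved union of those spots
    if len(kept) > 1:
        pos_arr = np.asarray(kept_pos)
        radii = np.array([diameters[s_i] / 2.0 for _, s_i, _ in kept])
        dists = np.linalg.norm(pos_arr[:, None] - pos_arr[None, :], axis=-1)
        children = (dists < radii[:, None]).sum(axis=1) - 1
        kept = [k for k, n in zip(kept, children) if n < 2]

    rows = []
    raw = frame.astype(float)
    bg = np.median(raw)
    for resp_val, s_i, pk in kept:
        diam = diameters[s_i]
        # quarter-diameter window: symmetric around an isolated blob but
        # short enough not to bleed into a near-touching neighbour
        half = np.maximum((diam / 4.0) / spacing, 1).astype(int)
        lo = np.maximum(pk - half, 0)
        hi = np.minimum(pk + half + 1, frame.shape)
        win = np.clip(raw[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] - bg, 0, None)
        if win.sum() == 0:
            center_vox = pk.astype(float)
        else:
            grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                                indexing="ij")
            center_vox = np.array([
                (g * win).sum() / win.sum() for g in grids])
        pos = (center_vox + 0.5) * spacing + np.asarray(origin, dtype=float)
        rows.append(dict(x_um=pos[2], y_um=pos[1], z_um=pos[0],
                         intensity=float(raw[tuple(pk)]),
                         diameter_um=float(diam),
                         response=float(resp_val / rmax)))
    if not rows:
        return _empty_spots()
    df = pd.DataFrame(rows)
    return df[df["diameter_um"] >= min_diameter].reset_index(drop=True)


def _empty_spots() -> pd.DataFrame:
    return pd.DataFrame(columns=["x_um", "y_um", "z_um", "intensity",
                                 "diameter_um", "response"])


def _weighted_percentile(values, weights, q):
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return np.interp(q / 100.0, cdf, v)


def identify_poles(tubulin: np.ndarray | None = None, spacing=None, *,
                   points=None, previous=None, origin=(0.0, 0.0, 0.0),
                   anisotropy_min: float = 1.5,
                   weight_percentile: float = 99.0):
    """Locate the two spindle poles in one frame.

    With ``points`` (two xyz positions in um) the coordinates pass through
    unchanged; labels A/B are kept consistent with ``previous`` (the prior
    frame's (pole_a, pole_b)) by nearest-position matching.  Otherwise poles
    are estimated from the tubulin channel: intensity-weighted PCA of voxel
    positions, poles at the 2nd/98th weighted percentiles of the projection
    onto the principal axis.  A near-isotropic intensity distribution (first
    to second eigenvalue ratio below ``anisotropy_min``) raises
    ``ValueError("no spindle axis")``.

    Returns ``(pole_a, pole_b)`` as xyz arrays in um.
    """
    if points is not None:
        pts = [np.asarray(p, dtype=float) for p in points]
        if len(pts) != 2:
            raise ValueError("exactly two pole positions required")
        a, b = pts
    else:
        if tubulin is None or spacing is None:
            raise ValueError("tubulin frame and spacing (or explicit points) "
                             "required")
        spacing = np.asarray(spacing, dtype=float)
        img = tubulin.astype(float)
        # the spindle occupies a small volume fraction: threshold high so
        # diffuse background carries no weight
        w = np.clip(img - np.percentile(img, weight_percentile), 0, None)
        if w.sum() == 0:
            raise ValueError("no spindle axis: empty tubulin signal")
        idx = np.nonzero(w)
        wts = w[idx]
        # voxel centers, physical zyx
        pos = (np.stack(idx, axis=1) + 0.5) * spacing + np.asarray(origin)
        mean = (pos * wts[:, None]).sum(0) / wts.sum()
        d = pos - mean
        cov = (d * wts[:, None]).T @ d / wts.sum()
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] < anisotropy_min * max(evals[-2], 1e-12):
            raise ValueError("no spindle axis: isotropic intensity "
                             "distribution")
        axis = evecs[:, -1]
        proj = d @ axis
        qlo = _weighted_percentile(proj, wts, 2.0)
        qhi = _weighted_percentile(proj, wts, 98.0)
        a_zyx = mean + qlo * axis
        b_zyx = mean + qhi * axis
        a = a_zyx[::-1].copy()  # return xyz
        b = b_zyx[::-1].copy()
    if previous is not None:
        pa, pb = (np.asarray(p, dtype=float) for p in previous)
        keep = (np.linalg.norm(a - pa) + np.linalg.norm(b - pb))
        swap = (np.linalg.norm(a - pb) + np.linalg.norm(b - pa))
        if swap < keep:
            a, b = b, a
    return a, b


def _mutual_nn_pairs(d: np.ndarray, max_disp: float):
    """Greedy mutual-nearest-neighbor pairs from a distance matrix."""
    pairs = []
    if d.size == 0:
        return pairs
    d = d.copy()
    d[d > max_disp] = np.inf
    alive_r = np.ones(d.shape[0], dtype=bool)
    alive_c = np.ones(d.shape[1], dtype=bool)
    while True:
        found = False
        nn_c = np.where(alive_r[:, None] & alive_c[None, :], d, np.inf)
        if not np.isfinite(nn_c).any():
            break
        for i in np.nonzero(alive_r)[0]:
            row = nn_c[i]
            j = int(np.argmin(row))
            if not np.isfinite(row[j]):
                continue
            if int(np.argmin(nn_c[:, j])) == i:
                pairs.append((i, j))
                alive_r[i] = False
                alive_c[j] = False
                found = True
        if not found:
            break
    return pairs


def link_tracks(spotsets, *, max_disp: float = 1.0,
                max_gap: int = 2) -> pd.DataFrame:
    """Link per-frame spot sets into tracks.

    ``spotsets`` is a sequence of ``(time_s, positions)`` with positions an
    (n, 3) array of xyz um (or a spot table with x_um/y_um/z_um columns).
    Greedy mutual-nearest-neighbor assignment under ``max_disp`` per frame;
    a track missing from up to ``max_gap`` consecutive frames is carried
    with a linearly predicted position and closed when the spot reappears
    (interpolated rows are flagged ``gap=True``); unlinked spots start new
    tracks.

    Returns a long table ``(track_id, time_s, x_um, y_um, z_um, gap)``.
    """
    prepared = []
    for t, pos in spotsets:
        if isinstance(pos, pd.DataFrame):
            pos = pos[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        else:
            pos = np.asarray(pos, dtype=float).reshape(-1, 3)
        prepared.append((float(t), pos))
    if len(prepared) < 2:
        raise ValueError("linking requires at least two frames")

    next_id = 0
    active = []   # dicts: id, samples [(t, pos, gap)], last_pos, vel, missed
    finished = []

    def new_track(t, p):
        nonlocal next_id
        tr = dict(id=next_id, samples=[(t, p, False)], last_pos=p,
                  prev_pos=None, last_t=t, prev_t=None, missed=0)
        next_id += 1
        active.append(tr)

    t0, pos0 = prepared[0]
    for p in pos0:
        new_track(t0, p)

    for t, pos in prepared[1:]:
        preds = []
        for tr in active:
            if tr["prev_pos"] is not None:
                vel = ((tr["last_pos"] - tr["prev_pos"])
                       / (tr["last_t"] - tr["prev_t"]))
            else:
                vel = 0.0
            preds.append(tr["last_pos"] + vel * (t - tr["last_t"]))
        preds = np.asarray(preds).reshape(-1, 3)
        lasts = np.asarray([tr["last_pos"] for tr in active]).reshape(-1, 3)
        if len(preds) and len(pos):
            # prediction helps directed anaphase motion; the raw last
            # position guards against overshoot on direction changes
            d_pred = np.linalg.norm(preds[:, None, :] - pos[None, :, :],
                                    axis=-1)
            d_last = np.linalg.norm(lasts[:, None, :] - pos[None, :, :],
                                    axis=-1)
            d = np.minimum(d_pred, d_last)
        else:
            d = np.empty((len(preds), len(pos)))
        # allowed displacement grows with the number of skipped frames
        if len(preds) and len(pos):
            allowed = max_disp * (1 + np.array(
                [tr["missed"] for tr in active]))
            d = np.where(d <= allowed[:, None], d, np.inf)
        pairs = _mutual_nn_pairs(d, np.inf)
        # leftovers (chained-preference deadlocks): optimal assignment on
        # the remaining admissible pairs
        if d.size:
            rem_r = sorted(set(range(d.shape[0])) - {i for i, _ in pairs})
            rem_c = sorted(set(range(d.shape[1])) - {j for _, j in pairs})
            if rem_r and rem_c:
                sub = d[np.ix_(rem_r, rem_c)]
                if np.isfinite(sub).any():
                    cost = np.where(np.isfinite(sub), sub, 1e6)
                    ri, ci = linear_sum_assignment(cost)
                    pairs.extend(
                        (rem_r[i], rem_c[j]) for i, j in zip(ri, ci)
                        if np.isfinite(sub[i, j]))
        matched_r = {i for i, _ in pairs}
        matched_c = {j for _, j in pairs}
        for i, j in pairs:
            tr = active[i]
            if tr["missed"]:
                # close the gap with linear interpolation
                tgap = np.linspace(tr["last_t"], t, tr["missed"] + 2)[1:-1]
                for tg in tgap:
                    frac = (tg - tr["last_t"]) / (t - tr["last_t"])
                    pg = tr["last_pos"] + frac * (pos[j] - tr["last_pos"])
                    tr["samples"].append((float(tg), pg, True))
                tr["missed"] = 0
            tr["samples"].append((t, pos[j], False))
            tr["prev_pos"], tr["prev_t"] = tr["last_pos"], tr["last_t"]
            tr["last_pos"], tr["last_t"] = pos[j], t
        survivors = []
        for i, tr in enumerate(active):
            if i in matched_r:
                survivors.append(tr)
            else:
                tr["missed"] += 1
                if tr["missed"] > max_gap:
                    finished.append(tr)
                else:
                    survivors.append(tr)
        active = survivors
        for j in range(len(pos)):
            if j not in matched_c:
                new_track(t, pos[j])
    finished.extend(active)

    rows = []
    for tr in finished:
        for t, p, gap in tr["samples"]:
            rows.append(dict(track_id=tr["id"], time_s=t, x_um=p[0],
                             y_um=p[1], z_um=p[2], gap=gap))
    return (pd.DataFrame(rows)
            .sort_values(["track_id", "time_s"]).reset_index(drop=True))


def pair_homologs(homolog_tracks: pd.DataFrame, pole_a, *,
                  pairing_time: float) -> pd.DataFrame:
    """Assign 12 homolog tracks to 6 bivalents at a pre-anaphase time.

    Minimum-total-distance perfect matching on the pairwise distances of the
    homolog positions at ``pairing_time``; pairs are labeled bivalent 1..6 by
    increasing distance of the pair centroid to pole A, and within a pair
    homolog 1 is the one nearer pole A.  Exactly 12 tracks must be alive at
    ``pairing_time``.

    Returns a table ``(track_id, bivalent_id, homolog_id)``.
    """
    at_t = homolog_tracks[np.isclose(homolog_tracks["time_s"], pairing_time)]
    if len(at_t) != 12:
        counts = (homolog_tracks.groupby("time_s")["track_id"].nunique())
        raise ValueError(
            f"expected exactly 12 homolog tracks at t={pairing_time:g} s, "
            f"found {len(at_t)}; tracks per frame: "
            f"{counts.to_dict()}")
    ids = at_t["track_id"].to_numpy()
    pos = at_t[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    g = nx.Graph()
    for i in range(12):
        for j in range(i + 1, 12):
            g.add_edge(i, j, weight=d[i, j])
    matching = nx.min_weight_matching(g)
    pole_a = np.asarray(pole_a, dtype=float)
    pairs = sorted(
        (tuple(sorted(p)) for p in matching),
        key=lambda p: np.linalg.norm((pos[p[0]] + pos[p[1]]) / 2 - pole_a))
    rows = []
    for b, (i, j) in enumerate(pairs, start=1):
        if (np.linalg.norm(pos[j] - pole_a)
                < np.linalg.norm(pos[i] - pole_a)):
            i, j = j, i
        rows.append(dict(track_id=ids[i], bivalent_id=b, homolog_id=1))
        rows.append(dict(track_id=ids[j], bivalent_id=b, homolog_id=2))
    return pd.DataFrame(rows)


def apply_edits(tracks: pd.DataFrame, edits: pd.DataFrame) -> pd.DataFrame:
    """Apply a manual-curation edits table after linking.

    ``edits`` rows: ``action`` in {``remap``, ``delete``};
    remap: ``track_id`` -> ``new_track_id`` (merging fragments);
    delete: drop the sample of ``track_id`` at ``time_s``.
    """
    out = tracks.copy()
    for _, e in edits.iterrows():
        if e["action"] == "remap":
            out.loc[out["track_id"] == e["track_id"], "track_id"] = \
                e["new_track_id"]
        elif e["action"] == "delete":
            out = out[~((out["track_id"] == e["track_id"])
                        & np.isclose(out["time_s"], e["time_s"]))]
        else:
            raise ValueError(f"unknown edit action {e['action']!r}")
    return out.reset_index(drop=True)


def match_points(truth: np.ndarray, detected: np.ndarray, tol: float):
    """Optimal one-to-one matching of detected points to ground truth.

    Returns ``(pairs, recall, precision)`` where pairs are (truth_index,
    detected_index) within ``tol``.
    """
    truth = np.asarray(truth, dtype=float).reshape(-1, 3)
    detected = np.asarray(detected, dtype=float).reshape(-1, 3)
    if len(truth) == 0 or len(detected) == 0:
        return [], 0.0, 0.0
    d = np.linalg.norm(truth[:, None] - detected[None, :], axis=-1)
    cost = np.where(d <= tol, d, 1e6)
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= tol]
    recall = len(pairs) / len(truth)
    precision = len(pairs) / len(detected)
    return pairs, recall, precision


def recover_tracks(stack: np.ndarray, geometry, origin, *,
                   min_diameter: float = 0.8, intensity_threshold: float = 0.15,
                   max_disp: float = 1.0, max_gap: int = 4,
                   pairing_time: float | None = None,
                   oocyte_id=1, condition: str = "") -> pd.DataFrame:
    """Full image-to-tracks pipeline for one rendered oocyte stack.

    Detects chromatin spots and tubulin poles per frame, links spots into
    tracks, keeps tracks spanning the pairing time, pairs homologs into
    bivalents, and returns a track table in the standard schema (homolog and
    pole rows; no endpoints).  The pipeline links with a longer gap
    tolerance than the bare linker default: chromosomes in the crowded
    metaphase plate can be occluded by a neighbour for several frames.
    """
    from .synthdata import TRACK_COLUMNS  # schema only

    times = geometry.times_s
    spacing = (geometry.dz, geometry.dxy, geometry.dxy)
    origin = np.asarray(origin, dtype=float)

    spotsets = []
    pole_rows = []
    prev = None
    for i, t in enumerate(times):
        spots = detect_spots(stack[i, 0], spacing,
                             min_diameter=min_diameter,
                             intensity_threshold=intensity_threshold,
                             origin=origin)
        spotsets.append((t, spots))
        pa, pb = identify_poles(stack[i, 1], spacing, origin=origin,
                                previous=prev)
        prev = (pa, pb)
        pole_rows.append(dict(time_s=t, pole_id="A",
                              x_um=pa[0], y_um=pa[1], z_um=pa[2]))
        pole_rows.append(dict(time_s=t, pole_id="B",
                              x_um=pb[0], y_um=pb[1], z_um=pb[2]))
    linked = link_tracks(spotsets, max_disp=max_disp, max_gap=max_gap)
    if pairing_time is None:
        # earliest frame where exactly 12 tracks are alive: bivalents are
        # well spread in early prometaphase, before congression
        per_frame = linked.groupby("time_s")["track_id"].nunique()
        full = per_frame[per_frame == 12]
        if full.empty:
            raise ValueError(
                "no frame with exactly 12 homolog tracks; tracks per "
                f"frame: {per_frame.to_dict()}")
        pairing_time = float(full.index[0])
    alive = linked[np.isclose(linked["time_s"], pairing_time)]["track_id"]
    linked = linked[linked["track_id"].isin(alive)]
    pa0 = next(r for r in pole_rows
               if r["pole_id"] == "A"
               and np.isclose(r["time_s"], pairing_time))
    assignment = pair_homologs(linked, (pa0["x_um"], pa0["y_um"],
                                        pa0["z_um"]),
                               pairing_time=pairing_time)
    hom = linked.merge(assignment, on="track_id", how="inner")

    hom_rows = pd.DataFrame({
        "oocyte_id": oocyte_id, "condition": condition,
        "time_s": hom["time_s"], "object_class": "homolog",
        "pole_id": "NA", "bivalent_id": hom["bivalent_id"],
        "homolog_id": hom["homolog_id"], "endpoint_id": np.nan,
        "x_um": hom["x_um"], "y_um": hom["y_um"], "z_um": hom["z_um"],
    })
    pole_df = pd.DataFrame(pole_rows)
    pole_out = pd.DataFrame({
        "oocyte_id": oocyte_id, "condition": condition,
        "time_s": pole_df["time_s"], "object_class": "pole",
        "pole_id": pole_df["pole_id"], "bivalent_id": np.nan,
        "homolog_id": np.nan, "endpoint_id": np.nan,
        "x_um": pole_df["x_um"], "y_um": pole_df["y_um"],
        "z_um": pole_df["z_um"],
    })
    out = pd.concat([pole_out, hom_rows], ignore_index=True)
    for col in ("bivalent_id", "homolog_id", "endpoint_id"):
        out[col] = out[col].astype("Int64")
    return out[TRACK_COLUMNS].sort_values(
        ["time_s", "object_class"]).reset_index(drop=True)
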