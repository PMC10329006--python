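"""Tabular/imaging I/O, cohort manifests, and the color-coded proportion plot.

Exchange formats are deliberately boring: CSV for all tables (tracks,
metrics, flags, fates), YAML for configuration and image sidecars, TIFF
(T x C x Z x Y x X) for rendered stacks.  Track tables round-trip losslessly
to 1e-6 um and unknown columns survive.
"""

from __future__ import annotations

import hashlib
import logging

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthdata import TRACK_COLUMNS, AcquisitionGeometry

log = logging.getLogger("meiotrack")

__all__ = [
    "read_tracks", "write_tracks", "read_sidecar", "write_sidecar",
    "write_stack", "read_stack", "read_manifest", "plot_colorcoded",
]

_ID_COLS = ["oocyte_id", "object_class", "pole_id", "bivalent_id",
            "homolog_id", "endpoint_id"]


def write_tracks(tracks: pd.DataFrame, path) -> None:
    """Write a track table as CSV (coordinates to 1e-6 um)."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    tracks.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path) -> pd.DataFrame:
    """Read a track table, validating schema and per-object time ordering."""
    df = pd.read_csv(path)
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    for col in ("bivalent_id", "homolog_id", "endpoint_id"):
        df[col] = df[col].astype("Int64")
    df["pole_id"] = df["pole_id"].fillna("NA")
    bad = (
        df.fillna({c: -1 for c in ("bivalent_id", "homolog_id",
                                   "endpoint_id")})
        .groupby(_ID_COLS)["time_s"]
        .apply(lambda s: bool((s.diff().dropna() <= 0).any()))
    )
    if bad.any():
        key = bad[bad].index[0]
        raise ValueError(f"non-monotone time for object {key}")
    return df


def write_sidecar(path, geometry: AcquisitionGeometry, *, origin=None,
                  extra: dict | None = None) -> None:
    """Write the YAML sidecar holding spacings, dt, channels, onset index."""
    d = geometry.to_dict()
    if origin is not None:
        d["origin_um"] = [float(v) for v in origin]
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_sidecar(path):
    """Read a sidecar; returns ``(AcquisitionGeometry, full dict)``."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    geo_keys = {f.name for f in
                __import__("dataclasses").fields(AcquisitionGeometry)}
    geom = AcquisitionGeometry.from_dict(
        {k: v for k, v in d.items() if k in geo_keys})
    return geom, d


def write_stack(path, stack: np.ndarray) -> None:
    """Write a T x C x Z x Y x X stack as multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     metadata={"axes": "TCZYX"})


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 5:
        raise ValueError(f"expected a T x C x Z x Y x X stack, got shape "
                         f"{arr.shape}")
    return arr


def read_manifest(path, *, require_control: bool = False) -> pd.DataFrame:
    """Read a cohort manifest CSV (condition, path, role[, onset_s])."""
    df = pd.read_csv(path)
    for col in ("condition", "path", "role"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col}")
    if not df["role"].isin(["control", "test"]).all():
        raise ValueError("manifest roles must be 'control' or 'test'")
    if require_control:
        n_ctrl = df.loc[df["role"] == "control", "condition"].nunique()
        if n_ctrl != 1:
            raise ValueError(
                "exactly one control condition must be designated for "
                f"calibration (found {n_ctrl})")
    return df


def plot_colorcoded(metrics: pd.DataFrame, metric: str, threshold: float,
                    path, *, time_bin: float | None = None,
                    cmap: str = "viridis") -> str:
    """Scatter of a per-bivalent metric vs time, color-coded by cohort state.

    Each dot is one bivalent at one time point; its color encodes the cohort
    proportion of bivalents at or below ``threshold`` in that time bin
    (colormap limits pinned to 0..1); the threshold is drawn as a horizontal
    line.  Output is deterministic for fixed input; returns the SHA-256 of
    the written file.
    """
    if metrics.empty:
        raise ValueError("empty metrics table")
    if metric not in metrics.columns:
        raise ValueError(f"unknown metric column {metric!r}")
    d = metrics.dropna(subset=[metric]).copy()
    if d.empty:
        raise ValueError("no defined values to plot")
    if time_bin:
        d["_bin"] = np.round(d["time_s"] / time_bin) * time_bin
    else:
        d["_bin"] = d["time_s"]
    prop = (d.assign(below=d[metric] <= threshold)
            .groupby("_bin")["below"].mean())
    colors = d["_bin"].map(prop).to_numpy()

    matplotlib.rcParams["svg.hashsalt"] = "meiotrack"
    fig, ax = plt.subplots(figsize=(6, 4))
    sc = ax.scatter(d["time_s"], d[metric], c=colors, cmap=cmap,
                    vmin=0.0, vmax=1.0, s=14, linewidths=0)
    ax.axhline(threshold, color="crimson", lw=1, ls="--")
    ax.set_xlabel("time relative to anaphase onset (s)")
    ax.set_ylabel(metric)
    fig.colorbar(sc, ax=ax, label="proportion below threshold")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None}
                if str(path).endswith(".svg") else None)
    plt.close(fig)
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()
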