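"""Threshold calibration, per-timepoint state and anaphase-fate classification.

Calibration follows the control-cohort recipe: the orientation threshold is
the mean over control oocytes of the per-oocyte *maximum* folded angle at the
anaphase-onset frame; the congression and compaction thresholds are the means
of the per-oocyte maxima of the equator and axis distances over the metaphase
window.  Published reference values for unperturbed oocytes are 22.5 degrees,
0.5 um and 1.6 um respectively; these are also the defaults when no control
cohort is supplied.

Fate calling works on the signed equator coordinate ``s(t) = (pos - m) . u``
of each homolog.  At the fate-call time a bivalent whose homologs sit on
opposite sides with ``|s| >= d_seg`` segregated normally; same side means
co-segregation.  A homolog is *lagging* when it is still within ``d_lag`` of
the equator at the mid-anaphase checkpoint while at least half of all
homologs in the oocyte have cleared ``d_seg``; lagging homologs resolve to
``lagging_correct`` (opposite-side final) or ``lagging_missegregated``
(same-side final, or still near the equator at the end).  An oocyte is
euploid iff no bivalent co-segregated or mis-segregated.

The angle-fate association fits a logistic regression of the mis-segregation
indicator on the folded angle at onset (maximum likelihood), and assesses
significance with a seeded label-permutation test on the logistic score
statistic — exactly valid at any sample size and monotone-equivalent to
testing the slope at zero.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ClassificationConfig",
    "calibrate_thresholds",
    "classify_timepoints",
    "classify_fates",
    "angle_fate_association",
    "detect_onset",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and times for state and fate classification.

    All comparisons against thresholds are inclusive (``<=``).  Times are in
    seconds relative to anaphase onset.
    """

    theta_max_deg: float = 22.5
    d_eq_max_um: float = 0.5
    d_ax_max_um: float = 1.6
    t_fate_check_s: float = 60.0
    t_fate_end_s: float = 120.0
    d_seg_um: float = 2.0
    d_lag_um: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("theta", "d_")) and v <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not self.t_fate_check_s < self.t_fate_end_s:
            raise ValueError("t_fate_check_s must precede t_fate_end_s")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationConfig":
        return cls(**d)


def calibrate_thresholds(control_metrics: pd.DataFrame, *,
                         onset_s: float = 0.0,
                         metaphase_window: tuple[float, float] = (-100.0, 0.0),
                         base: ClassificationConfig | None = None,
                         ) -> ClassificationConfig:
    """Calibrate the three state thresholds on a control cohort.

    ``theta_max`` = mean over oocytes of the per-oocyte maximum folded angle
    at the onset frame; ``d_eq_max`` / ``d_ax_max`` = means of the per-oocyte
    maxima over the metaphase window.  Fields not calibrated keep their
    values from ``base`` (or the defaults).
    """
    base = base or ClassificationConfig()
    m = control_metrics
    at_onset = m[np.isclose(m["time_s"], onset_s)]
    if at_onset.empty:
        raise ValueError("no metrics at the anaphase-onset frame; "
                         "is onset annotated (time_s == 0)?")
    theta_max = float(
        at_onset.groupby("oocyte_id")["theta_folded_deg"].max().mean())
    lo, hi = metaphase_window
    win = m[(m["time_s"] >= lo) & (m["time_s"] <= hi)]
    if win.empty:
        raise ValueError("no metrics inside the metaphase window")
    d_eq_max = float(win.groupby("oocyte_id")["d_eq_um"].max().mean())
    d_ax_max = float(win.groupby("oocyte_id")["d_ax_um"].max().mean())
    return dataclasses.replace(base, theta_max_deg=theta_max,
                               d_eq_max_um=d_eq_max, d_ax_max_um=d_ax_max)


def classify_timepoints(metrics: pd.DataFrame,
                        config: ClassificationConfig | None = None):
    """Per-timepoint orientation/congression/compaction flags and proportions.

    Returns ``(flags, proportions)``: ``flags`` is ``metrics`` with boolean
    ``oriented``, ``congressed``, ``compacted`` columns (nullable — NaN
    metrics give missing flags); ``proportions`` aggregates per time point
    the fraction of defined bivalents at or below each threshold, with the
    counts used in each denominator.
    """
    config = config or ClassificationConfig()
    flags = metrics.copy()
    for col, thr, name in [
        ("theta_folded_deg", config.theta_max_deg, "oriented"),
        ("d_eq_um", config.d_eq_max_um, "congressed"),
        ("d_ax_um", config.d_ax_max_um, "compacted"),
    ]:
        vals = flags[col]
        flag = pd.array(vals <= thr, dtype="boolean")
        flag[vals.isna().to_numpy()] = pd.NA
        flags[name] = flag

    rows = []
    for t, g in flags.groupby("time_s", sort=True):
        row = {"time_s": t}
        for name in ("oriented", "congressed", "compacted"):
            defined = g[name].dropna()
            row[f"n_{name}_defined"] = len(defined)
            row[f"prop_{name}"] = (float(defined.mean())
                                   if len(defined) else np.nan)
        rows.append(row)
    return flags, pd.DataFrame(rows)


def _signed_coords(odf: pd.DataFrame, t: float, *, onset_s: float = 0.0):
    """Signed equator coordinate of every homolog of one oocyte at time t.

    A homolog missing at ``t`` (e.g. its track ended inside the crowded
    polar chromosome mass) contributes its last observation after onset —
    a segregated chromosome stays on its side of the spindle.
    """
    poles = odf[(odf["object_class"] == "pole")
                & np.isclose(odf["time_s"], t)]
    pa = poles[poles["pole_id"] == "A"][["x_um", "y_um", "z_um"]].to_numpy()
    pb = poles[poles["pole_id"] == "B"][["x_um", "y_um", "z_um"]].to_numpy()
    if len(pa) != 1 or len(pb) != 1:
        return None
    axis = pb[0] - pa[0]
    u = axis / np.linalg.norm(axis)
    m = (pa[0] + pb[0]) / 2.0
    homs = odf[(odf["object_class"] == "homolog")
               & (odf["time_s"] >= onset_s)
               & (odf["time_s"] <= t + 1e-6)]
    s = {}
    for key, g in homs.groupby(["bivalent_id", "homolog_id"]):
        r = g.loc[g["time_s"].idxmax()]
        s[(int(key[0]), int(key[1]))] = float(
            (np.array([r.x_um, r.y_um, r.z_um]) - m) @ u)
    return s


def classify_fates(tracks: pd.DataFrame,
                   config: ClassificationConfig | None = None, *,
                   onset_s: float = 0.0,
                   metrics: pd.DataFrame | None = None):
    """Call the anaphase fate of every bivalent and the ploidy of every oocyte.

    Requires tracks covering onset through ``t_fate_end``; bivalents whose
    tracks end earlier are reported as ``uncallable`` with a warning and
    excluded from ploidy.  If ``metrics`` is given (or computable), the
    folded angle at onset is attached as ``theta_onset_deg``.

    Returns ``(fates, ploidy)`` data frames.
    """
    config = config or ClassificationConfig()
    t_check = onset_s + config.t_fate_check_s
    t_end = onset_s + config.t_fate_end_s

    theta_onset = {}
    if metrics is None:
        try:
            from .geometry import compute_metrics
            metrics = compute_metrics(tracks)
        except Exception:  # endpoint-less or partial tables are fine
            metrics = None
    if metrics is not None:
        at0 = metrics[np.isclose(metrics["time_s"], onset_s)]
        for _, r in at0.iterrows():
            theta_onset[(r.oocyte_id, int(r.bivalent_id))] = float(
                r.theta_folded_deg)

    fate_rows = []
    for oid, odf in tracks.groupby("oocyte_id", sort=True):
        tmax = odf["time_s"].max()
        s_check = _signed_coords(odf, _nearest_time(odf, t_check),
                                 onset_s=onset_s)
        s_end = _signed_coords(odf, _nearest_time(odf, t_end),
                               onset_s=onset_s)
        bivs = sorted(odf.loc[odf["object_class"] == "homolog",
                              "bivalent_id"].dropna().unique())
        if tmax < t_end or s_check is None or s_end is None:
            warnings.warn(
                f"oocyte {oid}: tracks end at {tmax:g} s before fate-call "
                f"time {t_end:g} s; fates uncallable")
            for bid in bivs:
                fate_rows.append(dict(oocyte_id=oid, bivalent_id=int(bid),
                                      fate="uncallable",
                                      theta_onset_deg=theta_onset.get(
                                          (oid, int(bid)), np.nan)))
            continue

        n_hom = len(s_check)
        n_cleared = sum(abs(v) >= config.d_seg_um for v in s_check.values())
        majority_cleared = n_cleared >= n_hom / 2.0

        for bid in bivs:
            bid = int(bid)
            keys = [(bid, 1), (bid, 2)]
            if not all(k in s_check and k in s_end for k in keys):
                fate_rows.append(dict(oocyte_id=oid, bivalent_id=bid,
                                      fate="uncallable",
                                      theta_onset_deg=theta_onset.get(
                                          (oid, bid), np.nan)))
                continue
            sc = np.array([s_check[k] for k in keys])
            se = np.array([s_end[k] for k in keys])
            lag = (np.abs(sc) < config.d_lag_um) & majority_cleared
            opposite = se[0] * se[1] < 0
            both_far = np.all(np.abs(se) >= config.d_seg_um)
            if lag.any():
                still_near = np.any(np.abs(se[lag]) < config.d_lag_um)
                if still_near or not opposite:
                    fate = "lagging_missegregated"
                else:
                    fate = "lagging_correct"
            elif opposite and both_far:
                fate = "normal"
            elif not opposite and both_far:
                fate = "co_segregating"
            else:
                # residual: judge by final sides
                fate = "normal" if opposite else "co_segregating"
            fate_rows.append(dict(oocyte_id=oid, bivalent_id=bid, fate=fate,
                                  theta_onset_deg=theta_onset.get(
                                      (oid, bid), np.nan)))

    fates = pd.DataFrame(fate_rows)
    callable_ = fates[fates["fate"] != "uncallable"]
    bad = callable_["fate"].isin(["co_segregating", "lagging_missegregated"])
    ploidy = (
        callable_.assign(bad=bad)
        .groupby("oocyte_id", as_index=False)["bad"].any()
        .assign(ploidy=lambda d: np.where(d["bad"], "aneuploid", "euploid"))
        .drop(columns="bad")
    )
    return fates, ploidy


def _nearest_time(odf: pd.DataFrame, t: float) -> float:
    times = odf["time_s"].unique()
    return float(times[np.argmin(np.abs(times - t))])


MIS_SEGREGATED = ("co_segregating", "lagging_missegregated")


def angle_fate_association(fates: pd.DataFrame, *,
                           metrics: pd.DataFrame | None = None,
                           n_permutations: int = 10_000,
                           seed: int = 0) -> dict:
    """Quantify the link between the angle at onset and mis-segregation.

    Fits ``P(mis-segregated) = logistic(b0 + b1 * theta_onset)`` by maximum
    likelihood and computes a label-permutation p-value on the logistic score
    statistic.  With complete separation the slope is reported as +/-inf
    (``separation`` flag set); the permutation p-value remains valid.  If
    fewer than two fate categories are present the association is undefined
    (``defined=False``).

    When ``metrics`` is given, also returns the mean +/- SEM folded-angle
    time course per fate group (``group_timecourses``).
    """
    d = fates[fates["fate"] != "uncallable"].dropna(subset=["theta_onset_deg"])
    y = d["fate"].isin(MIS_SEGREGATED).to_numpy(dtype=float)
    theta = d["theta_onset_deg"].to_numpy(dtype=float)
    result: dict = {"n": int(len(d)), "n_missegregated": int(y.sum())}

    if metrics is not None and len(d):
        merged = metrics.merge(
            d[["oocyte_id", "bivalent_id", "fate"]],
            on=["oocyte_id", "bivalent_id"], how="inner")
        tc = (merged.groupby(["fate", "time_s"])["theta_folded_deg"]
              .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                   n="count").reset_index())
        result["group_timecourses"] = tc

    if len(np.unique(y)) < 2:
        result.update(defined=False, slope=None, intercept=None,
                      p_value=None, separation=False)
        return result
    result["defined"] = True

    # complete separation: all mis-segregated angles beyond all correct ones
    hi, lo = theta[y == 1], theta[y == 0]
    separated = hi.min() > lo.max() or hi.max() < lo.min()
    if separated:
        result.update(separation=True,
                      slope=float(np.inf if hi.min() > lo.max() else -np.inf),
                      intercept=float("nan"))
    else:
        X = sm.add_constant(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        result.update(separation=False, intercept=float(fit.params[0]),
                      slope=float(fit.params[1]))

    # permutation test on the score statistic T = sum(theta * (y - ybar))
    rng = np.random.default_rng(seed)
    t_obs = float(theta @ (y - y.mean()))
    perm = np.tile(y, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    t_perm = perm @ theta - y.mean() * theta.sum()
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs))) / (n_permutations + 1.0)
    result["p_value"] = float(p)
    result["score_statistic"] = t_obs
    return result


def detect_onset(metrics: pd.DataFrame, *, k: float = 5.0) -> pd.DataFrame:
    """Detect anaphase onset per oocyte from the inter-homolog distance jump.

    Onset is the first frame whose preceding oocyte-median inter-homolog
    distance increment exceeds ``median + k * MAD`` of the increments.
    Raises ``ValueError`` when no qualifying jump exists
    ("onset not detected; supply --onset").
    """
    rows = []
    for oid, odf in metrics.groupby("oocyte_id", sort=True):
        med = (odf.groupby("time_s")["d_ih_um"].median()
               .sort_index())
        times = med.index.to_numpy()
        inc = np.diff(med.to_numpy())
        if len(inc) == 0:
            raise ValueError(
                f"oocyte {oid}: onset not detected; supply --onset")
        center = np.median(inc)
        mad = np.median(np.abs(inc - center))
        above = inc > center + k * mad
        if not above.any():
            raise ValueError(
                f"oocyte {oid}: onset not detected; supply --onset")
        rows.append(dict(oocyte_id=oid,
                         onset_time_s=float(times[int(np.argmax(above)) + 1])))
    return pd.DataFrame(rows)


def rezero_times(table: pd.DataFrame, onsets: pd.DataFrame) -> pd.DataFrame:
    """Shift ``time_s`` so each oocyte's detected onset becomes zero."""
    shift = onsets.set_index("oocyte_id")["onset_time_s"]
    out = table.copy()
    out["time_s"] = out["time_s"] - out["oocyte_id"].map(shift)
    return out
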