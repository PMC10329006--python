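"""Calibration, state flags, fate calls, association and onset detection."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import meiotrack as mt
from meiotrack.classify import ClassificationConfig, rezero_times


def _metrics(rows):
    base = dict(condition="c", bivalent_id=1, theta_labeled_deg=np.nan,
                theta_folded_deg=np.nan, d_eq_um=np.nan, d_ax_um=np.nan,
                osc_um=np.nan, l_hom1_um=np.nan, l_hom2_um=np.nan,
                d_ih_um=np.nan, l_biv_um=np.nan)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCalibration:
    def test_mean_of_two_oocyte_maxima(self):
        m = _metrics([
            dict(oocyte_id=1, time_s=0.0, theta_folded_deg=20.0,
                 d_eq_um=0.3, d_ax_um=1.0),
            dict(oocyte_id=2, time_s=0.0, theta_folded_deg=25.0,
                 d_eq_um=0.5, d_ax_um=2.0),
        ])
        cfg = mt.calibrate_thresholds(m)
        assert cfg.theta_max_deg == pytest.approx(22.5)
        assert cfg.d_eq_max_um == pytest.approx(0.4)
        assert cfg.d_ax_max_um == pytest.approx(1.5)

    def test_single_oocyte_uses_own_maximum(self):
        m = _metrics([
            dict(oocyte_id=1, time_s=0.0, theta_folded_deg=17.0,
                 d_eq_um=0.2, d_ax_um=1.2),
            dict(oocyte_id=1, bivalent_id=2, time_s=0.0,
                 theta_folded_deg=31.0, d_eq_um=0.6, d_ax_um=0.8),
        ])
        cfg = mt.calibrate_thresholds(m)
        assert cfg.theta_max_deg == pytest.approx(31.0)

    def test_matches_brute_force_and_permutation_invariant(
            self, control_metrics):
        cfg = mt.calibrate_thresholds(control_metrics)
        # brute-force oracle: plain loops over oocytes
        maxima_theta, maxima_deq, maxima_dax = [], [], []
        for oid in control_metrics["oocyte_id"].unique():
            o = control_metrics[control_metrics["oocyte_id"] == oid]
            maxima_theta.append(
                o[np.isclose(o["time_s"], 0.0)]["theta_folded_deg"].max())
            win = o[(o["time_s"] >= -100) & (o["time_s"] <= 0)]
            maxima_deq.append(win["d_eq_um"].max())
            maxima_dax.append(win["d_ax_um"].max())
        assert cfg.theta_max_deg == pytest.approx(np.mean(maxima_theta))
        assert cfg.d_eq_max_um == pytest.approx(np.mean(maxima_deq))
        assert cfg.d_ax_max_um == pytest.approx(np.mean(maxima_dax))
        shuffled = control_metrics.sample(frac=1.0, random_state=0)
        cfg2 = mt.calibrate_thresholds(shuffled)
        assert cfg2 == cfg

    def test_missing_onset_annotation_is_error(self):
        m = _metrics([dict(oocyte_id=1, time_s=-50.0,
                           theta_folded_deg=10.0, d_eq_um=0.1,
                           d_ax_um=0.1)])
        with pytest.raises(ValueError, match="onset"):
            mt.calibrate_thresholds(m)


class TestTimepointClassification:
    def test_threshold_is_inclusive(self):
        m = _metrics([dict(oocyte_id=1, time_s=0.0, theta_folded_deg=22.5,
                           d_eq_um=0.5, d_ax_um=1.6)])
        flags, _ = mt.classify_timepoints(m, ClassificationConfig())
        assert bool(flags["oriented"][0])
        assert bool(flags["congressed"][0])
        assert bool(flags["compacted"][0])

    def test_all_oriented_proportion_one(self):
        rows = [dict(oocyte_id=1, bivalent_id=b, time_s=t,
                     theta_folded_deg=5.0, d_eq_um=0.1, d_ax_um=0.1)
                for b in range(1, 7) for t in (-20.0, -10.0, 0.0)]
        _, props = mt.classify_timepoints(_metrics(rows))
        assert np.allclose(props["prop_oriented"], 1.0)

    def test_mixed_congression_proportion(self):
        rows = ([dict(oocyte_id=1, bivalent_id=b, time_s=0.0, d_eq_um=1.0)
                 for b in range(4)]
                + [dict(oocyte_id=1, bivalent_id=4 + b, time_s=0.0,
                        d_eq_um=0.2) for b in range(6)])
        _, props = mt.classify_timepoints(_metrics(rows))
        assert props["prop_congressed"][0] == pytest.approx(0.6)

    def test_undefined_angles_excluded_from_denominator(self):
        rows = [dict(oocyte_id=1, bivalent_id=1, time_s=0.0,
                     theta_folded_deg=np.nan),
                dict(oocyte_id=1, bivalent_id=2, time_s=0.0,
                     theta_folded_deg=10.0)]
        _, props = mt.classify_timepoints(_metrics(rows))
        assert props["n_oriented_defined"][0] == 1
        assert props["prop_oriented"][0] == pytest.approx(1.0)


def _fate_tracks(homolog_positions):
    """Build a minimal oocyte: fixed poles on x, homologs per (bid, hid)."""
    rows = []
    for t in np.arange(0.0, 130.0, 10.0):
        for pid, x in (("A", -5.0), ("B", 5.0)):
            rows.append(dict(oocyte_id=1, condition="c", time_s=t,
                             object_class="pole", pole_id=pid,
                             bivalent_id=None, homolog_id=None,
                             endpoint_id=None, x_um=x, y_um=0.0, z_um=0.0))
        for (bid, hid), fn in homolog_positions.items():
            rows.append(dict(oocyte_id=1, condition="c", time_s=t,
                             object_class="homolog", pole_id="NA",
                             bivalent_id=bid, homolog_id=hid,
                             endpoint_id=None, x_um=fn(t), y_um=0.0,
                             z_um=0.0))
    return pd.DataFrame(rows)


class TestFateClassification:
    def test_opposite_sides_normal(self):
        tracks = _fate_tracks({(1, 1): lambda t: -3.0, (1, 2): lambda t: 3.0})
        fates, ploidy = mt.classify_fates(tracks, metrics=None)
        assert fates["fate"].tolist() == ["normal"]
        assert ploidy["ploidy"].tolist() == ["euploid"]

    def test_same_side_co_segregating(self):
        tracks = _fate_tracks({(1, 1): lambda t: 2.5, (1, 2): lambda t: 3.5})
        fates, ploidy = mt.classify_fates(tracks, metrics=None)
        assert fates["fate"].tolist() == ["co_segregating"]
        assert ploidy["ploidy"].tolist() == ["aneuploid"]

    def test_lagging_then_correct(self):
        # partner clears early; laggard sits at the equator past the
        # checkpoint, then crosses to the opposite side before the call
        tracks = _fate_tracks({
            (1, 1): lambda t: -3.0,
            (1, 2): lambda t: 0.2 if t <= 70 else 0.08 * (t - 70) * 50 / 50,
            (2, 1): lambda t: -3.0, (2, 2): lambda t: 3.0,
        })
        # laggard reaches +4 um at t=120
        tracks.loc[(tracks["bivalent_id"] == 1)
                   & (tracks["homolog_id"] == 2)
                   & (tracks["time_s"] > 70), "x_um"] = 4.0
        fates, _ = mt.classify_fates(tracks, metrics=None)
        by_bid = fates.set_index("bivalent_id")["fate"]
        assert by_bid[1] == "lagging_correct"
        assert by_bid[2] == "normal"

    def test_simulated_knl1_cohort_accuracy(self, knl1_cohort):
        _, tracks, truth = knl1_cohort
        metrics = mt.compute_metrics(tracks)
        fates, ploidy = mt.classify_fates(tracks, metrics=metrics)
        merged = fates.merge(truth.fates, on=["oocyte_id", "bivalent_id"],
                             suffixes=("_est", "_true"))
        acc = (merged["fate_est"] == merged["fate_true"]).mean()
        assert acc >= 0.9
        pl = ploidy.merge(truth.ploidy, on="oocyte_id",
                          suffixes=("_est", "_true"))
        assert (pl["ploidy_est"] == pl["ploidy_true"]).mean() >= 0.9

    def test_pole_label_swap_leaves_categories(self, knl1_cohort):
        _, tracks, _ = knl1_cohort
        sub = tracks[tracks["oocyte_id"] <= 3]
        swapped = sub.copy()
        is_pole = swapped["object_class"] == "pole"
        swapped.loc[is_pole, "pole_id"] = swapped.loc[is_pole, "pole_id"].map(
            {"A": "B", "B": "A"})
        f0, _ = mt.classify_fates(sub, metrics=None)
        f1, _ = mt.classify_fates(swapped, metrics=None)
        assert f0["fate"].tolist() == f1["fate"].tolist()

    def test_short_tracks_uncallable_with_warning(self, small_geometry):
        cfg = mt.SyntheticCohortConfig(n_oocytes=1, geometry=small_geometry,
                                       seed=1)
        tracks, _ = mt.simulate_cohort(cfg)   # ends at +30 s
        with pytest.warns(UserWarning, match="uncallable"):
            fates, _ = mt.classify_fates(tracks, metrics=None)
        assert (fates["fate"] == "uncallable").all()


class TestAssociation:
    def test_single_category_undefined(self):
        fates = pd.DataFrame({
            "oocyte_id": 1, "bivalent_id": range(1, 7), "fate": "normal",
            "theta_onset_deg": np.linspace(5, 20, 6)})
        out = mt.angle_fate_association(fates)
        assert out["defined"] is False and out["slope"] is None

    def test_complete_separation_flagged(self):
        fates = pd.DataFrame({
            "oocyte_id": 1, "bivalent_id": range(1, 9),
            "fate": ["normal"] * 4 + ["co_segregating"] * 4,
            "theta_onset_deg": [5, 8, 11, 14, 50, 60, 70, 80.0]})
        out = mt.angle_fate_association(fates, seed=1)
        assert out["separation"] is True
        assert out["slope"] == np.inf
        assert 0 < out["p_value"] < 0.05

    def test_slope_sign_recovered_on_positive_link(self, small_geometry):
        geom = mt.AcquisitionGeometry(n_t=17, t_onset_index=16)
        positive = 0
        n = 20
        for s in range(n):
            cfg = mt.SyntheticCohortConfig(
                n_oocytes=8, preset=mt.PRESETS["knl1_null"], geometry=geom,
                seed=300 + s)
            _, truth = mt.simulate_cohort(cfg)
            out = mt.angle_fate_association(truth.fates, seed=s,
                                            n_permutations=2000)
            if out["defined"] and out["slope"] is not None \
                    and out["slope"] > 0:
                positive += 1
        assert positive >= int(0.9 * n)

    def test_type_one_error_controlled(self):
        geom = mt.AcquisitionGeometry(n_t=17, t_onset_index=16)
        null = replace(mt.PRESETS["knl1_null"], name="null", beta1=0.0,
                       beta0=-1.1)
        rej = 0
        n = 40
        for s in range(n):
            cfg = mt.SyntheticCohortConfig(n_oocytes=8, preset=null,
                                           geometry=geom, seed=700 + s)
            _, truth = mt.simulate_cohort(cfg)
            out = mt.angle_fate_association(truth.fates, seed=s,
                                            n_permutations=2000)
            if out["defined"] and out["p_value"] <= 0.05:
                rej += 1
        assert rej / n <= 0.15   # loose guard; the exact level is ~0.05

    def test_group_timecourses_reported(self, knl1_cohort):
        _, tracks, truth = knl1_cohort
        metrics = mt.compute_metrics(tracks)
        out = mt.angle_fate_association(truth.fates, metrics=metrics, seed=2)
        tc = out["group_timecourses"]
        assert {"fate", "time_s", "mean", "sem"}.issubset(tc.columns)
        assert tc["fate"].nunique() >= 2


class TestOnsetDetection:
    def test_step_detected_at_step_frame(self):
        rows = []
        for i, t in enumerate(np.arange(0.0, 300.0, 10.0)):
            for b in range(1, 4):
                rows.append(dict(oocyte_id=1, bivalent_id=b, time_s=t,
                                 d_ih_um=1.0 if i < 20 else 3.0))
        onsets = mt.detect_onset(_metrics(rows))
        assert onsets["onset_time_s"].tolist() == [200.0]

    def test_monotone_ramp_is_error(self):
        rows = [dict(oocyte_id=1, bivalent_id=1, time_s=10.0 * i,
                     d_ih_um=1.0 + 0.05 * i) for i in range(30)]
        with pytest.raises(ValueError, match="onset not detected"):
            mt.detect_onset(_metrics(rows))

    def test_simulated_onset_within_one_frame(self, small_geometry):
        cfg = mt.SyntheticCohortConfig(n_oocytes=20, geometry=small_geometry,
                                       seed=17)
        tracks, _ = mt.simulate_cohort(cfg)
        metrics = mt.compute_metrics(tracks)
        onsets = mt.detect_onset(metrics)
        hits = (np.abs(onsets["onset_time_s"]) <= small_geometry.dt).mean()
        assert hits >= 0.95

    def test_rezero_shifts_times(self):
        m = _metrics([dict(oocyte_id=1, time_s=200.0, d_ih_um=1.0)])
        onsets = pd.DataFrame([dict(oocyte_id=1, onset_time_s=150.0)])
        out = rezero_times(m, onsets)
        assert out["time_s"].tolist() == [50.0]
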