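"""Ground-truthed synthetic cohorts of meiosis-I oocyte chromosome dynamics.

Simulates the objects the downstream analysis tracks — two spindle poles and
six bivalents, each made of two homolog centroids plus two endpoint markers
per homolog — as kinematic point trajectories, and optionally renders them
into two-channel (chromatin, tubulin) image stacks.

The dynamics are deliberately phenomenological: first-order (discrete
Ornstein-Uhlenbeck) relaxation of the bivalent orientation angle toward the
spindle axis after spindle bipolarization, first-order congression of the
bivalent center toward the metaphase plate with no imposed oscillation, a
linear pre-anaphase stretching ramp of bivalent/homolog lengths, and
piecewise-linear anaphase separation kinematics chosen per drawn fate.
Mis-segregation fates are drawn with probability ``logistic(beta0 +
beta1 * theta_onset)`` from the folded orientation angle at anaphase onset,
so the programmed angle-fate coupling is recoverable by the analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "AcquisitionGeometry",
    "GenotypePreset",
    "SyntheticCohortConfig",
    "GroundTruth",
    "PRESETS",
    "simulate_cohort",
    "render_stack",
    "TRACK_COLUMNS",
]

# Schema of the tabular track exchange format (CSV).
TRACK_COLUMNS = [
    "oocyte_id",
    "condition",
    "time_s",
    "object_class",
    "pole_id",
    "bivalent_id",
    "homolog_id",
    "endpoint_id",
    "x_um",
    "y_um",
    "z_um",
]

FATE_CATEGORIES = (
    "normal",
    "lagging_correct",
    "lagging_missegregated",
    "co_segregating",
)

# Anaphase kinematic constants (micrometres / seconds).  The cohesion-release
# jump produces the step in inter-homolog distance used for onset detection;
# lagging homologs hover near the equator until T_RESOLVE_S and then move at
# V_FAST_UM_S toward their final side.
COHESION_JUMP_UM = 0.4
T_RESOLVE_S = 70.0
V_FAST_UM_S = 0.09
K_LAG_DRIFT = 0.02
HOMOLOG_JITTER_FRAC = 1.0 / 3.0  # of sigma_pos
POLE_JITTER_FRAC = 0.5
POLAR_SPREAD_PER_S = 0.004  # anaphase transverse spreading rate
ANAPHASE_ELONGATION_UM_S = 0.05


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Acquisition grid: Z sampling, pixel size, frame interval, onset frame.

    Defaults mirror a spinning-disk meiosis-I acquisition: 30 Z-planes
    separated by 0.3 um, one two-channel volume every 10 s.
    """

    n_z: int = 30
    dz: float = 0.3
    dxy: float = 0.11
    dt: float = 10.0
    n_t: int = 63
    t_onset_index: int = 50
    channels: tuple[str, ...] = ("chromatin", "tubulin")

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if min(self.dz, self.dxy, self.dt) <= 0:
            raise ValueError("dz, dxy and dt must be positive")
        if not (0 <= self.t_onset_index < self.n_t):
            raise ValueError("t_onset_index must lie within 0..n_t-1")

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds relative to anaphase onset (negative before)."""
        return (np.arange(self.n_t) - self.t_onset_index) * self.dt

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass(frozen=True)
class GenotypePreset:
    """Kinematic parameters of one genotype/perturbation condition.

    Rates are first-order relaxation rates (1/s); ``sigma_pos`` is the
    per-frame positional noise SD (um); ``stretch_ramp`` is
    (t_start_s, t_end_s, delta_um) with the window strictly before onset;
    ``beta0``/``beta1`` parameterise the logistic link from the folded
    orientation angle at onset (degrees) to the per-bivalent probability of
    mis-segregation.  The relaxation rates are tuning knobs of the simulator,
    not measured quantities.
    """

    name: str
    k_orient: float = 0.02
    k_congress: float = 0.01
    sigma_pos: float = 0.09
    sigma_theta_deg: float = 6.3
    f_persistent_misorient: float = 0.0
    stretch_ramp: tuple[float, float, float] = (-150.0, -50.0, 1.0)
    v_push: float = 0.03
    v_pull: float = 0.02
    beta0: float = -12.0
    beta1: float = 0.0
    t_bipolar_mean: float = -350.0
    t_bipolar_sd: float = 50.0
    f_lagging: float = 0.02
    p_coseg: float = 0.5
    plate_radius_scale: float = 1.0
    d_ih0: float = 1.0
    l_hom0: float = 1.0
    spindle_length: float = 7.0

    def __post_init__(self) -> None:
        for attr in ("k_orient", "k_congress", "sigma_pos", "sigma_theta_deg",
                     "v_push", "v_pull"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if not 0.0 <= self.f_persistent_misorient <= 1.0:
            raise ValueError("f_persistent_misorient must be in [0, 1]")
        t0, t1, _ = self.stretch_ramp
        if not (t0 < t1 <= 0.0):
            raise ValueError("stretch window must precede anaphase onset")


PRESETS: dict[str, GenotypePreset] = {}


def _register(p: GenotypePreset) -> GenotypePreset:
    PRESETS[p.name] = p
    return p


#: Unperturbed control: fast orientation relaxation coupled to bipolarization,
#: tight metaphase plate, essentially no mis-segregation.
CONTROL = _register(GenotypePreset("control"))

#: Kinetochore-null-like: a fraction of bivalents never relax their
#: orientation, congression is loose (wide excursions around the plate),
#: and mis-segregation probability rises with the angle at onset.
KNL1_NULL = _register(replace(
    CONTROL, name="knl1_null", f_persistent_misorient=0.35,
    sigma_pos=0.26, beta0=-4.5, beta1=0.08, f_lagging=0.15,
))

#: Loss of lateral (dynein-mediated) interactions: orientation relaxation is
#: delayed but ultimately recovers; mild segregation-error excess.
LATERAL_LOSS = _register(replace(
    CONTROL, name="lateral_loss", t_bipolar_mean=-150.0, t_bipolar_sd=30.0,
    beta0=-6.0, beta1=0.02,
))

#: Loss of end-on attachments: no stretching ramp, no pulling at anaphase,
#: widened congression steady state, but accurate segregation.
ENDON_LOSS = _register(replace(
    CONTROL, name="endon_loss", stretch_ramp=(-150.0, -50.0, 0.0),
    sigma_pos=0.25, k_congress=0.005, v_pull=0.0, plate_radius_scale=1.4,
))

#: End-on loss combined with loss of anaphase pushing: homologs barely
#: separate and segregation errors become angle-dependent.
COMBINED_LOSS = _register(replace(
    ENDON_LOSS, name="combined_loss", v_push=0.0,
    beta0=-3.0, beta1=0.05, f_persistent_misorient=0.3,
))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """A cohort to simulate: preset, size, acquisition geometry, seed."""

    n_oocytes: int
    preset: GenotypePreset = CONTROL
    geometry: AcquisitionGeometry = AcquisitionGeometry()
    n_bivalents: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if self.n_bivalents < 1:
            raise ValueError("n_bivalents must be >= 1")
        t0, t1, dl = self.preset.stretch_ramp
        if dl != 0.0 and self.geometry.times_s[0] > t0:
            raise ValueError(
                "acquisition too short to contain the stretch window: first "
                f"frame at {self.geometry.times_s[0]:g} s but ramp starts at {t0:g} s"
            )


@dataclass
class GroundTruth:
    """Everything the simulator knows that the analysis must recover.

    ``fates``: one row per bivalent with the drawn fate category and the
    measured folded angle at onset.  ``ploidy``: one row per oocyte.
    ``bipolarization``: per-oocyte bipolarization time (s, relative to onset).
    """

    fates: pd.DataFrame
    ploidy: pd.DataFrame
    bipolarization: pd.DataFrame
    onset_index: int
    onset_time_s: float = 0.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _fold(theta_deg: np.ndarray) -> np.ndarray:
    return np.minimum(theta_deg, 180.0 - theta_deg)


def _simulate_oocyte(oocyte_id, preset, geom, n_b, rng_traj, rng_fate):
    """Simulate one oocyte; returns (rows dict of arrays, fate records)."""
    times = geom.times_s
    n_t = geom.n_t
    dt = geom.dt
    onset_i = geom.t_onset_index

    # Spindle pose: axis mostly in-plane (limited z component) so rendered
    # stacks fit the 9 um axial range; fixed midpoint per oocyte.
    az = rng_traj.uniform(0, 2 * np.pi)
    uz = rng_traj.uniform(-0.25, 0.25)
    r_xy = np.sqrt(1 - uz**2)
    u = np.array([r_xy * np.cos(az), r_xy * np.sin(az), uz])
    e1, e2 = _perp_basis(u)
    m = np.array([rng_traj.normal(0, 0.5), rng_traj.normal(0, 0.5),
                  rng_traj.normal(0, 0.2)])

    t_bip = rng_traj.normal(preset.t_bipolar_mean, preset.t_bipolar_sd)

    # Per-bivalent layout: staggered azimuths and plate radii keep spots
    # resolvable in renders (min neighbour distance ~1 um).
    phi = (2 * np.pi * np.arange(n_b) / n_b
           + rng_traj.normal(0, 0.08, n_b))
    # interleave small/large plate radii so azimuthal neighbours never sit
    # at similar radii: keeps every homolog pair optically resolvable
    r_sorted = np.linspace(0.6, 1.4, n_b) * preset.plate_radius_scale
    r_target = np.empty(n_b)
    r_target[0::2] = r_sorted[: (n_b + 1) // 2]
    r_target[1::2] = r_sorted[(n_b + 1) // 2:]
    psi = rng_traj.uniform(0, 2 * np.pi, n_b)  # tilt-plane azimuth
    persistent = rng_traj.uniform(size=n_b) < preset.f_persistent_misorient
    theta0 = np.where(persistent,
                      rng_traj.uniform(30.0, 150.0, n_b),
                      rng_traj.uniform(10.0, 70.0, n_b))

    a_or = np.exp(-preset.k_orient * dt)
    a_or_persist = np.exp(-0.005 * dt)  # weak pull toward the set point
    a_co = np.exp(-preset.k_congress * dt)

    theta = theta0.copy()
    s_ax = rng_traj.normal(0, 1.2, n_b)            # axial (equator) coordinate
    r_rad = r_target + np.abs(rng_traj.normal(0, 0.8, n_b))

    t0r, t1r, dL = preset.stretch_ramp
    ramp = np.clip((times - t0r) / (t1r - t0r), 0.0, 1.0)
    d_ih_t = preset.d_ih0 + 0.5 * dL * ramp
    l_hom_t = preset.l_hom0 + 0.25 * dL * ramp

    w_b = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2   # (n_b, 3)
    tilt_b = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2

    hom = np.empty((n_t, n_b, 2, 3))   # homolog centroids
    ends = np.empty((n_t, n_b, 2, 2, 3))  # endpoints [hom][end]
    poles = np.empty((n_t, 2, 3))

    # ---- pre-onset frames (t <= 0), first-order relaxation -------------
    for i in range(onset_i + 1):
        t = times[i]
        if i > 0:
            relax_on = (t >= t_bip) & ~persistent
            theta = np.where(relax_on, theta * a_or,
                             theta0 + (theta - theta0) * a_or_persist)
            theta = theta + rng_traj.normal(0, preset.sigma_theta_deg, n_b)
            theta = np.abs(theta)
            theta = np.where(theta > 180.0, 360.0 - theta, theta)
            s_ax = s_ax * a_co + rng_traj.normal(0, preset.sigma_pos, n_b)
            r_rad = (r_target + (r_rad - r_target) * a_co
                     + rng_traj.normal(0, preset.sigma_pos, n_b))
        th = np.radians(theta)
        v_b = np.cos(th)[:, None] * u + np.sin(th)[:, None] * tilt_b
        c = m + s_ax[:, None] * u + np.abs(r_rad)[:, None] * w_b
        d_half = d_ih_t[i] / 2.0
        if i == onset_i:
            d_half += COHESION_JUMP_UM / 2.0  # cohesion release at onset
        jit = rng_traj.normal(0, preset.sigma_pos * HOMOLOG_JITTER_FRAC,
                              (n_b, 2, 3))
        hom[i, :, 0] = c - d_half * v_b + jit[:, 0]
        hom[i, :, 1] = c + d_half * v_b + jit[:, 1]
        half_rod = (l_hom_t[i] / 2.0) * v_b
        for h in (0, 1):
            ends[i, :, h, 0] = hom[i, :, h] - half_rod
            ends[i, :, h, 1] = hom[i, :, h] + half_rod

    theta_onset = _fold(theta)  # folded state angle at the onset frame

    # ---- fates (independent RNG stream; fixed draw count per bivalent) --
    u_draws = rng_fate.uniform(size=(n_b, 5))
    p_mis = expit(preset.beta0 + preset.beta1 * theta_onset)
    mis = u_draws[:, 0] < p_mis
    coseg = mis & (u_draws[:, 1] < preset.p_coseg)
    lag_corr = ~mis & (u_draws[:, 2] < preset.f_lagging)
    fate = np.where(coseg, "co_segregating",
                    np.where(mis, "lagging_missegregated",
                             np.where(lag_corr, "lagging_correct", "normal")))
    side_draw = np.where(u_draws[:, 3] < 0.5, -1.0, 1.0)
    which_lags = (u_draws[:, 4] < 0.5).astype(int)

    # ---- anaphase kinematics (t > 0), fate-programmed schedules ---------
    s_h0 = (hom[onset_i] - m) @ u                       # (n_b, 2)
    perp0 = hom[onset_i] - s_h0[..., None] * u          # transverse part + m
    # destination side: each homolog heads to the pole it faces; ties to A/B.
    dir1 = np.where(s_h0[:, 0] <= s_h0[:, 1], -1.0, 1.0)
    dirs = np.stack([dir1, -dir1], axis=1)              # (n_b, 2)
    dirs = np.where(fate[:, None] == "co_segregating",
                    side_draw[:, None], dirs)
    lagging = np.zeros((n_b, 2), dtype=bool)
    is_lag = np.isin(fate, ["lagging_correct", "lagging_missegregated"])
    lagging[np.arange(n_b), which_lags] = is_lag
    # a lagging homolog that mis-segregates ends on its partner's side
    flip = lagging & (fate == "lagging_missegregated")[:, None]
    dirs = np.where(flip, -dirs, dirs)

    v_sep = preset.v_push + preset.v_pull
    base_perp = m - (m @ u) * u  # transverse coordinate of the axis
    for i in range(onset_i + 1, n_t):
        t = times[i]
        s_lead = s_h0 + dirs * v_sep * t
        if t <= T_RESOLVE_S:
            s_lagv = s_h0 * np.exp(-K_LAG_DRIFT * t)
        else:
            s_lagv = (s_h0 * np.exp(-K_LAG_DRIFT * T_RESOLVE_S)
                      + dirs * V_FAST_UM_S * (t - T_RESOLVE_S))
        s_h = np.where(lagging, s_lagv, s_lead)
        # chromosomes spread slowly over the polar cup as they segregate
        spread = 1.0 + POLAR_SPREAD_PER_S * t
        pos = base_perp + (perp0 - base_perp) * spread + s_h[..., None] * u
        pos = pos + rng_traj.normal(0, preset.sigma_pos, (n_b, 2, 3))
        hom[i] = pos
        half_rod = (l_hom_t[-1] / 2.0) * u  # rods align with the axis
        for h in (0, 1):
            ends[i, :, h, 0] = pos[:, h] - half_rod
            ends[i, :, h, 1] = pos[:, h] + half_rod

    # ---- poles ----------------------------------------------------------
    L_t = preset.spindle_length + ANAPHASE_ELONGATION_UM_S * np.maximum(times, 0.0)
    pole_noise = rng_traj.normal(0, preset.sigma_pos * POLE_JITTER_FRAC, (n_t, 2, 3))
    poles[:, 0] = m - (L_t / 2.0)[:, None] * u + pole_noise[:, 0]
    poles[:, 1] = m + (L_t / 2.0)[:, None] * u + pole_noise[:, 1]

    fate_records = [
        dict(oocyte_id=oocyte_id, bivalent_id=b + 1, fate=str(fate[b]),
             theta_onset_deg=float(theta_onset[b]))
        for b in range(n_b)
    ]
    return dict(hom=hom, ends=ends, poles=poles), fate_records, t_bip


def _oocyte_frame_rows(oocyte_id, condition, geom, arrays, n_b):
    """Assemble one oocyte's arrays into rows of the track table."""
    times = geom.times_s
    n_t = geom.n_t
    rows_per_frame = 2 + n_b * 6
    n_rows = n_t * rows_per_frame
    rec = {
        "oocyte_id": np.full(n_rows, oocyte_id),
        "condition": np.full(n_rows, condition, dtype=object),
        "time_s": np.empty(n_rows),
        "object_class": np.empty(n_rows, dtype=object),
        "pole_id": np.full(n_rows, "NA", dtype=object),
        "bivalent_id": np.zeros(n_rows, dtype=float),
        "homolog_id": np.zeros(n_rows, dtype=float),
        "endpoint_id": np.zeros(n_rows, dtype=float),
    }
    xyz = np.empty((n_rows, 3))
    k = 0
    for i in range(n_t):
        t = times[i]
        for p, pid in enumerate("AB"):
            rec["time_s"][k] = t
            rec["object_class"][k] = "pole"
            rec["pole_id"][k] = pid
            rec["bivalent_id"][k] = np.nan
            rec["homolog_id"][k] = np.nan
            rec["endpoint_id"][k] = np.nan
            xyz[k] = arrays["poles"][i, p]
            k += 1
        for b in range(n_b):
            for h in (0, 1):
                rec["time_s"][k] = t
                rec["object_class"][k] = "homolog"
                rec["bivalent_id"][k] = b + 1
                rec["homolog_id"][k] = h + 1
                rec["endpoint_id"][k] = np.nan
                xyz[k] = arrays["hom"][i, b, h]
                k += 1
                for e in (0, 1):
                    rec["time_s"][k] = t
                    rec["object_class"][k] = "endpoint"
                    rec["bivalent_id"][k] = b + 1
                    rec["homolog_id"][k] = h + 1
                    rec["endpoint_id"][k] = e + 1
                    xyz[k] = arrays["ends"][i, b, h, e]
                    k += 1
    rec["x_um"], rec["y_um"], rec["z_um"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    df = pd.DataFrame(rec)
    for col in ("bivalent_id", "homolog_id", "endpoint_id"):
        df[col] = df[col].astype("Int64")
    return df


def simulate_cohort(config: SyntheticCohortConfig):
    """Simulate a cohort of oocytes.

    Parameters
    ----------
    config : SyntheticCohortConfig
        Preset, cohort size, acquisition geometry and RNG seed.  Identical
        configs produce bit-identical output.

    Returns
    -------
    tracks : pandas.DataFrame
        All object trajectories in the track-table schema
        (one row per object per frame; times in seconds relative to onset).
    truth : GroundTruth
        Drawn fates, ploidy, onset index and bipolarization times.
    """
    geom = config.geometry
    preset = config.preset
    root = np.random.default_rng(config.seed)
    # independent streams: trajectory noise vs fate draws, so changing the
    # fate link (beta0/beta1) never perturbs the trajectories
    rng_traj, rng_fate = root.spawn(2)

    frames = []
    fates = []
    bips = []
    for o in range(1, config.n_oocytes + 1):
        arrays, fate_records, t_bip = _simulate_oocyte(
            o, preset, geom, config.n_bivalents, rng_traj, rng_fate)
        frames.append(_oocyte_frame_rows(o, preset.name, geom, arrays,
                                         config.n_bivalents))
        fates.extend(fate_records)
        bips.append(dict(oocyte_id=o, t_bipolar_s=float(t_bip)))

    tracks = pd.concat(frames, ignore_index=True)
    fates_df = pd.DataFrame(fates)
    bad = fates_df["fate"].isin(["co_segregating", "lagging_missegregated"])
    ploidy = (
        fates_df.assign(bad=bad)
        .groupby("oocyte_id", as_index=False)["bad"].any()
        .assign(ploidy=lambda d: np.where(d["bad"], "aneuploid", "euploid"))
        .drop(columns="bad")
    )
    truth = GroundTruth(
        fates=fates_df, ploidy=ploidy, bipolarization=pd.DataFrame(bips),
        onset_index=geom.t_onset_index,
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: approximate radius (as a Gaussian SD, um) of a chromatin/pole object
CHROMATIN_OBJ_SIGMA = 0.25
POLE_OBJ_SIGMA = 0.35
SPINDLE_BODY_AMP = 0.35
BACKGROUND_LEVEL = 0.05


def _add_blob(vol, center_um, sigma_um, spacing, origin, amp):
    """Add an anisotropic Gaussian blob evaluated at voxel centers."""
    shape = vol.shape
    lo, hi, grids = [], [], []
    for ax in range(3):
        c = (center_um[ax] - origin[ax]) / spacing[ax] - 0.5
        s = sigma_um[ax] / spacing[ax]
        a = max(int(np.floor(c - 4 * s)), 0)
        b = min(int(np.ceil(c + 4 * s)) + 1, shape[ax])
        if a >= b:
            return
        idx = np.arange(a, b)
        grids.append((idx - c) / s)
        lo.append(a)
        hi.append(b)
    gz, gy, gx = np.meshgrid(*grids, indexing="ij")
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(
        -0.5 * (gz**2 + gy**2 + gx**2))


def render_stack(tracks: pd.DataFrame, geometry: AcquisitionGeometry,
                 psf_sigma=(0.35, 0.15, 0.15), snr: float = 10.0, *,
                 seed: int = 0, origin=None, shape_yx=None):
    """Render one oocyte's tracks into a two-channel T x C x Z x Y x X stack.

    Homolog centroids become anisotropic Gaussian blobs in the chromatin
    channel; the tubulin channel holds the two pole blobs plus an elongated
    spindle-shaped background.  Physical coordinates map to voxel indices by
    ``floor((x - origin) / spacing)`` (voxel centers at ``(i + 0.5) * spacing``).
    Poisson noise is scaled so the peak-signal-to-noise ratio equals ``snr``
    (``snr=inf`` renders noiselessly).

    Returns ``(stack, meta)`` where ``meta`` records origin and spacings.
    Raises ``ValueError`` (naming the offending frame) if any tracked point
    falls outside the rendered volume.
    """
    psf_sigma = np.broadcast_to(np.asarray(psf_sigma, dtype=float), (3,))
    if np.any(psf_sigma <= 0):
        raise ValueError("psf_sigma must be positive")
    if not snr > 0:
        raise ValueError("snr must be positive")
    if tracks["oocyte_id"].nunique() != 1:
        raise ValueError("render_stack renders a single oocyte at a time")

    spacing = np.array([geometry.dz, geometry.dxy, geometry.dxy])
    pts = tracks[["z_um", "y_um", "x_um"]].to_numpy()
    margin = 1.5
    if origin is None:
        center = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
        if shape_yx is None:
            extent = pts.max(axis=0) - pts.min(axis=0)
            n_y = int(np.ceil((extent[1] + 2 * margin) / geometry.dxy))
            n_x = int(np.ceil((extent[2] + 2 * margin) / geometry.dxy))
            shape_yx = (n_y, n_x)
        shape = (geometry.n_z, *shape_yx)
        origin = center - 0.5 * np.array(shape) * spacing
    else:
        origin = np.asarray(origin, dtype=float)
        if shape_yx is None:
            raise ValueError("shape_yx is required when origin is given")
        shape = (geometry.n_z, *shape_yx)

    upper = origin + np.array(shape) * spacing
    out = (pts < origin) | (pts >= upper)
    if out.any():
        bad_t = tracks.loc[out.any(axis=1), "time_s"].iloc[0]
        raise ValueError(
            f"track extends outside the rendered volume at time {bad_t:g} s")

    times = geometry.times_s
    chrom_sigma = np.sqrt(psf_sigma**2 + CHROMATIN_OBJ_SIGMA**2)
    pole_sigma = np.sqrt(psf_sigma**2 + POLE_OBJ_SIGMA**2)

    stack = np.zeros((geometry.n_t, 2, *shape), dtype=np.float32)
    zc = origin[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    yc = origin[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    xc = origin[2] + (np.arange(shape[2]) + 0.5) * spacing[2]
    gz, gy, gx = np.meshgrid(zc, yc, xc, indexing="ij")
    coords = np.stack([gz, gy, gx], axis=-1)

    hom = tracks[tracks["object_class"] == "homolog"]
    poles = tracks[tracks["object_class"] == "pole"]
    for i, t in enumerate(times):
        chan_chrom = stack[i, 0]
        chan_tub = stack[i, 1]
        for _, row in hom[np.isclose(hom["time_s"], t)].iterrows():
            _add_blob(chan_chrom, (row.z_um, row.y_um, row.x_um),
                      chrom_sigma, spacing, origin, 1.0)
        pframe = poles[np.isclose(poles["time_s"], t)]
        ppos = pframe[["z_um", "y_um", "x_um"]].to_numpy()
        for p in ppos:
            _add_blob(chan_tub, p, pole_sigma, spacing, origin, 1.0)
        if len(ppos) == 2:
            # elongated spindle body between the poles
            mid = ppos.mean(axis=0)
            axis = ppos[1] - ppos[0]
            L = np.linalg.norm(axis)
            if L > 0:
                axis = axis / L
                d = coords - mid
                along = d @ axis
                trans2 = np.einsum("zyxk,zyxk->zyx", d, d) - along**2
                chan_tub += (SPINDLE_BODY_AMP * np.exp(
                    -0.5 * (along / (L / 4.0))**2
                    - 0.5 * trans2 / 1.2**2)).astype(np.float32)

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        lam = snr**2
        stack = rng.poisson(lam * (stack + BACKGROUND_LEVEL)).astype(np.float32)
    meta = dict(origin=tuple(float(v) for v in origin),
                spacing=tuple(float(v) for v in spacing),
                shape=tuple(int(v) for v in shape), snr=float(snr))
    return stack, meta
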