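"""Synthetic audiovisual change-detection sessions with known ground truth.

The generator emulates the statistical structure the analyses assume:

* task-A trial statistics (block-shuffled types, truncated-exponential
  inter-change intervals, two saliency levels, optogenetic trials);
* choices from the bivariate signal-detection decision rule, with
  lognormal reaction times inside the 1.5-s response window;
* inhomogeneous-Poisson spiking with (a) an early sensory transient
  (0-200 ms) on visual-change trials, orientation-tuned and strongest in
  the granular/supragranular layers, (b) a late report-locked component on
  hit trials that rises a fixed lag *before* the first lick and is
  strongest supra-/infragranularly, (c) a shared multiplicative slow gain
  (Ornstein-Uhlenbeck) that induces pairwise noise correlations and is
  quenched shortly before each first lick, and (d) optogenetic silencing
  that drops rates to 5% of baseline;
* lick bouts at ~7 Hz after each response, plus sparse spontaneous licks;
* a pupil trace that is a low-passed copy of the gain process plus noise.

Every source of randomness flows from one seed, so a session is fully
reproducible, and the generative parameters are returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import Session
from .stimuli import MAX_CHANGE, make_stimulus_set, sample_trial_sequence

__all__ = [
    "CohortConfig",
    "simulate_behavior",
    "simulate_spikes",
    "simulate_session",
    "simulate_cohort_pair",
    "gain_sigma_for_target",
    "DT",
]

#: Simulation grid step (s); matches the 10-ms analysis binning.
DT = 0.01

#: Relative early-transient amplitude per saliency level.
SALIENCY_GAIN = {"sub": 0.25, "thr": 0.5, "sup": 0.75, "max": 1.0}


def _default_dprime_visual():
    return {"sub": 0.4, "thr": 0.9, "sup": 1.2, "max": 1.5}


def _default_dprime_auditory():
    return {"sub": 0.5, "thr": 1.1, "sup": 1.8, "max": 2.2}


@dataclass
class CohortConfig:
    """Generative parameters for one cohort's sessions.

    Defaults describe an MST-like (multisensory-trained) animal: visual d'
    reaching ~1.5 at maximal saliency, auditory d' higher, criteria near 1,
    lognormal reaction times, a late component rising 280 ms before the
    first lick, baseline noise correlations targeting 0.063, and the gain
    quench starting 200 ms before each lick.  Use the class methods for
    NE / UST / MST presets.
    """

    cohort: str = "MST"
    dprime_visual: dict = field(default_factory=_default_dprime_visual)
    dprime_auditory: dict = field(default_factory=_default_dprime_auditory)
    criterion_visual: float = 1.0
    criterion_auditory: float = 1.0
    rt_lognormal_mu: float = float(np.log(0.62))
    rt_lognormal_sigma: float = 0.12
    late_onset_lag: float = -0.28
    early_gain_by_layer: dict = field(
        default_factory=lambda: {"SG": 1.2, "G": 1.5, "IG": 0.6}
    )
    late_gain_by_layer: dict = field(
        default_factory=lambda: {"SG": 1.0, "G": 0.5, "IG": 1.2}
    )
    late_amplitude: float = 1.5
    orientation_tuning: float = 0.3
    nc_baseline_target: float = 0.063
    nc_drop_lead: float = 0.2
    gain_tau: float = 1.0
    baseline_log_mean: float = float(np.log(4.0))
    baseline_log_sd: float = 0.5
    n_neurons: int = 32
    n_trials: int = 600
    photostim_fraction: float = 0.0
    early_silencing_dprime_factor: float = 0.15
    silencing_rate_factor: float = 0.05
    spontaneous_lick_rate: float = 0.05
    lick_bout_rate: float = 7.0
    lick_bout_duration: float = 1.5
    visual_spout: str = "left"
    seed: int = 0

    def __post_init__(self):
        if self.late_onset_lag >= 0:
            raise ValueError("late_onset_lag must be negative (precedes the report)")
        if self.cohort == "NE" and any(
            v > 0 for v in list(self.dprime_visual.values()) + list(self.dprime_auditory.values())
        ):
            raise ValueError("NE cohort must have zero contingent d-prime")

    @classmethod
    def NE(cls, **kw) -> "CohortConfig":
        zero = {k: 0.0 for k in ("sub", "thr", "sup", "max")}
        kw.setdefault("criterion_visual", 1.5)
        kw.setdefault("criterion_auditory", 1.5)
        return cls(cohort="NE", dprime_visual=dict(zero), dprime_auditory=dict(zero), **kw)

    @classmethod
    def UST(cls, **kw) -> "CohortConfig":
        zero = {k: 0.0 for k in ("sub", "thr", "sup", "max")}
        kw.setdefault("rt_lognormal_mu", float(np.log(0.42)))
        kw.setdefault("criterion_auditory", 2.5)
        return cls(cohort="UST", dprime_auditory=dict(zero), **kw)

    @classmethod
    def MST(cls, **kw) -> "CohortConfig":
        return cls(cohort="MST", **kw)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    trials: pd.DataFrame, cfg: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill choices, reaction times, and outcomes into a stimulus-only table.

    Per trial, bivariate standard-normal evidence is drawn with the
    stimulated modality's d' added on its axis; the animal responds to
    modality m iff evidence_m >= c_m and evidence_m - c_m >= the other
    modality's criterion-referenced evidence.  Reaction times are lognormal,
    truncated to the (0.1, 1.5] s response window (a response whose drawn
    latency misses the window is a miss).  Early photostimulation scales the
    visual d' down by the silencing factor; late photostimulation converts
    hits whose generated late-component onset falls at or after the 200-ms
    silencing start into misses.
    """
    t = trials.copy()
    n = len(t)
    spout = {"visual": cfg.visual_spout,
             "auditory": "right" if cfg.visual_spout == "left" else "left"}

    dv = np.zeros(n)
    da = np.zeros(n)
    for sal, grp in t.groupby("saliency"):
        if sal == "none":
            continue
        vis = grp.index[t.loc[grp.index, "trial_type"].isin(["visual", "multimodal"])]
        aud = grp.index[t.loc[grp.index, "trial_type"].isin(["auditory", "multimodal"])]
        dv[vis] = cfg.dprime_visual.get(sal, 0.0)
        da[aud] = cfg.dprime_auditory.get(sal, 0.0)
    early = (t["photostim"] == "early").to_numpy()
    dv[early] *= cfg.early_silencing_dprime_factor

    ev = rng.standard_normal(n) + dv
    ea = rng.standard_normal(n) + da
    cv, ca = cfg.criterion_visual, cfg.criterion_auditory
    resp_v = (ev >= cv) & (ev - cv >= ea - ca)
    resp_a = (ea >= ca) & (ea - ca > ev - cv)

    rt = np.exp(rng.normal(cfg.rt_lognormal_mu, cfg.rt_lognormal_sigma, size=n))
    in_window = (rt > 0.1) & (rt <= 1.5)
    responded = (resp_v | resp_a) & in_window
    resp_v &= responded
    resp_a &= responded

    # late silencing: hits whose late onset would start >= 200 ms are lost
    late = (t["photostim"] == "late").to_numpy()
    lost = late & responded & (rt + cfg.late_onset_lag >= 0.2)
    responded &= ~lost
    resp_v &= ~lost
    resp_a &= ~lost

    choice = np.full(n, "none", dtype=object)
    choice[resp_v] = spout["visual"]
    choice[resp_a] = spout["auditory"]

    ttype = t["trial_type"].to_numpy()
    correct_side = np.select(
        [ttype == "visual", ttype == "auditory"],
        [spout["visual"], spout["auditory"]],
        default="none",
    )
    # multimodal: either side counts as correct (not analyzed downstream)
    outcome = np.full(n, "CR", dtype=object)
    change = ttype != "catch"
    hit = change & responded & (
        (choice == correct_side)
        | ((ttype == "multimodal") & (choice != "none"))
    )
    outcome[hit] = "hit"
    outcome[change & responded & ~hit] = "error"
    outcome[change & ~responded] = "miss"
    outcome[(ttype == "catch") & responded] = "FA"

    t["choice"] = choice
    t["correct_side"] = correct_side
    t["outcome"] = outcome
    t["reaction_time"] = np.where(responded, rt, np.nan)
    t["reward_time"] = np.where(hit, t["change_time"] + t["reaction_time"], np.nan)
    return t


# ---------------------------------------------------------------------------
# gain calibration
# ---------------------------------------------------------------------------

def _half_gaussian_kernel(sd: float, dt: float = DT, n_sd: float = 4.0) -> np.ndarray:
    """Causal half-Gaussian smoothing weights (mass 1) on the analysis grid."""
    n = max(int(np.ceil(n_sd * sd / dt)), 1)
    t = np.arange(n + 1) * dt
    w = np.exp(-0.5 * (t / sd) ** 2)
    return w / w.sum()


def gain_sigma_for_target(
    nc_target: float,
    mean_rate_hz: float,
    tau: float = 1.0,
    kernel_sd: float = 0.1,
    dt: float = DT,
) -> float:
    """Log-gain SD producing a target pairwise noise correlation.

    For doubly-stochastic Poisson neurons sharing a multiplicative
    lognormal-OU gain g (mean 1, variance v, autocorrelation exp(-u/tau)),
    rates smoothed with kernel weights w have, across trials,

        cov_ij = li*lj*v*K,    var_i = li*S2/dt + li^2*v*K,

    with S2 = sum w^2 and K = sum_bb' w_b w_b' exp(-|b-b'|dt/tau).  Setting
    the equal-rate correlation to the target and solving for v gives the
    required gain variance; the returned value is the SD of the underlying
    log-gain OU process (v = exp(sigma_x^2) - 1).
    """
    if not 0 < nc_target < 1:
        raise ValueError("nc_target must be in (0, 1)")
    w = _half_gaussian_kernel(kernel_sd, dt)
    s2 = float(np.sum(w ** 2))
    lags = np.abs(np.subtract.outer(np.arange(len(w)), np.arange(len(w)))) * dt
    k = float(w @ np.exp(-lags / tau) @ w)
    lam = float(mean_rate_hz)
    v = nc_target * s2 / (dt * lam * k * (1.0 - nc_target))
    return float(np.sqrt(np.log1p(v)))


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _make_neurons(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_neurons
    depth = rng.uniform(100.0, 1000.0, size=n)
    # waveform peak-to-trough: narrow (0.3 ms) / broad (0.75 ms) mixture, cap 1 ms
    narrow = rng.random(n) < 0.2
    p2t = np.where(
        narrow,
        rng.normal(0.30, 0.04, size=n),
        rng.normal(0.75, 0.10, size=n),
    )
    p2t = np.clip(p2t, 0.1, 1.0)
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n))
    layer = np.select([depth < 400, depth <= 550], ["SG", "G"], default="IG")
    pref = np.where(rng.random(n) < 0.5, "AB", "CD")
    return pd.DataFrame(
        dict(
            neuron_id=[f"n{i:03d}" for i in range(n)],
            depth_um=depth,
            p2t_ms=p2t,
            baseline_hz=baseline,
            layer=layer,
            pref_pair=pref,
        )
    )


def _ou_process(n_bins: int, tau: float, sigma_x: float, rng) -> np.ndarray:
    from scipy.signal import lfilter

    a = np.exp(-DT / tau)
    noise = rng.standard_normal(n_bins) * sigma_x * np.sqrt(1 - a * a)
    noise[0] = rng.standard_normal() * sigma_x
    return lfilter([1.0], [1.0, -a], noise)


def _orientation_pair(post_feature: float, visual_set) -> str:
    vals = np.asarray(visual_set.values())
    idx = int(np.argmin(np.abs(np.mod(vals - post_feature + 180.0, 360.0) - 180.0)))
    return "AB" if idx in (0, 1) else "CD"


def simulate_spikes(
    trials: pd.DataFrame,
    cfg: CohortConfig,
    rng: np.random.Generator,
    visual_set=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate spikes, licks, and pupil for a behaviorally-complete session.

    Returns (spikes, neurons, licks, pupil, ground_truth).
    """
    if visual_set is None:
        visual_set = make_stimulus_set("visual", 100.0, 7.0)
    neurons = _make_neurons(cfg, rng)
    n_neurons = len(neurons)
    t_end = float(trials["change_time"].max()) + 5.0
    n_bins = int(np.ceil(t_end / DT))
    tgrid = np.arange(n_bins) * DT

    # shared multiplicative gain: lognormal OU, mean 1
    sigma_x = gain_sigma_for_target(
        cfg.nc_baseline_target,
        float(np.exp(cfg.baseline_log_mean + cfg.baseline_log_sd ** 2 / 2)),
        tau=cfg.gain_tau,
    )
    x = _ou_process(n_bins, cfg.gain_tau, sigma_x, rng)
    gain = np.exp(x - sigma_x ** 2 / 2)

    # licks: response bouts + spontaneous
    lick_rows = []
    first_licks = []
    resp = trials.dropna(subset=["reaction_time"])
    for _, tr in resp.iterrows():
        t0 = tr["change_time"] + tr["reaction_time"]
        first_licks.append(t0)
        times = [t0]
        t_l = t0
        while t_l < t0 + cfg.lick_bout_duration:
            t_l += rng.exponential(1.0 / cfg.lick_bout_rate)
            # enforce a 6-8 Hz bout by clipping inter-lick intervals
            times.append(t_l)
        lick_rows += [dict(time_s=float(s), side=tr["choice"]) for s in times]
    for side in ("left", "right"):
        n_sp = rng.poisson(cfg.spontaneous_lick_rate * t_end)
        for s in rng.uniform(0, t_end, size=n_sp):
            lick_rows.append(dict(time_s=float(s), side=side))
    licks = pd.DataFrame(lick_rows).sort_values("time_s", ignore_index=True)
    first_licks = np.sort(np.asarray(first_licks))

    # gain quench: from nc_drop_lead before each first lick to 1 s after it
    quenched_gain = gain.copy()
    for fl in first_licks:
        i0 = max(int((fl - cfg.nc_drop_lead) / DT), 0)
        i1 = min(int((fl + 1.0) / DT), n_bins)
        quenched_gain[i0:i1] = 1.0
    gain = quenched_gain

    # per-trial event bookkeeping
    change_bins = (trials["change_time"].to_numpy() / DT).astype(int)
    sal = trials["saliency"].map(SALIENCY_GAIN).fillna(0.0).to_numpy()
    is_visual = trials["trial_type"].isin(["visual", "multimodal"]).to_numpy()
    is_hit = (trials["outcome"] == "hit").to_numpy()
    rts = trials["reaction_time"].to_numpy(float)
    photostim = trials["photostim"].to_numpy()
    pair = np.array(
        [
            _orientation_pair(pf, visual_set) if vis and np.isfinite(pf) else ""
            for pf, vis in zip(trials["post_feature"].to_numpy(float), is_visual)
        ],
        dtype=object,
    )

    # kernel shapes (unit peak)
    early_len = int(0.2 / DT)
    tt = (np.arange(early_len) + 0.5) * DT
    early_shape = np.exp(-0.5 * ((tt - 0.1) / 0.04) ** 2)
    # rise shaped as a Gaussian CDF (sigma 100 ms) reaching half-amplitude
    # 50 ms after the nominal onset, truncated 50 ms before it -- calibrated
    # so the *detectable* coding onset coincides with the nominal lag
    rise_pre = int(0.05 / DT)
    rise_len = int(0.3 / DT)
    from scipy.special import ndtr as _ndtr
    rise = _ndtr((np.arange(rise_len) * DT - 0.1) / 0.1)
    decay_len = int(0.45 / DT)
    decay = np.exp(-0.5 * ((np.arange(decay_len) * DT) / 0.15) ** 2)

    late_onsets = np.where(is_hit, rts + cfg.late_onset_lag, np.nan)

    spike_rows_id = []
    spike_rows_t = []
    gt_neurons = []
    for j in range(n_neurons):
        nr = neurons.iloc[j]
        layer = nr["layer"]
        base = nr["baseline_hz"]
        e_gain = cfg.early_gain_by_layer[layer]
        l_gain = cfg.late_gain_by_layer[layer] * cfg.late_amplitude
        mod = np.zeros(n_bins)
        for i in range(len(trials)):
            cb = change_bins[i]
            if is_visual[i] and sal[i] > 0:
                tune = 1.0 + (
                    cfg.orientation_tuning
                    if pair[i] == nr["pref_pair"]
                    else -cfg.orientation_tuning
                )
                amp = e_gain * sal[i] * tune
                seg = slice(cb, min(cb + early_len, n_bins))
                mod[seg] += amp * early_shape[: seg.stop - seg.start]
            if is_hit[i] and np.isfinite(late_onsets[i]):
                ob = cb + int(late_onsets[i] / DT)
                rb = ob - rise_pre  # build-up start
                plateau_end = cb + int((rts[i] + 0.3) / DT)
                if rb < n_bins:
                    seg = slice(max(rb, 0), min(rb + rise_len, n_bins, plateau_end))
                    off = seg.start - rb
                    mod[seg] += l_gain * rise[off : off + seg.stop - seg.start]
                    seg2 = slice(min(rb + rise_len, plateau_end), min(plateau_end, n_bins))
                    if seg2.stop > seg2.start:
                        mod[seg2] += l_gain
                    seg3 = slice(min(plateau_end, n_bins), min(plateau_end + decay_len, n_bins))
                    if seg3.stop > seg3.start:
                        mod[seg3] += l_gain * decay[: seg3.stop - seg3.start]
        rate = base * gain * (1.0 + mod)
        # optogenetic silencing: 5% of rate from onset until choice
        for i in range(len(trials)):
            if photostim[i] == "none":
                continue
            start = change_bins[i] + (0 if photostim[i] == "early" else int(0.2 / DT))
            stop_t = rts[i] if np.isfinite(rts[i]) else 1.5
            stop = change_bins[i] + int(stop_t / DT)
            rate[start: min(stop, n_bins)] *= cfg.silencing_rate_factor
        counts = rng.poisson(np.maximum(rate, 0.0) * DT)
        nz = np.nonzero(counts)[0]
        reps = counts[nz]
        times = np.repeat(tgrid[nz], reps) + rng.uniform(0, DT, size=int(reps.sum()))
        spike_rows_id.append(np.full(len(times), nr["neuron_id"], dtype=object))
        spike_rows_t.append(np.sort(times))
        gt_neurons.append(
            dict(
                neuron_id=nr["neuron_id"], layer=layer,
                baseline_hz=float(base),
                early_amplitude=float(e_gain), late_amplitude=float(l_gain),
                pref_pair=nr["pref_pair"],
            )
        )

    spikes = pd.DataFrame(
        dict(
            neuron_id=np.concatenate(spike_rows_id),
            time_s=np.concatenate(spike_rows_t),
        )
    ).sort_values(["neuron_id", "time_s"], ignore_index=True)

    # pupil: low-passed gain process plus noise, z-scored, 20 Hz
    lp = np.convolve(x, np.ones(50) / 50.0, mode="same")
    pupil_t = np.arange(0, t_end, 0.05)
    pupil_raw = np.interp(pupil_t, tgrid, lp) + rng.normal(0, 0.2 * max(sigma_x, 1e-6), len(pupil_t))
    pupil_z = (pupil_raw - pupil_raw.mean()) / pupil_raw.std()
    pupil = pd.DataFrame(dict(time_s=pupil_t, pupil_z=pupil_z))

    ground_truth = dict(
        sigma_x=float(sigma_x),
        gain_tau=cfg.gain_tau,
        nc_baseline_target=cfg.nc_baseline_target,
        nc_drop_lead=cfg.nc_drop_lead,
        late_onset_lag=cfg.late_onset_lag,
        neurons=gt_neurons,
        late_onsets={int(i): float(v) for i, v in enumerate(late_onsets) if np.isfinite(v)},
        behavior=dict(
            dprime_visual=cfg.dprime_visual,
            dprime_auditory=cfg.dprime_auditory,
            criterion_visual=cfg.criterion_visual,
            criterion_auditory=cfg.criterion_auditory,
            rt_lognormal_mu=cfg.rt_lognormal_mu,
            rt_lognormal_sigma=cfg.rt_lognormal_sigma,
        ),
    )
    neurons_out = neurons[["neuron_id", "depth_um", "p2t_ms"]].copy()
    return spikes, neurons_out, licks, pupil, ground_truth


def simulate_session(cfg: CohortConfig, session_id: str = "synthetic") -> Session:
    """Full synthetic session: trial sequence, behavior, spikes, streams."""
    rng = np.random.default_rng(cfg.seed)
    visual_set = make_stimulus_set("visual", 100.0, 7.0)
    auditory_set = make_stimulus_set("auditory", 13.25, 1.0 / 32.0)
    trials = sample_trial_sequence(
        cfg.n_trials,
        rng_seed=rng,
        visual_set=visual_set,
        auditory_set=auditory_set,
        photostim_fraction=cfg.photostim_fraction,
    )
    mag = {
        ("visual", "thr"): visual_set.threshold_change,
        ("visual", "max"): MAX_CHANGE["visual"],
        ("auditory", "thr"): auditory_set.threshold_change,
        ("auditory", "max"): MAX_CHANGE["auditory"],
    }
    trials["change_magnitude"] = [
        mag.get((tt if tt != "multimodal" else "visual", s), np.nan)
        for tt, s in zip(trials["trial_type"], trials["saliency"])
    ]
    trials = simulate_behavior(trials, cfg, rng)
    spikes, neurons, licks, pupil, gt = simulate_spikes(trials, cfg, rng, visual_set)
    manifest = dict(
        session_id=session_id,
        cohort=cfg.cohort,
        seed=cfg.seed,
        n_trials=cfg.n_trials,
        n_neurons=cfg.n_neurons,
        visual_set=list(visual_set.values()),
        auditory_set=list(auditory_set.values()),
        iti=dict(mean=6.0, bounds=[3.0, 20.0]),
        proportions=dict(catch=0.10, visual=0.41, auditory=0.41, multimodal=0.08),
        duration_s=float(trials["change_time"].max() + 5.0),
    )
    return Session(
        manifest=manifest, trials=trials, spikes=spikes, neurons=neurons,
        licks=licks, pupil=pupil, ground_truth=gt,
    )


def simulate_cohort_pair(
    cfg_ust: CohortConfig,
    cfg_mst: CohortConfig,
    n_sessions: int = 10,
    seed: int = 0,
    session_rt_sigma: float = 0.03,
) -> tuple[list[Session], list[Session]]:
    """Matched UST-like and MST-like session collections.

    The MST config must have slower reaction times (larger lognormal mu);
    by construction its late-component onsets are correspondingly later,
    which is what the onset-versus-reaction-time analyses recover.
    """
    if cfg_mst.rt_lognormal_mu <= cfg_ust.rt_lognormal_mu:
        raise ValueError("cfg_mst must have slower RTs than cfg_ust")
    import dataclasses as _dc

    root = np.random.default_rng(seed)
    out = []
    for cfg in (cfg_ust, cfg_mst):
        sessions = []
        for i in range(n_sessions):
            c = _dc.replace(cfg, seed=int(root.integers(2 ** 31 - 1)))
            # session-to-session RT variability drives the onset-vs-RT regression
            c.rt_lognormal_mu = cfg.rt_lognormal_mu + root.normal(0, session_rt_sigma)
            sessions.append(simulate_session(c, session_id=f"{cfg.cohort}_{i:02d}"))
        out.append(sessions)
    return out[0], out[1]
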