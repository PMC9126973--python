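"""Pairwise noise correlations and population decoding.

Noise correlations (NC) are Pearson correlations, across trials, of
residual firing rates after subtracting each condition's trial-mean time
course (per post-change orientation; or the lick-aligned mean for
lick-aligned analyses), per neuron pair and 10-ms bin.  Summaries average
Fisher-z-transformed correlations and back-transform.  The decorrelation
around the report is quantified as the first bin where the mean NC falls
below baseline mean - 2 SD, per reaction-time tertile.

Population decoding of the visual orientation pair ({A,B} vs {C,D}) uses
spike counts in 200-ms windows sliding by 50 ms (windows straddling the
change are dropped), ten subsampled neurons, a 200-tree random forest with
5 x 5 stratified cross-validation, and chance correction by label-permuted
surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.model_selection import cross_val_score

__all__ = [
    "residual_rates",
    "NCResult",
    "noise_correlations",
    "tertile_decorrelation",
    "prestim_state",
    "DecodingResult",
    "decode_orientation",
]


def residual_rates(
    values: np.ndarray,
    condition_labels: np.ndarray,
    min_trials: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each condition's mean time course per neuron.

    ``values`` is neurons x trials x bins; conditions with fewer than 10
    trials are excluded.  Returns (residuals, kept-trial mask); residuals
    have the excluded trials removed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(condition_labels)
    keep = np.zeros(values.shape[1], dtype=bool)
    resid = values.copy()
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < min_trials:
            continue
        keep |= sel
        resid[:, sel, :] -= values[:, sel, :].mean(axis=1, keepdims=True)
    return resid[:, keep, :], keep


def _pairwise_r_per_bin(resid: np.ndarray) -> np.ndarray:
    """Pearson r across trials for every pair and bin; (n_pairs, n_bins)."""
    n, t, b = resid.shape
    mu = resid.mean(axis=1, keepdims=True)
    x = resid - mu
    sd = x.std(axis=1)
    iu = np.triu_indices(n, k=1)
    out = np.empty((len(iu[0]), b))
    for k in range(b):
        xk = x[:, :, k]
        cov = xk @ xk.T / t
        denom = np.outer(sd[:, k], sd[:, k])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / denom
        r[denom == 0] = np.nan
        out[:, k] = r[iu]
    return out


def _fisher_mean(r: np.ndarray, axis=None) -> np.ndarray:
    """Average correlations through the Fisher z-transform."""
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    return np.tanh(np.nanmean(z, axis=axis))


@dataclass
class NCResult:
    """Pairwise noise correlations per 10-ms bin for one condition."""

    r_per_bin: np.ndarray  # (n_pairs, n_bins)
    mean_per_bin: np.ndarray  # Fisher-z averaged over pairs
    times: np.ndarray
    baseline_mean: float
    baseline_sd: float
    delta_nc: float
    align: str = "stimulus_change"
    condition: str = ""


def noise_correlations(
    residuals: np.ndarray,
    times: np.ndarray,
    align: str = "stimulus_change",
    condition: str = "",
    baseline: tuple[float, float] = (-0.5, 0.0),
    post: tuple[float, float] = (0.2, 1.0),
    min_trials: int = 10,
) -> NCResult:
    """Pairwise Pearson correlations of residual rates per bin.

    ``residuals`` is neurons x trials x bins after condition-mean
    subtraction (and after the >1 Hz inclusion filter upstream).  The
    baseline summary averages the pair-mean NC over -500 to 0 ms; delta_nc
    is the 200-1000 ms mean minus baseline.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape[1] < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {residuals.shape[1]}")
    times = np.asarray(times, dtype=float)
    r = _pairwise_r_per_bin(residuals)
    mean_per_bin = _fisher_mean(r, axis=0)
    bmask = (times >= baseline[0]) & (times < baseline[1])
    pmask = (times >= post[0]) & (times < post[1])
    baseline_mean = float(np.nanmean(mean_per_bin[bmask]))
    baseline_sd = float(np.nanstd(mean_per_bin[bmask]))
    delta = float(np.nanmean(mean_per_bin[pmask]) - baseline_mean)
    return NCResult(
        r_per_bin=r, mean_per_bin=mean_per_bin, times=times,
        baseline_mean=baseline_mean, baseline_sd=baseline_sd, delta_nc=delta,
        align=align, condition=condition,
    )


def _drop_onset(mean_nc: np.ndarray, times: np.ndarray,
                baseline: tuple[float, float], z: float = 2.0,
                consec: int = 5, stats_series: np.ndarray | None = None) -> float | None:
    """First sustained bin (>= consec in a row) below baseline mean - z SD,
    searched from the end of the baseline window onward.

    Baseline statistics may come from an unsmoothed copy of the series
    (``stats_series``) so that smoothing the tested series does not
    shrink the threshold.
    """
    ref = mean_nc if stats_series is None else stats_series
    bmask = (times >= baseline[0]) & (times < baseline[1])
    mu, sd = np.nanmean(ref[bmask]), np.nanstd(ref[bmask])
    below = (times >= baseline[1]) & (mean_nc < mu - z * sd)
    run = 0
    for i, x in enumerate(below):
        run = run + 1 if x else 0
        if run >= consec:
            return float(times[i - consec + 1])
    return None


def tertile_decorrelation(
    residuals: np.ndarray,
    rts: np.ndarray,
    times: np.ndarray,
    baseline: tuple[float, float] = (-0.5, 0.0),
    z: float = 2.0,
    min_trials: int = 30,
) -> dict:
    """Noise-correlation drop onset per reaction-time tertile of hit trials.

    Splits hit trials into fast/medium/slow RT tertiles, computes the
    pair-mean NC time course per tertile, and takes the first bin where it
    falls below baseline mean - 2 SD.  Returns per-tertile onsets, median
    RTs, and their Pearson correlation (3 points; a direction summary).
    """
    rts = np.asarray(rts, dtype=float)
    if residuals.shape[1] < min_trials:
        raise ValueError(f"need >= {min_trials} hit trials, got {residuals.shape[1]}")
    order = np.argsort(rts)
    tertiles = np.array_split(order, 3)
    onsets, med_rts = [], []
    smooth = np.ones(5) / 5.0  # 50-ms boxcar stabilizes the 10-ms NC series
    for idx in tertiles:
        nc = noise_correlations(residuals[:, idx, :], times, baseline=baseline,
                                min_trials=min(10, len(idx)))
        m = np.convolve(nc.mean_per_bin, smooth, mode="same")
        onsets.append(_drop_onset(m, times, baseline, z=z,
                                  stats_series=nc.mean_per_bin))
        med_rts.append(float(np.median(rts[idx])))
    ok = [i for i, o in enumerate(onsets) if o is not None]
    corr = np.nan
    if len(ok) == 3:
        corr = float(np.corrcoef(np.array(med_rts)[ok], np.array(onsets)[ok])[0, 1])
    return dict(onsets_s=onsets, median_rts_s=med_rts, rt_onset_correlation=corr)


def prestim_state(
    z_rates: np.ndarray,
    outcomes: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (0.1, 0.2),
    min_trials: int = 10,
) -> dict:
    """Hit-vs-miss contrast of rate and NC just before late photostimulation.

    ``z_rates`` is neurons x trials x bins (z-units) for late-photostim
    visual trials; the window is 100-200 ms after the change (just before
    the 200-ms silencing onset).  Returns mean z-rate and pair-mean NC in
    the window split by ensuing outcome, and their differences.
    """
    outcomes = np.asarray(outcomes)
    mask = (times >= window[0]) & (times < window[1])
    out: dict = {"flagged": False}
    groups = {}
    for name in ("hit", "miss"):
        sel = outcomes == name
        if sel.sum() < min_trials:
            out["flagged"] = True
        sub = z_rates[:, sel, :][:, :, mask]
        rate = float(np.nanmean(sub))
        resid = sub - np.nanmean(sub, axis=1, keepdims=True)
        r = _pairwise_r_per_bin(resid)
        groups[name] = dict(n_trials=int(sel.sum()), rate_z=rate,
                            nc=float(_fisher_mean(r)))
    out["hit"] = groups["hit"]
    out["miss"] = groups["miss"]
    out["rate_diff"] = groups["hit"]["rate_z"] - groups["miss"]["rate_z"]
    out["nc_diff"] = groups["hit"]["nc"] - groups["miss"]["nc"]
    return out


@dataclass
class DecodingResult:
    """Chance-corrected decoding accuracy per sliding window."""

    accuracy_per_window: np.ndarray
    raw_accuracy: np.ndarray
    surrogate_mean: np.ndarray
    window_centers: np.ndarray
    n_neurons_used: int
    n_surrogates: int


def decode_orientation(
    counts: np.ndarray,
    pair_labels: np.ndarray,
    times: np.ndarray,
    seed: int = 0,
    window: float = 0.2,
    step: float = 0.05,
    trange: tuple[float, float] | None = None,
    n_subsample: int = 10,
    n_trees: int = 200,
    n_surrogates: int = 50,
    min_neurons: int = 15,
    min_trials_per_class: int = 20,
) -> DecodingResult:
    """Random-forest decoding of the orientation pair from population counts.

    ``counts`` is neurons x trials x (10-ms) bins of visual trials;
    ``pair_labels`` gives the post-change pair ("AB"/"CD").  Windows whose
    span straddles the change at t = 0 are dropped.  Sessions need at
    least 15 neurons and 20 trials per class; ten neurons are randomly
    subsampled for comparability across sessions.  Accuracy comes from a
    5 x 5 stratified CV routine and is corrected by the mean accuracy over
    label-permuted surrogate datasets (each evaluated with one stratified
    5-fold pass).
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(pair_labels)
    y = (labels == labels[0]).astype(int)
    n_neurons, n_trials, _ = counts.shape
    if n_neurons < min_neurons:
        raise ValueError(f"session has {n_neurons} neurons; need >= {min_neurons}")
    if min(np.bincount(y, minlength=2)) < min_trials_per_class:
        raise ValueError(f"need >= {min_trials_per_class} trials per class")
    rng = np.random.default_rng(seed)
    if n_neurons > n_subsample:
        subset = rng.choice(n_neurons, size=n_subsample, replace=False)
    else:
        subset = np.arange(n_neurons)
    times = np.asarray(times, dtype=float)
    lo = trange[0] if trange else times[0]
    hi = trange[1] if trange else times[-1] + (times[1] - times[0])
    starts = np.round(np.arange(lo, hi - window + 1e-9, step), 9)
    # drop windows containing both pre- and post-change time
    starts = np.array([s for s in starts if not (s < 0.0 < round(s + window, 9))])
    centers = starts + window / 2.0

    raw = np.empty(len(starts))
    surro = np.empty(len(starts))
    for k, s in enumerate(starts):
        mask = (times >= s) & (times < s + window)
        Xw = counts[subset][:, :, mask].sum(axis=2).T  # trials x neurons
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31 - 1)),
            n_jobs=1,
        )
        cv = RepeatedStratifiedKFold(
            n_splits=5, n_repeats=5, random_state=int(rng.integers(2 ** 31 - 1))
        )
        raw[k] = cross_val_score(clf, Xw, y, cv=cv, scoring="accuracy").mean()
        accs = []
        for _ in range(n_surrogates):
            yp = rng.permutation(y)
            cv1 = StratifiedKFold(
                n_splits=5, shuffle=True,
                random_state=int(rng.integers(2 ** 31 - 1)),
            )
            accs.append(cross_val_score(clf, Xw, yp, cv=cv1, scoring="accuracy").mean())
        surro[k] = float(np.mean(accs))
    return DecodingResult(
        accuracy_per_window=raw - surro,
        raw_accuracy=raw,
        surrogate_mean=surro,
        window_centers=centers,
        n_neurons_used=len(subset),
        n_surrogates=n_surrogates,
    )
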