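"""Session-level convenience wrappers tying the analysis modules together.

These functions take a :class:`~latewave.session_io.Session` and run one
analysis end-to-end with the standard parameter choices: 25-ms analysis
bins for coding time courses, 100-ms-SD smoothing for noise correlations,
the {A,B}/{C,D} orientation grouping, and the per-context inclusion
filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popstats import (
    DecodingResult,
    NCResult,
    decode_orientation,
    noise_correlations,
    residual_rates,
)
from .rates import compute_rates, session_average_rate
from .roc import AUCSeries, auc_timecourse
from .session_io import Session

__all__ = [
    "rebin",
    "orientation_pairs",
    "session_auc_series",
    "session_noise_correlations",
    "session_decoding",
]


def rebin(values: np.ndarray, times: np.ndarray, width: float, bin_width: float = 0.01):
    """Average fine bins into coarser analysis bins (e.g. 10 ms -> 25 ms)."""
    f = int(round(width / bin_width))
    n = (values.shape[-1] // f) * f
    v = values[..., :n].reshape(*values.shape[:-1], n // f, f).mean(axis=-1)
    return v, times[:n:f]


def orientation_pairs(trials: pd.DataFrame, visual_set_values) -> np.ndarray:
    """Label each trial's post-change feature as pair "AB" or "CD"."""
    vals = np.asarray(visual_set_values, dtype=float)
    post = trials["post_feature"].to_numpy(float)
    d = np.abs(np.mod(vals[None, :] - post[:, None] + 180.0, 360.0) - 180.0)
    return np.where(np.argmin(d, axis=1) < 2, "AB", "CD")


def _label_trials(session: Session, variable: str, saliency: str | None):
    trials = session.trials
    vset = session.manifest.get("visual_set", [100.0, 107.0, 190.0, 197.0])
    if variable == "orientation":
        sel = trials["trial_type"] == "visual"
        if saliency:
            sel &= trials["saliency"] == saliency
        sub = trials[sel].reset_index(drop=True)
        labels = (orientation_pairs(sub, vset) == "AB").astype(int)
    elif variable == "occurrence":
        sel = (trials["trial_type"] == "visual") | (trials["trial_type"] == "catch")
        if saliency:
            sel &= (trials["saliency"] == saliency) | (trials["trial_type"] == "catch")
        sub = trials[sel].reset_index(drop=True)
        labels = (sub["trial_type"] == "visual").astype(int).to_numpy()
    elif variable == "hitmiss":
        sel = (trials["trial_type"] == "visual") & trials["outcome"].isin(["hit", "miss"])
        if saliency:
            sel &= trials["saliency"] == saliency
        sub = trials[sel].reset_index(drop=True)
        labels = (sub["outcome"] == "hit").astype(int).to_numpy()
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return sub, labels


def session_auc_series(
    session: Session,
    variable: str = "hitmiss",
    saliency: str | None = None,
    window: tuple[float, float] = (-0.5, 1.0),
    bin_width: float = 0.025,
    kernel_sd: float = 0.01,
    n_shuffles: int = 1000,
    seed: int = 0,
    min_per_class: int = 10,
) -> list[AUCSeries]:
    """Per-neuron AUC time courses for one coding variable.

    Rates are smoothed with a 10-ms-SD causal kernel and averaged into
    25-ms analysis bins.  Neurons whose comparison lacks 10 trials per
    class are skipped (here: the whole session is, since trial counts are
    shared across neurons).
    """
    sub, labels = _label_trials(session, variable, saliency)
    if min(labels.sum(), len(labels) - labels.sum()) < min_per_class:
        return []
    tensor = compute_rates(
        session.spikes, sub["change_time"].to_numpy(), window=window,
        kernel_sd=kernel_sd, neuron_ids=list(session.neurons["neuron_id"]),
        bin_width=bin_width,
    )
    v, t = tensor.values, tensor.times
    out = []
    for i in range(v.shape[0]):
        out.append(
            auc_timecourse(
                v[i], labels, times=t, n_shuffles=n_shuffles,
                seed=seed + i, variable=variable, saliency=saliency or "",
            )
        )
    return out


def session_noise_correlations(
    session: Session,
    align: str = "stim",
    window: tuple[float, float] = (-1.0, 1.5),
    kernel_sd: float = 0.1,
    min_rate_hz: float = 1.0,
) -> NCResult:
    """Stimulus- or lick-aligned pairwise noise correlations for a session.

    Neurons below 1 Hz session-average rate are excluded; residuals remove
    the per-orientation (or lick-aligned) mean time course.
    """
    span = session.span
    keep = [
        nid
        for nid in session.neurons["neuron_id"]
        if session_average_rate(session.spikes, nid, span) > min_rate_hz
    ]
    vis = session.trials[session.trials["trial_type"] == "visual"].reset_index(drop=True)
    if align == "stim":
        events = vis["change_time"].to_numpy()
        conditions = vis["post_feature"].to_numpy()
        align_name = "stimulus_change"
    elif align == "lick":
        resp = vis.dropna(subset=["reaction_time"])
        events = (resp["change_time"] + resp["reaction_time"]).to_numpy()
        conditions = np.zeros(len(resp))
        align_name = "first_lick"
    else:
        raise ValueError(f"unknown alignment {align!r}")
    tensor = compute_rates(
        session.spikes, events, window=window, kernel_sd=kernel_sd, neuron_ids=keep,
        align_event=align_name,
    )
    resid, _ = residual_rates(tensor.values, conditions)
    return noise_correlations(resid, tensor.times, align=align_name)


def session_decoding(
    session: Session,
    window: float = 0.2,
    step: float = 0.05,
    trange: tuple[float, float] = (-0.5, 1.0),
    n_trees: int = 200,
    n_surrogates: int = 50,
    seed: int = 0,
    **kw,
) -> DecodingResult:
    """Random-forest orientation-pair decoding for one session."""
    vis = session.trials[session.trials["trial_type"] == "visual"].reset_index(drop=True)
    vset = session.manifest.get("visual_set", [100.0, 107.0, 190.0, 197.0])
    pair = orientation_pairs(vis, vset)
    tensor = compute_rates(
        session.spikes, vis["change_time"].to_numpy(), window=trange,
        kernel_sd=0.0, neuron_ids=list(session.neurons["neuron_id"]),
    )
    counts = tensor.values * 0.01  # back to counts per 10-ms bin
    return decode_orientation(
        counts, pair, tensor.times, seed=seed, window=window, step=step,
        n_trees=n_trees, n_surrogates=n_surrogates, **kw,
    )
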