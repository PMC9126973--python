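"""Smoothed, aligned, z-scored firing-rate tensors and neuron classification.

Spikes are binned at 10 ms and convolved with a *causal* half-Gaussian
kernel (default SD 50 ms, mass 1), so no rate estimate leaks information
from future bins.  Rates are z-scored against the pre-stimulus baseline
(-1 to -0.2 s).  Cell types are classified from the waveform peak-to-trough
delay (narrow < 0.45 ms, broad > 0.55 ms, capped at 1 ms) and laminar zones
from cortical depth (granular layer = 400-550 um from the dura).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "RateTensor",
    "compute_rates",
    "zscore_rates",
    "classify_celltype",
    "assign_layer",
    "inclusion_filters",
    "session_average_rate",
    "stability_ok",
]

BIN_WIDTH = 0.01  # s


@dataclass
class RateTensor:
    """neurons x trials x bins firing rates with alignment metadata.

    ``values`` are Hz (or z-units after :func:`zscore_rates`); ``times``
    are bin-start offsets from the alignment event; bins tile
    [window[0], window[1]) exactly.
    """

    values: np.ndarray
    neuron_ids: list
    times: np.ndarray
    align_event: str
    kernel_sd: float
    window: tuple[float, float]
    units: str = "hz"
    excluded_neurons: list = None

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def bin_slice(self, start: float, end: float) -> np.ndarray:
        """Boolean mask over bins whose start lies in [start, end)."""
        return (self.times >= start) & (self.times < end)


def _causal_half_gaussian(sd: float, bin_width: float = BIN_WIDTH, n_sd: float = 4.0):
    """Discrete causal half-Gaussian kernel, truncated at 4 SD, mass 1."""
    n = max(int(np.ceil(n_sd * sd / bin_width)), 1)
    t = np.arange(n + 1) * bin_width
    w = np.exp(-0.5 * (t / sd) ** 2)
    return w / w.sum()


def compute_rates(
    spikes: pd.DataFrame,
    events: np.ndarray,
    window: tuple[float, float],
    kernel_sd: float = 0.05,
    neuron_ids: list | None = None,
    align_event: str = "stimulus_change",
    pad: float | None = None,
    bin_width: float = BIN_WIDTH,
) -> RateTensor:
    """Event-aligned smoothed firing rates.

    Parameters
    ----------
    spikes : DataFrame with neuron_id and time_s columns.
    events : alignment times (s, session clock), one per trial.
    window : (start, end) s relative to the event, half-open.
    kernel_sd : SD of the causal half-Gaussian in seconds (0 disables
        smoothing and returns binned counts / bin width).
    pad : extra pre-window padding used so smoothing at the window edge
        sees the preceding spikes; defaults to the kernel support.

    Counts are taken in 10-ms bins and convolved with the causal kernel,
    so the rate at bin t depends only on spikes at or before t.
    """
    events = np.asarray(events, dtype=float)
    if neuron_ids is None:
        neuron_ids = sorted(spikes["neuron_id"].unique())
    kernel = (
        _causal_half_gaussian(kernel_sd, bin_width) if kernel_sd > 0 else np.array([1.0])
    )
    if pad is None:
        pad = (len(kernel) - 1) * bin_width
    n_pad = int(round(pad / bin_width))
    start, end = window
    n_bins = int(round((end - start) / bin_width))
    # integer bin grid so that a bin edge falls exactly on t = 0
    i0 = int(round(start / bin_width))
    edges = (np.arange(n_bins + n_pad + 1) + i0 - n_pad) * bin_width

    grouped = {nid: grp["time_s"].to_numpy() for nid, grp in spikes.groupby("neuron_id")}
    values = np.zeros((len(neuron_ids), len(events), n_bins))
    for i, nid in enumerate(neuron_ids):
        st = grouped.get(nid, np.empty(0))
        for j, ev in enumerate(events):
            counts, _ = np.histogram(st, bins=ev + edges)
            rate = lfilter(kernel, [1.0], counts / bin_width)
            values[i, j] = rate[n_pad:]
    times = (np.arange(n_bins) + i0) * bin_width
    return RateTensor(
        values=values, neuron_ids=list(neuron_ids), times=times,
        align_event=align_event, kernel_sd=kernel_sd, window=window,
    )


def zscore_rates(
    tensor: RateTensor, baseline: tuple[float, float] = (-1.0, -0.2)
) -> RateTensor:
    """Z-score each neuron against its pre-stimulus baseline.

    The baseline mean and SD are taken over all trials x baseline bins.
    Neurons with zero baseline SD are flagged (listed in
    ``excluded_neurons``) and their rows set to NaN.
    """
    mask = tensor.bin_slice(*baseline)
    if not mask.any():
        raise ValueError(f"window {tensor.window} does not include baseline {baseline}")
    base = tensor.values[:, :, mask]
    mu = base.mean(axis=(1, 2), keepdims=True)
    sd = base.std(axis=(1, 2), keepdims=True)
    flat = sd[:, 0, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (tensor.values - mu) / sd_safe
    z[flat] = np.nan
    return replace(
        tensor,
        values=z,
        units="z",
        excluded_neurons=[tensor.neuron_ids[i] for i in np.nonzero(flat)[0]],
    )


def classify_celltype(peak_to_trough_ms: float) -> str:
    """Narrow- vs broad-spiking classification from the waveform.

    Peak-to-trough delay < 0.45 ms -> "narrow" (putative inhibitory),
    > 0.55 ms -> "broad" (putative excitatory), else "unclassified".
    Input values are capped at 1 ms upstream.
    """
    v = float(peak_to_trough_ms)
    if not 0 < v <= 1.0:
        raise ValueError("peak-to-trough must be in (0, 1] ms (capped at 1)")
    if v < 0.45:
        return "narrow"
    if v > 0.55:
        return "broad"
    return "unclassified"


def assign_layer(depth_um: float) -> str:
    """Laminar zone from cortical depth: SG < 400 um <= G <= 550 um < IG."""
    d = float(depth_um)
    if d < 0:
        raise ValueError("depth must be nonnegative")
    if d < 400:
        return "SG"
    if d <= 550:
        return "G"
    return "IG"


def session_average_rate(spikes: pd.DataFrame, neuron_id, span: tuple[float, float]) -> float:
    """Whole-session mean firing rate of one neuron in Hz."""
    t0, t1 = span
    st = spikes.loc[spikes["neuron_id"] == neuron_id, "time_s"]
    return float(((st >= t0) & (st < t1)).sum() / (t1 - t0))


def stability_ok(
    spike_times: np.ndarray, span: tuple[float, float], n_bins: int = 100, min_bins: int = 90
) -> bool:
    """Neuron is stably present if it spikes in >= 90 of 100 session bins."""
    counts, _ = np.histogram(spike_times, bins=np.linspace(span[0], span[1], n_bins + 1))
    return int((counts > 0).sum()) > min_bins


def inclusion_filters(
    context: str,
    *,
    session_rate_hz: float | None = None,
    z_tensor: RateTensor | None = None,
    neuron_index: int | None = None,
    stimulus_epoch: tuple[float, float] = (0.0, 1.0),
    n_trials_per_condition: int | None = None,
    spike_times: np.ndarray | None = None,
    span: tuple[float, float] | None = None,
) -> bool:
    """Context-dependent neuron inclusion rules.

    * ``glm``: session-average rate > 0.5 Hz;
    * ``nc``: session-average rate > 1 Hz;
    * ``responsive``: mean z-scored rate exceeds 2 at some stimulus-epoch
      bin (any visual condition), with at least 3 trials per condition;
    * ``stability``: spikes in more than 90 of 100 session time bins.
    """
    if context == "glm":
        return float(session_rate_hz) > 0.5
    if context == "nc":
        return float(session_rate_hz) > 1.0
    if context == "responsive":
        if n_trials_per_condition is not None and n_trials_per_condition < 3:
            return False
        mask = z_tensor.bin_slice(*stimulus_epoch)
        z = z_tensor.values[neuron_index][:, mask]
        return bool(np.nanmax(np.nanmean(z, axis=0)) > 2.0)
    if context == "stability":
        counts, _ = np.histogram(spike_times, bins=np.linspace(span[0], span[1], 101))
        return int((counts > 0).sum()) > 90
    raise ValueError(f"unknown inclusion context {context!r}")
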