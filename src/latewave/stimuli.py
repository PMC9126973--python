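"""Audiovisual stimulus space and trial-sequence generation for the change-detection task.

The task presents a continuous audiovisual stream: a full-field drifting
grating whose orientation occasionally changes (visual trials) and a
harmonic "Shepard" complex tone whose frequency content occasionally
changes (auditory trials).  Both stimulus spaces are circular, so the only
behaviorally relevant dimension is the *amount* of change, not its
direction.  This module constructs the stimuli symbolically (orientations
in degrees; tones as harmonic frequencies plus weights) and samples trial
sequences with the task's statistics: block-shuffled trial types, truncated
exponential inter-trial intervals, and a bias-correction rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ShepardStimulus",
    "StimulusSet",
    "make_shepard",
    "make_stimulus_set",
    "sample_trial_sequence",
    "apply_bias_rule",
    "circular_distance",
    "TRIAL_TYPE_PROPORTIONS",
]

#: Long-run trial-type mix: 10% catch, 41% visual, 41% auditory, 8% multimodal.
TRIAL_TYPE_PROPORTIONS = {
    "catch": 0.10,
    "visual": 0.41,
    "auditory": 0.41,
    "multimodal": 0.08,
}

#: Center of the fixed Gaussian weight profile, in octaves (log2 Hz).
SHEPARD_WEIGHT_CENTER = 13.5

#: Maximal change per modality: 90 deg orientation, 1/2 octave frequency.
MAX_CHANGE = {"visual": 90.0, "auditory": 0.5}


@dataclass(frozen=True)
class ShepardStimulus:
    """A five-tone harmonic complex named by its center tone.

    Harmonics sit at octave spacings around the center tone
    (f/4, f/2, f, 2f, 4f).  Tone weights are evaluations of a fixed
    Gaussian over log2-frequency centered at 2^13.5 Hz, renormalized to
    sum to one; because the weight profile is fixed while the center tone
    moves, the stimulus space is circular on one octave.
    """

    center_exponent: float
    harmonic_frequencies: tuple[float, ...]
    weights: tuple[float, ...]

    @property
    def center_hz(self) -> float:
        return 2.0 ** self.center_exponent


@dataclass(frozen=True)
class StimulusSet:
    """Four stimulus values A, B, C, D used in a recording session.

    AB and CD are separated by the animal's threshold change; AC and BD by
    the maximal change (90 deg or half an octave).  For the visual modality
    values are orientations in degrees (mod 360); for the auditory modality
    they are center-tone exponents in octaves.
    """

    modality: str
    A: float
    B: float
    C: float
    D: float
    threshold_change: float
    maximal_change: float

    def values(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)


def make_shepard(center_exponent: float, weight_sigma: float = 1.0) -> ShepardStimulus:
    """Build the five-tone Shepard stimulus for a given center exponent.

    Parameters
    ----------
    center_exponent : float
        Octave exponent of the center tone (log2 of its frequency in Hz);
        must lie in [13, 14], the octave the task uses.
    weight_sigma : float
        Standard deviation (octaves) of the fixed Gaussian weight profile.

    Returns
    -------
    ShepardStimulus with frequencies ``2**(center_exponent + k)`` for
    k = -2..2 and weights normalized to sum to 1.
    """
    if not 13.0 <= center_exponent <= 14.0:
        raise ValueError(
            f"center_exponent must be in [13, 14] octaves, got {center_exponent}"
        )
    if weight_sigma <= 0:
        raise ValueError("weight_sigma must be positive")
    ks = np.arange(-2, 3)
    exponents = center_exponent + ks
    freqs = 2.0 ** exponents
    w = np.exp(-0.5 * ((exponents - SHEPARD_WEIGHT_CENTER) / weight_sigma) ** 2)
    w /= w.sum()
    return ShepardStimulus(
        center_exponent=float(center_exponent),
        harmonic_frequencies=tuple(float(f) for f in freqs),
        weights=tuple(float(x) for x in w),
    )


def circular_distance(a: float, b: float, period: float = 360.0) -> float:
    """Smallest absolute distance between two angles on a circle."""
    d = np.mod(np.asarray(b) - np.asarray(a), period)
    return float(np.minimum(d, period - d))


def make_stimulus_set(
    modality: str, base_feature: float, threshold_change: float
) -> StimulusSet:
    """Construct the session's four-stimulus set from a threshold.

    A is the base feature, B = A + threshold, C = A + maximal change,
    D = C + threshold.  Visual arithmetic is modulo 360 degrees.
    """
    if modality not in ("visual", "auditory"):
        raise ValueError(f"unknown modality {modality!r}")
    maximal = MAX_CHANGE[modality]
    if not 0 < threshold_change < maximal:
        raise ValueError(
            f"threshold_change must be in (0, {maximal}), got {threshold_change}"
        )
    A = float(base_feature)
    B = A + threshold_change
    C = A + maximal
    D = C + threshold_change
    if modality == "visual":
        B, C, D = B % 360.0, C % 360.0, D % 360.0
        A = A % 360.0
    return StimulusSet(
        modality=modality,
        A=A,
        B=B,
        C=C,
        D=D,
        threshold_change=float(threshold_change),
        maximal_change=maximal,
    )


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n trials to the type proportions."""
    names = list(proportions)
    exact = np.array([proportions[k] * n for k in names])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(remainder)[::-1][: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


def sample_trial_sequence(
    n_trials: int,
    rng_seed: int | np.random.Generator = 0,
    visual_set: StimulusSet | None = None,
    auditory_set: StimulusSet | None = None,
    iti_mean: float = 6.0,
    iti_bounds: tuple[float, float] = (3.0, 20.0),
    photostim_fraction: float = 0.0,
    proportions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sample a task-A trial sequence (stimuli only, no choices).

    Trial types are block-shuffled per 10 trials at the 10/41/41/8 percent
    mix.  Inter-change intervals are exponential with the given pre-truncation
    mean, rejected outside [3, 20] s.  Change trials draw saliency
    (threshold or maximal, 50/50) and jump between the stimulus-set values:
    threshold changes swap A<->B or C<->D, maximal changes swap A<->C or
    B<->D, tracking the stream's current feature per modality.

    When ``photostim_fraction`` is positive, that fraction of trials is
    assigned photostimulation, split evenly between early (from change
    onset) and late (from 200 ms after the change).

    Returns a trials table with columns: trial_index (1-based), trial_type,
    pre_feature, post_feature, saliency, change_time, photostim.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    props = dict(proportions or TRIAL_TYPE_PROPORTIONS)
    counts = _allocate_counts(n_trials, props)
    pool = np.array(
        sum(([k] * v for k, v in counts.items()), []), dtype=object
    )
    # interleave types evenly, then shuffle within consecutive blocks of 10
    order = np.argsort(rng.random(n_trials))
    pool = pool[order]
    for start in range(0, n_trials, 10):
        block = pool[start : start + 10]
        rng.shuffle(block)
        pool[start : start + 10] = block

    if visual_set is None:
        visual_set = make_stimulus_set("visual", 100.0, 7.0)
    if auditory_set is None:
        auditory_set = make_stimulus_set("auditory", 13.25, 1.0 / 32.0)
    sets = {"visual": visual_set, "auditory": auditory_set}

    # current feature index per modality into (A, B, C, D)
    state = {"visual": 0, "auditory": 0}
    # threshold jumps: A<->B (0<->1), C<->D (2<->3); max jumps: A<->C, B<->D
    jump = {"thr": {0: 1, 1: 0, 2: 3, 3: 2}, "max": {0: 2, 2: 0, 1: 3, 3: 1}}

    lo, hi = iti_bounds
    rows = []
    t = 0.0
    for i, ttype in enumerate(pool):
        while True:
            iti = rng.exponential(iti_mean)
            if lo <= iti <= hi:
                break
        t += iti
        pre_v = sets["visual"].values()[state["visual"]]
        pre_a = sets["auditory"].values()[state["auditory"]]
        if ttype == "catch":
            saliency, pre, post = "none", np.nan, np.nan
        else:
            saliency = "thr" if rng.random() < 0.5 else "max"
            mods = ["visual", "auditory"] if ttype == "multimodal" else [ttype]
            for m in mods:
                state[m] = jump[saliency][state[m]]
            m0 = mods[0]
            pre = pre_v if m0 == "visual" else pre_a
            post = sets[m0].values()[state[m0]]
        if photostim_fraction > 0 and rng.random() < photostim_fraction:
            photostim = "early" if rng.random() < 0.5 else "late"
        else:
            photostim = "none"
        rows.append(
            dict(
                trial_index=i + 1,
                trial_type=ttype,
                pre_feature=pre,
                post_feature=post,
                saliency=saliency,
                change_time=t,
                photostim=photostim,
            )
        )
    return pd.DataFrame(rows)


def apply_bias_rule(
    recent_choices: list[str],
    candidate_type: str,
    rng: np.random.Generator,
    switch_prob: float = 0.95,
    bias_threshold: float = 0.90,
) -> str:
    """Bias-correction rule on the upcoming trial's modality.

    If, over the last 10 trials, the fraction of licks to one spout out of
    all licks is strictly above 90%, the next trial is selected with 95%
    probability to be of the other modality (left spout = visual,
    right spout = auditory).  Otherwise the candidate type stands.
    """
    licks = [c for c in recent_choices[-10:] if c in ("left", "right")]
    if not licks:
        return candidate_type
    frac_left = licks.count("left") / len(licks)
    if frac_left > bias_threshold:
        other = "auditory"
    elif 1.0 - frac_left > bias_threshold:
        other = "visual"
    else:
        return candidate_type
    if rng.random() < switch_prob:
        return other
    return candidate_type
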