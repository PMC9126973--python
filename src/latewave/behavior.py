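"""Behavioral models for the audiovisual change-detection task.

Three models cover the behavior:

* a cumulative-normal psychometric function with guess (false-alarm) and
  lapse rates, fitted per modality to response rates across saliency levels;
* a multi-alternative signal-detection (m-ADC) model in which a bivariate
  standard-normal decision variable carries evidence for each modality, the
  stimulated modality's axis is shifted by d', and the animal reports
  modality *m* iff its evidence exceeds the criterion c_m and exceeds the
  other modality's criterion-referenced evidence;
* a multinomial logistic side-detection model (for the visuotactile task)
  with saturating stimulus-intensity terms.

All fitted models follow the Model -> Results convention: construct a model
from data, call ``fit()``, inspect the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "cumnorm_psychometric",
    "PsychometricModel",
    "PsychometricResults",
    "madc_rates",
    "MADCModel",
    "MADCResults",
    "fit_madc",
    "hyperbolic_dprime",
    "dprime_from_rates",
    "MNLogitFit",
    "mnlogit_probs",
    "MNLogitModel",
    "response_table",
    "insert_artificial_catch",
    "session_filters",
    "silencing_effect",
]


# ---------------------------------------------------------------------------
# cumulative-normal psychometric (guess + lapse)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricFit:
    """Parameters of the four-parameter cumulative-normal psychometric.

    gamma is the false-alarm (guess) rate, lambda_ the lapse rate, mu the
    perceptual threshold and sigma the slope, both in stimulus units.
    """

    gamma: float
    lambda_: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not (0 <= self.gamma <= 1 and 0 <= self.lambda_ <= 1):
            raise ValueError("gamma and lambda_ must lie in [0, 1]")
        if self.gamma + self.lambda_ >= 1:
            raise ValueError("gamma + lambda_ must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def saliency_levels(self) -> dict[str, float]:
        """Fixed points along the curve: sub = mu - sigma, thr = mu, sup = mu + sigma."""
        return {"sub": self.mu - self.sigma, "thr": self.mu, "sup": self.mu + self.sigma}


def cumnorm_psychometric(x, fit: PsychometricFit):
    """Response probability gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma)."""
    z = (np.asarray(x, dtype=float) - fit.mu) / fit.sigma
    return fit.gamma + (1.0 - fit.gamma - fit.lambda_) * stats.norm.cdf(z)


class PsychometricModel:
    """Binomial maximum-likelihood fit of the cumulative-normal psychometric.

    Parameters
    ----------
    x_levels : array of stimulus change magnitudes (>= 4 distinct levels).
    n_resp, n_total : response counts and trial counts per level.
    """

    def __init__(self, x_levels, n_resp, n_total):
        self.x = np.asarray(x_levels, dtype=float)
        self.n_resp = np.asarray(n_resp, dtype=float)
        self.n_total = np.asarray(n_total, dtype=float)
        if len(np.unique(self.x)) < 4:
            raise ValueError("need at least 4 distinct stimulus levels")
        if np.any(self.n_resp > self.n_total):
            raise ValueError("response counts exceed trial counts")

    def loglike(self, params) -> float:
        g, l, mu, s = params
        p = g + (1 - g - l) * stats.norm.cdf((self.x - mu) / s)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(self.n_resp * np.log(p) + (self.n_total - self.n_resp) * np.log1p(-p)))

    def fit(self, n_restarts: int = 10, seed: int = 0) -> "PsychometricResults":
        rng = np.random.default_rng(seed)
        xspan = self.x.max() - self.x.min()
        bounds = [
            (0.0, 0.5),
            (0.0, 0.5),
            (self.x.min(), self.x.max()),
            (max(1e-3 * xspan, 1e-6), 2 * xspan),
        ]
        best = None
        for i in range(n_restarts):
            if i == 0:
                x0 = [0.1, 0.05, float(np.median(self.x)), 0.3 * xspan]
            else:
                x0 = [rng.uniform(lo, hi) for lo, hi in bounds]
            res = optimize.minimize(
                lambda p: -self.loglike(p), x0, bounds=bounds, method="L-BFGS-B"
            )
            if best is None or res.fun < best.fun:
                best = res
        g, l, mu, s = best.x
        converged = bool(best.success)
        return PsychometricResults(
            model=self,
            params=PsychometricFit(gamma=g, lambda_=l, mu=mu, sigma=s),
            loglike=-float(best.fun),
            converged=converged,
        )


@dataclass
class PsychometricResults:
    model: PsychometricModel
    params: PsychometricFit
    loglike: float
    converged: bool

    def predict(self, x):
        return cumnorm_psychometric(x, self.params)

    @property
    def saliency_levels(self):
        return self.params.saliency_levels

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cumulative-normal psychometric fit",
            "-" * 42,
            f"gamma (false-alarm rate) {p.gamma:10.4f}",
            f"lambda (lapse rate)      {p.lambda_:10.4f}",
            f"mu (threshold)           {p.mu:10.4f}",
            f"sigma (slope)            {p.sigma:10.4f}",
            f"log-likelihood           {self.loglike:10.2f}",
            f"converged                {self.converged!s:>10}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# multi-alternative signal detection (m-ADC)
# ---------------------------------------------------------------------------

_MODALITIES = ("visual", "auditory")


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


def madc_rates(
    d_visual: float,
    d_auditory: float,
    c_visual: float,
    c_auditory: float,
    n_grid: int = 1001,
) -> pd.DataFrame:
    """Response-probability table of the two-alternative detection model.

    Evidence (Psi_v, Psi_a) is independent standard normal, with the
    stimulated modality's mean shifted by its d'.  The observer responds
    to modality m iff Psi_m >= c_m and Psi_m - c_m >= Psi_other - c_other.
    Each probability is computed by 1-D numerical integration over Psi_m,
    vectorized over the six (trial type, response) cells.

    Returns a 3x3 DataFrame: rows = trial type (visual, auditory, catch),
    columns = response (visual, auditory, none); rows sum to 1.
    """
    if d_visual < 0 or d_auditory < 0:
        raise ValueError("d-prime values must be nonnegative")
    # six cells: (d of responded modality, d of other, c of responded, c of other)
    dm = np.array([d_visual, 0.0, 0.0, d_auditory, 0.0, 0.0])
    do = np.array([0.0, d_visual, 0.0, 0.0, d_auditory, 0.0])
    cm = np.array([c_visual, c_auditory, c_visual, c_auditory, c_visual, c_auditory])
    co = np.array([c_auditory, c_visual, c_auditory, c_visual, c_auditory, c_visual])
    hi = np.maximum(cm, dm) + 8.0
    u = np.linspace(0.0, 1.0, n_grid)[None, :]
    psi = cm[:, None] + (hi - cm)[:, None] * u
    from scipy.special import ndtr

    integrand = _norm_pdf(psi - dm[:, None]) * ndtr(psi - (cm - co + do)[:, None])
    p = np.trapezoid(integrand, psi, axis=1)
    # cells: [P(v|vis), P(a|vis), P(v|catch)... ] laid out per trial type below
    pv_vis, pa_vis = p[0], p[1]
    pa_aud, pv_aud = p[3], p[4]
    pv_cat, pa_cat = p[2], p[5]
    rows = {
        "visual": [pv_vis, pa_vis, max(0.0, 1.0 - pv_vis - pa_vis)],
        "auditory": [pv_aud, pa_aud, max(0.0, 1.0 - pv_aud - pa_aud)],
        "catch": [pv_cat, pa_cat, max(0.0, 1.0 - pv_cat - pa_cat)],
    }
    return pd.DataFrame(rows, index=["visual", "auditory", "none"]).T


def hyperbolic_dprime(x, d_max: float, n: float, s50: float):
    """Hyperbolic saturation of d' with stimulus strength: d_max * x^n / (x^n + s50^n)."""
    x = np.asarray(x, dtype=float)
    xn = np.power(np.maximum(x, 0.0), n)
    return d_max * xn / (xn + s50 ** n)


def response_table(
    trials: pd.DataFrame, visual_spout: str = "left"
) -> pd.DataFrame:
    """Tabulate response counts per (trial_type, saliency) from a trials table.

    Maps lick sides to modality responses (visual spout vs auditory spout).
    Multimodal (conflict) trials are excluded, as they are from all fits.
    Returns a DataFrame with columns trial_type, saliency, x (amount of
    change, NaN for catch), n_visual, n_auditory, n_none.
    """
    auditory_spout = "right" if visual_spout == "left" else "left"
    t = trials[trials["trial_type"].isin(["visual", "auditory", "catch"])]
    rows = []
    for (ttype, sal), grp in t.groupby(["trial_type", "saliency"], dropna=False):
        choice = grp["choice"].fillna("none")
        x = np.nan
        if "change_magnitude" in grp.columns and ttype != "catch":
            x = float(grp["change_magnitude"].iloc[0])
        rows.append(
            dict(
                trial_type=ttype,
                saliency=sal,
                x=x,
                n_visual=int((choice == visual_spout).sum()),
                n_auditory=int((choice == auditory_spout).sum()),
                n_none=int((choice == "none").sum()),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class MADCResults:
    """Fitted m-ADC parameters.

    For the two-level variant, ``dprime`` maps (modality, saliency) to d';
    for the hyperbolic variant, ``psychometric`` maps modality to
    (d_max, n, s50) and ``dprime`` holds the implied per-level d'.
    """

    variant: str
    criterion: dict
    dprime: dict
    psychometric: dict | None
    loglike: float
    n_trials: int
    valid: bool
    invalid_reason: str | None = None
    criterion_by_level: dict | None = None

    def summary(self) -> str:
        lines = [f"m-ADC fit ({self.variant} variant), n={self.n_trials}", "-" * 46]
        for m in _MODALITIES:
            lines.append(f"criterion c_{m:<9} {self.criterion[m]:8.3f}")
        if self.psychometric:
            for m in _MODALITIES:
                dm, n, s50 = self.psychometric[m]
                lines.append(f"{m}: d_max={dm:.3f} n={n:.3f} s50={s50:.4g}")
        for key, val in sorted(self.dprime.items()):
            lines.append(f"d'({key[0]}, {key[1]:<4}) {val:8.3f}")
        lines.append(f"log-likelihood {self.loglike:.2f}  valid={self.valid}")
        if self.invalid_reason:
            lines.append(f"  flagged: {self.invalid_reason}")
        return "\n".join(lines)


class MADCModel:
    """Multinomial maximum-likelihood fit of the m-ADC model to response counts.

    Parameters
    ----------
    counts : DataFrame as produced by :func:`response_table` (must include a
        catch row; the criterion is unidentifiable without one).
    variant : "two-level" fits one d' per modality per saliency level with a
        shared criterion per modality (the paper's 4-parameter-per-level
        form); "hyperbolic" constrains d'(x) to the saturating hyperbolic
        function of change magnitude x (8 parameters in total) and requires
        an ``x`` column.
    """

    def __init__(self, counts: pd.DataFrame, variant: str = "two-level"):
        if variant not in ("two-level", "hyperbolic"):
            raise ValueError(f"unknown variant {variant!r}")
        if not (counts["trial_type"] == "catch").any():
            raise ValueError("catch trials are required (criterion unidentifiable)")
        self.counts = counts.reset_index(drop=True)
        self.variant = variant
        self.saliencies = sorted(
            s
            for s in counts.loc[counts["trial_type"] != "catch", "saliency"].unique()
        )

    # -- likelihood -------------------------------------------------------

    @staticmethod
    def _nll_block(block: dict[str, np.ndarray], dv, da, cv, ca) -> float:
        table = madc_rates(dv, da, cv, ca)
        nll = 0.0
        for ttype, cnt in block.items():
            dvv, daa = (dv, 0.0) if ttype == "visual" else (0.0, da)
            if ttype == "catch":
                dvv = daa = 0.0
            p = np.clip(table.loc[ttype].to_numpy(), 1e-12, 1.0)
            nll -= float(cnt @ np.log(p))
        return nll

    def _blocks(self):
        """Counts arrays keyed by saliency: {sal: {trial_type: [nv, na, nn]}}."""
        out: dict = {}
        cols = ["n_visual", "n_auditory", "n_none"]
        catch = self.counts[self.counts["trial_type"] == "catch"][cols].sum().to_numpy(float)
        for sal in self.saliencies:
            sel = self.counts[
                (self.counts["saliency"] == sal) & (self.counts["trial_type"] != "catch")
            ]
            blk = {"catch": catch}
            for _, row in sel.iterrows():
                blk[row["trial_type"]] = row[cols].to_numpy(float)
            out[sal] = blk
        return out

    def fit(self, n_restarts: int = 10, seed: int = 0) -> MADCResults:
        rng = np.random.default_rng(seed)
        n_trials = int(
            self.counts[["n_visual", "n_auditory", "n_none"]].to_numpy().sum()
        )
        blocks = self._blocks()
        if self.variant == "two-level":
            return self._fit_two_level(blocks, rng, n_trials)
        return self._fit_hyperbolic(blocks, rng, n_trials)

    def _fit_two_level(self, blocks, rng, n_trials) -> MADCResults:
        # Independent 4-parameter fit (d_v, d_a, c_v, c_a) per saliency
        # level, each against that level's change trials plus the catch
        # trials.  Criteria per modality are also reported per level (in
        # ``criterion_by_level``); ``criterion`` averages across levels.
        sals = self.saliencies
        dprime: dict = {}
        crit_by_level: dict = {}
        loglike = 0.0
        ok = True
        bounds = [(-3.0, 5.0)] * 2 + [(0.0, 6.0)] * 2
        for sal in sals:
            blk = blocks[sal]

            def nll(theta, blk=blk):
                cv, ca, dv, da = theta
                return self._nll_block(blk, dv, da, cv, ca)

            best = self._multistart(nll, bounds, rng, n_restarts=10)
            cv, ca, dv, da = best.x
            dprime[("visual", sal)] = float(dv)
            dprime[("auditory", sal)] = float(da)
            crit_by_level[("visual", sal)] = float(cv)
            crit_by_level[("auditory", sal)] = float(ca)
            loglike += -float(best.fun)
            ok &= bool(best.success)
        criterion = {
            m: float(np.mean([crit_by_level[(m, s)] for s in sals]))
            for m in _MODALITIES
        }
        return MADCResults(
            variant="two-level",
            criterion=criterion,
            dprime=dprime,
            psychometric=None,
            loglike=loglike,
            n_trials=n_trials,
            valid=ok,
            criterion_by_level=crit_by_level,
        )

    def _fit_hyperbolic(self, blocks, rng, n_trials) -> MADCResults:
        sals = self.saliencies
        xs = {}
        for sal in sals:
            sel = self.counts[
                (self.counts["saliency"] == sal) & (self.counts["trial_type"] != "catch")
            ]
            for _, row in sel.iterrows():
                xs[(row["trial_type"], sal)] = float(row["x"])
        if any(np.isnan(v) for v in xs.values()):
            raise ValueError("hyperbolic variant needs change magnitudes (x)")
        xmax = {
            m: max(v for (t, s), v in xs.items() if t == m) for m in _MODALITIES
        }

        def nll(theta):
            cv, ca = theta[0], theta[1]
            dmv, nv, s50v, dma, na, s50a = theta[2:]
            total = 0.0
            for sal in sals:
                dv = float(hyperbolic_dprime(xs[("visual", sal)], dmv, nv, s50v))
                da = float(hyperbolic_dprime(xs[("auditory", sal)], dma, na, s50a))
                total += self._nll_block(blocks[sal], dv, da, cv, ca)
            if len(sals) > 1:
                table = madc_rates(0.0, 0.0, cv, ca)
                p = np.clip(table.loc["catch"].to_numpy(), 1e-12, 1.0)
                total += (len(sals) - 1) * float(blocks[sals[0]]["catch"] @ np.log(p))
            return total

        bounds = [(-3.0, 5.0)] * 2 + [
            (0.0, 8.0), (0.3, 6.0), (1e-4 * xmax["visual"], 2 * xmax["visual"]),
            (0.0, 8.0), (0.3, 6.0), (1e-4 * xmax["auditory"], 2 * xmax["auditory"]),
        ]
        best = self._multistart(nll, bounds, rng, n_restarts=10)
        cv, ca = best.x[0], best.x[1]
        dmv, nv, s50v, dma, na, s50a = best.x[2:]
        dprime = {
            (m, sal): float(
                hyperbolic_dprime(
                    xs[(m, sal)], *( (dmv, nv, s50v) if m == "visual" else (dma, na, s50a) )
                )
            )
            for m in _MODALITIES
            for sal in sals
            if (m, sal) in xs
        }
        valid, reason = True, None
        if not (1.0 <= s50v <= 45.0):
            valid, reason = False, f"implied visual threshold {s50v:.2f} deg outside [1, 45]"
        return MADCResults(
            variant="hyperbolic",
            criterion={"visual": float(cv), "auditory": float(ca)},
            dprime=dprime,
            psychometric={
                "visual": (float(dmv), float(nv), float(s50v)),
                "auditory": (float(dma), float(na), float(s50a)),
            },
            loglike=-float(best.fun),
            n_trials=n_trials,
            valid=valid,
            invalid_reason=reason,
        )

    @staticmethod
    def _multistart(nll, bounds, rng, n_restarts=10):
        best = None
        for i in range(n_restarts):
            x0 = np.array(
                [
                    (lo + hi) / 2 if i == 0 else rng.uniform(lo, hi)
                    for lo, hi in bounds
                ]
            )
            res = optimize.minimize(nll, x0, bounds=bounds, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        return best


def fit_madc(counts: pd.DataFrame, variant: str = "two-level", seed: int = 0) -> MADCResults:
    """Convenience wrapper: build an :class:`MADCModel` and fit it."""
    return MADCModel(counts, variant=variant).fit(seed=seed)


# ---------------------------------------------------------------------------
# d' from response rates (inverse-normal difference)
# ---------------------------------------------------------------------------

def dprime_from_rates(
    hit_rate: float, fa_rate: float, n_hit: int | None = None, n_fa: int | None = None
) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    Rates of exactly 0 or 1 are pulled in by the 1/(2N) correction, which
    requires the corresponding trial count.
    """
    def clip(r, n):
        if 0.0 < r < 1.0:
            return r
        if n is None:
            raise ValueError("rate of 0 or 1 needs a trial count for the 1/(2N) correction")
        return min(max(r, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    h = clip(float(hit_rate), n_hit)
    f = clip(float(fa_rate), n_fa)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


# ---------------------------------------------------------------------------
# multinomial logistic side-detection model (task B)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MNLogitFit:
    """Parameters of the saturating multinomial logistic choice model."""

    b_right: float
    b_left: float
    sL_right: float
    sR_right: float
    sL_left: float
    sR_left: float
    n_exp: float

    def __post_init__(self):
        if not 0 < self.n_exp <= 1:
            raise ValueError("saturation exponent n_exp must be in (0, 1]")


def mnlogit_probs(cL, cR, fit: MNLogitFit):
    """(p_left, p_right, p_nogo) from stimulus intensities on each side.

    Log-odds of each choice against no-go are linear in the saturated
    intensities cL^n and cR^n; probabilities are the softmax of the two
    log-odds and zero.
    """
    cL = np.asarray(cL, dtype=float)
    cR = np.asarray(cR, dtype=float)
    if np.any(cL < 0) or np.any(cR < 0):
        raise ValueError("stimulus intensities must be nonnegative")
    sL = np.power(cL, fit.n_exp)
    sR = np.power(cR, fit.n_exp)
    eta_r = fit.b_right + fit.sL_right * sL + fit.sR_right * sR
    eta_l = fit.b_left + fit.sL_left * sL + fit.sR_left * sR
    m = np.maximum(np.maximum(eta_r, eta_l), 0.0)
    zr, zl, z0 = np.exp(eta_r - m), np.exp(eta_l - m), np.exp(-m)
    denom = zr + zl + z0
    return zl / denom, zr / denom, z0 / denom


class MNLogitModel:
    """Maximum-likelihood fit of the side-detection choice model.

    Parameters
    ----------
    cL, cR : per-trial stimulus intensities (contrast / deflection angle).
    choice : per-trial choice in {"left", "right", "none"}.
    """

    def __init__(self, cL, cR, choice):
        self.cL = np.asarray(cL, dtype=float)
        self.cR = np.asarray(cR, dtype=float)
        choice = np.asarray(choice)
        self.y = np.select(
            [choice == "left", choice == "right"], [0, 1], default=2
        ).astype(int)

    def loglike(self, fit: MNLogitFit) -> float:
        pl, pr, p0 = mnlogit_probs(self.cL, self.cR, fit)
        p = np.stack([pl, pr, p0], axis=1)
        p = np.clip(p[np.arange(len(self.y)), self.y], 1e-12, 1.0)
        return float(np.log(p).sum())

    def fit(self, n_restarts: int = 10, seed: int = 0) -> "MNLogitResults":
        rng = np.random.default_rng(seed)
        bounds = [(-8, 8)] * 6 + [(0.05, 1.0)]

        def nll(theta):
            return -self.loglike(MNLogitFit(*theta))

        best = None
        for i in range(n_restarts):
            x0 = (
                np.array([-1, -1, 0.5, 0.5, 0.5, 0.5, 0.7])
                if i == 0
                else np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            )
            res = optimize.minimize(nll, x0, bounds=bounds, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        params = MNLogitFit(*best.x)
        return MNLogitResults(model=self, params=params, loglike=-float(best.fun),
                              converged=bool(best.success))


@dataclass
class MNLogitResults:
    model: MNLogitModel
    params: MNLogitFit
    loglike: float
    converged: bool

    def predict(self, cL, cR):
        return mnlogit_probs(cL, cR, self.params)

    def summary(self) -> str:
        p = self.params
        rows = [
            ("b_right", p.b_right), ("b_left", p.b_left),
            ("sL_right", p.sL_right), ("sR_right", p.sR_right),
            ("sL_left", p.sL_left), ("sR_left", p.sR_left),
            ("n_exp", p.n_exp),
        ]
        lines = ["Multinomial logistic side-detection fit", "-" * 40]
        lines += [f"{k:<10} {v:10.4f}" for k, v in rows]
        lines.append(f"log-likelihood {self.loglike:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# catch-trial insertion, session exclusion, silencing effect
# ---------------------------------------------------------------------------

def insert_artificial_catch(
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    rng: np.random.Generator,
    grace: float = 0.1,
    response_window: float = 1.5,
    iti_mean: float = 6.0,
    iti_bounds: tuple[float, float] = (3.0, 20.0),
    min_gap: float = 3.0,
    n_latency_bins: int = 5,
) -> pd.DataFrame:
    """Insert artificial catch trials into long inter-trial intervals.

    Candidate catch times are drawn from the session's inter-change-interval
    distribution (exponential, truncated) after each real change, accepted
    only if they leave ``min_gap`` seconds to the next real change, so that
    temporal expectation at the inserted times matches real trials.  Each
    inserted trial is labeled FA if a lick lands in its response window
    (after the grace period), else CR.  FA latencies are then subsampled so
    their distribution matches the hit reaction-time distribution
    (quantile-bin matching).

    Returns the trials table with inserted rows appended
    (``artificial=True``, trial_type="catch", outcome in {"FA", "CR"}).
    """
    lick_times = np.sort(np.asarray(licks["time_s"], dtype=float))
    change_times = np.sort(trials["change_time"].to_numpy(float))
    hit_rts = trials.loc[trials["outcome"] == "hit", "reaction_time"].dropna().to_numpy(float)

    inserted = []
    for t0, t1 in zip(change_times[:-1], change_times[1:]):
        t = t0
        while True:
            draw = rng.exponential(iti_mean)
            if not (iti_bounds[0] <= draw <= iti_bounds[1]):
                continue
            t = t + draw
            if t > t1 - min_gap:
                break
            i = np.searchsorted(lick_times, t + grace)
            has_lick = i < len(lick_times) and lick_times[i] <= t + response_window
            latency = float(lick_times[i] - t) if has_lick else np.nan
            inserted.append(
                dict(
                    trial_type="catch",
                    saliency="none",
                    change_time=float(t),
                    choice="none" if not has_lick else "spontaneous",
                    outcome="FA" if has_lick else "CR",
                    reaction_time=latency,
                    artificial=True,
                )
            )
    ins = pd.DataFrame(inserted)
    if len(ins) and len(hit_rts) >= n_latency_bins:
        ins = _match_fa_latencies(ins, hit_rts, rng, n_latency_bins)
    out = trials.copy()
    out["artificial"] = False
    if len(ins):
        out = pd.concat([out, ins], ignore_index=True, sort=False)
        out = out.sort_values("change_time", ignore_index=True)
    return out


def _match_fa_latencies(ins: pd.DataFrame, hit_rts, rng, n_bins: int) -> pd.DataFrame:
    """Subsample inserted FAs so their latencies match the hit RT histogram."""
    fa = ins[ins["outcome"] == "FA"]
    cr = ins[ins["outcome"] == "CR"]
    if len(fa) == 0:
        return ins
    edges = np.quantile(hit_rts, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    target = np.full(n_bins, 1.0 / n_bins)  # hits are uniform over own quantile bins
    fa_bins = np.clip(np.searchsorted(edges, fa["reaction_time"].to_numpy(float)) - 1, 0, n_bins - 1)
    counts = np.bincount(fa_bins, minlength=n_bins)
    with np.errstate(divide="ignore"):
        # scale so the most underrepresented matched bin is kept in full
        ratios = counts / target
        scale = ratios[counts > 0].min()
    keep_idx = []
    for b in range(n_bins):
        idx = fa.index[fa_bins == b].to_numpy()
        n_keep = int(round(target[b] * scale))
        if len(idx) > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep_idx.extend(idx.tolist())
    return pd.concat([fa.loc[sorted(keep_idx)], cr]).sort_index()


def session_filters(
    trials: pd.DataFrame,
    no_response_run: int = 20,
    min_max_hit_rate: float = 0.30,
) -> tuple[bool, pd.DataFrame, list[str]]:
    """Session-level trimming and exclusion rules.

    Trims the session from the start of the first run of 20 consecutive
    no-response trials (the animal stopped working), then excludes the
    session if the pooled hit rate on maximal-saliency visual and auditory
    trials is below 30%.

    Returns (included, trimmed trials, reasons).
    """
    reasons: list[str] = []
    t = trials.reset_index(drop=True)
    no_resp = (t["choice"].fillna("none") == "none").to_numpy()
    run = 0
    cut = None
    for i, x in enumerate(no_resp):
        run = run + 1 if x else 0
        if run >= no_response_run:
            cut = i - no_response_run + 1
            break
    if cut is not None:
        reasons.append(
            f"trimmed {len(t) - cut} trials from first run of "
            f"{no_response_run} consecutive no-response trials"
        )
        t = t.iloc[:cut].reset_index(drop=True)
    max_trials = t[(t["saliency"] == "max") & t["trial_type"].isin(["visual", "auditory"])]
    if len(max_trials) == 0:
        reasons.append("no maximal-saliency trials")
        return False, t, reasons
    hit_rate = float((max_trials["outcome"] == "hit").mean())
    if hit_rate < min_max_hit_rate:
        reasons.append(f"max-saliency hit rate {hit_rate:.2f} below {min_max_hit_rate:.2f}")
        return False, t, reasons
    return True, t, reasons


def _session_dprime(trials: pd.DataFrame, photostim: str, saliency: str = "max") -> float:
    """d' for visual trials of one photostim condition against catch FAs."""
    sel = trials[trials["photostim"] == photostim]
    vis = sel[(sel["trial_type"] == "visual") & (sel["saliency"] == saliency)]
    catch = sel[sel["trial_type"] == "catch"]
    if len(vis) == 0 or len(catch) == 0:
        return np.nan
    hit = (vis["outcome"] == "hit").mean()
    fa = (catch["choice"].fillna("none") != "none").mean()
    return dprime_from_rates(hit, fa, n_hit=len(vis), n_fa=len(catch))


def silencing_effect(
    sessions: list[pd.DataFrame],
    min_early_reduction: float = 0.50,
    saliency: str = "max",
) -> dict:
    """Per-session optogenetic-silencing effect and its relation to RT.

    For each session, computes the relative d' reduction
    ``(d'_control - d'_opto) / d'_control`` for early and late silencing on
    maximal visual changes.  Sessions enter the late-silencing regression
    only if early silencing reduced d' by at least ``min_early_reduction``
    (an internal control that the manipulation was effective; configurable
    to 0.25 or 0.75).  Returns the per-session table and the Pearson r,
    p-value and least-squares line of the late effect against median
    control reaction time.
    """
    rows = []
    for i, trials in enumerate(sessions):
        d_ctrl = _session_dprime(trials, "none", saliency)
        d_early = _session_dprime(trials, "early", saliency)
        d_late = _session_dprime(trials, "late", saliency)
        ctrl_hits = trials[(trials["photostim"] == "none") & (trials["outcome"] == "hit")]
        med_rt = float(ctrl_hits["reaction_time"].median()) if len(ctrl_hits) else np.nan
        rel = lambda d: (d_ctrl - d) / d_ctrl if d_ctrl and np.isfinite(d) else np.nan
        rows.append(
            dict(
                session=i,
                dprime_control=d_ctrl,
                delta_early=rel(d_early),
                delta_late=rel(d_late),
                median_rt=med_rt,
            )
        )
    table = pd.DataFrame(rows)
    qual = table[(table["delta_early"] >= min_early_reduction)].dropna(
        subset=["delta_late", "median_rt"]
    )
    out = {"table": table, "n_qualifying": len(qual)}
    if len(qual) < 3:
        out.update(r=np.nan, p=np.nan, slope=np.nan, intercept=np.nan)
        return out
    lin = stats.linregress(qual["median_rt"], qual["delta_late"])
    out.update(r=float(lin.rvalue), p=float(lin.pvalue), slope=float(lin.slope),
               intercept=float(lin.intercept))
    return out
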