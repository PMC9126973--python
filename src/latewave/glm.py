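"""Kernel-based Poisson encoding model of single-neuron firing rates.

Each neuron's 10-ms spike counts in a -0.5 to 2.5 s window around every
stimulus change are regressed on a design matrix built from five predictor
families, each event time course convolved with raised-cosine temporal
bases:

* sensory (96 columns): (2 early + 10 late bases) x 2 modalities x
  2 change levels x 2 grouped post-change feature pairs;
* hit (20): 10 stimulus-aligned bases on hit trials + 10 reward-aligned;
* movement (6): 3 bases around each lick, split by side;
* pupil (3): z-scored pupil area at lags 0, -400 and -800 ms;
* trial_number (1): within-session trial index.

The model is fit per neuron by elastic-net-penalized Poisson regression
(mixing parameter alpha = 0.95) with five-fold cross-validation over
trials, the penalty strength chosen by the one-standard-error rule.
Model performance is the cross-validated explained variance
EV = 1 - var(Y - Yhat) / var(Y), overall, per time bin, or on
condition-averaged PSTHs.  The elastic-net solver is an accelerated
proximal-gradient (FISTA) method with warm starts along the lambda path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import StimulusSet

__all__ = [
    "BasisSet",
    "raised_cosine_basis",
    "DesignMatrix",
    "build_design",
    "spike_counts",
    "PoissonEncodingModel",
    "PoissonGLMResults",
    "fit_poisson_elasticnet",
    "explained_variance",
    "subset_ev",
]

BIN = 0.01
WINDOW = (-0.5, 2.5)
FAMILIES = ("visual", "auditory", "hit", "movement", "pupil", "trial_number")


# ---------------------------------------------------------------------------
# raised-cosine bases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSet:
    """Raised-cosine bumps tiling a time span.

    bump_j(t) = 0.5 * (1 + cos(pi * (t - c_j) / w)) for |t - c_j| < w,
    clipped to the span.  With w equal to the center spacing, adjacent
    bumps sum to exactly 1 on the interior of the span.
    """

    n_funcs: int
    span: tuple[float, float]
    width: float
    centers: np.ndarray

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Basis values at times t (relative to the event); (len(t), n_funcs)."""
        t = np.asarray(t, dtype=float)
        u = (t[:, None] - self.centers[None, :]) / self.width
        vals = 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1.0, 1.0)))
        vals[np.abs(u) >= 1.0] = 0.0
        inside = (t >= self.span[0]) & (t < self.span[1] + 1e-12)
        vals[~inside] = 0.0
        return vals


def raised_cosine_basis(
    n_funcs: int, span: tuple[float, float], width: float | None = None
) -> BasisSet:
    """Evenly spaced raised-cosine bumps on a span.

    ``width`` is the bump half-width w; by default it equals the center
    spacing, which makes the interior sum of bumps exactly 1.  A single
    bump is centered on the span midpoint with w = half the span.
    """
    start, end = span
    if not end > start:
        raise ValueError("degenerate span")
    if n_funcs < 1:
        raise ValueError("need at least one basis function")
    if n_funcs == 1:
        centers = np.array([(start + end) / 2.0])
        w = width if width is not None else (end - start) / 2.0
    else:
        centers = np.linspace(start, end, n_funcs)
        w = width if width is not None else centers[1] - centers[0]
    return BasisSet(n_funcs=n_funcs, span=(start, end), width=float(w), centers=centers)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Stacked per-bin design matrix for one session.

    Rows are 10-ms bins of concatenated trial windows (window relative to
    each stimulus change); columns are grouped by predictor family.
    """

    X: np.ndarray
    columns: list[str]
    families: dict[str, np.ndarray]
    trial_of_row: np.ndarray
    bin_times: np.ndarray
    trial_ids: np.ndarray
    window: tuple[float, float] = WINDOW

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_times)


def _feature_pair(post: float, stim_set: StimulusSet) -> str:
    vals = np.asarray(stim_set.values())
    if stim_set.modality == "visual":
        d = np.abs(np.mod(vals - post + 180.0, 360.0) - 180.0)
    else:
        d = np.abs(vals - post)
    return "AB" if int(np.argmin(d)) < 2 else "CD"


def build_design(
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    pupil: pd.DataFrame | None,
    visual_set: StimulusSet,
    auditory_set: StimulusSet,
    window: tuple[float, float] = WINDOW,
    split_hit_by_modality: bool = False,
    null_model: bool = False,
    seed: int = 0,
) -> DesignMatrix:
    """Assemble the 126-column design matrix (or the 1-column null model).

    A separate sensory predictor set is made per modality x change level x
    grouped post-change feature pair ({A,B} vs {C,D}), each with 2 early
    (0-200 ms) and 10 late (0-2000 ms) bases = 96 columns.  Hit predictors
    are 10 stimulus-aligned bases on hit trials (shared across modalities
    unless ``split_hit_by_modality``, which uses 5 per modality) plus 10
    reward-aligned bases = 20.  Movement is 3 bases around each lick by
    side = 6; pupil enters at lags 0/-400/-800 ms = 3; plus the scaled
    trial number = 1.  All columns are normalized to maximum 1.  Missing
    pupil leaves the pupil family at zero.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = window
    n_bins = int(round((t1 - t0) / BIN))
    bin_times = t0 + np.arange(n_bins) * BIN
    trials = trials.reset_index(drop=True)
    n_trials = len(trials)
    n_rows = n_trials * n_bins
    abs_times = (
        trials["change_time"].to_numpy(float)[:, None] + bin_times[None, :]
    )  # (trials, bins)

    if null_model:
        X = rng.random((n_rows, 1))
        return DesignMatrix(
            X=X / np.abs(X).max(), columns=["null"], families={"null": np.arange(1)},
            trial_of_row=np.repeat(np.arange(n_trials), n_bins),
            bin_times=bin_times, trial_ids=trials["trial_index"].to_numpy(),
            window=window,
        )

    early = raised_cosine_basis(2, (0.0, 0.2))
    late = raised_cosine_basis(10, (0.0, 2.0))
    hit_stim = raised_cosine_basis(10, (0.0, 2.0))
    hit_rew = raised_cosine_basis(10, (-0.5, 1.5))
    move = raised_cosine_basis(3, (-0.2, 0.4))

    B_early = early.evaluate(bin_times)  # (bins, 2)
    B_late = late.evaluate(bin_times)
    B_hit = hit_stim.evaluate(bin_times)
    B_sensory = np.concatenate([B_early, B_late], axis=1)  # (bins, 12)

    cols: list[np.ndarray] = []
    names: list[str] = []
    families: dict[str, list[int]] = {f: [] for f in FAMILIES}

    def add(block: np.ndarray, family: str, label: str):
        start = sum(c.shape[1] for c in cols)
        cols.append(block)
        names.extend([f"{label}_{k}" for k in range(block.shape[1])])
        families[family].extend(range(start, start + block.shape[1]))

    # -- sensory: 96 columns
    sets = {"visual": visual_set, "auditory": auditory_set}
    post = trials["post_feature"].to_numpy(float)
    for modality in ("visual", "auditory"):
        in_mod = trials["trial_type"].isin([modality, "multimodal"]).to_numpy()
        pair_of_trial = np.array(
            [
                _feature_pair(p, sets[modality]) if ok and np.isfinite(p) else ""
                for p, ok in zip(post, in_mod)
            ],
            dtype=object,
        )
        for level in ("thr", "max"):
            in_level = (trials["saliency"] == level).to_numpy()
            for pair in ("AB", "CD"):
                sel = in_mod & in_level & (pair_of_trial == pair)
                block = np.zeros((n_rows, 12))
                rows = np.nonzero(sel)[0]
                for tr in rows:
                    block[tr * n_bins : (tr + 1) * n_bins] = B_sensory
                add(block, modality, f"{modality}_{level}_{pair}")

    # -- hit: 20 columns
    is_hit = (trials["outcome"] == "hit").to_numpy()
    if split_hit_by_modality:
        half = raised_cosine_basis(5, (0.0, 2.0))
        B_half = half.evaluate(bin_times)
        for modality in ("visual", "auditory"):
            sel = is_hit & trials["trial_type"].isin([modality, "multimodal"]).to_numpy()
            block = np.zeros((n_rows, 5))
            for tr in np.nonzero(sel)[0]:
                block[tr * n_bins : (tr + 1) * n_bins] = B_half
            add(block, "hit", f"hit_stim_{modality}")
    else:
        block = np.zeros((n_rows, 10))
        for tr in np.nonzero(is_hit)[0]:
            block[tr * n_bins : (tr + 1) * n_bins] = B_hit
        add(block, "hit", "hit_stim")
    reward = trials["reward_time"].to_numpy(float)
    block = np.zeros((n_rows, 10))
    for tr in np.nonzero(np.isfinite(reward))[0]:
        rel = abs_times[tr] - reward[tr]
        block[tr * n_bins : (tr + 1) * n_bins] = hit_rew.evaluate(rel)
    add(block, "hit", "hit_reward")

    # -- movement: 6 columns (licks by side)
    lick_t = {s: licks.loc[licks["side"] == s, "time_s"].to_numpy() for s in ("left", "right")}
    for side in ("left", "right"):
        lt = lick_t[side]
        block = np.zeros((n_rows, 3))
        for tr in range(n_trials):
            lo, hi = abs_times[tr, 0] - 0.4, abs_times[tr, -1] + 0.2
            near = lt[(lt >= lo) & (lt <= hi)]
            if len(near) == 0:
                continue
            acc = np.zeros((n_bins, 3))
            for lk in near:
                acc += move.evaluate(abs_times[tr] - lk)
            block[tr * n_bins : (tr + 1) * n_bins] = acc
        add(block, "movement", f"lick_{side}")

    # -- pupil: 3 columns at lags 0 / -400 / -800 ms
    block = np.zeros((n_rows, 3))
    if pupil is not None and len(pupil):
        pt = pupil["time_s"].to_numpy(float)
        pz = pupil["pupil_z"].to_numpy(float)
        flat = abs_times.ravel()
        for k, lag in enumerate((0.0, -0.4, -0.8)):
            block[:, k] = np.interp(flat + lag, pt, pz)
    add(block, "pupil", "pupil")

    # -- trial number: 1 column
    tn = np.repeat(trials["trial_index"].to_numpy(float), n_bins)[:, None]
    add(tn, "trial_number", "trial_number")

    X = np.concatenate(cols, axis=1)
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    X = X / scale
    return DesignMatrix(
        X=X, columns=names,
        families={f: np.asarray(ix, dtype=int) for f, ix in families.items()},
        trial_of_row=np.repeat(np.arange(n_trials), n_bins),
        bin_times=bin_times,
        trial_ids=trials["trial_index"].to_numpy(),
        window=window,
    )


def spike_counts(
    spikes: pd.DataFrame, neuron_id, events: np.ndarray, window: tuple[float, float] = WINDOW
) -> np.ndarray:
    """10-ms spike counts per trial for one neuron; (n_trials, n_bins)."""
    t0, t1 = window
    n_bins = int(round((t1 - t0) / BIN))
    edges = t0 + np.arange(n_bins + 1) * BIN
    st = spikes.loc[spikes["neuron_id"] == neuron_id, "time_s"].to_numpy()
    out = np.empty((len(events), n_bins), dtype=float)
    for j, ev in enumerate(np.asarray(events, dtype=float)):
        out[j], _ = np.histogram(st, bins=ev + edges)
    return out


# ---------------------------------------------------------------------------
# elastic-net Poisson solver (FISTA)
# ---------------------------------------------------------------------------

def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Mean Poisson deviance (glmnet's CV loss)."""
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.mean(term - (y - mu)))

def _top_eigenvalue(X: np.ndarray, n_iter: int = 30) -> float:
    """Largest eigenvalue of X'X by power iteration."""
    rng = np.random.default_rng(0)
    v = rng.standard_normal(X.shape[1])
    for _ in range(n_iter):
        v = X.T @ (X @ v)
        v /= np.linalg.norm(v) + 1e-30
    return float(v @ (X.T @ (X @ v)))


def _enet_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    eig_max: float,
    beta: np.ndarray,
    b0: float,
    max_iter: int = 300,
    tol: float = 2e-6,
) -> tuple[np.ndarray, float]:
    """One FISTA solve of mean Poisson NLL + lambda * elastic-net penalty.

    Warm-started from (beta, b0); the intercept is unpenalized.  The step
    size comes from the curvature bound mu_max * lambda_max(X'X) / n and is
    shrunk with an acceleration restart whenever the objective increases.
    """
    n, p = X.shape
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    beta = beta.copy()
    zb, zb0 = beta.copy(), b0
    tk = 1.0
    mu = np.exp(np.clip(X @ beta + b0, -30, 30))
    L = mu.max() * (eig_max + n) / n + l2 + 1e-12
    step = 1.0 / L
    f_prev = np.inf
    for it in range(max_iter):
        eta = X @ zb + zb0
        mu = np.exp(np.clip(eta, -30, 30))
        grad = X.T @ (mu - y) / n + l2 * zb
        grad0 = float(np.mean(mu - y))
        bnew = zb - step * grad
        bnew = np.sign(bnew) * np.maximum(np.abs(bnew) - step * l1, 0.0)
        b0new = zb0 - step * grad0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        zb = bnew + ((tk - 1.0) / t_next) * (bnew - beta)
        zb0 = b0new + ((tk - 1.0) / t_next) * (b0new - b0)
        dx = np.abs(bnew - beta).max() + abs(b0new - b0)
        beta, b0, tk = bnew, b0new, t_next
        if it % 10 == 0:
            eta = X @ beta + b0
            mu = np.exp(np.clip(eta, -30, 30))
            f = np.mean(mu - y * eta) + l1 * np.abs(beta).sum() + 0.5 * l2 * beta @ beta
            if f > f_prev + 1e-12:  # restart acceleration if not monotone
                zb, zb0, tk = beta.copy(), b0, 1.0
                L *= 1.5
                step = 1.0 / L
            f_prev = f
        if dx < tol:
            break
    return beta, b0


def _enet_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    max_iter: int = 300,
    tol: float = 2e-6,
    eig_max: float | None = None,
) -> np.ndarray:
    """Warm-started FISTA solutions along a descending lambda path.

    Returns (len(lambdas), p+1) with the intercept first.
    """
    n, p = X.shape
    if eig_max is None:
        eig_max = _top_eigenvalue(X)
    b0 = np.log(max(y.mean(), 1e-12))
    beta = np.zeros(p)
    out = np.empty((len(lambdas), p + 1))
    for li, lam in enumerate(lambdas):
        beta, b0 = _enet_fit(X, y, lam, alpha, eig_max, beta, b0,
                             max_iter=max_iter, tol=tol)
        out[li, 0] = b0
        out[li, 1:] = beta
    return out


def _lambda_path(X, y, alpha, n_lambda, lambda_min_ratio=1e-3):
    n = len(y)
    ybar = max(y.mean(), 1e-12)
    lam_max = np.abs(X.T @ (y - ybar)).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PoissonEncodingModel:
    """Elastic-net Poisson regression of one neuron's binned counts.

    Parameters
    ----------
    design : DesignMatrix for the session.
    y : flattened spike counts aligned with the design rows.
    alpha : elastic-net mixing parameter (0.95: nearly lasso).
    folds : cross-validation folds, assigned per trial (never per bin).
    lambda_rule : "1se" (largest lambda within one SE of the CV minimum)
        or "min".
    """

    def __init__(self, design: DesignMatrix, y: np.ndarray, alpha: float = 0.95,
                 folds: int = 5, lambda_rule: str = "1se", n_lambda: int = 100,
                 seed: int = 0):
        if lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")
        self.design = design
        self.y = np.asarray(y, dtype=float).ravel()
        if len(self.y) != design.X.shape[0]:
            raise ValueError("y length does not match design rows")
        self.alpha = alpha
        self.folds = folds
        self.lambda_rule = lambda_rule
        self.n_lambda = n_lambda
        self.seed = seed

    def _fold_assignment(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        n_trials = self.design.n_trials
        fold_of_trial = np.tile(np.arange(self.folds), n_trials // self.folds + 1)[:n_trials]
        rng.shuffle(fold_of_trial)
        return fold_of_trial[self.design.trial_of_row]

    def fit(self, max_iter: int = 300, plateau_patience: int = 3) -> "PoissonGLMResults":
        """Fit the CV lambda path, lambdas outermost with warm starts.

        The path terminates early once the mean CV deviance has risen for
        ``plateau_patience`` consecutive lambdas past its minimum.  The
        one-SE rule uses fold-centered deviances (each fold's mean over
        lambdas subtracted) so that between-fold difficulty offsets do not
        inflate the SE of the relative CV curve.
        """
        X, y = self.design.X, self.y
        lambdas = _lambda_path(X, y, self.alpha, self.n_lambda)
        fold_of_row = self._fold_assignment()
        eig = _top_eigenvalue(X)
        p = X.shape[1]
        masks = [fold_of_row != f for f in range(self.folds)]
        betas = [np.zeros(p) for _ in range(self.folds)]
        b0s = [float(np.log(max(y[m].mean(), 1e-12))) for m in masks]
        dev_rows = []
        fold_coef_rows = []
        n_used = 0
        for li, lam in enumerate(lambdas):
            row = np.empty(self.folds)
            coefs = np.empty((self.folds, p + 1))
            for f, m in enumerate(masks):
                betas[f], b0s[f] = _enet_fit(
                    X[m], y[m], lam, self.alpha, eig, betas[f], b0s[f],
                    max_iter=max_iter,
                )
                mu = np.exp(np.clip(X[~m] @ betas[f] + b0s[f], -30, 30))
                row[f] = _poisson_deviance(y[~m], mu)
                coefs[f, 0] = b0s[f]
                coefs[f, 1:] = betas[f]
            dev_rows.append(row)
            fold_coef_rows.append(coefs)
            n_used = li + 1
            means = np.array([r.mean() for r in dev_rows])
            i_min = int(np.argmin(means))
            if n_used - 1 - i_min >= plateau_patience:
                break
        lambdas = lambdas[:n_used]
        dev = np.stack(dev_rows, axis=1)  # folds x lambdas
        mean_dev = dev.mean(axis=0)
        centered = dev - dev.mean(axis=1, keepdims=True)
        se_dev = centered.std(axis=0, ddof=1) / np.sqrt(self.folds)
        i_min = int(np.argmin(mean_dev))
        if self.lambda_rule == "1se":
            ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
            i_sel = int(np.nonzero(ok)[0][0])  # lambdas descend: first ok = largest
        else:
            i_sel = i_min
        full = _enet_path(X, y, lambdas[: i_sel + 1], self.alpha,
                          max_iter=max_iter, eig_max=eig)
        coef = full[i_sel]
        fold_coefs = fold_coef_rows[i_sel]
        converged = bool(np.all(np.isfinite(coef)))
        return PoissonGLMResults(
            model=self,
            intercept_=float(coef[0]),
            coef_=coef[1:],
            lambda_=float(lambdas[i_sel]),
            lambda_index=i_sel,
            lambdas=lambdas,
            cv_deviance=mean_dev,
            cv_deviance_se=se_dev,
            fold_of_row=fold_of_row,
            fold_coefs=fold_coefs,
            converged=converged,
        )


@dataclass
class PoissonGLMResults:
    """Fitted encoding model: coefficients, CV path, held-out predictions."""

    model: PoissonEncodingModel
    intercept_: float
    coef_: np.ndarray
    lambda_: float
    lambda_index: int
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    fold_of_row: np.ndarray
    fold_coefs: np.ndarray

    converged: bool = True

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.design.X if X is None else X
        return np.exp(np.clip(X @ self.coef_ + self.intercept_, -30, 30))

    def cv_predict(self, family_set: list[str] | None = None) -> np.ndarray:
        """Held-out predictions, optionally using only some predictor families.

        Rows of each fold are predicted by the model fit on the other
        folds; when a family set is given, coefficients outside those
        families are zeroed (the intercept is kept).
        """
        design = self.model.design
        keep = np.ones(design.X.shape[1], dtype=bool)
        if family_set is not None:
            keep[:] = False
            for fam in family_set:
                if fam not in design.families:
                    raise KeyError(f"unknown predictor family {fam!r}")
                keep[design.families[fam]] = True
        yhat = np.empty(design.X.shape[0])
        for f in range(self.model.folds):
            te = self.fold_of_row == f
            b = self.fold_coefs[f, 1:] * keep
            yhat[te] = np.exp(np.clip(design.X[te] @ b + self.fold_coefs[f, 0], -30, 30))
        return yhat

    def summary(self) -> str:
        design = self.model.design
        nz = int(np.sum(self.coef_ != 0))
        lines = [
            "Poisson elastic-net encoding model",
            "-" * 40,
            f"predictors            {design.X.shape[1]:6d}",
            f"nonzero coefficients  {nz:6d}",
            f"alpha                 {self.model.alpha:6.2f}",
            f"lambda ({self.model.lambda_rule})          {self.lambda_:10.3e}",
            f"CV deviance           {self.cv_deviance[self.lambda_index]:10.4f}",
        ]
        for fam, ix in design.families.items():
            lines.append(f"  {fam:<13} nonzero {int(np.sum(self.coef_[ix] != 0)):3d} / {len(ix)}")
        return "\n".join(lines)


def fit_poisson_elasticnet(
    design: DesignMatrix, y: np.ndarray, alpha: float = 0.95, folds: int = 5,
    lambda_rule: str = "1se", seed: int = 0, n_lambda: int = 100,
) -> PoissonGLMResults:
    """Convenience wrapper around :class:`PoissonEncodingModel`."""
    return PoissonEncodingModel(
        design, y, alpha=alpha, folds=folds, lambda_rule=lambda_rule,
        n_lambda=n_lambda, seed=seed,
    ).fit()


# ---------------------------------------------------------------------------
# explained variance
# ---------------------------------------------------------------------------

def explained_variance(
    Y: np.ndarray,
    Yhat: np.ndarray,
    mode: str = "overall",
    condition_labels: np.ndarray | None = None,
    n_conditions: int = 5,
):
    """EV = 1 - var(Y - Yhat) / var(Y).

    * ``overall``: over all concatenated single-trial bins (scalar);
    * ``per_bin``: per time bin across trials (Y, Yhat shaped
      trials x bins; returns a vector);
    * ``condition_avg``: on concatenated condition-averaged PSTHs of the
      ``n_conditions`` most frequent labels (requires condition_labels).

    EV can be negative (prediction worse than the mean); zero-variance Y
    yields NaN.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError("Y and Yhat must be aligned")

    def ev(y, yh):
        v = np.var(y)
        if v == 0:
            return np.nan
        return 1.0 - np.var(y - yh) / v

    if mode == "overall":
        return float(ev(Y.ravel(), Yhat.ravel()))
    if mode == "per_bin":
        if Y.ndim != 2:
            raise ValueError("per_bin mode needs trials x bins arrays")
        return np.array([ev(Y[:, b], Yhat[:, b]) for b in range(Y.shape[1])])
    if mode == "condition_avg":
        if condition_labels is None or Y.ndim != 2:
            raise ValueError("condition_avg mode needs labels and trials x bins arrays")
        labels = pd.Series(condition_labels)
        top = labels.value_counts().index[:n_conditions]
        psth_y, psth_h = [], []
        for c in top:
            sel = (labels == c).to_numpy()
            psth_y.append(Y[sel].mean(axis=0))
            psth_h.append(Yhat[sel].mean(axis=0))
        return float(ev(np.concatenate(psth_y), np.concatenate(psth_h)))
    raise ValueError(f"unknown EV mode {mode!r}")


def subset_ev(
    results: PoissonGLMResults,
    Y: np.ndarray,
    family_set: list[str],
    mode: str = "overall",
    **kw,
):
    """Cross-validated EV of the prediction using only some predictor families."""
    yhat = results.cv_predict(family_set=family_set)
    if np.asarray(Y).ndim == 2:
        yhat = yhat.reshape(np.asarray(Y).shape)
    return explained_variance(np.asarray(Y, dtype=float), yhat, mode=mode, **kw)
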