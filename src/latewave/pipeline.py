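"""Pipeline orchestration: run the full analysis chain on session bundles.

A configuration (dict, or YAML/JSON file via the CLI) names the stages to
run and their parameters.  Stages execute in the fixed order
simulate -> fit-behavior -> rates -> glm -> roc -> noisecorr -> decode;
unknown stage names are a configuration error.  Every run writes a
provenance log (package version, seeds, parameters, config hash) and a
summary JSON to the report directory; reruns with the same configuration
produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .session_io import Session, config_hash, read_session, write_session

log = logging.getLogger("latewave")

STAGES = ("simulate", "fit-behavior", "rates", "glm", "roc", "noisecorr", "decode")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "latewave_report",
    "stages": ["simulate", "fit-behavior", "rates", "roc", "noisecorr"],
    "simulate": {"n_sessions": 2, "cohort": "MST", "n_trials": 240, "n_neurons": 16},
    "glm": {"alpha": 0.95, "folds": 5, "lambda_rule": "1se", "n_lambda": 20,
            "max_neurons": 3},
    "roc": {"n_shuffles": 1000, "kernel_sd": 0.01, "bin_width": 0.025},
    "decode": {"n_trees": 200, "n_surrogates": 10},
}


def run_pipeline(config: dict | None = None, sessions: list[Session] | None = None) -> Path:
    """Execute the configured stages; returns the report directory.

    Sessions are simulated (stage "simulate") or supplied/loaded from
    ``config["session_dirs"]``.  Stage failures halt the run with a
    stage-scoped log message.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; known stages: {STAGES}")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    summary: dict = {"config_hash": chash, "stages": {}}
    provenance = {
        "latewave_version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "config_hash": chash,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    if sessions is None:
        if "session_dirs" in cfg:
            sessions = [read_session(p) for p in cfg["session_dirs"]]
        elif "simulate" in cfg["stages"]:
            sessions = _stage_simulate(cfg, out, summary)
        else:
            raise ValueError("no sessions: provide session_dirs or a simulate stage")
    elif "simulate" in cfg["stages"]:
        summary["stages"]["simulate"] = {"n_sessions": len(sessions), "provided": True}

    runners = {
        "fit-behavior": _stage_behavior,
        "rates": _stage_rates,
        "roc": _stage_roc,
        "noisecorr": _stage_noisecorr,
        "glm": _stage_glm,
        "decode": _stage_decode,
    }
    state: dict = {}
    for stage in [s for s in STAGES if s in cfg["stages"] and s != "simulate"]:
        log.info("stage %s starting", stage)
        try:
            summary["stages"][stage] = runners[stage](cfg, sessions, state)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_round)
    )
    return out


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _round(x):
    if isinstance(x, (np.floating, float)):
        return round(float(x), 6)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_round(v) for v in x.tolist()]
    raise TypeError(str(type(x)))


def _stage_simulate(cfg, out, summary):
    from .simulate import CohortConfig, simulate_session

    p = cfg["simulate"]
    rng = np.random.default_rng(cfg["seed"])
    maker = getattr(CohortConfig, p.get("cohort", "MST"))
    sessions = []
    for i in range(p["n_sessions"]):
        c = maker(
            n_trials=p["n_trials"], n_neurons=p["n_neurons"],
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        s = simulate_session(c, session_id=f"sim_{i:02d}")
        write_session(s, Path(cfg["out_dir"]) / "sessions" / s.session_id)
        sessions.append(s)
    summary["stages"]["simulate"] = {
        "n_sessions": len(sessions),
        "session_ids": [s.session_id for s in sessions],
    }
    return sessions


def _stage_behavior(cfg, sessions, state):
    from .behavior import fit_madc, response_table, session_filters

    out = {}
    for s in sessions:
        included, trimmed, reasons = session_filters(s.trials)
        res = fit_madc(response_table(trimmed), variant="two-level", seed=cfg["seed"])
        out[s.session_id] = {
            "included": included,
            "reasons": reasons,
            "criterion": res.criterion,
            "dprime": {f"{m}_{sal}": v for (m, sal), v in res.dprime.items()},
            "loglike": res.loglike,
        }
        state.setdefault("behavior", {})[s.session_id] = res
    return out


def _stage_rates(cfg, sessions, state):
    from .rates import compute_rates, zscore_rates

    out = {}
    state["tensors"] = {}
    for s in sessions:
        vis = s.trials[s.trials["trial_type"] == "visual"].reset_index(drop=True)
        tensor = compute_rates(
            s.spikes, vis["change_time"].to_numpy(), window=(-1.0, 1.5),
            neuron_ids=list(s.neurons["neuron_id"]),
            kernel_sd=cfg["roc"].get("kernel_sd", 0.01),
        )
        z = zscore_rates(tensor)
        state["tensors"][s.session_id] = (tensor, z, vis)
        out[s.session_id] = {
            "n_neurons": tensor.n_neurons,
            "n_visual_trials": tensor.n_trials,
            "excluded_flat": z.excluded_neurons,
        }
    return out


def _stage_roc(cfg, sessions, state):
    from .analysis import session_auc_series
    from .roc import classify_coder, coding_fraction, onset_from_fraction

    p = cfg["roc"]
    out = {}
    for s in sessions:
        series = session_auc_series(
            s, variable="hitmiss", bin_width=p.get("bin_width", 0.025),
            kernel_sd=p.get("kernel_sd", 0.01), n_shuffles=p["n_shuffles"],
            seed=cfg["seed"],
        )
        if not series:
            out[s.session_id] = {"skipped": "fewer than 10 hits or misses"}
            continue
        frac = coding_fraction(series, cohort=s.manifest.get("cohort", ""))
        onset = onset_from_fraction(frac)
        out[s.session_id] = {
            "n_coders": int(sum(classify_coder(x) for x in series)),
            "onset_ms": onset.onset_ms,
        }
        state.setdefault("roc", {})[s.session_id] = (series, frac, onset)
    return out


def _stage_noisecorr(cfg, sessions, state):
    from .popstats import noise_correlations, residual_rates
    from .rates import compute_rates

    out = {}
    for s in sessions:
        _, _, vis = state["tensors"][s.session_id]
        tensor = compute_rates(
            s.spikes, vis["change_time"].to_numpy(), window=(-1.0, 1.5),
            neuron_ids=list(s.neurons["neuron_id"]), kernel_sd=0.1,
        )
        resid, kept = residual_rates(tensor.values, vis["post_feature"].to_numpy())
        nc = noise_correlations(resid, tensor.times)
        out[s.session_id] = {
            "baseline_nc": nc.baseline_mean,
            "delta_nc": nc.delta_nc,
        }
    return out


def _stage_glm(cfg, sessions, state):
    from .glm import build_design, explained_variance, fit_poisson_elasticnet, spike_counts
    from .stimuli import make_stimulus_set

    p = cfg["glm"]
    out = {}
    for s in sessions:
        vset = make_stimulus_set("visual", *_set_params(s, "visual"))
        aset = make_stimulus_set("auditory", *_set_params(s, "auditory"))
        trials = s.trials[s.trials["trial_type"] != "multimodal"].reset_index(drop=True)
        design = build_design(trials, s.licks, s.pupil, vset, aset, seed=cfg["seed"])
        evs = {}
        for nid in list(s.neurons["neuron_id"])[: p.get("max_neurons", 3)]:
            y = spike_counts(s.spikes, nid, trials["change_time"].to_numpy()).ravel()
            if y.mean() / 0.01 <= 0.5:
                continue
            res = fit_poisson_elasticnet(
                design, y, alpha=p["alpha"], folds=p["folds"],
                lambda_rule=p["lambda_rule"], seed=cfg["seed"],
                n_lambda=p.get("n_lambda", 20),
            )
            evs[nid] = explained_variance(y, res.cv_predict(), mode="overall")
        out[s.session_id] = {"ev_overall": evs, "n_predictors": design.X.shape[1]}
    return out


def _set_params(session, modality):
    vals = session.manifest.get(f"{'visual' if modality == 'visual' else 'auditory'}_set")
    if vals:
        base = vals[0]
        thr = vals[1] - vals[0]
        return base, thr
    return (100.0, 7.0) if modality == "visual" else (13.25, 1.0 / 32.0)


def _stage_decode(cfg, sessions, state):
    from .glm import spike_counts
    from .popstats import decode_orientation

    p = cfg["decode"]
    out = {}
    for s in sessions:
        vis = s.trials[s.trials["trial_type"] == "visual"].reset_index(drop=True)
        counts = np.stack(
            [
                spike_counts(s.spikes, nid, vis["change_time"].to_numpy(), window=(-0.5, 1.0))
                for nid in s.neurons["neuron_id"]
            ]
        )
        times = -0.5 + np.arange(counts.shape[2]) * 0.01
        vset_vals = s.manifest.get("visual_set", [100.0, 107.0, 190.0, 197.0])
        pair = np.where(
            np.isin(vis["post_feature"].round(3), np.round(vset_vals[:2], 3)), "AB", "CD"
        )
        try:
            res = decode_orientation(
                counts, pair, times, seed=cfg["seed"],
                n_trees=p["n_trees"], n_surrogates=p["n_surrogates"],
            )
        except ValueError as e:
            out[s.session_id] = {"skipped": str(e)}
            continue
        out[s.session_id] = {
            "corrected_accuracy": res.accuracy_per_window,
            "window_centers": res.window_centers,
        }
    return out
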