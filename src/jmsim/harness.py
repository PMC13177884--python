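"""Simulation-study harness: run scenarios, collect fits, summarize.

For each scenario replicate the harness generates a dataset and applies the
requested estimation methods, recording point estimates, standard errors,
95% intervals and convergence status.  Summaries report per scenario and
method: the median estimate and its bias against the generating value,
empirical spread, empirical coverage of the 95% intervals, the convergence
rate, and data-density descriptors (mean events, mean longitudinal
observations, and the observation-to-event ratio, defined as total
longitudinal observations divided by total events).

Three conditioning modes are available: ``converged_only`` (the primary
view; a method is additionally flagged when fewer than a display threshold
of replicates converged, 50 of 200 by default), ``unconditional`` (every
replicate with extractable estimates), and ``all_methods_converged``
(replicates where every requested method converged).
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import replace

import numpy as np
import pandas as pd

from jmsim import jointml, lmm, tvcox, twostage
from jmsim.synthetic_data import (
    ScenarioConfig,
    SimulatedDataset,
    build_scenarios,
    generate_dataset,
    true_trajectory,
)

__all__ = ["run_scenario", "summarize", "run_study", "METHODS"]

logger = logging.getLogger(__name__)

METHODS = ("tvcox", "twostage", "jointml", "tvcox_truth_oracle")
MODES = ("converged_only", "unconditional", "all_methods_converged")

#: parameters tracked in result rows, per method, mapped to truth getters
_TRACKED = ("alpha", "gamma_age", "gamma_sex")


def _truth_lookup(config: ScenarioConfig) -> dict:
    return {
        "alpha": config.survival.alpha,
        "gamma_age": config.survival.gamma_age,
        "gamma_sex": config.survival.gamma_sex,
    }


def _fit_one(method: str, dataset: SimulatedDataset) -> dict:
    """Fit one method; returns estimate/se/ci/converged for tracked params."""
    if method == "tvcox":
        cp = tvcox.build_counting_process(
            dataset.longitudinal, dataset.survival, "observed_LOCF"
        )
        fit = tvcox.fit_tvcox(cp)
        keymap = {"alpha": "y", "gamma_age": "age", "gamma_sex": "sex"}
        return {
            "converged": fit.converged,
            **{
                f"{k}_hat": fit.estimates[v] for k, v in keymap.items()
            },
            **{f"{k}_se": fit.se[v] for k, v in keymap.items()},
            **{f"{k}_lo": fit.ci95[v][0] for k, v in keymap.items()},
            **{f"{k}_hi": fit.ci95[v][1] for k, v in keymap.items()},
        }
    if method == "tvcox_truth_oracle":
        truth = dataset.truth.set_index("id")
        config = dataset.config

        def predict(sid, t):
            row = truth.loc[sid]
            from jmsim.synthetic_data import SubjectTruth

            subj = SubjectTruth(
                id=sid, age=row["age"], sex=int(row["sex"]),
                b0=row["b0"], b1=row["b1"],
            )
            return true_trajectory(subj, config.trajectory, t)

        cp = tvcox.build_counting_process(
            dataset.longitudinal,
            dataset.survival,
            "supplied_function",
            predict_fn=predict,
        )
        fit = tvcox.fit_tvcox(cp)
        keymap = {"alpha": "y", "gamma_age": "age", "gamma_sex": "sex"}
        return {
            "converged": fit.converged,
            **{f"{k}_hat": fit.estimates[v] for k, v in keymap.items()},
            **{f"{k}_se": fit.se[v] for k, v in keymap.items()},
            **{f"{k}_lo": fit.ci95[v][0] for k, v in keymap.items()},
            **{f"{k}_hi": fit.ci95[v][1] for k, v in keymap.items()},
        }
    if method == "twostage":
        res = twostage.run_two_stage(dataset)
        if res.stage2 is None:
            return {"converged": False}
        fit = res.stage2
        keymap = {"alpha": "y", "gamma_age": "age", "gamma_sex": "sex"}
        return {
            "converged": res.converged,
            **{f"{k}_hat": fit.estimates[v] for k, v in keymap.items()},
            **{f"{k}_se": fit.se[v] for k, v in keymap.items()},
            **{f"{k}_lo": fit.ci95[v][0] for k, v in keymap.items()},
            **{f"{k}_hi": fit.ci95[v][1] for k, v in keymap.items()},
        }
    if method == "jointml":
        fit = jointml.fit_joint(dataset)
        p = fit.params_hat
        vals = {"alpha": p.alpha, "gamma_age": p.gamma_age, "gamma_sex": p.gamma_sex}
        return {
            "converged": fit.converged,
            **{f"{k}_hat": vals[k] for k in vals},
            **{f"{k}_se": fit.se[k] for k in vals},
            **{f"{k}_lo": fit.ci95[k][0] for k in vals},
            **{f"{k}_hi": fit.ci95[k][1] for k in vals},
            "phi_hat": p.phi,
            "sigma_hat": p.sigma,
        }
    raise ValueError(f"unknown method {method!r}")


def run_scenario(
    config: ScenarioConfig,
    methods=("tvcox", "twostage", "jointml"),
    n_reps: int | None = None,
) -> pd.DataFrame:
    """Run all replicates of one scenario; one row per (rep, method).

    A method that raises on a replicate is recorded as a missing-coded row
    (``crashed=True``, no estimates) rather than aborting the scenario.
    """
    n_reps = config.n_reps if n_reps is None else n_reps
    rows = []
    for rep in range(n_reps):
        dataset = generate_dataset(config, rep)
        n_events = int(dataset.survival["event"].sum())
        n_obs = len(dataset.longitudinal)
        for method in methods:
            base_row = {
                "scenario": config.label,
                "rep": rep,
                "method": method,
                "n_events": n_events,
                "n_longitudinal_obs": n_obs,
                "crashed": False,
                "converged": False,
            }
            try:
                base_row.update(_fit_one(method, dataset))
            except Exception as exc:  # missing-coded, study continues
                logger.warning(
                    "method %s crashed on rep %d of %s: %s",
                    method, rep, config.label, exc,
                )
                base_row["crashed"] = True
            rows.append(base_row)
    return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame,
    truth: ScenarioConfig,
    mode: str = "converged_only",
    min_converged: int = 50,
) -> pd.DataFrame:
    """Per-method evaluation summary of one scenario's result table.

    ``min_converged`` implements the display rule for the primary
    (converged-only) view: methods with fewer converged replicates than the
    threshold are flagged ``below_display_threshold`` rather than dropped.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if results.empty:
        raise ValueError("empty results table")
    truths = _truth_lookup(truth)
    out = []
    if mode == "all_methods_converged":
        conv_by_rep = results.groupby("rep")["converged"].all()
        keep_reps = set(conv_by_rep[conv_by_rep].index)
    for method, g in results.groupby("method", sort=False):
        n_total = len(g)
        n_conv = int(g["converged"].sum())
        if mode == "converged_only":
            sel = g[g["converged"]]
        elif mode == "unconditional":
            sel = g[~g["crashed"] & g["alpha_hat"].notna()] if "alpha_hat" in g else g.iloc[0:0]
        else:
            sel = g[g["rep"].isin(keep_reps) & g["converged"]]
        row = {
            "scenario": g["scenario"].iloc[0],
            "method": method,
            "mode": mode,
            "n_total": n_total,
            "n_used": len(sel),
            "convergence_rate_pct": 100.0 * n_conv / n_total,
            "below_display_threshold": bool(
                mode == "converged_only" and n_conv < min_converged
            ),
            "mean_events": g.groupby("rep")["n_events"].first().mean(),
            "mean_obs": g.groupby("rep")["n_longitudinal_obs"].first().mean(),
        }
        tot_ev = g.groupby("rep")["n_events"].first().sum()
        tot_obs = g.groupby("rep")["n_longitudinal_obs"].first().sum()
        row["obs_to_event_ratio"] = tot_obs / tot_ev if tot_ev else np.nan
        for p in _TRACKED:
            hat = sel.get(f"{p}_hat")
            if hat is None or sel.empty:
                row.update(
                    {
                        f"{p}_median": np.nan,
                        f"{p}_bias": np.nan,
                        f"{p}_mean_bias": np.nan,
                        f"{p}_emp_sd": np.nan,
                        f"{p}_coverage_pct": np.nan,
                    }
                )
                continue
            med = float(np.nanmedian(hat))
            row[f"{p}_median"] = med
            row[f"{p}_bias"] = med - truths[p]
            row[f"{p}_mean_bias"] = float(np.nanmean(hat)) - truths[p]
            row[f"{p}_emp_sd"] = float(np.nanstd(hat, ddof=1)) if len(sel) > 1 else np.nan
            lo = sel[f"{p}_lo"].to_numpy(dtype=float)
            hi = sel[f"{p}_hi"].to_numpy(dtype=float)
            cover = (lo <= truths[p]) & (truths[p] <= hi)
            row[f"{p}_coverage_pct"] = 100.0 * float(np.nanmean(cover))
        out.append(row)
    return pd.DataFrame(out)


def run_study(
    settings,
    out_dir,
    methods=("tvcox", "twostage", "jointml"),
    n_reps: int | None = None,
    seed: int | None = None,
    modes=("converged_only", "unconditional"),
) -> pd.DataFrame:
    """Run a list of settings end to end and write tidy summary tables.

    Writes ``results.csv`` (one row per scenario x rep x method),
    ``summary.csv`` (one row per scenario x method x mode) and
    ``manifest.json`` (seeds, grids, package version) to ``out_dir``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_results, all_summaries, manifest = [], [], {"settings": {}}
    for setting in settings:
        scenarios = build_scenarios(setting)
        if seed is not None:
            scenarios = [replace(c, seed=seed) for c in scenarios]
        manifest["settings"][setting] = [
            {"label": c.label, "seed": c.seed} for c in scenarios
        ]
        for config in scenarios:
            try:
                res = run_scenario(config, methods=methods, n_reps=n_reps)
            except Exception as exc:
                logger.error("scenario %s failed: %s", config.label, exc)
                continue
            all_results.append(res)
            for mode in modes:
                all_summaries.append(summarize(res, config, mode=mode))
    results = pd.concat(all_results, ignore_index=True)
    summary = pd.concat(all_summaries, ignore_index=True)
    results.to_csv(out / "results.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    from jmsim import __version__

    manifest["version"] = __version__
    manifest["methods"] = list(methods)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
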