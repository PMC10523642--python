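"""Full-study orchestration: calibrate -> simulate -> fit -> summarize -> ridge.

Writes five comma-separated outputs plus a run log into the configured
directory:

* ``replicates.csv``   one row per replicate x analysis family
* ``summary.csv``      bias/MSE/coverage per (n, generative family, analysis family)
* ``preference.csv``   percentage of replicates preferring NB by AIC
* ``odds_ratios.csv``  ridge-adjusted and univariable ORs for ZINB preference
* ``exclusions.csv``   per-family exclusion accounting
* ``run_log.txt``      seeds, versions, calibrated parameters, stage progress

A given (config, master_seed) reproduces all outputs byte-identically.
"""

from __future__ import annotations

import sys
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .harness import (
    apply_exclusions,
    preference_fraction,
    records_to_frame,
    run_scenario,
    summarize_metrics,
)
from .preference import PreferenceModel, build_preference_dataset, fit_ridge_logistic
from .synthetic import (
    DEFAULT_LOGIT_INTERCEPT,
    calibrate_intercepts,
    make_generative_model,
)

__all__ = ["run_study", "calibrate_generative_model"]

# fixed sub-stream labels so calibration and scenarios never share randomness
_CAL_STREAM = 90_000
_SCEN_STREAM = 100


def calibrate_generative_model(config: StudyConfig, family: str):
    """Calibrate one outcome's generative model under the study config."""
    model = make_generative_model(config.outcome, family)
    if family == "zinb" and config.logit_intercept is not None:
        model = replace(
            model,
            logit_coefficients=(config.logit_intercept, model.logit_coefficients[1]),
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, _CAL_STREAM])
    )
    targets = config.calibration_targets.get(config.outcome)
    return calibrate_intercepts(model, targets=targets, rng=rng)


def _scenario_seed(master_seed: int, n: int, family: str) -> int:
    fam_code = {"nb": 1, "zinb": 2}[family]
    return int((master_seed + 1000 * fam_code + n) % (2**31))


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Execute the whole pipeline; returns a dict of output paths.

    Partial failures keep completed stages' outputs and are recorded in the
    run log rather than raised.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"zicount {__version__} | python {sys.version.split()[0]} | numpy {np.__version__}",
        f"master_seed={config.master_seed}",
        f"config: {config.as_dict()}",
    ]

    def log(msg):
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    all_records = {}  # (n, dd_family) -> records
    models = {}
    for family in config.dd_families:
        model = calibrate_generative_model(config, family)
        models[family] = model
        log(
            f"calibrated {config.outcome}/{family}: beta0={model.count_coefficients[0]:.4f}, "
            f"r={model.dispersion_r:.4f}"
            + (
                f", gamma0={model.logit_coefficients[0]:.4f}"
                if model.logit_coefficients
                else ""
            )
        )
        for n in config.sample_sizes:
            seed = _scenario_seed(config.master_seed, n, family)
            log(f"scenario n={n} dd={family}: reps={config.reps} seed={seed}")
            recs = run_scenario(
                model,
                n=n,
                reps=config.reps,
                master_seed=seed,
                analysis_families=config.analysis_families,
                compute_ci=config.compute_ci,
                ci_level=config.ci_level,
                n_jobs=config.n_jobs,
            )
            all_records[(n, family)] = recs

    paths = {}

    # per-replicate table
    frames = []
    for (n, family), recs in all_records.items():
        df = records_to_frame(recs)
        df.insert(0, "dd_family", family)
        frames.append(df)
    rep_df = pd.concat(frames, ignore_index=True)
    paths["replicates"] = out / "replicates.csv"
    rep_df.to_csv(paths["replicates"], index=False)
    log(f"wrote {paths['replicates']}")

    # bias/MSE/coverage summary + exclusion report + NB-preference table
    summary_rows, excl_rows, pref_rows = [], [], []
    for (n, family), recs in all_records.items():
        beta_dd = models[family].beta_dd
        for fam in config.analysis_families:
            kept, report = apply_exclusions(recs, family=fam)
            excl_rows.append(
                {
                    "n": n,
                    "dd_family": family,
                    "analysis_family": fam,
                    "n_total": report["n_total"],
                    "n_excluded": report["per_family"][fam]["n_excluded"],
                    "pct_excluded": report["per_family"][fam]["pct_excluded"],
                }
            )
            if len(kept) >= 2 and fam in ("nb", "zinb"):
                s = summarize_metrics(
                    kept,
                    beta_dd=beta_dd,
                    family=fam,
                    level=config.ci_level,
                    n_excluded=report["per_family"][fam]["n_excluded"],
                )
                row = {"n": n, "dd_family": family}
                row.update(s.as_dict())
                summary_rows.append(row)
        if {"nb", "zinb"} <= set(config.analysis_families):
            kept_both, _ = apply_exclusions(recs)
            try:
                frac = preference_fraction(kept_both)
                pref_rows.append(
                    {
                        "n": n,
                        "dd_family": family,
                        "pct_nb_preferred": 100.0 * frac,
                        "pct_zinb_preferred": 100.0 * (1.0 - frac),
                        "n_used": len(kept_both),
                    }
                )
            except ValueError as exc:
                log(f"preference fraction skipped for n={n} dd={family}: {exc}")
    paths["summary"] = out / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(paths["summary"], index=False)
    paths["exclusions"] = out / "exclusions.csv"
    pd.DataFrame(excl_rows).to_csv(paths["exclusions"], index=False)
    paths["preference"] = out / "preference.csv"
    pd.DataFrame(pref_rows).to_csv(paths["preference"], index=False)
    log("wrote summary.csv, exclusions.csv, preference.csv")

    # ridge meta-regression, pooled across generative families at the base n
    base_n = config.sample_sizes[0]
    pooled = []
    for family in config.dd_families:
        kept_both, _ = apply_exclusions(all_records[(base_n, family)])
        pooled.extend(kept_both)
    or_path = out / "odds_ratios.csv"
    try:
        dataset = build_preference_dataset(pooled)
        ridge_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, 77])
        )
        ridge = fit_ridge_logistic(
            dataset,
            cv_folds=config.cv_folds,
            rng=ridge_rng,
            n_bootstrap=config.n_bootstrap,
        )
        ridge.summary().rename_axis("predictor").to_csv(or_path)
        log(f"ridge lambda={ridge.lambda_:.4g}; wrote {or_path}")
    except (ValueError, Warning) as exc:
        log(f"ridge analysis failed: {exc}")
        pd.DataFrame().to_csv(or_path)
    paths["odds_ratios"] = or_path

    paths["run_log"] = out / "run_log.txt"
    paths["run_log"].write_text("\n".join(log_lines) + "\n")
    return paths
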