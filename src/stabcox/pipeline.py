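"""End-to-end pipeline: simulate/ingest -> descriptives -> curves -> EPV
-> bootstrap stability, with a manifest recording seeds, parameters and
output checksums so a run can be reproduced byte for byte.

All randomness flows from one master seed through named sub-streams
(generator, cross-validation folds, bootstrap draws), so each stage can
be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COVARIATES, read_cohort, write_cohort
from .km import fit_km, stratified_curves
from .simulate import default_config, generate_cohort
from .stability import bootstrap_lasso

logger = logging.getLogger("stabcox")

# fixed offsets carving independent sub-streams out of the master seed
_SEED_STREAMS = {"generator": 0, "bootstrap": 1}


def _sub_seed(master: int, stream: str) -> int:
    ss = np.random.SeedSequence([master, _SEED_STREAMS[stream]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of one full pipeline run."""

    out_dir: str
    seed: int
    input_csv: str | None = None  # ingest this cohort instead of simulating
    n: int = 179
    effect: float = 0.3
    B: int = 1000
    K: int = 50
    rule: str = "min"
    level: float = 0.95
    n_lambda: int = 50
    min_ratio: float = 0.05
    stratify_covariates: tuple[str, ...] = (
        "edeq_shape_concerns",
        "vomit_28d",
        "binge_28d",
        "hscl_depression",
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _life_table_csv(lt, path: Path) -> None:
    lt.table.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "n": config.n,
            "effect": config.effect,
            "B": config.B,
            "K": config.K,
            "rule": config.rule,
            "level": config.level,
            "n_lambda": config.n_lambda,
            "min_ratio": config.min_ratio,
        },
        "stages": {},
        "outputs": {},
    }
    # -- stage 1: cohort -----------------------------------------------------
    if config.input_csv:
        cohort = read_cohort(config.input_csv)
        manifest["stages"]["input"] = {
            "path": str(config.input_csv),
            "sha256": _sha256(Path(config.input_csv)),
            "n": len(cohort),
        }
        logger.info("ingested %d records from %s", len(cohort), config.input_csv)
    else:
        gen_seed = _sub_seed(config.seed, "generator")
        cfg = default_config(n=config.n, effect=config.effect)
        cohort = generate_cohort(cfg, gen_seed)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        manifest["stages"]["simulate"] = {
            "generator_seed": gen_seed,
            "n": config.n,
            "session_hazard": float(cfg.session_hazards[0]),
        }
        manifest["outputs"]["cohort.csv"] = None
        logger.info(
            "simulated cohort n=%d, %d events", len(cohort), cohort.n_events
        )

    # -- stage 2: descriptives ----------------------------------------------
    desc = cohort.describe()
    outcome = pd.DataFrame(
        {
            "mean": [cohort.dropout_rate(), cohort.event_times.mean()],
            "sd": [np.nan, cohort.event_times.std(ddof=1)],
            "min": [np.nan, cohort.event_times.min()],
            "max": [np.nan, cohort.event_times.max()],
        },
        index=["dropout_fraction", "last_session"],
    )
    pd.concat([desc, outcome]).to_csv(out / "descriptives.csv")
    manifest["outputs"]["descriptives.csv"] = None

    # -- stage 3: attrition curves -------------------------------------------
    overall = fit_km(cohort.event_times, cohort.events)
    _life_table_csv(overall, out / "attrition_overall.csv")
    manifest["outputs"]["attrition_overall.csv"] = None
    for cov in config.stratify_covariates:
        strat = stratified_curves(cohort, cov)
        for grp in ("low", "high"):
            _life_table_csv(strat[grp], out / f"attrition_{cov}_{grp}.csv")
            manifest["outputs"][f"attrition_{cov}_{grp}.csv"] = None

    # -- stage 4: EPV diagnostic ----------------------------------------------
    epv, below = cohort.events_per_variable(len(COVARIATES))
    manifest["stages"]["epv"] = {
        "events": cohort.n_events,
        "n_predictors": len(COVARIATES),
        "epv": epv,
        "below_recommended_10": below,
    }
    logger.info("EPV = %.2f (below recommended: %s)", epv, below)

    # -- stage 5: bootstrap stability ------------------------------------------
    boot_seed = _sub_seed(config.seed, "bootstrap")
    res = bootstrap_lasso(
        cohort,
        B=config.B,
        K=config.K,
        seed=boot_seed,
        rule=config.rule,
        level=config.level,
        n_lambda=config.n_lambda,
        min_ratio=config.min_ratio,
    )
    res.report_table().to_csv(out / "stability_report.csv", index=False)
    res.selection_counts().rename_axis("covariate").reset_index().to_csv(
        out / "selection_counts.csv", index=False
    )
    with open(out / "stability_full.json", "w") as fh:
        json.dump(res.to_json_dict(), fh)
    manifest["stages"]["bootstrap"] = {
        "seed": boot_seed,
        "redraws": res.redraws,
        "identified": res.identified_covariates,
    }
    for name in (
        "stability_report.csv",
        "selection_counts.csv",
        "stability_full.json",
    ):
        manifest["outputs"][name] = None
    logger.info("identified predictors: %s", res.identified_covariates)

    # -- manifest with checksums ----------------------------------------------
    for name in manifest["outputs"]:
        manifest["outputs"][name] = _sha256(out / name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
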