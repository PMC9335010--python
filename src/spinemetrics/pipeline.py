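"""End-to-end study orchestration: simulate → measure → cohort → analyze.

A single run seed fans out to stable per-stage child seeds (via
``numpy.random.SeedSequence.spawn``) so each stage is individually
reproducible; two runs with identical configuration produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_cohort
from .stats import (
    IMPORTANCE_PREDICTORS,
    ancova,
    descriptive_table,
    fit_by_stratum,
    gb_importance,
    spearman_matrix,
)
from .synthetic import GeneratorConfig, generate_cohort, truth_table
from .validation import agreement_report, simulate_observers

__all__ = ["RunConfig", "run_study", "DESCRIPTIVE_PARAMETERS", "DEFAULT_ANCOVA_SPECS"]

logger = logging.getLogger(__name__)

DESCRIPTIVE_PARAMETERS = (
    "pi", "pt", "ss", "ll_l1l5", "ll_roussouly", "tk_t1t12", "tk_t4t12",
    "pi_ll", "sva", "tpa", "cobb_angle", "rot_angle",
)

#: (response, factor, covariates) — the sagittal parameters tested for sex
#: and age-group differences, each adjusted for plausible confounders
DEFAULT_ANCOVA_SPECS = (
    ("ll_l1l5", "sex", ("age", "pi")),
    ("ll_l1l5", "age_group", ("pi", "cobb_angle")),
    ("tk_t4t12", "sex", ("age", "ll_l1l5")),
    ("tk_t4t12", "age_group", ("ll_l1l5", "cobb_angle")),
    ("pi", "sex", ("age",)),
    ("sva", "age_group", ("pi", "ll_l1l5")),
    ("pi_ll", "age_group", ("pi", "cobb_angle")),
)

SPEARMAN_VARIABLES = ("age", "cobb_angle", "pi", "ss", "ll_l1l5", "tk_t4t12",
                      "sva", "tpa", "rot_angle")


@dataclass
class RunConfig:
    """Configuration of a full synthetic study run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    out_dir: str | Path = "study_out"
    sva_reference: str = "T1"
    ancova_specs: tuple = DEFAULT_ANCOVA_SPECS
    observer_noise_sd: float = 3.0   # deg; manual inter-observer spread
    tool_noise_sd: float = 3.0       # deg; simulated tool error
    n_validation_cases: int = 30
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "ancova_specs" in d:
            d["ancova_specs"] = tuple(
                (r, f, tuple(c)) for r, f, c in d["ancova_specs"]
            )
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def run_study(cfg: RunConfig) -> Path:
    """Run the full pipeline and write every output table to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    gen_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    obs_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    # --- simulate ----------------------------------------------------------
    gen_cfg = dataclasses.replace(cfg.generator, seed=gen_seed)
    logger.info("simulate: n=%d seed=%d", gen_cfg.n_subjects, gen_seed)
    recons, truths = generate_cohort(gen_cfg, out_dir=out)
    logger.info("simulate: %d reconstructions", len(recons))

    # --- measure + cohort --------------------------------------------------
    cohort = build_cohort(recons, sva_reference=cfg.sva_reference)
    cohort.to_csv(out / "cohort.csv", index=False)
    logger.info("cohort: %d kept of %d generated", len(cohort), len(recons))

    # --- analyze -----------------------------------------------------------
    desc = pd.DataFrame(
        [r.__dict__ for r in descriptive_table(cohort, list(DESCRIPTIVE_PARAMETERS))]
    )
    _fmt(desc).to_csv(out / "descriptive.csv", index=False)

    fits = []
    for x, y, filt_label in (
        ("age", "ll_l1l5", None),
        ("age", "tk_t4t12", None),
        ("pi", "ll_l1l5", None),
        ("pi", "pi_ll", None),
        ("pi", "pi_ll", "no_deformity"),
        ("ll_l1l5", "tk_t4t12", None),
        ("ll_l1l5", "sva", None),
        ("cobb_angle", "ll_l1l5", None),
    ):
        mask = ~cohort["deformity"] if filt_label else None
        for res in fit_by_stratum(cohort, x, y, stratum_var="age_group",
                                  filter=mask):
            fits.append({"x": x, "y": y, "filter": filt_label or "all",
                         **res.__dict__})
    _fmt(pd.DataFrame(fits)).to_csv(out / "fits.csv", index=False)

    _fmt(spearman_matrix(cohort, list(SPEARMAN_VARIABLES))).to_csv(
        out / "spearman.csv"
    )

    anc = [
        ancova(cohort, resp, fac, list(cov)).__dict__
        for resp, fac, cov in cfg.ancova_specs
    ]
    anc_df = pd.DataFrame(anc)
    anc_df["covariates"] = anc_df["covariates"].map(lambda c: ";".join(c))
    _fmt(anc_df).to_csv(out / "ancova.csv", index=False)

    importances = gb_importance(cohort)
    for label, mat in importances.items():
        _fmt(mat).to_csv(out / f"importance_{label}.csv")

    # --- simulated-observer validation -------------------------------------
    truth_df = truth_table(truths).head(cfg.n_validation_cases)
    sets = simulate_observers(
        truth_df, cfg.observer_noise_sd, cfg.tool_noise_sd, seed=obs_seed
    )
    agree = pd.DataFrame([r.__dict__ for r in agreement_report(sets)])
    _fmt(agree).to_csv(out / "agreement.csv", index=False)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {"generator": gen_seed, "observers": obs_seed},
        "config": {**cfg.to_dict(), "generator": gen_cfg.to_dict()},
        "counts": {
            "generated": len(recons),
            "kept": int(len(cohort)),
            "scoliosis": int(cohort["scoliosis"].sum()),
            "deformity": int(cohort["deformity"].sum()),
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    logger.info("run complete: %s", out)
    return out
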