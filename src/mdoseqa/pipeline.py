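"""End-to-end workflow: simulate -> split -> train -> predict -> QA evaluate.

``run_pipeline`` ties the synthetic cohort generator, the dose-prediction
network and the QA evaluation stack (volume metrics, DVH metrics, 3D gamma)
together and writes per-case and cohort-level CSV reports.  Every artifact
is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import PatientCase
from .dose_metrics import metric_report
from .dvh_engine import metric_report as dvh_metric_report
from .fusion_net import ModelConfig
from .gamma_engine import GammaCriteria, gamma_map
from .phantom_sim import CohortRanges, PerturbationSpec, PhantomSpec, generate_cohort
from .trainer import TrainConfig, predict, split_cohort, train

__all__ = ["RunConfig", "run_pipeline", "evaluate_case"]

logger = logging.getLogger("mdoseqa")


@dataclass
class RunConfig:
    """Full pipeline configuration, serializable to/from YAML."""

    n_cases: int = 30
    seed: int = 0
    out_dir: str = "mdoseqa_run"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(levels=3, base_channels=4))
    training: TrainConfig = field(default_factory=lambda: TrainConfig(learning_rate=1e-3, max_epochs=20, patience=10))
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    dvh_bin_width: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "phantom": PhantomSpec,
            "perturbation": PerturbationSpec,
            "model": ModelConfig,
            "training": TrainConfig,
            "gamma": GammaCriteria,
        }
        for key, value in raw.items():
            if key in nested:
                if "hu_window" in value:
                    value["hu_window"] = tuple(value["hu_window"])
                for tup in ("grid_shape", "spacing", "body_semiaxes", "ptv_center",
                            "ptv_semiaxes", "split_fractions"):
                    if tup in value:
                        value[tup] = tuple(value[tup])
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def evaluate_case(
    case: PatientCase,
    pdose,
    gamma_criteria: GammaCriteria,
) -> dict:
    """QA metrics of a predicted dose against the case's measured dose."""
    ref = case.mdose
    vol = metric_report(ref, pdose)
    gamma = gamma_map(ref, pdose, gamma_criteria)
    row = {"case_id": case.case_id, **vol.as_dict(), "gpr": gamma.gpr,
           "gamma_pass": gamma.pass_fail}
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns paths and the cohort summary frame."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("mdoseqa %s pipeline start: seed=%d n_cases=%d variant=%s",
                    __version__, config.seed, config.n_cases, config.model.variant)
        # --- simulate ---------------------------------------------------
        try:
            cohort = generate_cohort(
                config.n_cases,
                CohortRanges(base=config.phantom),
                config.perturbation,
                seed=config.seed,
            )
        except Exception as e:
            raise RuntimeError(f"stage 'simulate' failed: {e}") from e
        # --- split ------------------------------------------------------
        try:
            cases_train, cases_val, cases_test = split_cohort(
                cohort, config.training.split_fractions, seed=config.seed
            )
        except Exception as e:
            raise RuntimeError(f"stage 'split' failed: {e}") from e
        logger.info("split sizes: %d/%d/%d", len(cases_train), len(cases_val), len(cases_test))
        # --- train ------------------------------------------------------
        try:
            reg, history = train(cases_train, cases_val, config.model, config.training)
        except Exception as e:
            raise RuntimeError(f"stage 'train' failed: {e}") from e
        history.to_csv(out / "history.csv", index=False)
        # --- predict + evaluate ----------------------------------------
        rows = []
        try:
            for case in cases_test:
                pdose = predict(reg, case)
                row = evaluate_case(case, pdose, config.gamma)
                # copy-the-plan baseline for reference
                base = evaluate_case(case, case.rtdose, config.gamma)
                row.update({f"plan_{k}": v for k, v in base.items() if k != "case_id"})
                rows.append(row)
                dvh = dvh_metric_report(
                    case.mdose, pdose, case.structures, case.prescription_dose
                )
                dvh.to_csv(out / f"dvh_{case.case_id}.csv")
        except Exception as e:
            raise RuntimeError(f"stage 'evaluate' failed: {e}") from e
        per_case = pd.DataFrame(rows)
        per_case.to_csv(out / "per_case.csv", index=False)
        summary = per_case.drop(columns=["case_id"]).mean(numeric_only=True).to_frame().T
        summary.insert(0, "variant", config.model.variant)
        summary.insert(1, "seed", config.seed)
        summary.insert(2, "version", __version__)
        summary.to_csv(out / "summary.csv", index=False)
        logger.info("pipeline done in %.1f s", time.time() - t0)
        return {
            "out_dir": out,
            "summary": summary,
            "per_case": per_case,
            "history": history,
            "regressor": reg,
            "test_cases": cases_test,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
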