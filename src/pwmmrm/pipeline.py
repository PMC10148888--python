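"""End-to-end orchestration of the five-step propensity-weighted analysis.

Stages: label the placebo arm for end-of-study response -> split it 75/25 ->
grid-search and train the propensity network -> bootstrap-validate it ->
score every randomized subject -> weighted and unweighted MMRM -> sensitivity
grid and bias metric.  One master seed deterministically spawns the per-stage
seeds, so a report is fully reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .data import HAMD17, MADRS, ItemScale, TrialDataset, read_trial_long
from .labeling import HAMD17_RESPONSE_THRESHOLD, ThresholdSpec
from .mlp import TrainConfig
from .mmrm import MMRM, MMRMSpec
from .propensity import PlaceboPropensityModel
from .sensitivity import bin_propensity, run_sensitivity_grid
from .simulate import SimConfig, generate_trial

__all__ = ["RunConfig", "RunReport", "run_pipeline", "PipelineError"]

log = logging.getLogger("pwmmrm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    Exactly one of ``input_path`` (a long-format data file) or ``sim`` (a
    generator config) must be set.
    """

    input_path: str | None = None
    schema: dict | None = None
    sim: SimConfig | None = None
    scale: ItemScale = field(default_factory=lambda: HAMD17)
    placebo_arm: str | None = None
    threshold: ThresholdSpec = HAMD17_RESPONSE_THRESHOLD
    split_fraction: float = 0.75
    candidates: list[tuple[int, ...]] | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    clip: tuple[float, float] = (0.05, 1.0)
    n_boot: int = 1000
    mmrm: MMRMSpec = field(default_factory=MMRMSpec)
    low_cut: float = 0.2
    high_cut: float = 0.8
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be configured")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("input_path", "schema", "placebo_arm", "split_fraction",
                    "n_boot", "low_cut", "high_cut", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "scale" in raw:
            kwargs["scale"] = MADRS if str(raw["scale"]).upper() == "MADRS" else HAMD17
        if "threshold" in raw:
            kwargs["threshold"] = ThresholdSpec(
                raw.get("scale", "HAMD17"), float(raw["threshold"])
            )
        if "clip" in raw:
            kwargs["clip"] = tuple(raw["clip"])
        if "candidates" in raw:
            kwargs["candidates"] = [tuple(c) for c in raw["candidates"]]
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        if "mmrm" in raw:
            kwargs["mmrm"] = MMRMSpec(**raw["mmrm"])
        if "sim" in raw:
            sim_kwargs = dict(raw["sim"])
            for tup_key in ("arms", "arm_sizes", "visit_weeks", "baseline_mean",
                            "baseline_sd", "propensity_beta", "placebo_asymptote",
                            "drug_effect_week8"):
                if tup_key in sim_kwargs:
                    sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
            kwargs["sim"] = SimConfig(**sim_kwargs)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All stage outputs of one pipeline run, JSON-serializable."""

    census: dict
    threshold: float
    n_labeled: int
    n_unlabeled: int
    split_sizes: dict
    topology: list
    grid_table: list
    validation_auc: dict
    propensity_distribution: list
    treatment_effects: dict  # scheme -> comparison -> stats
    sensitivity: dict
    bias: dict
    version: str
    config_hash: str
    seed: int

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    def render(self) -> str:
        lines = [
            "Propensity-weighted trial analysis",
            "=" * 50,
            f"arm census         : {self.census}",
            f"response threshold : {self.threshold:.0%} reduction from baseline",
            f"labeled placebo    : {self.n_labeled} "
            f"(excluded, missing EOS: {self.n_unlabeled})",
            f"train/validation   : {self.split_sizes['train']}/"
            f"{self.split_sizes['valid']}",
            f"selected topology  : {tuple(self.topology)}",
            f"validation AUC     : {self.validation_auc['auc']:.3f} "
            f"(95% CI {self.validation_auc['ci_low']:.3f}-"
            f"{self.validation_auc['ci_high']:.3f})",
            "",
            "Treatment effects at the final visit (active - placebo)",
            "-" * 50,
        ]
        for scheme in ("unweighted", "weighted"):
            for comp, st in self.treatment_effects[scheme].items():
                lines.append(
                    f"{scheme:<10s} {comp:<28s} TE {st['te']:>8.3f}  "
                    f"p {st['p']:.4g}  ES {st['effect_size']:.3f}"
                )
        lines += [
            "",
            f"sensitivity bias B : unweighted {self.bias.get('unweighted', float('nan')):.3f}, "
            f"weighted {self.bias.get('weighted', float('nan')):.3f}",
            f"seed {self.seed}   config {self.config_hash}   pwmmrm {self.version}",
        ]
        return "\n".join(lines)


def _spawn_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; raises :class:`PipelineError` with the
    stage name and a partial report on failure."""
    cfg.validate()
    partial: dict = {}
    seeds = _spawn_seeds(cfg.seed, 4)  # sim, propensity, bootstrap handled inside
    stage = "load"
    try:
        if cfg.input_path is not None:
            dataset = read_trial_long(
                cfg.input_path, cfg.schema, cfg.scale, cfg.placebo_arm
            )
        else:
            dataset, _truth = generate_trial(cfg.sim, seed=seeds[0])
        census = dataset.arm_census()
        partial["census"] = census
        log.info("stage load: %d subjects, arms %s", dataset.n_subjects, census)

        stage = "propensity"
        prop_model = PlaceboPropensityModel(
            dataset=dataset,
            threshold=cfg.threshold,
            split_fraction=cfg.split_fraction,
            candidates=cfg.candidates,
            train_config=cfg.train,
            clip=cfg.clip,
            n_boot=cfg.n_boot,
        )
        prop = prop_model.fit(seed=seeds[1])
        partial["topology"] = list(prop.topology)
        log.info(
            "stage propensity: topology %s, validation AUC %.3f",
            prop.topology, prop.roc.auc,
        )

        stage = "mmrm"
        effects: dict[str, dict] = {}
        for scheme, w in (("unweighted", None), ("weighted", prop.weights())):
            fit = MMRM.from_dataset(dataset, weights=w).fit()
            effects[scheme] = {}
            for arm in dataset.arms:
                if arm == dataset.placebo_arm:
                    continue
                eff = fit.treatment_effect(
                    arm,
                    visit=cfg.mmrm.analysis_visit,
                    alpha=cfg.mmrm.alpha,
                    df_method=cfg.mmrm.df_method,
                )
                effects[scheme][eff.comparison] = {
                    "te": eff.te, "se": eff.se, "df": eff.df, "p": eff.p,
                    "effect_size": eff.effect_size,
                    "n_active": eff.n_active, "n_placebo": eff.n_placebo,
                }
            log.info("stage mmrm (%s): %s", scheme, effects[scheme])

        stage = "sensitivity"
        report = run_sensitivity_grid(
            dataset, prop.table, cfg.low_cut, cfg.high_cut, cfg.mmrm
        )
        dist = bin_propensity(prop.table)
        log.info("stage sensitivity: bias %s", report.bias)

        stage = "report"
        run_report = RunReport(
            census=census,
            threshold=cfg.threshold.percent_reduction,
            n_labeled=len(prop.train_ids) + len(prop.valid_ids),
            n_unlabeled=prop.n_unlabeled,
            split_sizes={"train": len(prop.train_ids), "valid": len(prop.valid_ids)},
            topology=list(prop.topology),
            grid_table=[
                {**row, "topology": list(row["topology"])}
                for row in prop.grid_table.to_dict(orient="records")
            ],
            validation_auc={
                "auc": prop.roc.auc, "ci_low": prop.roc.ci_low,
                "ci_high": prop.roc.ci_high, "n_bootstrap": prop.roc.n_bootstrap,
            },
            propensity_distribution=dist.to_dict(orient="records"),
            treatment_effects=effects,
            sensitivity=report.to_json_dict(),
            bias=report.bias,
            version=__version__,
            config_hash=cfg.config_hash(),
            seed=cfg.seed,
        )
        if cfg.out_dir:
            os.makedirs(cfg.out_dir, exist_ok=True)
            run_report.to_json(os.path.join(cfg.out_dir, "report.json"))
            prop.table.to_csv(
                os.path.join(cfg.out_dir, "propensity.csv"), index=False
            )
            prop.net.save(os.path.join(cfg.out_dir, "model.json"))
            report.to_csv(os.path.join(cfg.out_dir, "sensitivity_contrasts.csv"))
        return run_report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc, partial) from exc
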