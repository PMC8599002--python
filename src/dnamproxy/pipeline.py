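"""End-to-end orchestration: simulate → QC → transform → train → project →
deconvolve → validate, with a manifest for reproducible runs.

The pipeline carries two-cohort semantics built in: one simulated cohort is
split batch-disjointly into a *training* cohort (where the elastic-net
predictor is fit with batch-defined cross-validation folds) and a
*projection* cohort (where the trained score is projected, cell proportions
are estimated, and the association battery runs).  This mirrors the standard
train-in-one-cohort / validate-in-an-independent-cohort design.

Every artifact is written under the output directory together with a
``manifest.json`` recording the configuration hash, master seed, package and
library versions, per-stage timings and record counts.  Reruns with the same
configuration and seed produce byte-identical weights and report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import estimate_proportions
from .elasticnet import ElasticNetConfig, fit_predictor
from .methdata import BetaMatrix, filter_probes_by_detection, filter_samples_by_callrate
from .pheno import rank_inverse_normal, residualize
from .score import ProbeWeights, project_score, write_weights
from .simulate import SimulationConfig, simulate_cohort
from .validate import BatteryConfig, run_battery

__all__ = ["RunConfig", "QCConfig", "run_pipeline", "PipelineError", "config_hash"]

logger = logging.getLogger("dnamproxy")

ALL_STAGES = (
    "simulate", "qc", "transform", "train", "project", "deconvolve", "validate",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class QCConfig:
    """Detection-based QC thresholds (probe filter and sample call rate)."""

    probe_p_threshold: float = 0.01
    probe_max_fail_fraction: float = 0.05
    sample_p_threshold: float = 0.01
    sample_min_detected_fraction: float = 0.95


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "dnamproxy_run"
    stages: tuple[str, ...] = ALL_STAGES
    train_batch_fraction: float = 2.0 / 3.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    elasticnet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    write_matrices: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("simulation", SimulationConfig),
            ("qc", QCConfig),
            ("elasticnet", ElasticNetConfig),
            ("battery", BatteryConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = dict(kwargs[key])
                for f in dataclasses.fields(sub):
                    if f.name in d and isinstance(d[f.name], list):
                        d[f.name] = tuple(d[f.name])
                kwargs[key] = sub(**d)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def clean(v):
            if isinstance(v, tuple):
                return [clean(x) for x in v]
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            return v

        return clean(d)


def config_hash(config: RunConfig) -> str:
    """SHA-256 over the canonical JSON form of the configuration."""
    blob = json.dumps(config.to_canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _split_batches(batches: pd.Series, fraction: float):
    labels = sorted(batches.unique())
    if len(labels) < 2:
        raise ValueError("need ≥ 2 batches for a batch-disjoint split")
    k = max(1, min(len(labels) - 1, round(len(labels) * fraction)))
    train_labels = set(labels[:k])
    train = batches.index[batches.isin(train_labels)]
    test = batches.index[~batches.isin(train_labels)]
    return list(train), list(test)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Raises :class:`PipelineError` naming the failed stage; in that case a
    manifest flagging the partial artifacts is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dnamproxy",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": int(config.seed),
        "config_hash": config_hash(config),
        "stages": {},
        "complete": False,
    }
    state: dict = {}

    def stage(name: str):
        def deco(fn):
            if name not in config.stages:
                return
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                counts = fn() or {}
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }
            logger.info("stage %s: done (%s)", name, counts)

        return deco

    @stage("simulate")
    def _simulate():
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
        state["cohort"] = cohort
        train_ids, test_ids = _split_batches(
            cohort.beta.batch, config.train_batch_fraction
        )
        state["train_ids"], state["test_ids"] = train_ids, test_ids
        if config.write_matrices:
            cohort.beta.values.to_csv(out / "beta.tsv", sep="\t",
                                      float_format="%.6g")
            cohort.beta.detection_p.to_csv(out / "detection_p.tsv", sep="\t",
                                           float_format="%.6g")
        cohort.phenotypes.to_csv(out / "phenotypes.csv")
        cohort.truth.cell_proportions_true.to_csv(
            out / "true_cell_proportions.csv", float_format="%.10g"
        )
        truth_probes = pd.DataFrame(
            {
                "probe": list(cohort.truth.causal_probe_ids)
                + list(cohort.truth.smoking_probe_ids),
                "role": ["causal"] * len(cohort.truth.causal_probe_ids)
                + ["smoking"] * len(cohort.truth.smoking_probe_ids),
                "effect": np.concatenate(
                    [cohort.truth.causal_effects, cohort.truth.smoking_effects]
                ),
            }
        )
        truth_probes.to_csv(out / "true_probe_effects.tsv", sep="\t", index=False,
                            float_format="%.10g")
        return {
            "n_samples": cohort.beta.n_samples,
            "n_probes": cohort.beta.n_probes,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
        }

    @stage("qc")
    def _qc():
        cohort = state["cohort"]
        qc = config.qc
        min_det = int(np.ceil(qc.sample_min_detected_fraction * cohort.beta.n_probes))

        def run_qc(m: BetaMatrix) -> BetaMatrix:
            m = filter_samples_by_callrate(m, qc.sample_p_threshold, min_det)
            m = filter_probes_by_detection(
                m, qc.probe_p_threshold, qc.probe_max_fail_fraction
            )
            return m

        train_m = run_qc(cohort.beta.subset(samples=state["train_ids"]))
        test_m = run_qc(cohort.beta.subset(samples=state["test_ids"]))
        # score projection needs a shared probe vocabulary: train on the probes
        # that also survive in the projection cohort (array-intersection analog)
        state["train_beta"], state["test_beta"] = train_m, test_m
        return {
            "train_probes": train_m.n_probes,
            "train_samples": train_m.n_samples,
            "test_probes": test_m.n_probes,
            "test_samples": test_m.n_samples,
        }

    @stage("transform")
    def _transform():
        cohort = state["cohort"]
        train_m = state["train_beta"]
        ph = cohort.phenotypes.loc[train_m.sample_ids]
        ri = rank_inverse_normal(ph["serum_biomarker"])
        target = residualize(ri, ph[["age", "sex"]])
        state["target"] = target
        return {"n_target": int(target.size)}

    @stage("train")
    def _train():
        train_m = state["train_beta"]
        weights, cv = fit_predictor(
            train_m,
            state["target"],
            config=config.elasticnet,
            trait_name="serum_biomarker",
        )
        state["weights"], state["cv"] = weights, cv
        write_weights(weights, out / "weights.tsv")
        pd.DataFrame(
            {
                "lambda": cv.lambdas,
                "mean_cv_error": cv.mean_cv_error,
                "cv_se": cv.cv_se,
                "nonzero": cv.nonzero,
            }
        ).to_csv(out / "cv_curve.tsv", sep="\t", index=False, float_format="%.10g")
        return {
            "n_selected": len(weights),
            "selected_lambda": cv.selected_lambda,
        }

    @stage("project")
    def _project():
        scores = project_score(state["test_beta"], state["weights"])
        state["scores"] = scores
        scores.to_frame().to_csv(out / "scores.csv", float_format="%.10g")
        return {"n_scored": int(scores.size)}

    @stage("deconvolve")
    def _deconvolve():
        cohort = state["cohort"]
        props = estimate_proportions(
            state["test_beta"], cohort.truth.reference_used
        )
        state["cells"] = props
        props.to_csv(out / "cell_proportions.csv", float_format="%.10g")
        return {"n_samples": int(props.shape[0])}

    @stage("validate")
    def _validate():
        cohort = state["cohort"]
        test_ids = state["test_beta"].sample_ids
        ph = cohort.phenotypes.loc[test_ids]
        # synthetic methylation smoking score: project the true smoking-probe
        # effects as an externally-derived weight set
        truth = cohort.truth
        smoking_score = None
        if truth.smoking_probe_ids:
            smk_w = ProbeWeights(
                weights=pd.Series(
                    truth.smoking_effects, index=list(truth.smoking_probe_ids)
                ),
                metadata={"trait": "smoking(synthetic)"},
            )
            smoking_score = project_score(state["test_beta"], smk_w)
        report = run_battery(
            ph,
            state["scores"],
            cell_proportions=state.get("cells"),
            smoking_score=smoking_score,
            config=config.battery,
        )
        state["report"] = report
        (out / "report.json").write_text(report.to_json())
        return {
            "n_correlations": len(report.correlations),
            "n_associations": len(report.all_results()),
        }

    manifest["complete"] = all(
        manifest["stages"].get(s, {}).get("status") == "ok"
        for s in config.stages
    )
    _write_manifest(out, manifest)
    manifest["_state"] = state
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
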