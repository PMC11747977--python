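"""Configuration-driven orchestration of the full analysis chain.

A single YAML config selects stages and parameters; one master seed spawns
per-stage seeds through a counter scheme, so the same config reproduces
byte-identical summary tables.  The default demo chain runs entirely on
the synthetic cohort: simulate -> feature extraction -> both classifiers
-> reviewer-label agreement -> prevalence model, and writes a run report
with per-stage provenance.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import agreement as agr
from . import classify as clf
from . import features as feat
from . import posterior as post
from . import synthetic as syn


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    features: bool = True
    classify: bool = True
    agreement: bool = True
    model: bool = True


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 10
    seizures_per_patient: int = 3
    snr_db: float = 10.0
    n_ic: int = 6
    n_clear_ic: int = 2
    effects: list = []


class ClassifyParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 500
    max_depth: int = 3


class AgreementParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 2000
    miss_rate: float = 0.1
    confusion_rate: float = 0.05


class ModelParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    side: str = "onset"
    chains: int = 2
    iterations: int = 2000
    warmup: int = 500
    covariates: list = ["vigilance"]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    out_dir: str = "seizdyn_run"
    master_seed: int = 0
    stages: StageToggles = StageToggles()
    simulate: SimulateParams = SimulateParams()
    classify: ClassifyParams = ClassifyParams()
    agreement: AgreementParams = AgreementParams()
    model: ModelParams = ModelParams()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class RunReport:
    stages: list = field(default_factory=list)
    summaries: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "summaries": self.summaries,
             "warnings": self.warnings},
            indent=1, default=str,
        )


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31 - 1))


def extract_ic_features(ic_table: pd.DataFrame) -> pd.DataFrame:
    """Per-IC, per-side feature rows for both classification tasks."""
    rows = []
    for r in ic_table.itertuples(index=False):
        for side in ("onset", "offset"):
            trace = r.trace if side == "onset" else feat.flip_trace(r.trace)
            T = trace.size / r.fs
            annot = r.true_onset_s if side == "onset" else T - r.true_offset_s
            cp = feat.detect_change_point(trace, r.fs, center_s=annot)
            fv = feat.extract_feature_vector(
                trace, r.fs, side, cp, brain_score=r.brain_score
            )
            meta = {
                "patient_id": r.patient_id,
                "seizure_id": r.seizure_id,
                "ic_index": r.ic_index,
                "side": side,
                "label_clear": bool(r.clear),
                "label_slowing": bool(
                    r.clear
                    and (
                        (side == "onset" and r.onset_bifm == "SNIC")
                        or (side == "offset" and r.offset_bifm == "SNIC/SH")
                    )
                ),
                "anchor_s": cp.time_s,
            }
            rows.append((meta, fv))
    meta_df = pd.DataFrame([m for m, _ in rows])
    vals_df = pd.DataFrame([fv.values for _, fv in rows])
    return pd.concat([meta_df.reset_index(drop=True), vals_df.reset_index(drop=True)], axis=1)


_META_COLS = ("patient_id", "seizure_id", "ic_index", "side", "label_clear",
              "label_slowing", "anchor_s")


def run_classification_tasks(
    feature_table: pd.DataFrame, config: clf.ClassifierConfig
) -> dict[str, clf.CvReport]:
    """Both LOOCV tasks from an assembled per-IC feature table."""
    values = feature_table.drop(columns=list(_META_COLS))
    vectors = []
    for _, row in values.iterrows():
        fv = feat.FeatureVector(side="onset")
        for name, v in row.items():
            fv.set(name, v)
        vectors.append(fv)
    reports = {}
    fm = feat.assemble_feature_matrix(vectors, "transition_detection")
    reports["transition_detection"] = clf.loocv_evaluate(
        fm, feature_table.label_clear.to_numpy(),
        feature_table.patient_id.to_numpy(), config, task="transition_detection",
    )
    clear_mask = feature_table.label_clear.to_numpy()
    clear_vectors = [v for v, keep in zip(vectors, clear_mask) if keep]
    fm2 = feat.assemble_feature_matrix(clear_vectors, "isi_slowing")
    reports["isi_slowing"] = clf.loocv_evaluate(
        fm2, feature_table.label_slowing.to_numpy()[clear_mask],
        feature_table.patient_id.to_numpy()[clear_mask], config, task="isi_slowing",
    )
    return reports


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in dependency order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    t_start = time.time()

    ic_table = None
    truth = None
    meta = None
    if config.stages.simulate:
        seed = _stage_seed(config.master_seed, 1)
        cohort = syn.CohortSpec(
            n_patients=config.simulate.n_patients,
            seizures_per_patient=config.simulate.seizures_per_patient,
            snr_db=config.simulate.snr_db,
            effects=[tuple(e) for e in config.simulate.effects],
            seed=seed,
        )
        specs, meta, truth = syn.generate_cohort(cohort)
        ic_table = syn.simulate_ic_dataset(
            cohort, seed=seed, n_ic=config.simulate.n_ic,
            n_clear_ic=config.simulate.n_clear_ic,
        )
        meta.to_csv(out / "cohort_metadata.csv", index=False)
        truth.to_csv(out / "cohort_truth.csv", index=False)
        report.stages.append({"stage": "simulate", "seed": seed,
                              "n_seizures": len(truth)})

    feature_table = None
    if config.stages.features:
        if ic_table is None:
            raise RuntimeError("features stage requires the simulate stage")
        feature_table = extract_ic_features(ic_table)
        feature_table.to_csv(out / "features.csv", index=False)
        report.stages.append({"stage": "features", "rows": len(feature_table)})

    if config.stages.classify:
        if feature_table is None:
            raise RuntimeError("classify stage requires the features stage")
        seed = _stage_seed(config.master_seed, 2)
        cc = clf.ClassifierConfig(
            max_depth=config.classify.max_depth,
            n_trees=config.classify.n_trees, seed=seed,
        )
        reports = run_classification_tasks(feature_table, cc)
        for task, rep in reports.items():
            rep.per_patient.to_csv(out / f"classification_{task}_by_patient.csv",
                                   index=False)
            report.summaries[f"{task}_pooled_ba"] = rep.pooled_ba
            report.summaries[f"{task}_pooled_auc"] = rep.pooled_auc
        report.stages.append({"stage": "classify", "seed": seed})

    final = None
    if config.stages.agreement:
        if truth is None:
            raise RuntimeError("agreement stage requires the simulate stage")
        seed = _stage_seed(config.master_seed, 3)
        labels = syn.simulate_reviewer_labels(
            truth, miss_rate=config.agreement.miss_rate,
            confusion_rate=config.agreement.confusion_rate, seed=seed,
        )
        labels.to_csv(out / "reviewer_labels.csv", index=False)
        agr_res = agr.agreement_report(labels, n_perm=config.agreement.n_perm,
                                       seed=seed)
        final = agr.reconcile_labels(labels)
        per_seizure, summary = agr.seizure_level_bifm(final)
        per_seizure.to_csv(out / "seizure_level_bifm.csv", index=False)
        summary.to_csv(out / "bifm_summary.csv", index=False)
        report.summaries["agreement"] = {
            name: {"kappa": r.kappa, "n": r.n,
                   "perm_mean": r.perm_mean_kappa, "p": r.p_value}
            for name, r in agr_res.items()
        }
        report.stages.append({"stage": "agreement", "seed": seed})

    if config.stages.model:
        if final is None or meta is None:
            raise RuntimeError("model stage requires the agreement stage")
        seed = _stage_seed(config.master_seed, 4)
        per_seizure, _ = agr.seizure_level_bifm(final)
        side = config.model.side
        recs = per_seizure[per_seizure.side == side].merge(
            meta, on=["patient_id", "seizure_id"]
        )
        posterior = post.fit_bifm_model(
            recs, side,
            post.McmcConfig(chains=config.model.chains,
                            iterations=config.model.iterations,
                            warmup=config.model.warmup, seed=seed),
            covariates=config.model.covariates or None,
        )
        diag = post.diagnostics(posterior)
        report.summaries["model"] = {
            "side": side,
            "max_rhat": diag.max_rhat,
            "pp_check_ok": bool(diag.pp_check.inside.all()) if len(diag.pp_check) else None,
        }
        report.stages.append({"stage": "model", "seed": seed})

    report.summaries["runtime_s"] = round(time.time() - t_start, 2)
    (out / "run_report.json").write_text(report.to_json())
    return report
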