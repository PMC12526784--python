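"""End-to-end pipeline orchestration with provenance.

Runs simulate -> extract -> rank -> classify -> stats as one reproducible
run: every stage writes plain CSV/JSON artifacts into the output directory,
and a run manifest records the config snapshot, seeds, package version,
SHA-256 digests of all artifacts, stage timings and warning counts.
Re-running with the same config and seed reproduces identical artifacts;
stages whose outputs already match the manifest digests are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import sample_cohort
from .config import CohortConfig, ConfigError, PipelineConfig
from .features import FEATURE_NAMES, build_feature_table
from .groupstats import format_report, summarize_cohort
from .io import write_cohort_csv, write_ground_truth_json, write_recording_csv
from .models import cv_logistic_accuracy, dementia_outcome, fit_logistic, train_eval_svm
from .relieff import rank_and_select, relieff_weights
from .report import confusion_matrix_figure, relieff_table
from .simulate import synthesize_recording

__all__ = ["RunManifest", "run_pipeline", "STAGES", "ARTIFACTS"]

STAGES = ("simulate", "extract", "rank", "classify", "stats")

#: stage -> primary artifact files
ARTIFACTS = {
    "simulate": ("cohort.csv", "ground_truth.json"),
    "extract": ("features.csv",),
    "rank": ("relieff.csv",),
    "classify": ("svm_report.json", "logistic.json"),
    "stats": ("groupstats.csv",),
}


@dataclass
class RunManifest:
    config: dict
    pipeline: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> {status, seconds, warnings}
    artifacts: dict = field(default_factory=dict)  # filename -> sha256
    error: str | None = None

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        try:
            return cls(**json.loads(path.read_text()))
        except Exception:
            return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: CohortConfig | None = None,
    pipeline: PipelineConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path = "gaitsev_run",
    stages: tuple[str, ...] = STAGES,
    write_recordings: bool = False,
    resume: bool = True,
) -> RunManifest:
    """Execute the pipeline stages, writing artifacts and the run manifest.

    With ``resume`` (default), stages whose artifacts already exist with
    digests matching a previous manifest for the same config and seed are
    skipped.  On a stage failure the manifest records the stage and error;
    partial outputs keep a ``.partial`` suffix.
    """
    config = config or CohortConfig()
    pipeline = pipeline or PipelineConfig()
    config.validate()
    pipeline.validate(config.sampling_rate_hz)
    if config.n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    master = config.seed if seed is None else seed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    def _norm(d: dict) -> dict:  # JSON-normalized (tuples -> lists) for comparison
        return json.loads(json.dumps(d))

    manifest = RunManifest(
        config=_norm(config.to_dict()),
        pipeline=_norm(dataclasses.asdict(pipeline)),
        seed=master,
    )
    prev = RunManifest.load(out / "run_manifest.json") if resume else None
    if prev is not None and (
        prev.config != manifest.config
        or prev.seed != manifest.seed
        or prev.pipeline != manifest.pipeline
    ):
        prev = None

    def stage_done(name: str) -> bool:
        if prev is None:
            return False
        for f in ARTIFACTS[name]:
            p = out / f
            if not p.exists() or prev.artifacts.get(f) != _sha256(p):
                return False
        return True

    def finish_stage(name: str, t0: float, warnings: int = 0, skipped=False) -> None:
        manifest.stages[name] = {
            "status": "skipped" if skipped else "ok",
            "seconds": round(time.time() - t0, 3),
            "warnings": warnings,
        }
        for f in ARTIFACTS[name]:
            p = out / f
            if p.exists():
                manifest.artifacts[f] = _sha256(p)

    profiles = None
    table = None
    try:
        for name in STAGES:
            if name not in stages:
                continue
            t0 = time.time()
            if resume and stage_done(name) and name in ("simulate", "extract"):
                # reuse on-disk artifacts without recomputation
                if name == "extract":
                    table = pd.read_csv(out / "features.csv")
                finish_stage(name, t0, skipped=True)
                continue

            if name == "simulate":
                profiles = sample_cohort(config, master)
                write_cohort_csv(profiles, out / "cohort.csv")
                write_ground_truth_json(profiles, out / "ground_truth.json")
                if write_recordings:
                    rec_dir = out / "recordings"
                    rec_dir.mkdir(exist_ok=True)
                    for p in profiles:
                        rec = synthesize_recording(p, config, master)
                        write_recording_csv(rec, rec_dir / f"{p.subject_id}.csv")
                n_warn = sum(len(p.warnings) for p in profiles)
                finish_stage(name, t0, warnings=n_warn)

            elif name == "extract":
                if profiles is None:
                    profiles = sample_cohort(config, master)
                table, excluded = build_feature_table(
                    config, pipeline, master, profiles=profiles
                )
                table.to_csv(out / "features.csv", index=False)
                if excluded:
                    (out / "excluded_subjects.txt").write_text("\n".join(excluded))
                finish_stage(name, t0, warnings=len(excluded))

            elif name == "rank":
                table = _need_table(table, out)
                w = relieff_weights(
                    table[list(FEATURE_NAMES)].to_numpy(),
                    table["group"].to_numpy(),
                    FEATURE_NAMES,
                    k=pipeline.relieff_k,
                    seed=master,
                )
                pd.DataFrame(
                    {
                        "feature": list(w.feature_names),
                        "weight": w.weights,
                        "rank": [w.rank_of(f) for f in w.feature_names],
                    }
                ).to_csv(out / "relieff.csv", index=False)
                (out / "relieff.txt").write_text(relieff_table(w))
                (out / "relieff.json").write_text(
                    json.dumps(
                        {
                            "weights": w.as_dict(),
                            "ranking": w.ranking,
                            "k_neighbors": w.k_neighbors,
                            "n_sampled": w.n_sampled,
                        },
                        indent=1,
                    )
                )
                finish_stage(name, t0)

            elif name == "classify":
                table = _need_table(table, out)
                w = relieff_weights(
                    table[list(FEATURE_NAMES)].to_numpy(),
                    table["group"].to_numpy(),
                    FEATURE_NAMES,
                    k=pipeline.relieff_k,
                    seed=master,
                )
                selected = rank_and_select(w, pipeline.n_features_select)
                report = train_eval_svm(
                    table,
                    selected,
                    folds=pipeline.svm_folds,
                    seed=master,
                    kernel=pipeline.svm_kernel,
                )
                (out / "svm_report.json").write_text(json.dumps(report.as_dict(), indent=1))
                confusion_matrix_figure(report, out / "confusion.png")
                sub = dementia_outcome(table)
                fit = fit_logistic(sub, ["knee_rom", "hip_rom"])
                payload = fit.as_dict()
                payload["cv_accuracy"] = cv_logistic_accuracy(
                    sub, ["knee_rom", "hip_rom"], folds=pipeline.svm_folds, seed=master
                )
                (out / "logistic.json").write_text(json.dumps(payload, indent=1))
                finish_stage(name, t0)

            elif name == "stats":
                table = _need_table(table, out)
                demo = None
                cohort_path = out / "cohort.csv"
                if cohort_path.exists():
                    demo = pd.read_csv(cohort_path)
                summary = summarize_cohort(table, demographics=demo, seed=master)
                summary.to_csv(out / "groupstats.csv", index=False)
                (out / "groupstats.txt").write_text(format_report(summary))
                finish_stage(name, t0)
    except Exception as exc:
        manifest.error = f"stage {name}: {exc}\n{traceback.format_exc(limit=3)}"
        for f in ARTIFACTS.get(name, ()):
            p = out / f
            if p.exists() and f not in manifest.artifacts:
                p.rename(p.with_suffix(p.suffix + ".partial"))
        manifest.save(out / "run_manifest.json")
        raise

    manifest.save(out / "run_manifest.json")
    return manifest


def _need_table(table, out: Path) -> pd.DataFrame:
    if table is not None:
        return table
    path = out / "features.csv"
    if not path.exists():
        raise ConfigError("features.csv missing: run the extract stage first")
    return pd.read_csv(path)
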