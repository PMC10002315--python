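"""End-to-end orchestration: synthesize -> extract -> cluster -> classify.

A run is fully described by a :class:`RunConfig` (YAML-serializable); all
stage randomness derives deterministically from the master seed, so two
runs from one config produce byte-identical metrics.  Stages communicate
only through the declared files/types: HAM-D CSV, per-subject WAVs, the
feature CSV, the assignment CSV and the metrics JSON.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio import read_wav, write_wav
from .classify import crossvalidate, feature_report
from .clustering import cluster_cohort, item_wise_tests, write_assignment_csv
from .cohort import CohortConfig, generate_cohort_dataset
from .featurevector import (
    DEFAULT_REGISTRY,
    extract_feature_vector,
    feature_table,
    write_feature_csv,
)
from .hamd import HamdRecord, read_hamd_csv, write_hamd_csv


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    out_dir: str = "voicesym_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_restarts: int = 20
    n_folds: int = 5
    learner: dict = field(default_factory=dict)
    cutoff_on: str = "train"
    skip_synthesis: bool = False
    audio_dir: str | None = None   # used when skip_synthesis
    hamd_csv: str | None = None
    write_wavs: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in d and isinstance(d["cohort"], dict):
            ck = set(CohortConfig.__dataclass_fields__)
            bad = set(d["cohort"]) - ck
            if bad:
                raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)


@dataclass
class RunReport:
    """Summary of a completed run plus the artifact manifest."""

    config: dict
    timings: dict[str, float]
    group_sizes: dict[str, int]
    item_test_tiers: dict[str, int]
    accuracy: float
    sensitivity: float
    specificity: float
    manifest: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _load_user_dataset(audio_dir: str, hamd_csv: str) -> tuple[list[HamdRecord], dict]:
    records = read_hamd_csv(hamd_csv)
    recs = {}
    root = Path(audio_dir)
    for r in records:
        for wav in sorted(root.glob(f"{r.subject_id}_phrase*.wav")):
            pid = int(wav.stem.split("phrase")[-1])
            recs[(r.subject_id, pid)] = read_wav(wav, phrase_id=pid, subject_id=r.subject_id)
    return records, recs


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; any stage error aborts with its name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    timings: dict[str, float] = {}

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return _Ctx()

    # --- synthesis (or user-data loading) -------------------------------
    with _stage("synthesis"):
        if config.skip_synthesis:
            if not (config.audio_dir and config.hamd_csv):
                raise ValueError("skip_synthesis requires audio_dir and hamd_csv")
            records, recordings = _load_user_dataset(config.audio_dir, config.hamd_csv)
        else:
            cohort_cfg = config.cohort
            if cohort_cfg.seed != config.seed:
                cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.seed})
            ds = generate_cohort_dataset(cohort_cfg)
            records, recordings = ds.hamd, ds.recordings
            hamd_path = out / "hamd.csv"
            write_hamd_csv(hamd_path, records)
            manifest.append(str(hamd_path))
            if config.write_wavs:
                wav_dir = out / "wav"
                wav_dir.mkdir(exist_ok=True)
                for (sid, pid), rec in sorted(recordings.items()):
                    p = wav_dir / f"{sid}_phrase{pid:02d}.wav"
                    write_wav(p, rec)
                    manifest.append(str(p))

    # --- feature extraction ---------------------------------------------
    with _stage("extract"):
        by_subject: dict[str, list] = {}
        for (sid, pid), rec in sorted(recordings.items()):
            by_subject.setdefault(sid, []).append(rec)
        vectors = [extract_feature_vector(v) for v in by_subject.values()]
        feats = feature_table(vectors)
        feat_path = out / "features.csv"
        write_feature_csv(feat_path, feats)
        manifest.append(str(feat_path))
        reg_path = out / "registry.json"
        DEFAULT_REGISTRY.to_json(reg_path)
        manifest.append(str(reg_path))

    # --- clustering ------------------------------------------------------
    with _stage("cluster"):
        clus = cluster_cohort(records, seed=config.seed, n_restarts=config.n_restarts)
        assign_path = out / "assignment.csv"
        write_assignment_csv(assign_path, clus)
        manifest.append(str(assign_path))
        report = item_wise_tests(records, clus.assignment)
        tests_path = out / "item_tests.json"
        report.to_json(tests_path)
        manifest.append(str(tests_path))
        groups = {s: g for s, g in clus.assignment.items() if g != "excluded"}

    # --- classification --------------------------------------------------
    with _stage("classify"):
        cv = crossvalidate(
            feats, groups, n_folds=config.n_folds, seed=config.seed,
            learner_config=config.learner, cutoff_on=config.cutoff_on,
        )
        metrics_path = out / "metrics.json"
        cv.to_json(metrics_path)
        manifest.append(str(metrics_path))
        rep = feature_report(cv)
        rep_path = out / "feature_report.csv"
        rep.to_csv(rep_path, index=False)
        manifest.append(str(rep_path))

    report_obj = RunReport(
        config=asdict(config),
        timings=timings,
        group_sizes={
            "group_1": sum(1 for g in groups.values() if g == 1),
            "group_2": sum(1 for g in groups.values() if g == 2),
            "excluded": sum(1 for g in clus.assignment.values() if g == "excluded"),
        },
        item_test_tiers={k: int(v["tier"]) for k, v in report.tests.items()},
        accuracy=cv.accuracy,
        sensitivity=cv.sensitivity,
        specificity=cv.specificity,
        manifest=manifest,
    )
    report_obj.to_json(out / "run_report.json")
    return report_obj


def validate_inputs(audio_dir: str | Path, hamd_csv: str | Path) -> pd.DataFrame:
    """Check user-supplied WAVs and HAM-D CSV; one pass/fail row per subject.

    Checks: every WAV readable, mono; phrase coverage 1-21 per subject;
    HAM-D items in range with total equal to the item sum.
    """
    audio_dir = Path(audio_dir)
    hamd_csv = Path(hamd_csv)
    if not audio_dir.exists() or not hamd_csv.exists():
        raise FileNotFoundError("audio_dir and hamd_csv must exist")
    df = pd.read_csv(hamd_csv)
    rows = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        problems = []
        try:
            items = np.array([row[f"item_{k + 1}"] for k in range(17)], dtype=int)
            HamdRecord(subject_id=sid, items=items, total=int(row.get("total", -1)))
        except (ValueError, KeyError) as exc:
            problems.append(f"hamd: {exc}")
        found = set()
        for wav in sorted(audio_dir.glob(f"{sid}_phrase*.wav")):
            try:
                rec = read_wav(wav)
                found.add(int(wav.stem.split("phrase")[-1]))
            except ValueError as exc:
                problems.append(f"{wav.name}: {exc}")
        missing = set(range(1, 22)) - found
        if missing:
            problems.append(f"missing phrases: {sorted(missing)}")
        rows.append(
            {"subject_id": sid, "ok": not problems, "problems": "; ".join(problems)}
        )
    return pd.DataFrame(rows)
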