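"""Feature registry and per-subject feature-vector assembly.

Every acoustic feature of every phrase is an independent predictor: the
registry enumerates the (feature, statistic, phrase) triples in a fixed
order, per-recording extraction aggregates frame/cycle series to a mean and
standard deviation (jitter and shimmer are single per-recording values),
and a subject's 21 phrase recordings flatten into one fixed-dimension
vector.  Missing features (no voiced frames, too few cycles) stay missing
(NaN) rather than being imputed here; the tree learner consumes NaN
natively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioRecording, FrameSeries
from .features import (
    _acf_pitch_frames,
    F0_MAX_DEFAULT,
    F0_MIN_DEFAULT,
    HNR_CEILING_DB,
    VOICING_THRESHOLD,
    extract_cycles,
    formants,
    jitter_local,
    mfcc,
    shimmer_local,
    spectral_features,
)
from .glottalflow import glottal_quotients, iaif

N_PHRASES = 21

# Frame/cycle-wise features carry both mean and std; scalar features only mean.
SERIES_FEATURES: tuple[str, ...] = (
    "naq",
    "qoq",
    "band_power_0_500",
    "band_power_500_1000",
    "band_power_1000_4000",
    "spectral_centroid",
    "spectral_flux",
    "formant_1",
    "formant_2",
    "formant_3",
    "formant_4",
    "formant_5",
    *tuple(f"mfcc_{i}" for i in range(1, 13)),
    "energy_rms",
    "f0",
    "hnr",
)
SCALAR_FEATURES: tuple[str, ...] = ("jitter", "shimmer")


@dataclass(frozen=True)
class FeatureRegistry:
    """Single source of truth for which (feature, statistic, phrase)
    triples exist and in what order."""

    series_features: tuple[str, ...] = SERIES_FEATURES
    scalar_features: tuple[str, ...] = SCALAR_FEATURES
    phrase_ids: tuple[int, ...] = tuple(range(1, N_PHRASES + 1))
    version: str = "v1"

    def triples(self) -> list[tuple[str, str, int]]:
        out = []
        for pid in self.phrase_ids:
            for f in self.series_features:
                out.append((f, "mean", pid))
                out.append((f, "std", pid))
            for f in self.scalar_features:
                out.append((f, "mean", pid))
        return out

    @property
    def dimension(self) -> int:
        return (2 * len(self.series_features) + len(self.scalar_features)) * len(self.phrase_ids)

    def column_names(self) -> list[str]:
        return [f"{f}__{s}__phrase{p:02d}" for f, s, p in self.triples()]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "series_features": list(self.series_features),
            "scalar_features": list(self.scalar_features),
            "phrase_ids": list(self.phrase_ids),
            "dimension": self.dimension,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


DEFAULT_REGISTRY = FeatureRegistry()


@dataclass
class FeatureVector:
    """Ordered (feature, statistic, phrase) -> value map for one subject."""

    subject_id: str
    entries: dict[tuple[str, str, int], float]
    registry_version: str = DEFAULT_REGISTRY.version

    def as_array(self, registry: FeatureRegistry = DEFAULT_REGISTRY) -> np.ndarray:
        return np.array([self.entries.get(t, np.nan) for t in registry.triples()])


def _agg(values: np.ndarray) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan
    return float(np.mean(v)), float(np.std(v))


def extract_recording_features(rec: AudioRecording) -> dict[tuple[str, str], float]:
    """All registry features for one recording, keyed (feature, statistic).

    One pitch pass feeds F0, HNR, the formant voicing gate, cycle
    extraction and IAIF, so the expensive analyses run once each.
    """
    out: dict[tuple[str, str], float] = {}

    f0_vals, r_vals, _ = _acf_pitch_frames(rec, F0_MIN_DEFAULT, F0_MAX_DEFAULT)
    voiced = r_vals > VOICING_THRESHOLD
    f0_voiced = f0_vals[voiced]
    out[("f0", "mean")], out[("f0", "std")] = _agg(f0_voiced)
    rv = np.clip(r_vals[voiced], 1e-6, 1 - 1e-9)
    hnr_vals = np.minimum(10.0 * np.log10(rv / (1.0 - rv)), HNR_CEILING_DB)
    out[("hnr", "mean")], out[("hnr", "std")] = _agg(hnr_vals)

    for name, series in spectral_features(rec).items():
        out[(name, "mean")], out[(name, "std")] = _agg(series.voiced_values())

    for i, series in enumerate(mfcc(rec), start=1):
        out[(f"mfcc_{i}", "mean")], out[(f"mfcc_{i}", "std")] = _agg(series.values)

    f0_hint = float(np.median(f0_voiced)) if len(f0_voiced) else None
    for i, series in enumerate(formants(rec, voiced_mask=voiced), start=1):
        out[(f"formant_{i}", "mean")], out[(f"formant_{i}", "std")] = _agg(series.values)

    jit = shim = np.nan
    if f0_hint is not None:
        periods, amps = extract_cycles(rec, f0_hint=f0_hint)
        if len(periods) >= 2:
            jit = jitter_local(periods)
            shim = shimmer_local(amps)
    out[("jitter", "mean")] = jit
    out[("shimmer", "mean")] = shim

    naq_m = naq_s = qoq_m = qoq_s = np.nan
    if f0_hint is not None:
        gf = iaif(rec, f0_hint=f0_hint)
        if gf.voiced and len(gf.cycle_boundaries) >= 2:
            q = glottal_quotients(gf)
            if len(q.naq):
                naq_m, naq_s = _agg(q.naq)
                qoq_m, qoq_s = _agg(q.qoq)
    out[("naq", "mean")], out[("naq", "std")] = naq_m, naq_s
    out[("qoq", "mean")], out[("qoq", "std")] = qoq_m, qoq_s
    return out


def extract_feature_vector(
    recordings: list[AudioRecording],
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> FeatureVector:
    """Flatten one subject's phrase recordings into the registry vector.

    Phrases absent from ``recordings`` yield missing values for their whole
    block; phrase ids outside the registry raise.
    """
    subjects = {r.subject_id for r in recordings}
    if len(subjects) > 1:
        raise ValueError(f"recordings from multiple subjects: {sorted(subjects)}")
    by_phrase: dict[int, AudioRecording] = {}
    for r in recordings:
        if r.phrase_id not in registry.phrase_ids:
            raise ValueError(f"unknown phrase id {r.phrase_id}")
        by_phrase[r.phrase_id] = r

    entries: dict[tuple[str, str, int], float] = {}
    per_phrase: dict[int, dict[tuple[str, str], float]] = {}
    for pid, rec in by_phrase.items():
        per_phrase[pid] = extract_recording_features(rec)
    for f, s, pid in registry.triples():
        entries[(f, s, pid)] = per_phrase.get(pid, {}).get((f, s), np.nan)
    sid = recordings[0].subject_id if recordings else ""
    return FeatureVector(subject_id=sid, entries=entries, registry_version=registry.version)


def feature_table(
    vectors: list[FeatureVector], registry: FeatureRegistry = DEFAULT_REGISTRY
) -> pd.DataFrame:
    """One row per subject, columns named feature__stat__phraseNN."""
    data = np.vstack([v.as_array(registry) for v in vectors])
    df = pd.DataFrame(data, columns=registry.column_names())
    df.insert(0, "subject_id", [v.subject_id for v in vectors])
    return df


def write_feature_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
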