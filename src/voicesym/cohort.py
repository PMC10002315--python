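"""Linked synthetic cohorts: HAM-D records plus per-subject phrase recordings.

Each subject belongs to one of two latent symptom groups.  The group drives
both the HAM-D item profile (via :func:`voicesym.hamd.generate_hamd_cohort`)
and the distribution of the glottal/tract parameters of the subject's 21
phrase recordings, so the downstream classifier has a recoverable acoustic
signal whose strength is one knob (``acoustic_effect``; 0 = identical
groups).

The group contrast mirrors the study's interpretation: the inactivity group
speaks with lower and flatter F0, a breathier source (higher open quotient,
lower aspiration SNR) and more cycle-to-cycle instability than the insomnia
group.  Between-group parameter shifts at ``acoustic_effect = 1`` are on
the order of the between-subject SD, a realistic overlap for clinical
voice data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioRecording
from .hamd import HamdRecord, default_profiles, generate_hamd_cohort
from .synth import FormantSpec, GlottalParams, synthesize_voice

N_PHRASES = 21

# Vowel-like tract templates cycled over the phrase catalogue so different
# phrases have different spectral character (first five formants, Hz).
_VOWEL_TEMPLATES: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...] = (
    ((710.0, 1100.0, 2540.0, 3400.0, 4500.0), (90.0, 110.0, 170.0, 250.0, 300.0)),  # /a/
    ((390.0, 1990.0, 2550.0, 3600.0, 4700.0), (70.0, 100.0, 160.0, 220.0, 300.0)),  # /e/-ish
    ((300.0, 870.0, 2240.0, 3400.0, 4400.0), (60.0, 90.0, 150.0, 220.0, 280.0)),   # /u/-ish
    ((530.0, 1840.0, 2480.0, 3500.0, 4600.0), (80.0, 100.0, 160.0, 230.0, 300.0)),  # /ae/-ish
)


def phrase_tract(phrase_id: int) -> FormantSpec:
    centers, bws = _VOWEL_TEMPLATES[(phrase_id - 1) % len(_VOWEL_TEMPLATES)]
    return FormantSpec(centers=centers, bandwidths=bws)


@dataclass
class CohortConfig:
    """Everything needed to generate a linked cohort reproducibly."""

    n_per_group: int = 20
    n_phrases: int = N_PHRASES
    duration: float = 2.0          # seconds per phrase recording
    rate: float = 11025.0
    acoustic_effect: float = 1.0   # scales all between-group parameter shifts
    hamd_effect: float = 1.5       # HAM-D profile separation in item-SD units
    item_corr_target: float = 0.7
    seed: int = 0
    # baseline glottal source (midpoint between the groups)
    f0_base: float = 120.0
    open_quotient_base: float = 0.62
    jitter_base: float = 1.2
    shimmer_base: float = 3.0
    noise_snr_base: float = 22.0
    # half-shifts applied +/- by group at acoustic_effect = 1
    f0_shift: float = 7.0
    open_quotient_shift: float = 0.06
    jitter_shift: float = 0.5
    shimmer_shift: float = 1.2
    noise_snr_shift: float = 3.0
    formant_scale_shift: float = 0.015
    # between-subject SDs
    f0_subject_sd: float = 9.0
    open_quotient_subject_sd: float = 0.045
    jitter_subject_sd: float = 0.35
    shimmer_subject_sd: float = 0.8
    noise_snr_subject_sd: float = 2.5
    formant_subject_sd: float = 0.02  # relative

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if not np.isfinite(self.acoustic_effect):
            raise ValueError("acoustic_effect must be finite")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class CohortDataset:
    """HAM-D records, recordings keyed (subject_id, phrase_id), true groups."""

    hamd: list[HamdRecord]
    recordings: dict[tuple[str, int], AudioRecording]
    true_group: dict[str, int]
    seed: int

    def subject_recordings(self, subject_id: str) -> list[AudioRecording]:
        return [rec for (sid, _), rec in sorted(self.recordings.items()) if sid == subject_id]


def _subject_glottal(
    cfg: CohortConfig, group: int, rng: np.random.Generator
) -> tuple[GlottalParams, float]:
    """Draw one subject's glottal parameters and formant scale factor."""
    sign = -1.0 if group == 1 else 1.0  # group 1: lower f0, breathier, less stable
    e = cfg.acoustic_effect
    f0 = cfg.f0_base + sign * e * cfg.f0_shift + cfg.f0_subject_sd * rng.standard_normal()
    oq = (
        cfg.open_quotient_base
        - sign * e * cfg.open_quotient_shift
        + cfg.open_quotient_subject_sd * rng.standard_normal()
    )
    jit = (
        cfg.jitter_base - sign * e * cfg.jitter_shift
        + cfg.jitter_subject_sd * rng.standard_normal()
    )
    shim = (
        cfg.shimmer_base - sign * e * cfg.shimmer_shift
        + cfg.shimmer_subject_sd * rng.standard_normal()
    )
    snr = (
        cfg.noise_snr_base + sign * e * cfg.noise_snr_shift
        + cfg.noise_snr_subject_sd * rng.standard_normal()
    )
    params = GlottalParams(
        f0_mean=float(np.clip(f0, 70.0, 320.0)),
        f0_sd=2.0,
        open_quotient=float(np.clip(oq, 0.35, 0.9)),
        jitter_pct=float(np.clip(jit, 0.1, 6.0)),
        shimmer_pct=float(np.clip(shim, 0.2, 12.0)),
        noise_snr_db=float(np.clip(snr, 8.0, 40.0)),
        amplitude=0.5,
    )
    fscale = 1.0 + sign * e * cfg.formant_scale_shift + cfg.formant_subject_sd * rng.standard_normal()
    return params, float(np.clip(fscale, 0.85, 1.15))


def generate_cohort_dataset(config: CohortConfig) -> CohortDataset:
    """Generate a full linked cohort; byte-identical given the same config."""
    root = np.random.SeedSequence(config.seed)
    ss_hamd, ss_audio = root.spawn(2)

    profiles = default_profiles(effect=config.hamd_effect)
    records, true_group = generate_hamd_cohort(
        config.n_per_group,
        profiles=profiles,
        item_corr_target=config.item_corr_target,
        seed=np.random.default_rng(ss_hamd),
    )

    recordings: dict[tuple[str, int], AudioRecording] = {}
    subject_seeds = ss_audio.spawn(len(records))
    for rec_h, ss in zip(records, subject_seeds):
        sid = rec_h.subject_id
        rng = np.random.default_rng(ss)
        params, fscale = _subject_glottal(config, true_group[sid], rng)
        for pid in range(1, config.n_phrases + 1):
            tract = phrase_tract(pid)
            centers = tuple(
                min(c * fscale, 0.95 * config.rate / 2) for c in tract.centers
            )
            tract_p = FormantSpec(centers=centers, bandwidths=tract.bandwidths)
            # small per-phrase prosodic variation around the subject's voice
            p = GlottalParams(
                f0_mean=params.f0_mean * float(1.0 + 0.03 * rng.standard_normal()),
                f0_sd=params.f0_sd,
                open_quotient=float(np.clip(params.open_quotient + 0.015 * rng.standard_normal(), 0.3, 0.92)),
                jitter_pct=params.jitter_pct,
                shimmer_pct=params.shimmer_pct,
                noise_snr_db=params.noise_snr_db,
                amplitude=params.amplitude,
            )
            audio = synthesize_voice(p, tract_p, config.duration, config.rate, seed=rng)
            audio.phrase_id = pid
            audio.subject_id = sid
            recordings[(sid, pid)] = audio
    return CohortDataset(
        hamd=records, recordings=recordings, true_group=true_group, seed=config.seed
    )
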