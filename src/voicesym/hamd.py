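"""HAM-D-17 records, symptom profiles and synthetic cohort generation.

The 17-item Hamilton Depression Rating Scale is clinician-rated; items
4, 5, 6, 12, 13, 14, 16 and 17 are scored 0-2 and the remainder 0-4, and
the severity total is the plain sum.  Synthetic cohorts are drawn from a
one-factor Gaussian latent model so that chosen item pairs (by default
item 1 "depressed mood" and item 7 "work and activities") carry a target
inter-item correlation, then rounded and clipped into the integer ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

N_ITEMS = 17
# 0-based indices of the items scored 0-2; all others are 0-4.
_RANGE2_ITEMS = frozenset({3, 4, 5, 11, 12, 13, 15, 16})
ITEM_MAX = np.array([2 if i in _RANGE2_ITEMS else 4 for i in range(N_ITEMS)], dtype=int)


@dataclass
class HamdRecord:
    """One subject's 17 item scores and their total."""

    subject_id: str
    items: np.ndarray
    total: int = -1

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        if self.items.shape != (N_ITEMS,):
            raise ValueError("HAM-D record needs exactly 17 item scores")
        if np.any(self.items < 0) or np.any(self.items > ITEM_MAX):
            raise ValueError(f"{self.subject_id}: item score outside its range")
        s = int(self.items.sum())
        if self.total < 0:
            self.total = s
        elif self.total != s:
            raise ValueError(f"{self.subject_id}: total {self.total} != item sum {s}")


@dataclass
class SymptomProfile:
    """Latent per-item means/SDs of one symptom group, pre-discretization."""

    item_means: np.ndarray
    item_sds: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.item_means = np.asarray(self.item_means, dtype=float)
        self.item_sds = np.asarray(self.item_sds, dtype=float)
        if self.item_means.shape != (N_ITEMS,) or self.item_sds.shape != (N_ITEMS,):
            raise ValueError("profile needs 17 means and 17 SDs")
        if np.any(self.item_means < 0) or np.any(self.item_sds < 0):
            raise ValueError("profile means and SDs must be non-negative")


def default_profiles(
    effect: float = 1.5,
    g1_items: tuple[int, ...] = (2, 7, 12),
    g2_items: tuple[int, ...] = (4,),
) -> tuple[SymptomProfile, SymptomProfile]:
    """Two symptom profiles mirroring the clinical group contrast.

    By default group 1 ("inactivity") is elevated on guilt (item 2), work
    and activities (item 7) and loss of appetite (item 12); group 2
    ("insomnia") is elevated on insomnia early (item 4).  ``effect`` scales
    the elevations in units of the latent item SD; item numbers are
    1-based.  Passing ``g2_items=(4, 5, 6)`` gives a broader insomnia
    contrast (all three insomnia items), used by the clustering-recovery
    benchmark.
    """
    # SDs sized to the scale ranges so elevated means stay clear of the
    # clipping boundaries (clipping would silently shrink the separation)
    base_mean = np.where(ITEM_MAX == 4, 0.8, 0.4).astype(float)
    sds = np.where(ITEM_MAX == 4, 0.7, 0.35).astype(float)
    m1 = base_mean.copy()
    m2 = base_mean.copy()
    for item in g1_items:
        m1[item - 1] += effect * sds[item - 1]
    for item in g2_items:
        m2[item - 1] += effect * sds[item - 1]
    return (
        SymptomProfile(m1, sds, label="inactivity"),
        SymptomProfile(m2, sds, label="insomnia"),
    )


def generate_hamd_cohort(
    n_per_group: int,
    profiles: tuple[SymptomProfile, SymptomProfile] | None = None,
    item_corr_target: float = 0.7,
    seed: int | np.random.Generator = 0,
    corr_items: tuple[int, int] = (1, 7),
    background_loading: float = 0.3,
) -> tuple[list[HamdRecord], dict[str, int]]:
    """Draw a two-group synthetic HAM-D cohort.

    A shared standard-normal factor z per subject loads on the two
    ``corr_items`` (1-based) so their *observed* (post-discretization)
    correlation hits the target: rounding to integers adds variance h^2/12
    (Sheppard's correction, h = 1), which attenuates the latent correlation
    by ``sd_i / sqrt(sd_i^2 + 1/12)`` per item, so the latent target is
    inflated by the inverse factor before being split into equal loadings.
    All other items load with ``sqrt(background_loading)``.  Continuous
    scores are ``mean + sd * (loading*z + sqrt(1-loading^2)*eps)``, rounded
    and clipped into the item ranges.

    Returns the records (group 1 first) and a subject -> true-group map.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    if profiles is None:
        profiles = default_profiles()
    if len(profiles) != 2:
        raise ValueError("need exactly two profiles")
    if not (0.0 <= item_corr_target < 1.0):
        raise ValueError("item_corr_target must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    atten = 1.0
    for it in corr_items:
        sd = float(np.mean([p.item_sds[it - 1] for p in profiles]))
        atten *= sd / np.sqrt(sd * sd + 1.0 / 12.0) if sd > 0 else 1.0
    latent_target = min(item_corr_target / max(atten, 1e-6), 0.97)

    loadings = np.full(N_ITEMS, np.sqrt(background_loading))
    for it in corr_items:
        loadings[it - 1] = np.sqrt(latent_target)
    resid = np.sqrt(1.0 - loadings**2)

    records: list[HamdRecord] = []
    true_group: dict[str, int] = {}
    sid = 0
    for g, prof in enumerate(profiles, start=1):
        z = rng.standard_normal((n_per_group, 1))
        eps = rng.standard_normal((n_per_group, N_ITEMS))
        latent = loadings[None, :] * z + resid[None, :] * eps
        cont = prof.item_means[None, :] + prof.item_sds[None, :] * latent
        scores = np.clip(np.round(cont), 0, ITEM_MAX[None, :]).astype(int)
        for row in scores:
            subject = f"S{sid:04d}"
            records.append(HamdRecord(subject_id=subject, items=row))
            true_group[subject] = g
            sid += 1
    return records, true_group


def cohort_to_frame(records: list[HamdRecord]) -> pd.DataFrame:
    cols = {f"item_{k + 1}": [int(r.items[k]) for r in records] for k in range(N_ITEMS)}
    df = pd.DataFrame({"subject_id": [r.subject_id for r in records], **cols})
    df["total"] = [r.total for r in records]
    return df


def write_hamd_csv(path: str | Path, records: list[HamdRecord]) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_hamd_csv(path: str | Path) -> list[HamdRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        items = np.array([row[f"item_{k + 1}"] for k in range(N_ITEMS)], dtype=int)
        total = int(row["total"]) if "total" in df.columns else -1
        records.append(HamdRecord(subject_id=str(row["subject_id"]), items=items, total=total))
    return records
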