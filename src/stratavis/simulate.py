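"""Synthetic five-stage dementia cohort generator.

Emulates the schema of a clinical dementia registry: per-patient
demographics (gender, age, years of education), a diagnosis stage on the
five-step ladder SMI -> MCI -> VCI -> SVD -> AD, and the 15 S-IADL
(Seoul-Instrumental Activities of Daily Living) items, each scored on a
4-point Likert scale encoded 0..3 where higher = better daily function.

Item scores are drawn per patient as ``round(clip(Normal(mean, sd), 0, 3))``
with a per-stage, per-item mean: a simple generative model giving direct
control over how well the stages separate.  Everything is reproducible
from a single seed (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataTable, VariableSpec

__all__ = ["STAGES", "ITEM_NAMES", "CohortConfig", "generate_cohort", "default_separated_config"]

#: Diagnosis stages, mildest to most severe.
STAGES = ("SMI", "MCI", "VCI", "SVD", "AD")

#: The 15 S-IADL daily-function items.
ITEM_NAMES = tuple(f"item_{i:02d}" for i in range(1, 16))

N_ITEMS = len(ITEM_NAMES)
ITEM_MIN, ITEM_MAX = 0, 3


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort draw.

    ``item_means`` is a 5 x 15 matrix: mean item score per stage (rows in
    :data:`STAGES` order) and item, on the 0-3 scale.  ``item_sd`` is the
    shared pre-rounding noise scale.
    """

    n_patients: int
    stage_proportions: tuple[float, ...]
    item_means: np.ndarray
    item_sd: float
    seed: int
    age_range: tuple[float, float] = (55.0, 90.0)
    gender_proportions: tuple[float, float] = (0.6, 0.4)  # (F, M)
    education_range: tuple[float, float] = (0.0, 18.0)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        p = np.asarray(self.stage_proportions, dtype=float)
        if p.shape != (len(STAGES),) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage_proportions must be 5 non-negative numbers summing to 1")
        self.item_means = np.asarray(self.item_means, dtype=float)
        if self.item_means.shape != (len(STAGES), N_ITEMS):
            raise ValueError(f"item_means must be {len(STAGES)}x{N_ITEMS}")
        if np.any(self.item_means < ITEM_MIN) or np.any(self.item_means > ITEM_MAX):
            raise ValueError(f"item_means entries must lie in [{ITEM_MIN}, {ITEM_MAX}]")
        if self.item_sd <= 0:
            raise ValueError("item_sd must be positive")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "stage_proportions": list(self.stage_proportions),
            "item_means": self.item_means.tolist(),
            "item_sd": self.item_sd,
            "seed": self.seed,
            "age_range": list(self.age_range),
            "gender_proportions": list(self.gender_proportions),
            "education_range": list(self.education_range),
        }


def default_separated_config(n_patients: int, seed: int) -> CohortConfig:
    """A well-separated cohort: stage mean scores 2.8, 2.2, 1.6, 1.0, 0.4
    (SMI..AD) on every item, sd 0.25, equal stage proportions.

    Daily function degrades monotonically with stage severity, far enough
    apart relative to the noise that k-means with k=5 recovers the stages.
    """
    stage_levels = np.array([2.8, 2.2, 1.6, 1.0, 0.4])
    item_means = np.tile(stage_levels[:, None], (1, N_ITEMS))
    return CohortConfig(
        n_patients=n_patients,
        stage_proportions=(0.2, 0.2, 0.2, 0.2, 0.2),
        item_means=item_means,
        item_sd=0.25,
        seed=seed,
    )


#: Academic-background bands derived from years of schooling.
EDUCATION_LEVELS = ("none", "elementary", "middle", "high", "college")


def _education_level(years: np.ndarray) -> np.ndarray:
    bands = np.digitize(years, [1, 7, 10, 13])  # none <1, elem <7, middle <10, high <13
    return np.asarray(EDUCATION_LEVELS)[bands]


def cohort_schema() -> list[VariableSpec]:
    """The VariableSpec list every generated cohort carries: the five
    covariates (diagnosis, gender, academic background, education years,
    age), then the 15 items with declared bounds [0, 3]."""
    specs = [
        VariableSpec("diagnosis", "categorical", categories=STAGES),
        VariableSpec("gender", "categorical", categories=("F", "M")),
        VariableSpec("education_level", "categorical", categories=EDUCATION_LEVELS),
        VariableSpec("age", "numeric", 0.0, 120.0),
        VariableSpec("education_years", "numeric", 0.0, 30.0),
    ]
    specs += [VariableSpec(n, "numeric", float(ITEM_MIN), float(ITEM_MAX)) for n in ITEM_NAMES]
    return specs


def generate_cohort(config: CohortConfig) -> DataTable:
    """Draw one cohort. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    stage_idx = rng.choice(len(STAGES), size=n, p=np.asarray(config.stage_proportions))
    stages = np.asarray(STAGES)[stage_idx]
    gender = rng.choice(["F", "M"], size=n, p=np.asarray(config.gender_proportions))
    age = np.round(rng.uniform(*config.age_range, size=n), 1)
    edu = np.round(rng.uniform(*config.education_range, size=n))

    means = config.item_means[stage_idx]  # n x 15
    raw = rng.normal(means, config.item_sd)
    items = np.round(np.clip(raw, ITEM_MIN, ITEM_MAX)).astype(int)

    ids = [f"P{i:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "diagnosis": stages,
            "gender": gender,
            "education_level": _education_level(edu),
            "age": age,
            "education_years": edu,
            **{name: items[:, j].astype(float) for j, name in enumerate(ITEM_NAMES)},
        },
        index=pd.Index(ids, name="id"),
    )
    return DataTable(df, cohort_schema())
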