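"""Core in-memory containers shared across the pipeline.

A patient is represented by three pieces: a bag of tile-level feature
vectors (:class:`FeatureBag`), right-censored follow-up information
(:class:`SurvivalRecord`), and staging covariates
(:class:`ClinicalCovariates`).  A :class:`Cohort` holds the aligned lists
plus, for synthetic cohorts, the hidden latent risk used to generate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Follow-up horizon in months; hazards are monthly, so curves have 60 points.
HORIZON = 60

AGE_GROUPS = ("<60", "60-69", "70-79", ">80")
UICC_STAGES = ("I", "IIa", "IIb", "III", "IV")
CLR_STAGES = frozenset({"I", "IIa"})
CHR_STAGES = frozenset({"IIb", "III", "IV"})


@dataclass
class FeatureBag:
    """One patient's K x d matrix of tile-level features."""

    patient_id: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a K x d matrix with K >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]


@dataclass
class SurvivalRecord:
    """Follow-up time in months plus an event (death) indicator."""

    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError("time_months must be positive")
        self.event = bool(self.event)

    @property
    def label5y(self):
        """Five-year status: 1 died within 60 months, 0 survived past 60.

        ``None`` for patients censored at or before 60 months without an
        event — their five-year status is unknown.
        """
        if self.event and self.time_months <= HORIZON:
            return 1
        if self.time_months > HORIZON:
            return 0
        if self.time_months == HORIZON and not self.event:
            # administrative censoring maps survivors to exactly t=60
            return 0
        return None


@dataclass
class ClinicalCovariates:
    """Staging covariates; UICC stage determines the CHR/CLR stratum."""

    age_group: str
    T: str
    N: str
    M: str
    UICC: str | None

    @property
    def stratum(self) -> str:
        from .stratification import assign_clinical_risk

        return assign_clinical_risk(self)


@dataclass
class Cohort:
    """Aligned per-patient lists, with the generating truth kept aside."""

    bags: list[FeatureBag]
    records: list[SurvivalRecord]
    covariates: list[ClinicalCovariates]
    latent_risk: np.ndarray | None = None
    name: str = "cohort"
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bags)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_months for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=bool)

    def frame(self) -> pd.DataFrame:
        """Cohort table in the on-disk CSV layout."""
        rows = []
        for bag, rec, cov in zip(self.bags, self.records, self.covariates):
            rows.append(
                {
                    "patient_id": bag.patient_id,
                    "time_months": rec.time_months,
                    "event": int(rec.event),
                    "age_group": cov.age_group,
                    "T": cov.T,
                    "N": cov.N,
                    "M": cov.M,
                    "UICC": "" if cov.UICC is None else cov.UICC,
                    "stratum": cov.stratum,
                    "cohort": self.name,
                }
            )
        return pd.DataFrame(rows)

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)
        return Cohort(
            bags=[self.bags[i] for i in idx],
            records=[self.records[i] for i in idx],
            covariates=[self.covariates[i] for i in idx],
            latent_risk=None if self.latent_risk is None else self.latent_risk[idx],
            name=self.name,
            extra=dict(self.extra),
        )
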