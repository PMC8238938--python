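"""Cohort sorting: outcome labeling, exclusions, CTG quality filter, balancing.

The pipeline mirrors a delivery-registry workflow: stillbirths, multiple
gestations and preterm deliveries are excluded first, remaining deliveries are
labeled normal/abnormal from umbilical-artery pH and the 1-minute Apgar score,
each branch is filtered on CTG record quality (>= 30 min, <= 16% FHR signal
loss), emergency cesarean sections are removed from the normal branch, and an
equal-size normal subsample is drawn to balance the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_core import CTGTrace, passes_quality

__all__ = [
    "ClinicalRecord",
    "CohortSummary",
    "ABNORMAL",
    "NORMAL",
    "label_outcome",
    "apply_exclusions",
    "quality_filter",
    "build_balanced_dataset",
    "read_registry_csv",
    "write_registry_csv",
    "PRETERM_WEEKS",
]

NORMAL = "normal"
ABNORMAL = "abnormal"

#: Clinical definition of preterm delivery.
PRETERM_WEEKS = 37.0

PH_THRESHOLD = 7.20
APGAR1_THRESHOLD = 7


@dataclass
class ClinicalRecord:
    """One delivery's outcomes and exclusion-relevant covariates."""

    id: str
    ua_pH: float | None = None
    apgar1: int | None = None
    gestational_age_weeks: float = 39.0
    plurality: int = 1
    stillbirth: bool = False
    emergency_cs: bool = False
    has_sufficient_data: bool = True
    ctg: CTGTrace | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plurality < 1:
            raise ValueError(f"{self.id}: plurality must be >= 1")
        if not self.gestational_age_weeks > 0:
            raise ValueError(f"{self.id}: gestational age must be positive")
        if self.apgar1 is not None and not (0 <= self.apgar1 <= 10):
            raise ValueError(f"{self.id}: Apgar score must lie in 0..10")


@dataclass
class CohortSummary:
    """Counts at each stage of the sorting pipeline (Fig.-1 style flowchart)."""

    initial: int = 0
    removed_stillbirth: int = 0
    removed_twins: int = 0
    removed_preterm: int = 0
    removed_insufficient: int = 0
    after_exclusions: int = 0
    abnormal_labeled: int = 0
    normal_labeled: int = 0
    abnormal_after_quality: int = 0
    normal_after_cs: int = 0
    normal_after_quality: int = 0
    final_per_group: int = 0


def label_outcome(record: ClinicalRecord) -> str:
    """Label a delivery abnormal iff ua_pH < 7.20 or 1-min Apgar < 7 (strict)."""
    if record.ua_pH is None or record.apgar1 is None or not np.isfinite(record.ua_pH):
        raise ValueError(f"{record.id}: cannot label outcome without ua_pH and apgar1")
    if record.ua_pH < PH_THRESHOLD or record.apgar1 < APGAR1_THRESHOLD:
        return ABNORMAL
    return NORMAL


def _lacks_outcome(record: ClinicalRecord) -> bool:
    return (
        record.ua_pH is None
        or record.apgar1 is None
        or not np.isfinite(record.ua_pH)
    )


def apply_exclusions(
    registry: Sequence[ClinicalRecord],
) -> tuple[list[ClinicalRecord], CohortSummary]:
    """Remove stillbirths, multiples, preterm and data-insufficient deliveries.

    Stages apply in order and each record is counted at the first stage it
    fails, so the per-stage counts are disjoint. Records with missing outcome
    fields are routed to the "insufficient data" stage rather than failing
    later during labeling.
    """
    summary = CohortSummary(initial=len(registry))
    kept: list[ClinicalRecord] = []
    for rec in registry:
        if rec.stillbirth:
            summary.removed_stillbirth += 1
        elif rec.plurality > 1:
            summary.removed_twins += 1
        elif rec.gestational_age_weeks < PRETERM_WEEKS:
            summary.removed_preterm += 1
        elif not rec.has_sufficient_data or _lacks_outcome(rec):
            summary.removed_insufficient += 1
        else:
            kept.append(rec)
    summary.after_exclusions = len(kept)
    return kept, summary


def quality_filter(
    records: Sequence[ClinicalRecord],
    min_duration_s: float = 1800.0,
    max_loss: float = 0.16,
) -> list[ClinicalRecord]:
    """Keep records whose attached CTG trace passes the quality gate."""
    kept = []
    for rec in records:
        if rec.ctg is None:
            raise ValueError(f"{rec.id}: record has no CTG trace attached")
        if passes_quality(rec.ctg, min_duration_s=min_duration_s, max_loss=max_loss):
            kept.append(rec)
    return kept


def attach_traces(
    records: Sequence[ClinicalRecord], traces: Mapping[str, CTGTrace]
) -> list[ClinicalRecord]:
    """Attach traces to records by id; records without a trace raise later."""
    for rec in records:
        rec.ctg = traces.get(rec.id, rec.ctg)
    return list(records)


def build_balanced_dataset(
    normals: Sequence[ClinicalRecord],
    abnormals: Sequence[ClinicalRecord],
    n_per_group: int,
    seed: int,
) -> tuple[list[ClinicalRecord], np.ndarray]:
    """Assemble a class-balanced dataset of ``2 * n_per_group`` records.

    All ``n_per_group`` abnormals are taken (they must number exactly
    ``n_per_group``, or more, in which case a seeded subsample is drawn);
    normals are sampled uniformly without replacement.

    Returns the records and a label vector (1 = abnormal, 0 = normal).
    """
    if len(normals) < n_per_group:
        raise ValueError(
            f"insufficient normal records: need {n_per_group}, have {len(normals)}"
        )
    if len(abnormals) < n_per_group:
        raise ValueError(
            f"insufficient abnormal records: need {n_per_group}, have {len(abnormals)}"
        )
    rng = np.random.default_rng(seed)
    if len(abnormals) == n_per_group:
        ab = list(abnormals)
    else:
        ab = [abnormals[i] for i in rng.choice(len(abnormals), n_per_group, replace=False)]
    if len(normals) == n_per_group:
        no = list(normals)
    else:
        no = [normals[i] for i in rng.choice(len(normals), n_per_group, replace=False)]
    records = ab + no
    labels = np.concatenate([np.ones(n_per_group, int), np.zeros(n_per_group, int)])
    return records, labels


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "id",
    "ua_pH",
    "apgar1",
    "gestational_age_weeks",
    "plurality",
    "stillbirth",
    "emergency_cs",
    "has_sufficient_data",
]


def records_to_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "ua_pH": r.ua_pH,
                "apgar1": r.apgar1,
                "gestational_age_weeks": r.gestational_age_weeks,
                "plurality": r.plurality,
                "stillbirth": r.stillbirth,
                "emergency_cs": r.emergency_cs,
                "has_sufficient_data": r.has_sufficient_data,
                **{k: v for k, v in r.meta.items()},
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ClinicalRecord]:
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry missing column(s) {missing}")
    records = []
    extra = [c for c in df.columns if c not in _REGISTRY_COLUMNS]
    for row in df.itertuples(index=False):
        d = row._asdict()
        apgar = d["apgar1"]
        apgar = None if pd.isna(apgar) else int(apgar)
        ph = d["ua_pH"]
        ph = None if pd.isna(ph) else float(ph)
        records.append(
            ClinicalRecord(
                id=str(d["id"]),
                ua_pH=ph,
                apgar1=apgar,
                gestational_age_weeks=float(d["gestational_age_weeks"]),
                plurality=int(d["plurality"]),
                stillbirth=bool(d["stillbirth"]),
                emergency_cs=bool(d["emergency_cs"]),
                has_sufficient_data=bool(d["has_sufficient_data"]),
                meta={k: d[k] for k in extra},
            )
        )
    return records


def write_registry_csv(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_registry_csv(path: str | Path) -> list[ClinicalRecord]:
    return frame_to_records(pd.read_csv(path))
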