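"""Reading and writing cohort data as delimited text.

A cohort lives in two CSV tables. The visit table has one row per
interview: ``id, age, y1, y2``. The subject table has one row per
person: ``id, baseline_age, last_age, death`` plus any covariate
columns. Ages are stored raw (years) and rescaled on load by
subtracting a configurable offset so that model time starts near zero
for the youngest entrants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .longitudinal import Subject

logger = logging.getLogger("jointbin")

VISIT_COLUMNS = ["id", "age", "y1", "y2"]
SUBJECT_COLUMNS = ["id", "baseline_age", "last_age", "death"]


@dataclass
class DataConfig:
    """Schema and filter settings for reading a cohort.

    age_offset : subtracted from all ages on load (default 49)
    m1, m2 : score supports, used for validation
    min_records : minimum total records per subject, where a record is a
        visit or a death (default 2)
    baseline_age_max : raw-age cap at entry, exclusive (default 90)
    covariates : names of subject-table covariate columns to carry
    """

    age_offset: float = 49.0
    m1: int = 10
    m2: int = 10
    min_records: int = 2
    baseline_age_max: float = 90.0
    covariates: list[str] = field(default_factory=list)


def read_dataset(
    visit_path, subject_path, config: DataConfig | None = None
) -> list[Subject]:
    """Load, validate, rescale and filter a cohort.

    Exclusion counts per filter are logged. Malformed rows and
    out-of-support scores raise with the offending location named.
    """
    config = config or DataConfig()
    visits = pd.read_csv(visit_path)
    subjects = pd.read_csv(subject_path)
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            raise ValueError(f"visit table missing column {col!r}")
    for col in SUBJECT_COLUMNS + list(config.covariates):
        if col not in subjects.columns:
            raise ValueError(f"subject table missing column {col!r}")
    bad = visits[VISIT_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (np.where(bad)[0] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"malformed visit rows at lines {lines}")
    known = set(subjects["id"])
    orphan = ~visits["id"].isin(known)
    if orphan.any():
        raise ValueError(
            f"visit rows for unknown subjects: {sorted(set(visits.loc[orphan, 'id']))}"
        )
    out: list[Subject] = []
    n_excl_age = n_excl_records = 0
    for row in subjects.itertuples(index=False):
        sid = row.id
        sv = visits[visits["id"] == sid].sort_values("age")
        y1 = sv["y1"].to_numpy(dtype=np.int64)
        y2 = sv["y2"].to_numpy(dtype=np.int64)
        if len(y1) and (
            y1.min() < 0 or y1.max() > config.m1 or y2.min() < 0 or y2.max() > config.m2
        ):
            raise ValueError(f"subject {sid}: score outside declared supports")
        n_records = len(sv) + int(row.death)
        if row.baseline_age >= config.baseline_age_max:
            n_excl_age += 1
            continue
        if n_records < config.min_records:
            n_excl_records += 1
            continue
        x = np.array([getattr(row, c) for c in config.covariates], dtype=float)
        off = config.age_offset
        out.append(
            Subject(
                id=str(sid),
                t=sv["age"].to_numpy(dtype=float) - off,
                y1=y1,
                y2=y2,
                t1=float(row.baseline_age) - off,
                t_last=float(row.last_age) - off,
                delta=int(row.death),
                x=x,
            )
        )
    if n_excl_age:
        logger.info("excluded %d subjects at/over baseline age cap", n_excl_age)
    if n_excl_records:
        logger.info("excluded %d subjects below minimum record count", n_excl_records)
    return out


def write_dataset(
    dataset: list[Subject],
    visit_path,
    subject_path,
    config: DataConfig | None = None,
) -> None:
    """Write a cohort back to the two-table CSV layout (inverse of read)."""
    config = config or DataConfig()
    off = config.age_offset
    vrows, srows = [], []
    for s in dataset:
        for t, a, b in zip(s.t, s.y1, s.y2):
            vrows.append({"id": s.id, "age": t + off, "y1": int(a), "y2": int(b)})
        row = {
            "id": s.id,
            "baseline_age": s.t1 + off,
            "last_age": s.t_last + off,
            "death": int(s.delta),
        }
        for i, c in enumerate(config.covariates):
            row[c] = s.x[i]
        srows.append(row)
    pd.DataFrame(vrows, columns=VISIT_COLUMNS).to_csv(visit_path, index=False)
    pd.DataFrame(srows).to_csv(subject_path, index=False)
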