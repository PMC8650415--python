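"""Activity standardization for heterogeneous kinase bioactivity tables.

Raw measurements arrive as Ki/Kd concentrations in assorted units, as
already-transformed pKi/pKd values, or as percent-of-control (POC)
readouts. This module unifies concentrations to nanomolar, converts them
to p-affinity (the negative base-10 logarithm of the molar binding
constant, so 1 µM ↔ 6 and 0.01 nM ↔ 11), collapses repeated measurements
of the same compound–kinase pair using a coefficient-of-variation filter,
and labels each pair active when its p-affinity reaches the 1 µM cutoff.

The CV of a duplicate group is computed on the transformed p-affinity
values (sample standard deviation over mean), which makes the filter
invariant to the unit the assay was reported in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: multiplicative factor taking each concentration unit to nanomolar
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9, "pM": 1e-3}

#: measurement types carrying a concentration (to be log-transformed)
CONCENTRATION_TYPES = frozenset({"Ki", "Kd"})
#: measurement types already on the p-affinity scale
P_TYPES = frozenset({"pKi", "pKd"})

MEASURE_TYPES = CONCENTRATION_TYPES | P_TYPES | {"POC"}

DEFAULT_CUTOFF = 6.0
DEFAULT_CV_THRESHOLD = 0.05


@dataclass(frozen=True)
class ActivityRecord:
    """One raw activity measurement before standardization."""

    compound_smiles: str
    kinase_id: str
    measure_type: str  # Ki | Kd | pKi | pKd | POC
    value: float
    unit: str  # nM | uM | M | pM | dimensionless

    def __post_init__(self):
        if self.measure_type not in MEASURE_TYPES:
            raise ValueError(f"unknown measure_type {self.measure_type!r}")
        if not math.isfinite(self.value):
            raise ValueError("measurement value must be finite")


@dataclass(frozen=True)
class StandardRecord:
    """A standardized compound–kinase pair with its p-affinity label."""

    compound_smiles: str
    kinase_id: str
    p_affinity: float
    active: bool


def to_nanomolar(value: float, unit: str) -> float:
    """Convert a concentration to nanomolar.

    Raises ``ValueError`` for unknown units or non-positive concentrations
    (a non-positive Ki/Kd has no physical meaning and cannot be
    log-transformed).
    """
    if unit not in _UNIT_TO_NM:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if value <= 0:
        raise ValueError(f"non-positive concentration {value!r}")
    return value * _UNIT_TO_NM[unit]


def to_p_affinity(value_nM: float) -> float:
    """−log10 of the molar concentration given a value in nM.

    ``p = 9 − log10(value_nM)``: 1000 nM (1 µM) → 6, 1 nM → 9,
    0.01 nM → 11.
    """
    if value_nM <= 0:
        raise ValueError(f"non-positive concentration {value_nM!r}")
    return 9.0 - math.log10(value_nM)


def label_active(p_affinity: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Active iff p-affinity ≥ cutoff (inclusive: 1 µM itself is active)."""
    if not math.isfinite(p_affinity):
        raise ValueError("p_affinity must be finite")
    return p_affinity >= cutoff


def standardize_record(
    record: ActivityRecord,
    cutoff: float = DEFAULT_CUTOFF,
    poc_converter: Callable[[float], float] | None = None,
) -> StandardRecord | None:
    """Standardize one raw record; ``None`` means the record was rejected.

    POC readouts are percentages, not concentrations, and have no
    universal p-affinity mapping; they are converted only through a
    user-supplied ``poc_converter`` and otherwise dropped with a warning.
    """
    mt = record.measure_type
    if mt in P_TYPES:
        p = float(record.value)
    elif mt in CONCENTRATION_TYPES:
        try:
            p = to_p_affinity(to_nanomolar(record.value, record.unit))
        except ValueError as exc:
            logger.warning("rejected %s/%s: %s", record.compound_smiles, record.kinase_id, exc)
            return None
    elif mt == "POC":
        if poc_converter is None:
            logger.warning(
                "dropped POC record %s/%s: no POC→p-affinity converter supplied",
                record.compound_smiles, record.kinase_id,
            )
            return None
        p = float(poc_converter(record.value))
    else:  # pragma: no cover - guarded by ActivityRecord
        raise ValueError(f"unknown measure_type {mt!r}")
    if not math.isfinite(p):
        logger.warning("rejected %s/%s: non-finite p-affinity", record.compound_smiles, record.kinase_id)
        return None
    return StandardRecord(record.compound_smiles, record.kinase_id, p, label_active(p, cutoff))


def dedupe_by_cv(
    records: Sequence[StandardRecord],
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    seed: int = 0,
) -> list[StandardRecord]:
    """Collapse repeated measurements of each compound–kinase pair.

    Groups with coefficient of variation (sample SD / mean of the
    p-affinities) at or below ``cv_threshold`` keep one randomly chosen
    member; groups above the threshold are discarded entirely. Singletons
    pass through. A zero group mean with nonzero spread leaves the CV
    undefined and the group is removed.

    Output order follows first appearance of each surviving group, so the
    operation is idempotent.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[StandardRecord]] = {}
    for rec in records:
        groups.setdefault((rec.compound_smiles, rec.kinase_id), []).append(rec)

    kept: list[StandardRecord] = []
    for key, members in groups.items():
        if len(members) == 1:
            kept.append(members[0])
            continue
        values = np.array([m.p_affinity for m in members])
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0.0:
            cv = 0.0
        elif mean == 0.0:
            logger.warning("removed group %s: zero mean with nonzero spread (CV undefined)", key)
            continue
        else:
            cv = abs(sd / mean)
        if cv > cv_threshold:
            logger.info("removed group %s: CV %.4f > %.4f", key, cv, cv_threshold)
            continue
        kept.append(members[int(rng.integers(len(members)))])
    return kept


def standardize_table(
    table: pd.DataFrame,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    poc_converter: Callable[[float], float] | None = None,
) -> pd.DataFrame:
    """Standardize a raw activity table.

    Expects columns ``smiles, kinase_id, measure_type, value, unit``;
    returns a table with columns ``smiles, kinase_id, p_affinity, active``,
    deduplicated by the CV rule.
    """
    required = {"smiles", "kinase_id", "measure_type", "value", "unit"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")

    std: list[StandardRecord] = []
    for row in table.itertuples(index=False):
        try:
            rec = ActivityRecord(str(row.smiles), str(row.kinase_id),
                                 str(row.measure_type), float(row.value), str(row.unit))
        except ValueError as exc:
            logger.warning("rejected row %r: %s", row, exc)
            continue
        out = standardize_record(rec, cutoff=cutoff, poc_converter=poc_converter)
        if out is not None:
            std.append(out)

    kept = dedupe_by_cv(std, cv_threshold=cv_threshold, seed=seed)
    return pd.DataFrame(
        {
            "smiles": [r.compound_smiles for r in kept],
            "kinase_id": [r.kinase_id for r in kept],
            "p_affinity": [r.p_affinity for r in kept],
            "active": [r.active for r in kept],
        }
    )


def read_activity_table(path) -> pd.DataFrame:
    """Read a raw activity CSV/TSV (delimiter sniffed from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)
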