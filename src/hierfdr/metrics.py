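"""Error and power estimators aggregated over Monte-Carlo replications.

The false discovery proportion (FDP) of one realization is ``V/(R v 1)``
(false rejections over rejections, with 0/0 read as 0); its expectation is
the FDR.  The global FDR pools all hypotheses; per-family FDRs restrict the
count to one family; "mean FDR" averages the per-family estimates over the
families.  Power is the expected fraction of false nulls that are rejected,
``S/(m_A v 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import TestResult
from .procedures import FamilyPartition

__all__ = [
    "GroundTruth",
    "MetricsReport",
    "fdp",
    "power_fraction",
    "stage1_family_error",
    "aggregate",
    "metrics_table",
]


@dataclass(frozen=True)
class GroundTruth:
    """Which hypotheses are true alternatives (false nulls)."""

    is_false_null: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.is_false_null, dtype=bool)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("is_false_null must be a non-empty 1-D boolean vector")
        object.__setattr__(self, "is_false_null", arr)

    @property
    def m(self) -> int:
        return self.is_false_null.size

    @property
    def m_A(self) -> int:
        return int(self.is_false_null.sum())

    def family_alt_counts(self, part: FamilyPartition) -> np.ndarray:
        """m_A_ell per family code (0..k-1)."""
        if part.m != self.m:
            raise ValueError("partition and ground truth have mismatched lengths")
        return np.bincount(part.codes, weights=self.is_false_null,
                           minlength=part.k).astype(int)


def _reject_vector(result) -> np.ndarray:
    if isinstance(result, TestResult):
        return result.reject
    if hasattr(result, "global_reject"):
        return np.asarray(result.global_reject, dtype=bool)
    return np.asarray(result, dtype=bool)


def fdp(result, truth: GroundTruth, scope: Optional[np.ndarray] = None) -> float:
    """False discovery proportion ``V/(R v 1)``, optionally within a scope mask."""
    reject = _reject_vector(result)
    if reject.size != truth.m:
        raise ValueError("rejection vector and ground truth have mismatched lengths")
    if scope is not None:
        scope = np.asarray(scope)
        if scope.dtype == bool:
            if scope.size != truth.m:
                raise ValueError("scope mask has mismatched length")
            reject = reject[scope]
            is_alt = truth.is_false_null[scope]
        else:
            reject = reject[scope]
            is_alt = truth.is_false_null[scope]
    else:
        is_alt = truth.is_false_null
    R = int(reject.sum())
    V = int((reject & ~is_alt).sum())
    return V / max(R, 1)


def power_fraction(result, truth: GroundTruth) -> float:
    """Fraction of false nulls correctly rejected, ``S/(m_A v 1)``."""
    reject = _reject_vector(result)
    if reject.size != truth.m:
        raise ValueError("rejection vector and ground truth have mismatched lengths")
    S = int((reject & truth.is_false_null).sum())
    return S / max(truth.m_A, 1)


def stage1_family_error(selected: Iterable[Hashable], truth: GroundTruth,
                        part: FamilyPartition,
                        u: Mapping[Hashable, int]) -> bool:
    """True iff some selected family satisfies its screening null (m_A_ell < u_ell).

    Selecting a family with at least ``u_ell`` false nulls is a correct
    selection; the screening null holds only strictly below ``u_ell``.
    """
    alt_counts = truth.family_alt_counts(part)
    by_label = {part.label(c): alt_counts[c] for c in range(part.k)}
    for label in selected:
        if by_label[label] < u[label]:
            return True
    return False


@dataclass(frozen=True)
class MetricsReport:
    """Monte-Carlo means of the error/power quantities over B replications."""

    gFDR: float
    per_family_FDR: np.ndarray
    mean_FDR: float
    stage1_FWER: Optional[float]
    gpower: float
    B: int
    gFDR_se: float = float("nan")
    gpower_se: float = float("nan")
    per_family_FDR_se: Optional[np.ndarray] = None


def aggregate(records: Sequence[Mapping], k: Optional[int] = None) -> MetricsReport:
    """Aggregate per-replication records into a MetricsReport.

    Each record carries ``gfdp`` (float), ``family_fdp`` (length-k array),
    ``power`` (float) and optionally ``stage1_error`` (bool).
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one replication record")
    B = len(records)
    gfdp = np.array([r["gfdp"] for r in records], dtype=float)
    fam = np.array([r["family_fdp"] for r in records], dtype=float)
    if k is not None and fam.shape[1] != k:
        raise ValueError(f"expected {k} families, got {fam.shape[1]}")
    power = np.array([r["power"] for r in records], dtype=float)
    if "stage1_error" in records[0]:
        stage1 = float(np.mean([bool(r["stage1_error"]) for r in records]))
    else:
        stage1 = None
    per_family = fam.mean(axis=0)
    return MetricsReport(
        gFDR=float(gfdp.mean()),
        per_family_FDR=per_family,
        mean_FDR=float(per_family.mean()),
        stage1_FWER=stage1,
        gpower=float(power.mean()),
        B=B,
        gFDR_se=float(gfdp.std(ddof=1) / np.sqrt(B)) if B > 1 else float("nan"),
        gpower_se=float(power.std(ddof=1) / np.sqrt(B)) if B > 1 else float("nan"),
        per_family_FDR_se=(fam.std(axis=0, ddof=1) / np.sqrt(B)) if B > 1 else None,
    )


def metrics_table(reports: Dict[str, MetricsReport]) -> pd.DataFrame:
    """Tabulate reports with rows gFDR, FDR Fam. 1..k, mean FDR and one column per procedure."""
    if not reports:
        raise ValueError("no reports to tabulate")
    k = len(next(iter(reports.values())).per_family_FDR)
    rows = ["gFDR"] + [f"FDR Fam. {i}" for i in range(1, k + 1)] + ["mean FDR"]
    data = {}
    for name, rep in reports.items():
        data[name] = [rep.gFDR] + list(rep.per_family_FDR) + [rep.mean_FDR]
    return pd.DataFrame(data, index=rows)
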