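"""Step-up-down multiple testing engine with linear (BH) and AORC critical values.

A step-up-down (SUD) test of order ``lam`` compares the ordered p-values
``p_{1:m} <= ... <= p_{m:m}`` against a nondecreasing sequence of critical
values ``a_{1:m} <= ... <= a_{m:m}``.  If ``p_{lam:m} <= a_{lam:m}`` the test
scans upward from ``lam`` and stops at the last index ``j`` such that every
ordered p-value between ``lam`` and ``j`` passes its critical value; otherwise
it steps down and takes the largest ``j < lam`` whose ordered p-value passes.
Hypothesis ``H_i`` is rejected iff ``p_i <= a_{i*:m}``.  The Benjamini-Hochberg
linear step-up (LSU) test is the special case ``a_{i:m} = i*alpha/m`` with
``lam = m``; the asymptotically optimal rejection curve (AORC) uses
``a_{i:m} = i*alpha / (m - i*(1-alpha))``, which implicitly adapts to the
proportion of signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CriticalValues",
    "TestResult",
    "as_pvalues",
    "linear_critical_values",
    "aorc_critical_values",
    "sud_test",
    "lsu_test",
]


def as_pvalues(values) -> np.ndarray:
    """Validate and return a 1-D float array of p-values in [0, 1]."""
    p = np.asarray(values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p-values must form a non-empty 1-D vector")
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha


@dataclass(frozen=True)
class CriticalValues:
    """A nondecreasing critical-value sequence together with an SUD order.

    Attributes
    ----------
    thresholds : ndarray
        Critical values ``a_{1:m} <= ... <= a_{m:m}``, each in [0, 1].
    order : int
        The SUD order ``lam`` in ``{1, ..., m}``; ``lam = m`` gives a pure
        step-up test, ``lam = 1`` a pure step-down test.
    """

    thresholds: np.ndarray
    order: int

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("thresholds must form a non-empty 1-D vector")
        if not np.all(np.isfinite(t)):
            raise ValueError("thresholds must be finite")
        if t.min() < 0.0 or t.max() > 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be nondecreasing")
        object.__setattr__(self, "thresholds", t)
        m = t.size
        lam = int(self.order)
        if not 1 <= lam <= m:
            raise ValueError(f"order must lie in {{1, ..., {m}}}, got {lam}")
        object.__setattr__(self, "order", lam)

    @property
    def m(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class TestResult:
    """Decisions of a stepwise multiple test, in the original input order.

    ``threshold_index`` is the 1-based index ``i*`` of the effective critical
    value, or ``None`` when no ordered p-value passed (in which case nothing
    is rejected).
    """

    reject: np.ndarray
    threshold_index: Optional[int]
    threshold_value: Optional[float]
    num_rejections: int = field(default=0)

    def __post_init__(self):
        r = np.asarray(self.reject, dtype=bool)
        object.__setattr__(self, "reject", r)
        object.__setattr__(self, "num_rejections", int(r.sum()))
        if self.threshold_index is None and self.num_rejections:
            raise ValueError("no threshold implies no rejections")


def linear_critical_values(m: int, alpha: float, order: Optional[int] = None) -> CriticalValues:
    """BH/LSU critical values ``a_{i:m} = i*alpha/m``; default order is ``m`` (step-up)."""
    alpha = _check_alpha(alpha)
    m = int(m)
    if m < 1:
        raise ValueError("m must be a positive integer")
    thresholds = np.arange(1, m + 1, dtype=float) * alpha / m
    return CriticalValues(thresholds, m if order is None else order)


def aorc_critical_values(m: int, alpha: float, order: int = 1) -> CriticalValues:
    """AORC critical values ``a_{i:m} = i*alpha / (m - i*(1-alpha))``.

    The sequence is strictly increasing with ``a_{m:m} = 1`` exactly, so a
    pure step-up application is degenerate (it rejects everything as soon as
    any p-value is <= 1); callers use an SUD order ``lam < m``, which defaults
    to 1 (step-down).
    """
    alpha = _check_alpha(alpha)
    m = int(m)
    if m < 1:
        raise ValueError("m must be a positive integer")
    i = np.arange(1, m + 1, dtype=float)
    thresholds = i * alpha / (m - i * (1.0 - alpha))
    thresholds[-1] = 1.0  # i = m gives m*alpha / (m*alpha) = 1 algebraically
    return CriticalValues(thresholds, order)


def sud_test(p, crit: CriticalValues) -> TestResult:
    """Run the step-up-down test of order ``crit.order`` on unsorted p-values.

    Sorting is internal; decisions are returned in the input order, via the
    cutoff comparison ``p_i <= a_{i*:m}`` so that tied p-values always receive
    identical decisions.
    """
    p = as_pvalues(p)
    m = p.size
    if crit.m != m:
        raise ValueError(f"length mismatch: {m} p-values vs {crit.m} critical values")
    sp = np.sort(p, kind="stable")
    ok = sp <= crit.thresholds
    li = crit.order - 1  # 0-based lam

    if ok[li]:
        # scan up: largest j >= lam with all of lam..j passing
        fail = ~ok[li:]
        istar = (li + int(np.argmax(fail)) - 1) if fail.any() else (m - 1)
    else:
        passing = np.flatnonzero(ok[:li])
        if passing.size == 0:
            return TestResult(np.zeros(m, dtype=bool), None, None)
        istar = int(passing[-1])

    cutoff = float(crit.thresholds[istar])
    reject = p <= cutoff
    return TestResult(reject, istar + 1, cutoff)


def lsu_test(p, alpha: float) -> TestResult:
    """Benjamini-Hochberg linear step-up test at FDR level ``alpha``."""
    p = as_pvalues(p)
    return sud_test(p, linear_critical_values(p.size, alpha))
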