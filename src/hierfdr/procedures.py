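"""Two-stage multiple testing on a partitioned hypothesis set.

Two hierarchical procedures operate on hypotheses grouped into disjoint
families:

* ``ho_procedure`` — screen families with partial-conjunction p-values at a
  Bonferroni-type threshold ``alpha/kappa`` (controlling the family-wise error
  on the screening level), then test within each selected family with the
  AORC-based step-up-down test of order ``u`` at level ``alpha``.
* ``bog_procedure`` — the selection-adjusted comparator: screen with per-family
  Simes p-values through a BH step-up across families, then run BH within each
  selected family at a selection-adjusted level.

``flat_procedure`` runs a non-hierarchical test on the pooled p-values and
serves as the comparator that ignores the family structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence

import numpy as np

from .core import (
    TestResult,
    aorc_critical_values,
    as_pvalues,
    lsu_test,
    sud_test,
)
from .conjunction import pc_pvalue, u_from_kappa

__all__ = [
    "FamilyPartition",
    "HierarchicalResult",
    "ho_procedure",
    "bog_procedure",
    "flat_procedure",
]

STAGE2_RULES = ("R_alpha_over_k", "R_alpha_over_m_ell")


@dataclass(frozen=True)
class FamilyPartition:
    """A surjective assignment of hypotheses to families.

    External labels may be arbitrary hashable values; internally they are
    coded 0..k-1 in first-appearance order.  ``indices(code)`` returns the
    positions of one family in the flat hypothesis vector.
    """

    labels: np.ndarray        # original external labels, length m
    codes: np.ndarray         # 0-based internal family codes, length m
    unique_labels: np.ndarray  # external label per code, length k
    sizes: np.ndarray         # m_ell per code, length k

    @classmethod
    def from_labels(cls, labels: Sequence[Hashable]) -> "FamilyPartition":
        labels = np.asarray(labels)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must form a non-empty 1-D vector")
        uniques, first = np.unique(labels, return_index=True)
        # recode in first-appearance order
        order = np.argsort(first, kind="stable")
        uniques = uniques[order]
        lut = {lab: c for c, lab in enumerate(uniques.tolist())}
        codes = np.fromiter((lut[v] for v in labels.tolist()), dtype=np.intp,
                            count=labels.size)
        sizes = np.bincount(codes, minlength=uniques.size)
        return cls(labels=labels, codes=codes, unique_labels=uniques, sizes=sizes)

    @property
    def m(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return self.unique_labels.size

    def indices(self, code: int) -> np.ndarray:
        return np.flatnonzero(self.codes == code)

    def label(self, code: int):
        """External label for an internal family code, as a native Python object."""
        lab = self.unique_labels[code]
        return lab.item() if hasattr(lab, "item") else lab


@dataclass(frozen=True)
class HierarchicalResult:
    """Combined outcome of a two-stage procedure.

    ``stage1_pvalues`` and ``u_values`` cover *all* families (diagnostics);
    ``per_family_results`` holds within-family decisions for selected families
    only.  ``global_reject`` is aligned with the original hypothesis order and
    is identically false on non-selected families.
    """

    selected_families: List[Hashable]
    R: int
    stage1_pvalues: Dict[Hashable, float]
    u_values: Dict[Hashable, int]
    per_family_results: Dict[Hashable, TestResult]
    global_reject: np.ndarray

    @property
    def num_rejections(self) -> int:
        return int(self.global_reject.sum())


def _assemble(part: FamilyPartition, selected_codes, per_family) -> np.ndarray:
    global_reject = np.zeros(part.m, dtype=bool)
    for code in selected_codes:
        idx = part.indices(code)
        global_reject[idx] = per_family[part.label(code)].reject
    return global_reject


def ho_procedure(p, part: FamilyPartition, alpha: float = 0.05,
                 kappa: float = 1000.0) -> HierarchicalResult:
    """Partial-conjunction screening followed by within-family AORC-SUD tests.

    Stage 1: for each family of size ``m_ell`` set ``u_ell =
    floor(m_ell/kappa) + 1`` and select the family if its partial-conjunction
    p-value is at most ``alpha/kappa``.  Stage 2: within each selected family
    run the AORC step-up-down test of order ``u_ell`` at level ``alpha``.
    Requires ``kappa > k`` so the screening threshold is a valid
    Bonferroni-type bound.
    """
    p = as_pvalues(p)
    if p.size != part.m:
        raise ValueError("p-values and partition have mismatched lengths")
    kappa = float(kappa)
    if kappa <= part.k:
        raise ValueError(f"kappa must exceed the number of families k={part.k}")

    stage1: Dict[Hashable, float] = {}
    u_values: Dict[Hashable, int] = {}
    selected_codes = []
    threshold = alpha / kappa
    for code in range(part.k):
        label = part.label(code)
        idx = part.indices(code)
        u = u_from_kappa(idx.size, kappa)
        u_values[label] = u
        pc = pc_pvalue(p[idx], u)
        stage1[label] = pc
        if pc <= threshold:
            selected_codes.append(code)

    per_family: Dict[Hashable, TestResult] = {}
    for code in selected_codes:
        label = part.label(code)
        idx = part.indices(code)
        crit = aorc_critical_values(idx.size, alpha, order=u_values[label])
        per_family[label] = sud_test(p[idx], crit)

    return HierarchicalResult(
        selected_families=[part.label(c) for c in selected_codes],
        R=len(selected_codes),
        stage1_pvalues=stage1,
        u_values=u_values,
        per_family_results=per_family,
        global_reject=_assemble(part, selected_codes, per_family),
    )


def bog_procedure(p, part: FamilyPartition, alpha: float = 0.05,
                  stage2_rule: str = "R_alpha_over_k") -> HierarchicalResult:
    """Selection-adjusted two-stage BH: Simes screening, then within-family BH.

    Stage 1 applies the linear step-up test at level ``alpha`` to the k
    per-family Simes p-values, selecting R families.  Stage 2 runs BH within
    each selected family at level ``R*alpha/k`` (``stage2_rule =
    "R_alpha_over_k"``, the default selection-adjusted level) or
    ``R*alpha/m_ell`` (``"R_alpha_over_m_ell"``).
    """
    p = as_pvalues(p)
    if p.size != part.m:
        raise ValueError("p-values and partition have mismatched lengths")
    if stage2_rule not in STAGE2_RULES:
        raise ValueError(f"unknown stage2_rule {stage2_rule!r}; expected one of {STAGE2_RULES}")

    stage1: Dict[Hashable, float] = {}
    u_values: Dict[Hashable, int] = {}
    simes = np.empty(part.k)
    for code in range(part.k):
        label = part.label(code)
        idx = part.indices(code)
        u_values[label] = 1
        simes[code] = pc_pvalue(p[idx], 1)
        stage1[label] = float(simes[code])

    family_test = lsu_test(simes, alpha)
    selected_codes = [c for c in range(part.k) if family_test.reject[c]]
    R = len(selected_codes)

    per_family: Dict[Hashable, TestResult] = {}
    for code in selected_codes:
        label = part.label(code)
        idx = part.indices(code)
        if stage2_rule == "R_alpha_over_k":
            level = R * alpha / part.k
        else:
            level = R * alpha / idx.size
        per_family[label] = lsu_test(p[idx], level)

    return HierarchicalResult(
        selected_families=[part.label(c) for c in selected_codes],
        R=R,
        stage1_pvalues=stage1,
        u_values=u_values,
        per_family_results=per_family,
        global_reject=_assemble(part, selected_codes, per_family),
    )


def flat_procedure(p, alpha: float = 0.05, method: str = "lsu",
                   lam: Optional[int] = None) -> TestResult:
    """Non-hierarchical comparator on the pooled p-values.

    ``method="lsu"`` is BH; ``method="aorc_sud"`` runs the AORC step-up-down
    test of order ``lam`` (default 1, i.e. step-down — a pure step-up
    application of the AORC is degenerate because its last critical value
    equals 1).
    """
    p = as_pvalues(p)
    if method == "lsu":
        return lsu_test(p, alpha)
    if method == "aorc_sud":
        order = 1 if lam is None else int(lam)
        return sud_test(p, aorc_critical_values(p.size, alpha, order=order))
    raise ValueError(f"unknown method {method!r}; expected 'lsu' or 'aorc_sud'")
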