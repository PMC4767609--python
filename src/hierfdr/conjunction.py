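"""Partial-conjunction p-values for family screening.

The partial-conjunction null ``H^{u/m}`` states that a family of ``m``
hypotheses contains fewer than ``u`` false nulls; its alternative is that at
least ``u`` are false.  A Simes-type combination of the upper order statistics
gives a valid p-value for this null under PRDS:

    p^{u/m} = min_{1 <= i <= m-u+1}  ((m - u + 1) / i) * p_{u-1+i : m}

capped at 1.  With ``u = 1`` this is the ordinary Simes p-value for the
intersection null.
"""

from __future__ import annotations

import math

import numpy as np

from .core import as_pvalues

__all__ = ["pc_pvalue", "u_from_kappa"]


def pc_pvalue(p, u: int) -> float:
    """Simes-type partial-conjunction p-value for "at least ``u`` signals"."""
    p = as_pvalues(p)
    m = p.size
    u = int(u)
    if not 1 <= u <= m:
        raise ValueError(f"u must lie in {{1, ..., {m}}}, got {u}")
    sp = np.sort(p, kind="stable")
    n_terms = m - u + 1
    factors = n_terms / np.arange(1, n_terms + 1, dtype=float)
    val = float(np.min(factors * sp[u - 1:]))
    # the combination can exceed 1; cap so the result remains a p-value
    return min(1.0, val)


def u_from_kappa(m_family: int, kappa: float) -> int:
    """Minimum signal count ``u = floor(m_family / kappa) + 1``, capped at ``m_family``.

    ``kappa`` tunes how large a fraction of a family must be non-null before
    the family counts as active: ``kappa > m_family`` reduces the screening
    null to the intersection hypothesis (``u = 1``).
    """
    m_family = int(m_family)
    if m_family < 1:
        raise ValueError("m_family must be a positive integer")
    kappa = float(kappa)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return min(m_family, int(math.floor(m_family / kappa)) + 1)
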