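"""One-sided normal-means power study.

Hypotheses ``H_j: mu_j = 0`` versus ``K_j: mu_j > 0`` for an observable
``T ~ N_m(mu, I_m)``; the p-value is ``p_j = 1 - Phi(t_j)``.  All false nulls
share a common effect size ``mu* > 0``.  The m hypotheses are split into k
block families with size proportions ``pi_ell`` and per-family true-null
proportions ``q_N_ell``, so unbalanced signal densities between families can
be dialled in directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .conjunction import u_from_kappa
from .metrics import GroundTruth, aggregate, fdp, power_fraction, stage1_family_error
from .procedures import FamilyPartition, bog_procedure, flat_procedure, ho_procedure

__all__ = [
    "NormalMeansConfig",
    "table1_configs",
    "generate_dataset",
    "run_study",
    "DEFAULT_PROCEDURES",
]

DEFAULT_PROCEDURES = ("ho", "bog", "aorc_flat")


@dataclass(frozen=True)
class NormalMeansConfig:
    """Full parameterization of one normal-means simulation cell."""

    m: int = 2500
    pi: Tuple[float, ...] = (0.5, 0.5)
    q_N: Tuple[float, ...] = (0.5, 0.5)
    mu_star: float = 2.5
    alpha: float = 0.05
    kappa: float = 1000.0
    B: int = 10000
    seed: int = 0

    def __post_init__(self):
        if len(self.pi) != len(self.q_N):
            raise ValueError("pi and q_N must have equal length")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("family proportions pi must sum to 1")
        for prop in self.q_N:
            if not 0.0 <= prop <= 1.0:
                raise ValueError("true-null proportions must lie in [0, 1]")
        for size in self.family_sizes:
            if size < 1:
                raise ValueError("every family must contain at least one hypothesis")

    @property
    def k(self) -> int:
        return len(self.pi)

    @property
    def family_sizes(self) -> Tuple[int, ...]:
        sizes = []
        for prop in self.pi:
            exact = prop * self.m
            size = int(round(exact))
            if abs(exact - size) > 1e-9:
                raise ValueError(f"pi_ell * m = {exact} is not an integer")
            sizes.append(size)
        return tuple(sizes)

    @property
    def family_alt_counts(self) -> Tuple[int, ...]:
        """False-null count per family, rounding half-up on the alternatives."""
        return tuple(int(np.floor(size * (1.0 - q) + 0.5))
                     for size, q in zip(self.family_sizes, self.q_N))


def table1_configs(mu_star: float = 2.5, alpha: float = 0.05,
                   kappa: float = 1000.0, B: int = 10000,
                   seed: int = 0) -> list:
    """The five (pi, q_N) study configurations at m = 2500, k = 2."""
    rows = [
        ((0.5, 0.5), (0.5, 0.5)),
        ((0.5, 0.5), (0.8, 0.1)),
        ((0.8, 0.2), (0.8, 0.1)),
        ((0.5, 0.5), (0.99, 0.01)),
        ((0.8, 0.2), (0.99, 0.01)),
    ]
    return [NormalMeansConfig(m=2500, pi=pi, q_N=q, mu_star=mu_star,
                              alpha=alpha, kappa=kappa, B=B, seed=seed)
            for pi, q in rows]


def generate_dataset(config: NormalMeansConfig,
                     rng: Optional[np.random.Generator] = None,
                     ) -> Tuple[np.ndarray, GroundTruth, FamilyPartition]:
    """Draw one replication: p-values, ground truth, and the block partition.

    False nulls occupy the first ``m_A_ell`` positions of each family (their
    position is irrelevant by exchangeability but fixed for reproducibility).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.family_sizes
    alt_counts = config.family_alt_counts

    labels = np.repeat(np.arange(1, config.k + 1), sizes)
    is_alt = np.zeros(config.m, dtype=bool)
    offset = 0
    for size, m_A in zip(sizes, alt_counts):
        is_alt[offset:offset + m_A] = True
        offset += size

    mu = np.where(is_alt, config.mu_star, 0.0)
    t = mu + rng.standard_normal(config.m)
    p = stats.norm.sf(t)
    return p, GroundTruth(is_alt), FamilyPartition.from_labels(labels)


def _run_procedures(p, part, truth, config, procedures) -> Dict[str, dict]:
    records = {}
    for proc in procedures:
        if proc == "ho":
            res = ho_procedure(p, part, config.alpha, config.kappa)
            rec = _record(res.global_reject, part, truth)
            rec["stage1_error"] = stage1_family_error(
                res.selected_families, truth, part, res.u_values)
        elif proc == "bog":
            res = bog_procedure(p, part, config.alpha)
            rec = _record(res.global_reject, part, truth)
        elif proc == "aorc_flat":
            lam = u_from_kappa(part.m, config.kappa)
            res = flat_procedure(p, config.alpha, method="aorc_sud", lam=lam)
            rec = _record(res.reject, part, truth)
        elif proc == "lsu":
            res = flat_procedure(p, config.alpha, method="lsu")
            rec = _record(res.reject, part, truth)
        else:
            raise ValueError(f"unknown procedure {proc!r}")
        records[proc] = rec
    return records


def _record(reject, part, truth) -> dict:
    fam_fdp = [fdp(reject, truth, scope=part.codes == c) for c in range(part.k)]
    return {
        "gfdp": fdp(reject, truth),
        "family_fdp": fam_fdp,
        "power": power_fraction(reject, truth),
    }


def run_study(configs: Sequence[NormalMeansConfig],
              mu_grid: Optional[Sequence[float]] = None,
              B: Optional[int] = None,
              seed: Optional[int] = None,
              procedures: Sequence[str] = DEFAULT_PROCEDURES) -> pd.DataFrame:
    """Monte-Carlo power/FDR table over (config, mu*, procedure) cells.

    Each replication's dataset is shared by all procedures (paired
    comparison).  Replication streams are spawned from the master seed, so
    increasing B extends rather than reshuffles the sequence.  The default
    effect grid is 0.5 to 5 in steps of 0.5.
    """
    if mu_grid is None:
        mu_grid = np.arange(0.5, 5.01, 0.5)
    rows = []
    for ci, base in enumerate(configs, start=1):
        config = base if B is None else replace(base, B=B)
        if seed is not None:
            config = replace(config, seed=seed)
        for mu in mu_grid:
            cell = replace(config, mu_star=float(mu))
            streams = np.random.SeedSequence(cell.seed).spawn(cell.B)
            per_proc = {proc: [] for proc in procedures}
            for b in range(cell.B):
                rng = np.random.default_rng(streams[b])
                p, truth, part = generate_dataset(cell, rng)
                recs = _run_procedures(p, part, truth, cell, procedures)
                for proc, rec in recs.items():
                    per_proc[proc].append(rec)
            for proc in procedures:
                rep = aggregate(per_proc[proc], k=cell.k)
                row = {
                    "config": ci, "mu_star": float(mu), "procedure": proc,
                    "gpower": rep.gpower, "gpower_se": rep.gpower_se,
                    "gFDR": rep.gFDR, "gFDR_se": rep.gFDR_se,
                    "stage1_FWER": rep.stage1_FWER, "B": rep.B,
                }
                for c in range(cell.k):
                    row[f"FDR_fam{c + 1}"] = rep.per_family_FDR[c]
                    if rep.per_family_FDR_se is not None:
                        row[f"FDR_fam{c + 1}_se"] = rep.per_family_FDR_se[c]
                rows.append(row)
    return pd.DataFrame(rows)
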