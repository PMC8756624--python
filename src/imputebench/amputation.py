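"""Controlled amputation of the hemorrhage-volume variable.

Given a complete cohort, these routines introduce missingness into the
single target variable (``volume_ge30ml``) under one of three mechanisms:

* ``MCAR`` — cells are drawn uniformly over all records, blind to any
  variable.
* ``MAR_1_2`` / ``MAR_2_1`` — missingness depends on the observed discharge
  outcome: the cohort is split into failure and success groups and the
  per-group missing *proportions* are held at a 1:2 (respectively 2:1)
  failure:success ratio, while the overall missing proportion is held at
  the requested value.

The missingness pattern is univariate and monotone: only the target column
is ever masked.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import OUTCOME, TARGET, Cohort

__all__ = [
    "MECHANISMS",
    "CANONICAL_PROPORTIONS",
    "MissingScenario",
    "IncompleteCohort",
    "Allocation",
    "InfeasibleAllocationError",
    "allocate_missing_counts",
    "ampute",
    "enumerate_scenarios",
]

MCAR = "MCAR"
MAR_1_2 = "MAR_1_2"
MAR_2_1 = "MAR_2_1"

#: canonical mechanism order (mechanism-major in scenario enumeration)
MECHANISMS = (MCAR, MAR_1_2, MAR_2_1)

#: the six canonical overall missing proportions
CANONICAL_PROPORTIONS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.50)

#: failure:success missing-proportion ratio per MAR mechanism
_MAR_RATIOS = {MAR_1_2: 0.5, MAR_2_1: 2.0}


class InfeasibleAllocationError(ValueError):
    """Requested missing counts exceed an outcome group's size."""


class Allocation(NamedTuple):
    """Missing-cell allocation; group counts are ``None`` under MCAR."""

    total: int
    m_failure: int | None
    m_success: int | None


@dataclasses.dataclass(frozen=True)
class MissingScenario:
    """One missing-data scenario: mechanism, overall proportion, seed."""

    mechanism: str
    proportion: float
    seed: int

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0 <= self.proportion < 1:
            raise ValueError("missing proportion must be in [0, 1)")

    @property
    def label(self) -> str:
        return f"{self.mechanism}_p{self.proportion:g}"


@dataclasses.dataclass
class IncompleteCohort:
    """A cohort with masked target cells plus audit information."""

    records: pd.DataFrame          # target column NA where masked
    mask: np.ndarray               # boolean, True where target is masked
    original_target: pd.Series     # pre-amputation values, for audit
    scenario: MissingScenario
    allocation: Allocation

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def complete_index(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)

    @property
    def missing_index(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def allocate_missing_counts(
    n_failure: int, n_success: int, p: float, mechanism: str
) -> Allocation:
    """Split the overall missing count between the two outcome groups.

    The total is ``round(p * n)``, preserved exactly.  For MAR mechanisms
    the success-group count is the rounded real-valued share solving
    ``m_f / n_f = r * m_s / n_s`` with ``r`` the failure:success ratio
    (2 for ``MAR_2_1``, 1/2 for ``MAR_1_2``); the failure group takes the
    remainder.  MCAR returns the total only.
    """
    if n_failure <= 0 or n_success <= 0:
        raise ValueError("group sizes must be positive")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    total = _round_half_up(p * (n_failure + n_success))
    if mechanism == MCAR:
        if total > n_failure + n_success:
            raise InfeasibleAllocationError("total exceeds cohort size")
        return Allocation(total, None, None)
    if mechanism not in _MAR_RATIOS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    r = _MAR_RATIOS[mechanism]
    # success missing proportion q solves n_s*q + n_f*(r*q) = total
    q_success = total / (n_success + r * n_failure)
    m_success = _round_half_up(n_success * q_success)
    m_failure = total - m_success
    if not (0 <= m_failure <= n_failure and 0 <= m_success <= n_success):
        raise InfeasibleAllocationError(
            f"allocation ({m_failure}, {m_success}) infeasible for group "
            f"sizes ({n_failure}, {n_success}) at p={p}, ratio {r}"
        )
    return Allocation(total, m_failure, m_success)


def ampute(cohort: Cohort | pd.DataFrame, scenario: MissingScenario) -> IncompleteCohort:
    """Mask target cells according to a missing scenario.

    Cells are sampled uniformly without replacement — across all records
    under MCAR, within each outcome group under MAR.  Deterministic given
    the scenario seed.
    """
    records = cohort.records if isinstance(cohort, Cohort) else cohort
    if records[TARGET].isna().any():
        raise ValueError("cohort must be complete before amputation")
    outcome = records[OUTCOME].to_numpy()
    n_failure = int((outcome == 1).sum())
    n_success = int((outcome == 0).sum())
    alloc = allocate_missing_counts(
        n_failure, n_success, scenario.proportion, scenario.mechanism
    )

    rng = np.random.default_rng(scenario.seed)
    mask = np.zeros(len(records), dtype=bool)
    if scenario.mechanism == MCAR:
        chosen = rng.choice(len(records), size=alloc.total, replace=False)
        mask[chosen] = True
    else:
        fail_idx = np.flatnonzero(outcome == 1)
        succ_idx = np.flatnonzero(outcome == 0)
        mask[rng.choice(fail_idx, size=alloc.m_failure, replace=False)] = True
        mask[rng.choice(succ_idx, size=alloc.m_success, replace=False)] = True

    amputed = records.copy()
    original = amputed[TARGET].copy()
    amputed[TARGET] = amputed[TARGET].where(~mask, other=pd.NA)
    return IncompleteCohort(
        records=amputed,
        mask=mask,
        original_target=original,
        scenario=scenario,
        allocation=alloc,
    )


def _scenario_seed(seed_base: int, mechanism: str, proportion: float) -> int:
    digest = hashlib.sha256(
        f"{seed_base}|{mechanism}|{proportion:.6f}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def enumerate_scenarios(
    proportions: tuple[float, ...] = CANONICAL_PROPORTIONS,
    mechanisms: tuple[str, ...] = MECHANISMS,
    seed_base: int = 0,
) -> list[MissingScenario]:
    """Cross-product of mechanisms and proportions, mechanism-major order.

    Each scenario gets a distinct seed derived stably from ``seed_base``,
    the mechanism and the proportion, so the full grid of incomplete
    datasets is reproducible.
    """
    if not proportions or not mechanisms:
        raise ValueError("proportions and mechanisms must be non-empty")
    return [
        MissingScenario(mech, p, _scenario_seed(seed_base, mech, p))
        for mech in mechanisms
        for p in proportions
    ]
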