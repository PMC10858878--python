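"""Group comparison of index values: two-sided Mann-Whitney U test.

The cohort design is 20 healthy subjects versus 18 patients (10 mild + 8
severe central facial palsy, graded clinically on the NIHSS); with groups
this small and index distributions bounded on [0, 1], a rank test is the
appropriate comparison.  The exact null distribution is used whenever the
smaller group has at most 8 observations and the pooled data are tie-free;
otherwise the normal approximation with tie and continuity corrections is
used, and the choice is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .errors import ValidationError

__all__ = [
    "SubjectRecord",
    "GroupTestResult",
    "mann_whitney_u",
    "compare_groups",
]

GROUPS = ("healthy", "mild", "severe")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label and the two index values."""

    subject_id: str
    group: str  # healthy | mild | severe
    smm: float
    dms: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name in ("smm", "dms"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.subject_id}: {name}={v} outside [0, 1]")

    @property
    def is_patient(self) -> bool:
        return self.group in ("mild", "severe")


@dataclass(frozen=True)
class GroupTestResult:
    u_statistic: float
    p_value: float
    n_healthy: int
    n_patient: int
    method: str  # "exact" | "normal-approx-tie-corrected"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")
        if self.u_statistic < 0 or self.u_statistic > self.n_healthy * self.n_patient:
            raise ValidationError("U statistic outside [0, n_a * n_b]")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test of *values_a* versus *values_b*.

    ``u_statistic`` is the U of the first sample (midranks for ties).  The
    p-value is exact (full rank enumeration) when ``min(n_a, n_b) <= 8``
    and the pooled sample is tie-free, else a tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(np.concatenate([a, b]))
    res = mannwhitneyu(
        a, b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return GroupTestResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_healthy=int(a.size),
        n_patient=int(b.size),
        method="exact" if exact else "normal-approx-tie-corrected",
    )


def compare_groups(
    records: Iterable[SubjectRecord],
) -> tuple[GroupTestResult, GroupTestResult]:
    """Healthy-versus-patient U tests for SMM and for DMS (in that order)."""
    records = list(records)
    healthy = [r for r in records if not r.is_patient]
    patient = [r for r in records if r.is_patient]
    if not healthy or not patient:
        raise ValidationError(
            f"need both groups; got {len(healthy)} healthy and {len(patient)} patient records"
        )
    smm = mann_whitney_u([r.smm for r in healthy], [r.smm for r in patient])
    dms = mann_whitney_u([r.dms for r in healthy], [r.dms for r in patient])
    return smm, dms
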