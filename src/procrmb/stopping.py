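"""Safety stopping at the lowest dose via Agresti–Coull binomial intervals.

The trial halts when the observed DLT count at the lowest study dose is large
enough that the lower limit of an Agresti–Coull confidence interval (default
70% confidence) strictly exceeds the endpoint's target rate.  Boundaries are
pre-tabulated per endpoint for every attainable sample size at the lowest
dose, and checked after each completed cohort on cumulative counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "StoppingBoundary",
    "agresti_coull_interval",
    "stopping_bounds",
    "safety_stop_triggered",
]


def agresti_coull_interval(y: int, n: int, confidence: float) -> tuple[float, float]:
    """Agresti–Coull adjusted-Wald interval for a binomial proportion.

    Uses the two-sided normal quantile z at (1 + confidence)/2, the adjusted
    count ``n~ = n + z^2`` and proportion ``p~ = (y + z^2/2)/n~``, returning
    ``p~ -/+ z * sqrt(p~ (1 - p~)/n~)``.  The bounds are deliberately not
    clipped to [0, 1].
    """
    if n < 1 or not 0 <= y <= n:
        raise ValueError("need 0 <= y <= n with n >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    n_adj = n + z * z
    p_adj = (y + z * z / 2.0) / n_adj
    half = z * math.sqrt(p_adj * (1.0 - p_adj) / n_adj)
    return p_adj - half, p_adj + half


@dataclass(frozen=True)
class StoppingBoundary:
    """Minimum DLT count triggering a lowest-dose safety stop, per sample size.

    ``rows`` maps each n in [cohort_size, n_max] to the smallest DLT count
    whose Agresti–Coull lower limit strictly exceeds the target, or None when
    no count of at most n qualifies.
    """

    endpoint_id: str
    target: float
    confidence: float
    rows: tuple[tuple[int, Optional[int]], ...]

    def boundary_at(self, n: int) -> Optional[int]:
        """Boundary for ``n`` patients at the lowest dose; None if no rule applies."""
        for row_n, bound in self.rows:
            if row_n == n:
                return bound
        return None

    def collapsed(self) -> list[tuple[int, int, Optional[int]]]:
        """Rows merged into (n_lo, n_hi, boundary) ranges of equal boundary."""
        out: list[tuple[int, int, Optional[int]]] = []
        for n, bound in self.rows:
            if out and out[-1][2] == bound:
                lo, _, b = out.pop()
                out.append((lo, n, b))
            else:
                out.append((n, n, bound))
        return out


def stopping_bounds(
    target: float,
    n_max: int,
    confidence: float,
    cohort_size: int = 3,
    endpoint_id: str = "clinician",
) -> StoppingBoundary:
    """Tabulate lowest-dose stopping boundaries for one endpoint.

    For each n from ``cohort_size`` to ``n_max``, the boundary is the
    smallest DLT count y whose interval lower limit strictly exceeds the
    target rate.
    """
    if n_max < cohort_size:
        raise ValueError("n_max must be at least cohort_size")
    rows = []
    for n in range(cohort_size, n_max + 1):
        bound: Optional[int] = None
        for y in range(0, n + 1):
            lower, _ = agresti_coull_interval(y, n, confidence)
            if lower > target:
                bound = y
                break
        rows.append((n, bound))
    return StoppingBoundary(
        endpoint_id=endpoint_id,
        target=target,
        confidence=confidence,
        rows=tuple(rows),
    )


def safety_stop_triggered(
    lowest_dose_counts: Sequence[tuple[int, int]],
    bounds: Sequence[StoppingBoundary],
) -> tuple[bool, tuple[str, ...]]:
    """Check cumulative lowest-dose counts against each endpoint's boundary.

    ``lowest_dose_counts`` pairs (dlt, evaluated) align with ``bounds``.
    Returns (stop?, ids of the triggering endpoints).  Sample sizes below the
    first tabulated row have no rule and never trigger.
    """
    triggered = []
    for (y, n), boundary in zip(lowest_dose_counts, bounds):
        bound = boundary.boundary_at(n) if n >= 1 else None
        if bound is not None and y >= bound:
            triggered.append(boundary.endpoint_id)
    return bool(triggered), tuple(triggered)
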