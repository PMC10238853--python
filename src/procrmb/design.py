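"""Dose-assignment logic: per-endpoint targeting, the combined minimum rule,
the no-skip escalation restriction, and the end-of-trial MTD.

Each endpoint nominates the dose whose estimated DLT rate is closest to that
endpoint's target; the next cohort is assigned the minimum of the two
nominations, capped at one level above the current dose when escalating.
The MTD is the dose that would have been assigned to the next cohort had the
trial continued past its maximum sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

from .model import PosteriorSummary

__all__ = ["Recommendation", "endpoint_best_dose", "recommend_next_dose", "declare_mtd"]


@dataclass(frozen=True)
class Recommendation:
    """Outcome of one model update.  All dose indices are 1-based."""

    per_endpoint_best: tuple[int, int]
    combined: int  # min of the pair, before the no-skip restriction
    assigned: int  # after the no-skip restriction
    timestamp: str  # ISO-8601, for the audit trail


def endpoint_best_dose(
    posterior: PosteriorSummary | Sequence[float], target: float
) -> int:
    """1-based index of the dose whose estimate is closest to the target.

    Exact ties in |estimate - target| are broken toward the lower dose.
    """
    probs = posterior.mean_prob if isinstance(posterior, PosteriorSummary) else posterior
    if len(probs) == 0:
        raise ValueError("posterior summary is empty")
    # distances equal to within 1e-12 count as ties and keep the lower dose
    best, best_dist = 1, abs(probs[0] - target)
    for j, p in enumerate(probs[1:], start=2):
        d = abs(p - target)
        if d < best_dist - 1e-12:
            best, best_dist = j, d
    return best


def recommend_next_dose(
    best_pair: tuple[int, int], current_dose: int
) -> Recommendation:
    """Combine the per-endpoint nominations and apply the no-skip rule.

    The combined recommendation is the minimum of the pair; escalation is
    capped at ``current_dose + 1``.  De-escalation may skip levels.
    """
    if current_dose < 1:
        raise ValueError("current_dose must be a 1-based dose index")
    combined = min(best_pair)
    assigned = min(combined, current_dose + 1)
    return Recommendation(
        per_endpoint_best=tuple(best_pair),
        combined=combined,
        assigned=assigned,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def declare_mtd(final_recommendation: Recommendation | None) -> int:
    """MTD at the end of a completed trial: the dose the next cohort would get.

    Raises if the trial was stopped for safety (no final recommendation).
    """
    if final_recommendation is None:
        raise RuntimeError("no MTD: the trial was stopped before completion")
    return final_recommendation.assigned
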