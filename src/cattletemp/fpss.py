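"""Movement-based temperament scoring from four-platform standing scale traces.

A trace is the ~15 Hz record of the weight on each scale quadrant while a calf
stands on the platform.  Scoring proceeds in two steps:

1. **Start point.**  The first record where the animal is judged to be fully
   standing on the scale: the total weight must agree with the chute-recorded
   weaning weight within a tolerance, and the next few records must be mutually
   stable (all pairwise absolute differences within a tolerance).  The numeric
   tolerances are not fixed by the protocol; defaults are 5% of the chute
   weight for agreement and 2% for pairwise stability, with a 5-record
   look-ahead.  All are configurable and recorded in every score.
2. **Scores.**  The start point and the 499 records after it (500 total) give
   the window mean, the standard deviation of total weight (SSD, the movement
   score) and its coefficient of variation (CVSSD = SSD / mean).

QC flags are advisory only — they never change the scoring window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import FPSSTrace

WINDOW = 500  # start point + 499 subsequent records


class StartPointNotFound(ValueError):
    """No index satisfies the start-point criteria.

    Carries the best candidate index (closest weight agreement with enough
    records remaining) and the criterion it failed, mirroring the role of the
    operator's QC log.
    """

    def __init__(self, message: str, best_index: int | None = None,
                 failed_criterion: str | None = None):
        super().__init__(message)
        self.best_index = best_index
        self.failed_criterion = failed_criterion


@dataclass(frozen=True)
class StartPointCriteria:
    """Tolerances of the start-point search.

    weight_tolerance_kg : max |total[ssp] - chute weight| to accept a candidate
    stability_window    : number of look-ahead records i = 1..w checked
    pairwise_tolerance_kg : max pairwise |difference| among records ssp..ssp+w
    """

    weight_tolerance_kg: float
    pairwise_tolerance_kg: float
    stability_window: int = 5

    def __post_init__(self) -> None:
        if self.weight_tolerance_kg <= 0 or self.pairwise_tolerance_kg <= 0:
            raise ValueError("tolerances must be positive")
        if self.stability_window < 1:
            raise ValueError("stability_window must be >= 1")

    @classmethod
    def from_chute_weight(cls, chute_weight_kg: float,
                          weight_frac: float = 0.05,
                          pairwise_frac: float = 0.02,
                          stability_window: int = 5) -> "StartPointCriteria":
        """Default relative tolerances: 5% / 2% of the chute weight."""
        return cls(weight_frac * chute_weight_kg, pairwise_frac * chute_weight_kg,
                   stability_window)


@dataclass(frozen=True)
class FPSSScore:
    """Movement score of one animal over the 500-record window."""

    animal_id: str
    start_index: int
    window_mean: float   # kg
    SSD: float           # kg, sample SD (n-1) of total weight over the window
    CVSSD: float         # dimensionless, SSD / window_mean
    criteria: StartPointCriteria | None = field(default=None, compare=False)


def find_start_point(trace: FPSSTrace, chute_weight_kg: float,
                     criteria: StartPointCriteria | None = None) -> int:
    """Earliest index where the animal is fully and stably on the scale.

    An index ``ssp`` qualifies when (a) ``|total[ssp] - chute_weight| <=
    weight_tolerance``, (b) every pairwise absolute difference among
    ``total[ssp .. ssp+stability_window]`` is within ``pairwise_tolerance``,
    and (c) at least 499 records follow, so the full scoring window fits.
    Deterministic given inputs.
    """
    if chute_weight_kg <= 0:
        raise ValueError("chute weight must be positive")
    if criteria is None:
        criteria = StartPointCriteria.from_chute_weight(chute_weight_kg)
    total = trace.total_weight
    n = total.size
    last = n - WINDOW  # last index with 499 records after it
    if last < 0:
        raise StartPointNotFound(
            f"trace has {n} records; {WINDOW} are required after any start point",
            best_index=None, failed_criterion="window",
        )
    w = criteria.stability_window
    cand = np.abs(total[: last + 1] - chute_weight_kg) <= criteria.weight_tolerance_kg
    # pairwise stability over [i, i+w]: max - min of the (w+1)-record slice
    view = np.lib.stride_tricks.sliding_window_view(total, w + 1)[: last + 1]
    stable = view.max(axis=1) - view.min(axis=1) <= criteria.pairwise_tolerance_kg
    ok = np.flatnonzero(cand & stable)
    if ok.size:
        return int(ok[0])
    if cand.any():
        best = int(np.flatnonzero(cand)[0])
        raise StartPointNotFound(
            f"no stable start point: index {best} matches the chute weight but "
            f"fails look-ahead stability",
            best_index=best, failed_criterion="pairwise_stability",
        )
    best = int(np.argmin(np.abs(total[: last + 1] - chute_weight_kg)))
    raise StartPointNotFound(
        f"no record within {criteria.weight_tolerance_kg:.3g} kg of the chute "
        f"weight {chute_weight_kg:.3g} kg (closest: index {best})",
        best_index=best, failed_criterion="weight_agreement",
    )


def compute_score(trace: FPSSTrace, start_index: int,
                  criteria: StartPointCriteria | None = None) -> FPSSScore:
    """SSD / CVSSD over records [start_index, start_index + 499] inclusive."""
    total = trace.total_weight
    if start_index < 0 or start_index + WINDOW > total.size:
        raise ValueError(
            f"window [{start_index}, {start_index + WINDOW - 1}] exceeds trace "
            f"length {total.size}"
        )
    window = total[start_index: start_index + WINDOW]
    mean = float(window.mean())
    ssd = float(window.std(ddof=1))
    return FPSSScore(trace.animal_id, int(start_index), mean, ssd, ssd / mean,
                     criteria=criteria)


def score_trace(trace: FPSSTrace, chute_weight_kg: float,
                criteria: StartPointCriteria | None = None) -> FPSSScore:
    """Find the start point and score in one call."""
    if criteria is None:
        criteria = StartPointCriteria.from_chute_weight(chute_weight_kg)
    ssp = find_start_point(trace, chute_weight_kg, criteria)
    return compute_score(trace, ssp, criteria)


# QC flag names
SHORT_TRACE = "SHORT_TRACE"
NEGATIVE_WEIGHT = "NEGATIVE_WEIGHT"
NONFINITE = "NONFINITE"
NEVER_STABLE = "NEVER_STABLE"

MIN_DURATION_S = 45.0


def qc_trace(trace: FPSSTrace, criteria: StartPointCriteria | None = None,
             chute_weight_kg: float | None = None) -> list[str]:
    """Advisory quality flags for a raw trace; empty list = pass.

    ``NEVER_STABLE`` is only assessed when a chute weight (or explicit
    criteria) is supplied.  Flags never alter the scoring window.
    """
    flags: list[str] = []
    q = trace.quadrant_weights
    if trace.n_records < MIN_DURATION_S * trace.rate_hz:
        flags.append(SHORT_TRACE)
    if not np.all(np.isfinite(q)):
        flags.append(NONFINITE)
    elif np.any(q < 0):
        flags.append(NEGATIVE_WEIGHT)
    if chute_weight_kg is not None and np.all(np.isfinite(q)):
        try:
            find_start_point(trace, chute_weight_kg, criteria)
        except StartPointNotFound:
            flags.append(NEVER_STABLE)
    return flags
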