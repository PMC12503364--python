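"""Distal-histidine swing-out event statistics.

A swing-out event is binary per chain-replicate trace: did the HisE7
Ne-Fe distance ever exceed the 7 A (0.7 nm) threshold in the analyzed
window (t >= equilibration cutoff)?  Excursion-level detail (every maximal
run above the threshold) and return-to-down detection are recorded as
well.  Event counts and first-passage ("swing-out") times are normalized
for unequal simulation lengths; both normalization factors are reported
separately so alternative normalizations can be recomputed from the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DistanceTrace

__all__ = [
    "SWING_THRESHOLD_NM",
    "SwingRecord",
    "TreatmentSummary",
    "detect_swing",
    "count_events",
    "normalized_swing_times",
]

SWING_THRESHOLD_NM = 0.7  # "greater than 7 A"
DEFAULT_RETURN_DWELL_NS = 5.0


@dataclass(frozen=True)
class SwingRecord:
    """Gating outcome of one chain-replicate distance trace."""

    replicate_id: str
    chain_id: str
    swung_out: bool
    first_exceed_time: float | None  # ns; present iff swung_out
    excursions: tuple[tuple[float, float | None], ...]  # (start ns, end ns | open)
    returned_down: bool
    replicate_total_time: float  # ns

    def __post_init__(self) -> None:
        if self.swung_out != (self.first_exceed_time is not None):
            raise ValueError("first_exceed_time must be present iff swung_out")
        if self.returned_down and not self.swung_out:
            raise ValueError("returned_down implies swung_out")
        last_end = -np.inf
        for start, end in self.excursions:
            if start <= last_end:
                raise ValueError("excursions must be ordered and non-overlapping")
            last_end = end if end is not None else np.inf


@dataclass
class TreatmentSummary:
    """Per-treatment (species x protonation state) event bookkeeping."""

    treatment: str
    n_chain_replicates: int
    raw_event_count: int
    normalized_event_count: float
    total_time: float  # ns, summed over distinct replicates
    reference_total_time: float  # ns
    normalized_swing_times: list[float] = field(default_factory=list)

    @property
    def mean_normalized_swing_time(self) -> float | None:
        if not self.normalized_swing_times:
            return None
        return float(np.mean(self.normalized_swing_times))


def detect_swing(
    trace: DistanceTrace,
    *,
    threshold: float = SWING_THRESHOLD_NM,
    down_threshold: float = SWING_THRESHOLD_NM,
    dwell_min: float = DEFAULT_RETURN_DWELL_NS,
    replicate_id: str = "",
    chain_id: str = "",
) -> SwingRecord:
    """Scan one trace for threshold crossings.

    Ties at exactly the threshold do not count (strict ``>``).  A return to
    the down position requires, after the first excursion, a contiguous run
    at or below ``down_threshold`` lasting at least ``dwell_min`` ns — a
    dwell requirement that keeps single-frame dips from counting as returns.
    """
    times, values = trace.analyzed()
    if len(times) == 0:
        raise ValueError("trace has no frames past the equilibration cutoff")
    above = values > threshold
    swung = bool(above.any())
    first_time = float(times[int(np.argmax(above))]) if swung else None

    excursions: list[tuple[float, float | None]] = []
    in_exc = False
    start = 0.0
    for t, up in zip(times, above):
        if up and not in_exc:
            in_exc, start = True, float(t)
        elif not up and in_exc:
            excursions.append((start, float(t)))
            in_exc = False
    if in_exc:
        excursions.append((start, None))

    returned = False
    if swung and excursions:
        first_end = excursions[0][1]
        if first_end is not None:
            after = times >= first_end
            t_after = times[after]
            down = values[after] <= down_threshold
            run_start = None
            for t, is_down in zip(t_after, down):
                if is_down and run_start is None:
                    run_start = t
                elif not is_down:
                    if run_start is not None and t - run_start >= dwell_min:
                        returned = True
                        break
                    run_start = None
            if not returned and run_start is not None and t_after[-1] - run_start >= dwell_min:
                returned = True

    return SwingRecord(
        replicate_id=replicate_id,
        chain_id=chain_id,
        swung_out=swung,
        first_exceed_time=first_time,
        excursions=tuple(excursions),
        returned_down=returned,
        replicate_total_time=float(trace.total_time),
    )


def _treatment_total_time(records: list[SwingRecord]) -> float:
    per_rep: dict[str, float] = {}
    for rec in records:
        per_rep[rec.replicate_id] = rec.replicate_total_time
    return float(sum(per_rep.values()))


def count_events(
    records: list[SwingRecord],
    reference_total_time: float,
    *,
    treatment: str = "",
) -> TreatmentSummary:
    """Raw and time-corrected event counts for one treatment.

    The raw count is the number of chain-replicate traces that ever exceeded
    the threshold (for 2 alpha chains x 5 replicates the maximum is 10).
    The normalized count corrects for unequal total simulation time:
    ``raw x reference_total_time / treatment_total_time`` where the
    treatment total sums each distinct replicate's length once (the two
    chains of one replicate share one simulation).
    """
    if not records:
        raise ValueError("no records")
    if reference_total_time <= 0:
        raise ValueError("reference_total_time must be positive")
    total = _treatment_total_time(records)
    if total <= 0:
        raise ValueError("treatment total simulation time is zero")
    raw = sum(1 for r in records if r.swung_out)
    return TreatmentSummary(
        treatment=treatment,
        n_chain_replicates=len(records),
        raw_event_count=raw,
        normalized_event_count=raw * reference_total_time / total,
        total_time=total,
        reference_total_time=reference_total_time,
    )


def normalized_swing_times(
    records: list[SwingRecord],
    longest_replicate_time: float,
    reference_total_time: float,
    treatment_total_time: float | None = None,
) -> list[float]:
    """Length-normalized first-passage times of the traces that swung out.

    Each contributing record's time is rescaled for within-treatment length
    differences (to the longest replicate) and between-treatment differences
    (to the reference total time)::

        t_norm = t x (longest / replicate_total) x (reference / treatment_total)

    Records with no event contribute nothing: the result is an empty list,
    not zero, when nothing swung out.
    """
    if longest_replicate_time <= 0 or reference_total_time <= 0:
        raise ValueError("normalization times must be positive")
    if treatment_total_time is None:
        treatment_total_time = _treatment_total_time(records)
    if treatment_total_time <= 0:
        raise ValueError("treatment total simulation time must be positive")
    out: list[float] = []
    for rec in records:
        if not rec.swung_out:
            continue
        factor_within = longest_replicate_time / rec.replicate_total_time
        factor_between = reference_total_time / treatment_total_time
        out.append(rec.first_exceed_time * factor_within * factor_between)
    return out
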