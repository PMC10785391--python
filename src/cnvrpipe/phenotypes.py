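"""Derivation of growth, feed-efficiency and feeding-behavior traits.

Traits handled here, with their field-standard definitions:

* W210 — weaning weight linearly adjusted to 210 days of age:
  ``W210 = ((WW - BW) / AAW) * 210 + BW`` with WW the weaning weight (kg),
  BW the birth weight (kg) and AAW the age at weaning (days).
* ADG — average daily gain (kg/day), the slope of an ordinary
  least-squares regression of test-period weights on days on test (DOT).
* DMI — dry matter intake (kg/day): as-fed intake per valid day times the
  diet dry-matter proportion of that week, averaged over valid days.
* RFI — residual feed intake (kg/day): the residual of an OLS regression
  of DMI on ADG and mid-test metabolic body weight BW^0.75 (Koch
  residual), fitted within a contemporary test group.
* TF / FF — daily time at the feed bunk (min/day) and daily frequency of
  bunk visits (events/day), derived from electronic tag-read streams.

Meal events are segmented from raw tag reads: an event opens at a tag's
first read and closes when the same tag's inter-read gap exceeds 300 s or
when a different tag is read at the same bunk.  Reads of one animal at
different bunks within the gap window remain a single meal event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MealEvent",
    "compute_w210",
    "compute_wsel",
    "compute_adg",
    "mid_test_metabolic_weight",
    "compute_dmi",
    "compute_rfi",
    "derive_meal_events",
    "filter_meal_events",
    "compute_tf_ff",
    "events_to_frame",
]


@dataclass(frozen=True)
class MealEvent:
    """One contiguous feeding bout reconstructed from tag reads."""

    animal_id: str
    bunk_id: str
    start_time: float
    end_time: float
    intake: float
    n_reads: int = 1

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("end_time < start_time")
        if self.intake < 0:
            raise ValueError("negative intake")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def compute_w210(bw: float, ww: float, aaw: float) -> float:
    """Weaning weight adjusted to 210 days of age.

    W210 = ((WW - BW) / AAW) * 210 + BW.  ``aaw`` must be positive;
    negative pre-weaning gain is allowed (flag upstream if needed).
    """
    if np.any(np.asarray(aaw) <= 0):
        raise ValueError("age at weaning must be positive")
    bw = np.asarray(bw, dtype=float)
    ww = np.asarray(ww, dtype=float)
    aaw = np.asarray(aaw, dtype=float)
    out = (ww - bw) / aaw * 210.0 + bw
    return float(out) if out.ndim == 0 else out


def compute_wsel(ages_days: Sequence[float], weights_kg: Sequence[float], target_age: float) -> float:
    """Body weight linearly interpolated/extrapolated to a target age.

    Uses the two weighings nearest to ``target_age`` that bracket it when
    possible, otherwise the two nearest overall.  Experimental: intended
    for selection-weight targets (e.g. 378 d males, 550 d females).
    """
    ages = np.asarray(ages_days, dtype=float)
    wts = np.asarray(weights_kg, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least two weighings")
    order = np.argsort(ages)
    ages, wts = ages[order], wts[order]
    below = np.where(ages <= target_age)[0]
    above = np.where(ages >= target_age)[0]
    if below.size and above.size:
        i, j = below[-1], above[0]
        if i == j:  # exact age match
            return float(wts[i])
    else:  # extrapolate from the two nearest points
        nearest = np.argsort(np.abs(ages - target_age))[:2]
        i, j = sorted(nearest)
    slope = (wts[j] - wts[i]) / (ages[j] - ages[i])
    return float(wts[i] + slope * (target_age - ages[i]))


def compute_adg(dot: Sequence[float], weights: Sequence[float], *, max_gap_days: float = 28.0):
    """OLS regression of weight on days-on-test; slope is ADG.

    Returns ``(intercept, slope, diagnostics)`` where diagnostics include
    R^2, n and a flag when consecutive weighings are more than
    ``max_gap_days`` apart (warns, does not fail).
    """
    dot = np.asarray(dot, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dot.shape != weights.shape:
        raise ValueError("dot and weights lengths differ")
    if np.unique(dot).size < 2:
        raise ValueError("need >= 2 distinct days-on-test for the ADG regression")
    X = np.column_stack([np.ones_like(dot), dot])
    coef, _, _, _ = np.linalg.lstsq(X, weights, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((weights - fitted) ** 2))
    ss_tot = float(np.sum((weights - weights.mean()) ** 2))
    gaps = np.diff(np.sort(dot))
    diagnostics = {
        "n": int(dot.size),
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        "max_gap_days": float(gaps.max()) if gaps.size else 0.0,
        "gap_warning": bool(gaps.size and gaps.max() > max_gap_days),
    }
    return float(coef[0]), float(coef[1]), diagnostics


def mid_test_metabolic_weight(dot: Sequence[float], weights: Sequence[float]) -> float:
    """BW^0.75 at the median day on test, from the ADG regression line."""
    intercept, slope, _ = compute_adg(dot, weights)
    bw_mid = intercept + slope * float(np.median(np.asarray(dot, dtype=float)))
    if bw_mid <= 0:
        raise ValueError("non-positive mid-test weight")
    return bw_mid ** 0.75


def compute_dmi(
    intakes_asfed: Sequence[float],
    weeks: Sequence[int],
    dm_by_week: Mapping[int, float],
) -> float:
    """Average daily dry matter intake over valid days.

    Each valid day's as-fed intake is multiplied by the dry-matter
    proportion of the diet offered that week, then averaged.
    """
    intakes = np.asarray(intakes_asfed, dtype=float)
    weeks = np.asarray(weeks)
    if intakes.size == 0:
        raise ValueError("no valid intake days")
    if intakes.shape != weeks.shape:
        raise ValueError("intakes and weeks lengths differ")
    dm = np.array([dm_by_week[int(w)] for w in weeks], dtype=float)
    if np.any((dm <= 0) | (dm > 1)):
        raise ValueError("dry matter proportions must lie in (0, 1]")
    return float(np.mean(intakes * dm))


def compute_rfi(
    dmi: Sequence[float],
    adg: Sequence[float],
    bw075: Sequence[float],
    groups: Sequence | None = None,
) -> np.ndarray:
    """Koch residual feed intake: residuals of DMI ~ 1 + ADG + BW^0.75.

    When ``groups`` is given the regression is fitted within each
    contemporary test group separately; residuals average zero within
    each fitted group.
    """
    dmi = np.asarray(dmi, dtype=float)
    adg = np.asarray(adg, dtype=float)
    bw075 = np.asarray(bw075, dtype=float)
    if not (dmi.shape == adg.shape == bw075.shape):
        raise ValueError("dmi, adg and bw075 lengths differ")
    resid = np.full_like(dmi, np.nan)
    group_arr = np.zeros(dmi.size) if groups is None else np.asarray(groups)
    for g in pd.unique(group_arr):
        mask = group_arr == g
        if mask.sum() < 4:
            raise ValueError(f"group {g!r} has fewer than 4 records")
        X = np.column_stack([np.ones(mask.sum()), adg[mask], bw075[mask]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient RFI design in group {g!r}")
        coef, _, _, _ = np.linalg.lstsq(X, dmi[mask], rcond=None)
        resid[mask] = dmi[mask] - X @ coef
    return resid


def derive_meal_events(reads: pd.DataFrame, gap_s: float = 300.0) -> list[MealEvent]:
    """Segment a tag-read stream into meal events.

    ``reads`` needs columns animal_id, bunk_id, timestamp_s, intake_kg and
    must be sorted by timestamp (raises otherwise — no silent sort).  An
    animal's open event closes when its own inter-read gap exceeds
    ``gap_s`` or when a different tag is read at the bunk the animal was
    last seen at; bunk changes by the same animal within the gap window
    extend the same event.
    """
    required = {"animal_id", "bunk_id", "timestamp_s", "intake_kg"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"reads missing columns {sorted(missing)}")
    ts = reads["timestamp_s"].to_numpy(dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("reads must be sorted by timestamp_s")

    # open[animal] = [first_t, last_t, intake, n_reads, current_bunk]
    open_events: dict[str, list] = {}
    events: list[MealEvent] = []

    def close(animal: str) -> None:
        first, last, intake, n, bunk = open_events.pop(animal)
        events.append(
            MealEvent(
                animal_id=animal, bunk_id=bunk, start_time=first,
                end_time=last, intake=intake, n_reads=n,
            )
        )

    for row in reads.itertuples(index=False):
        animal = str(row.animal_id)
        bunk = str(row.bunk_id)
        t = float(row.timestamp_s)
        intake = float(row.intake_kg)
        # a new tag at this bunk interrupts whoever was last read there
        for other in [a for a, st in open_events.items() if st[4] == bunk and a != animal]:
            close(other)
        state = open_events.get(animal)
        if state is not None and t - state[1] > gap_s:
            close(animal)
            state = None
        if state is None:
            open_events[animal] = [t, t, intake, 1, bunk]
        else:
            state[1] = t
            state[2] += intake
            state[3] += 1
            state[4] = bunk
    for animal in list(open_events):
        close(animal)
    events.sort(key=lambda e: (e.start_time, e.animal_id))
    return events


def filter_meal_events(
    events: Sequence[MealEvent],
    min_intake_kg: float = 1.0,
    min_duration_s: float = 3.0,
    rule: str = "both",
) -> list[MealEvent]:
    """Discard trivially small events.

    ``rule="both"`` (default) discards an event only when intake < 1 kg
    AND duration < 3 s (the literal conjunction); ``rule="either"``
    discards when either bound is violated.
    """
    if rule not in {"both", "either"}:
        raise ValueError("rule must be 'both' or 'either'")
    kept = []
    for e in events:
        small_intake = e.intake < min_intake_kg
        short = e.duration < min_duration_s
        discard = (small_intake and short) if rule == "both" else (small_intake or short)
        if not discard:
            kept.append(e)
    return kept


def compute_tf_ff(events: Sequence[MealEvent], n_test_days: int) -> pd.DataFrame:
    """Per-animal TF (min/day) and FF (events/day).

    TF sums event durations (in minutes) over the test and divides by the
    number of test days; FF is the event count per day.
    """
    if n_test_days < 1:
        raise ValueError("n_test_days must be >= 1")
    rows: dict[str, dict] = {}
    for e in events:
        r = rows.setdefault(e.animal_id, {"dur_s": 0.0, "count": 0})
        r["dur_s"] += e.duration
        r["count"] += 1
    return pd.DataFrame(
        [
            {
                "animal_id": a,
                "TF": r["dur_s"] / 60.0 / n_test_days,
                "FF": r["count"] / n_test_days,
            }
            for a, r in sorted(rows.items())
        ],
        columns=["animal_id", "TF", "FF"],
    )


def events_to_frame(events: Sequence[MealEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": e.animal_id,
                "bunk_id": e.bunk_id,
                "start_time": e.start_time,
                "end_time": e.end_time,
                "duration": e.duration,
                "intake": e.intake,
                "n_reads": e.n_reads,
            }
            for e in events
        ],
        columns=["animal_id", "bunk_id", "start_time", "end_time", "duration", "intake", "n_reads"],
    )
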