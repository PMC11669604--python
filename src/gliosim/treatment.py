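"""Treatment timeline, linear-quadratic radiotherapy and chemotherapy sinks.

The standard-of-care regimen (Stupp protocol) is 60 Gy of radiotherapy in
30 weekday fractions of 2 Gy over six weeks with concurrent daily
temozolomide, followed by six adjuvant chemotherapy cycles of five
consecutive days every 28 days.  A second-line block (PCV-like, modelled
as dose-rescaled equivalents) can be appended from config.

Radiotherapy intensity per fraction follows the linear-quadratic model
``rbar(j) = alpha D(j) + beta D(j)^2``.  Chemotherapy kill combines an
exponential kill factor ``b (1 - exp(-zeta W))`` with a Holling type-II
saturation ``mu K / (K + s c)`` realising the Norton-Simon hypothesis
(kill effectiveness drops as the tumour nears carrying capacity).  Each
administration acts in time through a smooth asymmetric bump supported on
``(T - rise, T + decay)`` with peak 1 at the administration time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHEMO_FACTOR_SET = (1.0, 1.1, 1.5, 2.0, 2.4, 2.5, 2.8)


class ScheduleError(ValueError):
    """Inconsistent treatment schedule configuration."""


@dataclass(frozen=True)
class TherapyParams:
    alpha: float = 0.3  # LQ linear coefficient [1/Gy]
    beta: float = 0.03  # LQ quadratic coefficient [1/Gy^2]
    b: float = 0.4  # maximal fractional chemo kill
    zeta: float = 1.0  # drug sensitivity
    W: float = 1.0  # drug concentration (constant per administration)
    K: float = 1.0  # carrying capacity
    s: float = 1.0  # Norton-Simon extent (s=0 disables saturation)
    mu: float = 0.4  # growth rate shared with the macro kinetics [1/day]
    literal_exponential_kill: bool = False  # reproduce the printed sign

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "b", "zeta", "W", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s < 0:
            raise ValueError("s must be nonnegative")


@dataclass
class TreatmentTimeline:
    """Radiotherapy / chemotherapy calendar over ``total_days`` days.

    Days are 1-based; day 1 is a Monday by convention.  ``radio_doses``
    maps fraction day -> dose in Gy; ``chemo_doses`` maps chemo day ->
    administered dose in mg.  Administration times sit at midday
    (``day - 0.5`` in continuous days from t=0).
    """

    total_days: int
    radio_doses: dict[int, float] = field(default_factory=dict)
    chemo_doses: dict[int, float] = field(default_factory=dict)
    chemo_dose_ref: float = 130.0  # reference (day-1) chemo dose in mg
    stages_per_day: int = 5
    bump_rise: float = 0.1  # [day]
    bump_decay: float = 0.4  # [day]

    def __post_init__(self) -> None:
        for day in list(self.radio_doses) + list(self.chemo_doses):
            if not 1 <= day <= self.total_days:
                raise ScheduleError(f"treatment day {day} outside 1..{self.total_days}")
        if any(d <= 0 for d in self.radio_doses.values()):
            raise ScheduleError("radiotherapy doses must be positive")

    @property
    def radio_days(self) -> list[int]:
        return sorted(self.radio_doses)

    @property
    def chemo_days(self) -> list[int]:
        return sorted(self.chemo_doses)

    @property
    def n_stages(self) -> int:
        return self.total_days * self.stages_per_day

    def admin_time(self, day: int) -> float:
        return day - 0.5

    def to_records(self) -> list[dict]:
        recs = [
            {"day": d, "modality": "radio", "dose": self.radio_doses[d]}
            for d in self.radio_days
        ]
        recs += [
            {"day": d, "modality": "chemo", "dose": self.chemo_doses[d]}
            for d in self.chemo_days
        ]
        return sorted(recs, key=lambda r: (r["day"], r["modality"]))

    @classmethod
    def from_records(cls, records, total_days, **kw) -> "TreatmentTimeline":
        radio = {int(r["day"]): float(r["dose"]) for r in records
                 if r["modality"] == "radio"}
        chemo = {int(r["day"]): float(r["dose"]) for r in records
                 if r["modality"] == "chemo"}
        return cls(total_days, radio, chemo, **kw)


def is_weekday(day: int) -> bool:
    """Day 1 is a Monday; weekdays are Monday..Friday."""
    return (day - 1) % 7 < 5


def build_stupp_timeline(
    total_days: int = 900,
    fraction_dose: float = 2.0,
    n_fractions: int = 30,
    concurrent_dose: float = 130.0,
    adjuvant_dose: float = 265.0,
    n_adjuvant_cycles: int = 6,
    adjuvant_cycle_days: int = 5,
    adjuvant_period: int = 28,
    adjuvant_gap: int = 28,
    second_line: list[dict] | None = None,
    stages_per_day: int = 5,
) -> TreatmentTimeline:
    """Standard Stupp-protocol calendar starting on day 1 (a Monday).

    Radiotherapy: ``n_fractions`` weekday fractions of ``fraction_dose``
    Gy (default 30 x 2 Gy = 60 Gy over six weeks) with concurrent daily
    chemotherapy (7 days/week) for the whole radiotherapy period.
    Adjuvant: ``n_adjuvant_cycles`` cycles of ``adjuvant_cycle_days``
    consecutive chemo days whose starts are ``adjuvant_period`` days
    apart, beginning ``adjuvant_gap`` days after radiotherapy ends.
    ``second_line`` optionally appends extra blocks, each a dict with
    keys ``start_day``, ``n_cycles``, ``cycle_days``, ``period``,
    ``dose``.
    """
    radio: dict[int, float] = {}
    day = 1
    while len(radio) < n_fractions:
        if day > total_days:
            raise ScheduleError("radiotherapy does not fit in the timeline")
        if is_weekday(day):
            radio[day] = fraction_dose
        day += 1
    # Concurrent chemo runs 7 days/week through the whole radiotherapy
    # period (to the end of the week of the last fraction).
    rt_end = 7 * ((max(radio) + 6) // 7)

    chemo: dict[int, float] = {d: concurrent_dose for d in range(1, rt_end + 1)}

    cycle_starts = [rt_end + adjuvant_gap + m * adjuvant_period
                    for m in range(n_adjuvant_cycles)]
    for start in cycle_starts:
        for d in range(start, start + adjuvant_cycle_days):
            if d > total_days:
                raise ScheduleError("adjuvant cycles do not fit in the timeline")
            if d in chemo:
                raise ScheduleError(f"overlapping chemo administrations on day {d}")
            chemo[d] = adjuvant_dose

    for block in second_line or []:
        for m in range(int(block.get("n_cycles", 1))):
            start = int(block["start_day"]) + m * int(block.get("period", 28))
            for d in range(start, start + int(block.get("cycle_days", 1))):
                if d > total_days:
                    raise ScheduleError("second-line block does not fit")
                if d in chemo:
                    raise ScheduleError(f"overlapping chemo administrations on day {d}")
                chemo[d] = float(block["dose"])

    return TreatmentTimeline(
        total_days=total_days, radio_doses=radio, chemo_doses=chemo,
        chemo_dose_ref=concurrent_dose, stages_per_day=stages_per_day,
    )


def stage_day_map(stage_index: int, stages_per_day: int = 5) -> int:
    """0-based day index of a 0-based stage: ``day = floor(stage / spd)``."""
    if stage_index < 0:
        raise ValueError("stage index must be nonnegative")
    return stage_index // stages_per_day


def day_stages(day_index: int, stages_per_day: int = 5) -> range:
    """The stages making up one 0-based day (inverse of stage_day_map)."""
    return range(day_index * stages_per_day, (day_index + 1) * stages_per_day)


def radio_intensity(dose: float, alpha: float, beta: float) -> float:
    """Linear-quadratic fraction intensity ``rbar = alpha D + beta D^2``."""
    return alpha * dose + beta * dose * dose


def delivery_bump(t, admin_time: float, rise: float, decay: float):
    """Smooth asymmetric delivery bump: support (T-rise, T+decay), peak 1 at T.

    Built from two half mollifier lobes ``exp(1 - 1/(1 - s^2))`` with
    different widths, giving a C1 compactly supported bump normalised by
    peak value (the fraction intensity carries the magnitude).
    """
    if rise <= 0 or decay <= 0:
        raise ValueError("bump rise and decay must be positive")
    t = np.asarray(t, dtype=np.float64)
    s = np.where(t < admin_time, (t - admin_time) / rise, (t - admin_time) / decay)
    inside = np.abs(s) < 1.0
    s2 = np.where(inside, s * s, 0.0)
    out = np.where(inside, np.exp(1.0 - 1.0 / (1.0 - s2)), 0.0)
    return out if out.ndim else float(out)


def dose_factor(day: int, timeline: TreatmentTimeline) -> float:
    """Per-day chemo upscaling factor: the member of the printed factor set
    nearest to ``dose_mg(day) / chemo_dose_ref`` (0 on non-chemo days)."""
    if day not in timeline.chemo_doses:
        return 0.0
    ratio = timeline.chemo_doses[day] / timeline.chemo_dose_ref
    return min(CHEMO_FACTOR_SET, key=lambda f: abs(f - ratio))


def radio_rate(t: float, timeline: TreatmentTimeline,
               params: TherapyParams) -> float:
    """Radiotherapy kill rate per unit density at time ``t`` (days):
    ``sum_m rbar(j_m) psi_radio_{j_m}(t)``."""
    rate = 0.0
    for day, dose in timeline.radio_doses.items():
        T = timeline.admin_time(day)
        if T - timeline.bump_rise < t < T + timeline.bump_decay:
            rate += radio_intensity(dose, params.alpha, params.beta) * delivery_bump(
                t, T, timeline.bump_rise, timeline.bump_decay
            )
    return rate


def chemo_delivery(t: float, timeline: TreatmentTimeline) -> float:
    """``sum_k rho_g(i_k) psi_chemo_{i_k}(t)`` at time ``t`` (days)."""
    tot = 0.0
    for day in timeline.chemo_doses:
        T = timeline.admin_time(day)
        if T - timeline.bump_rise < t < T + timeline.bump_decay:
            tot += dose_factor(day, timeline) * delivery_bump(
                t, T, timeline.bump_rise, timeline.bump_decay
            )
    return tot


def exponential_kill(params: TherapyParams) -> float:
    """Fractional kill ``b (1 - exp(-zeta W))``; the config switch
    ``literal_exponential_kill`` reproduces the printed ``b (1 - exp(zeta W))``
    (negative for positive zeta, W — kept only for comparison)."""
    sign = 1.0 if params.literal_exponential_kill else -1.0
    return params.b * (1.0 - np.exp(sign * params.zeta * params.W))


def radiotherapy_sink(c: np.ndarray, t: float, timeline: TreatmentTimeline,
                      params: TherapyParams) -> np.ndarray:
    """Radiotherapy sink field ``sum_m rbar(j_m) psi(t) c``."""
    return radio_rate(t, timeline, params) * np.asarray(c)


def chemo_rate(c: np.ndarray, t: float, timeline: TreatmentTimeline,
               params: TherapyParams) -> np.ndarray:
    """Chemotherapy kill rate per unit density (the factor multiplying c)."""
    deliv = chemo_delivery(t, timeline)
    if deliv == 0.0:
        return np.zeros_like(np.asarray(c, dtype=np.float64))
    satur = params.mu * params.K / (params.K + params.s * np.asarray(c))
    return satur * exponential_kill(params) * deliv


def chemo_sink(c: np.ndarray, t: float, timeline: TreatmentTimeline,
               params: TherapyParams) -> np.ndarray:
    """Chemotherapy sink field (Norton-Simon saturated exponential kill)."""
    return chemo_rate(c, t, timeline, params) * np.asarray(c)
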