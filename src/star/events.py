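"""Event-level processing of operant self-administration sessions.

A session is a timestamped stream of nose-pokes, licks, and sipper
extensions/retractions recorded at millisecond resolution.  This module
validates those streams, derives the per-session scalars used by the
phenotyping analysis (intake in g/kg, response counts, reinforcers),
and implements the timeseries summaries used for within-session
analysis: cumulative records, fixed-width binned rates, and lick
microstructure (burst partitioning of the interlick-interval sequence).
It also implements the phased operant-acquisition state machine
(magazine training -> FR-1/30 s -> FR-1/10 s -> discrimination) with
its revert-on-failure and removal rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, EventValidationError, SchemaError

__all__ = [
    "EVENT_KINDS",
    "EventRecord",
    "SessionSummary",
    "LickCalibration",
    "AcquisitionOutcome",
    "SessionOutcome",
    "ETHANOL_DENSITY_G_PER_ML",
    "read_event_log",
    "compute_intake_gkg",
    "fit_lick_calibration",
    "predict_intake_from_licks",
    "cumulative_record",
    "binned_rate",
    "discrimination_index",
    "lick_microstructure",
    "LickMicrostructure",
    "evaluate_acquisition",
    "summarize_session",
    "debounce_licks",
]

EVENT_KINDS = ("active_poke", "inactive_poke", "lick", "sipper_extend", "sipper_retract")

#: Density of ethanol used to convert consumed volume to grams (g/mL).
ETHANOL_DENSITY_G_PER_ML = 0.789

#: Quinine concentrations (mM) used in the standard punished-session series.
STANDARD_QUININE_MM = (0.0, 0.25, 0.5, 0.75, 1.0)

EPOCHS = (
    "acquisition",
    "pre_binge",
    "binge",
    "phenotyping",
    "extinction",
    "conditioned_reinforcement",
)
CONDITIONS = ("alcohol_only", "alcohol_quinine", "dry", "water_choice")


@dataclass
class EventRecord:
    """One subject-session event stream.

    Times are seconds from session start (0-based floats, millisecond
    precision).  Sipper extend/retract events must strictly alternate,
    beginning with an extend.
    """

    subject_id: str
    session_id: str
    events: list[tuple[float, str]] = field(default_factory=list)
    duration_s: float = 3600.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev = 0.0
        sipper_open = False
        for t, kind in self.events:
            if kind not in EVENT_KINDS:
                raise EventValidationError(
                    f"{self.subject_id}/{self.session_id}: unknown event kind {kind!r}"
                )
            if t < 0 or t > self.duration_s:
                raise EventValidationError(
                    f"{self.subject_id}/{self.session_id}: event at t={t} s outside "
                    f"[0, {self.duration_s}] s"
                )
            if t < prev:
                raise EventValidationError(
                    f"{self.subject_id}/{self.session_id}: events not sorted at t={t}"
                )
            prev = t
            if kind == "sipper_extend":
                if sipper_open:
                    raise EventValidationError(
                        f"{self.subject_id}/{self.session_id}: sipper_extend while open"
                    )
                sipper_open = True
            elif kind == "sipper_retract":
                if not sipper_open:
                    raise EventValidationError(
                        f"{self.subject_id}/{self.session_id}: sipper_retract while closed"
                    )
                sipper_open = False

    def times(self, kind: str) -> np.ndarray:
        """Timestamps (s) of all events of ``kind``, in order."""
        return np.asarray([t for t, k in self.events if k == kind], dtype=float)

    def counts(self) -> dict[str, int]:
        out = dict.fromkeys(EVENT_KINDS, 0)
        for _, k in self.events:
            out[k] += 1
        return out

    def access_windows(self) -> list[tuple[float, float]]:
        """(extend, retract) pairs; an unclosed final window ends at duration."""
        windows: list[tuple[float, float]] = []
        start: float | None = None
        for t, k in self.events:
            if k == "sipper_extend":
                start = t
            elif k == "sipper_retract" and start is not None:
                windows.append((start, t))
                start = None
        if start is not None:
            windows.append((start, self.duration_s))
        return windows


@dataclass
class SessionSummary:
    """Per-session scalar summary used by all downstream analyses."""

    subject_id: str
    session_index: int
    epoch: str
    condition: str
    quinine_mM: float
    consumed_volume_mL: float
    weight_g: float
    intake_gkg: float
    active_responses: int
    inactive_responses: int
    licks: int
    reinforcers: int


@dataclass
class LickCalibration:
    """Linear lick-count -> intake (g/kg) calibration.

    ``slope_se`` is a heteroscedasticity-robust (HC3) standard error:
    session intake is a sum of per-lick volumes, so its variance grows
    with the lick count and the classical homoscedastic OLS standard
    error is anti-conservative.
    """

    slope: float
    intercept: float
    r: float
    n_pairs: int
    slope_se: float = float("nan")

    def slope_ci95(self) -> tuple[float, float]:
        """Robust 95% confidence interval for the slope."""
        half = stats.t.ppf(0.975, self.n_pairs - 2) * self.slope_se
        return (self.slope - half, self.slope + half)


@dataclass
class LickMicrostructure:
    n_licks: int
    n_bursts: int
    mean_burst_size: float
    burst_sizes: np.ndarray
    interlick_intervals: np.ndarray


@dataclass
class SessionOutcome:
    """Inputs to the acquisition state machine for one training session."""

    licks: int
    cap_reached: bool
    discrimination_index: float | None = None


@dataclass
class AcquisitionOutcome:
    phase_trajectory: list[str]
    status: str  # acquired | removed | in_progress
    sessions_to_acquire: int | None
    reverts_used: int


def compute_intake_gkg(
    consumed_volume_mL: float,
    ethanol_vv: float,
    weight_g: float,
    density_g_per_mL: float = ETHANOL_DENSITY_G_PER_ML,
) -> float:
    """Convert consumed solution volume to grams ethanol per kg body weight.

    ``volume (mL) x ethanol fraction (v/v) x density (g/mL) / weight (kg)``.
    """
    if weight_g <= 0:
        raise ValueError(f"weight_g must be positive, got {weight_g}")
    if consumed_volume_mL < 0:
        raise ValueError("consumed_volume_mL must be non-negative")
    if not 0 < ethanol_vv < 1:
        raise ValueError("ethanol_vv must be a fraction in (0, 1)")
    return consumed_volume_mL * ethanol_vv * density_g_per_mL / (weight_g / 1000.0)


def fit_lick_calibration(pairs: Sequence[tuple[float, float]]) -> LickCalibration:
    """Ordinary least-squares fit of intake (g/kg) on lick count.

    Requires at least three pairs and a non-constant lick predictor.
    ``r`` is the Pearson correlation of the pairs.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateFitError("calibration needs >= 3 (licks, intake) pairs")
    licks, intake = arr[:, 0], arr[:, 1]
    if np.ptp(licks) == 0:
        raise DegenerateFitError("lick counts are constant; slope is unidentifiable")
    fit = stats.linregress(licks, intake)
    import statsmodels.api as sm

    robust = sm.OLS(intake, sm.add_constant(licks)).fit(cov_type="HC3")
    return LickCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_pairs=len(arr),
        slope_se=float(robust.bse[1]),
    )


def predict_intake_from_licks(cal: LickCalibration, licks: float) -> float:
    """Predicted g/kg for a lick count, clipped at zero."""
    if licks < 0:
        raise ValueError("licks must be non-negative")
    return max(0.0, cal.slope * licks + cal.intercept)


def cumulative_record(
    times: Sequence[float], duration_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Step series (t, cumulative count) for plotting cumulative records.

    Starts at (0, 0) and is extended to (duration, n) so the record spans
    the whole session.
    """
    t = np.asarray(times, dtype=float)
    if t.size and (np.any(np.diff(t) < 0)):
        raise ValueError("event times must be sorted")
    if t.size and (t[0] < 0 or t[-1] > duration_s):
        raise ValueError("event times outside [0, duration_s]")
    xs = np.concatenate(([0.0], t, [duration_s]))
    ys = np.concatenate(([0.0], np.arange(1, t.size + 1, dtype=float), [float(t.size)]))
    return xs, ys


def binned_rate(
    times: Sequence[float], bin_s: float, duration_s: float
) -> np.ndarray:
    """Event counts in consecutive half-open bins ``[i*bin, (i+1)*bin)``.

    There are ``ceil(duration/bin)`` bins; an event exactly at the session
    end is assigned to the last bin so that counts are conserved.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    t = np.asarray(times, dtype=float)
    n_bins = max(1, math.ceil(duration_s / bin_s))
    if t.size == 0:
        return np.zeros(n_bins, dtype=int)
    if t.min() < 0 or t.max() > duration_s:
        raise ValueError("event times outside [0, duration_s]")
    idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def discrimination_index(active: int, inactive: int) -> float:
    """Active / (active + inactive); NaN when no responses were made.

    The NaN marker is distinct from 0 and is treated as a failed session
    by the acquisition criteria.
    """
    if active < 0 or inactive < 0:
        raise ValueError("response counts must be non-negative")
    total = active + inactive
    if total == 0:
        return float("nan")
    return active / total


def debounce_licks(times: np.ndarray, min_gap_s: float = 0.020) -> np.ndarray:
    """Collapse lick timestamps closer than ``min_gap_s`` (lickometer chatter).

    Keeps the first lick of each chatter run, measured from the last kept lick.
    """
    t = np.asarray(times, dtype=float)
    if t.size <= 1:
        return t.copy()
    keep = [0]
    last = t[0]
    for i in range(1, t.size):
        if t[i] - last >= min_gap_s:
            keep.append(i)
            last = t[i]
    return t[keep]


def lick_microstructure(
    lick_times: Sequence[float], ili_burst_threshold_s: float = 0.5
) -> LickMicrostructure:
    """Partition licks into bursts: maximal runs with gaps <= threshold."""
    if ili_burst_threshold_s <= 0:
        raise ValueError("ili_burst_threshold_s must be positive")
    t = np.asarray(lick_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("lick times must be sorted")
    if t.size == 0:
        return LickMicrostructure(0, 0, float("nan"), np.array([], dtype=int), np.array([]))
    ili = np.diff(t)
    breaks = np.flatnonzero(ili > ili_burst_threshold_s)
    sizes = np.diff(np.concatenate(([0], breaks + 1, [t.size])))
    return LickMicrostructure(
        n_licks=int(t.size),
        n_bursts=int(sizes.size),
        mean_burst_size=float(sizes.mean()),
        burst_sizes=sizes.astype(int),
        interlick_intervals=ili,
    )


# --------------------------------------------------------------------------
# Acquisition state machine
# --------------------------------------------------------------------------

ACQUISITION_PHASES = ("magazine", "criteria1", "criteria2", "discrimination")
_DI_CRITERION = 0.70
_CONSECUTIVE_SUCCESSES = 2
_CONSECUTIVE_FAILURES = 3
_MAX_REVERTS = 3


def _session_meets_criteria(phase: str, outcome: SessionOutcome) -> bool:
    if phase == "discrimination":
        di = outcome.discrimination_index
        di_ok = di is not None and not math.isnan(di) and di >= _DI_CRITERION
        return di_ok and outcome.cap_reached
    return outcome.cap_reached


def evaluate_acquisition(session_outcomes: Iterable[SessionOutcome]) -> AcquisitionOutcome:
    """Run the phased acquisition protocol over chronological session outcomes.

    Phases advance in the fixed order magazine -> criteria1 -> criteria2 ->
    discrimination.  Magazine training advances after the lick cap is reached
    once; criteria1/criteria2 after the cap is reached on two consecutive
    days; discrimination is acquired after two consecutive sessions with
    discrimination index >= 0.70 and the cap reached.  Three consecutive
    failing sessions revert the animal one phase (consecutive-success windows
    reset on revert); three reverts in total remove the animal.  Magazine
    training has no previous phase, so failures there do not accrue reverts.
    """
    phase_i = 0
    consec_ok = 0
    consec_fail = 0
    reverts = 0
    trajectory: list[str] = []
    n_sessions = 0

    for outcome in session_outcomes:
        phase = ACQUISITION_PHASES[phase_i]
        trajectory.append(phase)
        n_sessions += 1
        if _session_meets_criteria(phase, outcome):
            consec_fail = 0
            consec_ok += 1
            needed = 1 if phase == "magazine" else _CONSECUTIVE_SUCCESSES
            if consec_ok >= needed:
                if phase == "discrimination":
                    return AcquisitionOutcome(trajectory, "acquired", n_sessions, reverts)
                phase_i += 1
                consec_ok = 0
        else:
            consec_ok = 0
            consec_fail += 1
            if consec_fail >= _CONSECUTIVE_FAILURES:
                consec_fail = 0
                if phase_i > 0:
                    phase_i -= 1
                    reverts += 1
                    if reverts >= _MAX_REVERTS:
                        return AcquisitionOutcome(trajectory, "removed", None, reverts)
    return AcquisitionOutcome(trajectory, "in_progress", None, reverts)


# --------------------------------------------------------------------------
# I/O and session summarization
# --------------------------------------------------------------------------

_REQUIRED_LOG_COLUMNS = ("subject", "session", "time_s", "kind")


def read_event_log(
    source,
    delimiter: str = ",",
    duration_s: float = 3600.0,
    debounce_ms: float | None = 20.0,
) -> list[EventRecord]:
    """Parse a long-format delimited event log into validated records.

    The log must carry a header with columns ``subject, session, time_s,
    kind`` (an ``epoch`` column is tolerated and ignored here).  Rows with
    unparsable times or unknown event kinds are skipped with a warning that
    names their line numbers.  Lick chatter closer than ``debounce_ms`` is
    collapsed; pass ``None`` to disable (e.g. for simulated logs).
    """
    df = pd.read_csv(source, sep=delimiter, dtype=str)
    missing = [c for c in _REQUIRED_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event log missing required columns: {missing}")

    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() | ~df["kind"].isin(EVENT_KINDS)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(
            f"skipped {bad.sum()} malformed event-log rows at lines {lines}",
            stacklevel=2,
        )
        df = df[~bad]
        times = times[~bad]

    records: list[EventRecord] = []
    df = df.assign(_t=times.astype(float))
    for (subject, session), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("_t", kind="stable")
        events = list(zip(grp["_t"].tolist(), grp["kind"].tolist()))
        if debounce_ms is not None:
            min_gap = debounce_ms / 1000.0
            filtered: list[tuple[float, str]] = []
            last_lick: float | None = None
            for t, k in events:
                if k == "lick":
                    if last_lick is not None and t - last_lick < min_gap:
                        continue
                    last_lick = t
                filtered.append((t, k))
            events = filtered
        records.append(
            EventRecord(
                subject_id=str(subject),
                session_id=str(session),
                events=events,
                duration_s=duration_s,
            )
        )
    return records


def summarize_session(
    rec: EventRecord,
    *,
    epoch: str,
    condition: str,
    session_index: int,
    consumed_volume_mL: float,
    weight_g: float,
    quinine_mM: float = 0.0,
    ethanol_vv: float = 0.15,
) -> SessionSummary:
    """Aggregate an event stream into the per-session scalar summary.

    Reinforcers are counted as sipper presentations.  Dry (conditioned
    reinforcement) and water-only sessions have zero alcohol intake by
    definition, whatever volume was recorded.
    """
    counts = rec.counts()
    if condition in ("alcohol_only", "alcohol_quinine"):
        intake = compute_intake_gkg(consumed_volume_mL, ethanol_vv, weight_g)
    else:
        intake = 0.0
    return SessionSummary(
        subject_id=rec.subject_id,
        session_index=session_index,
        epoch=epoch,
        condition=condition,
        quinine_mM=quinine_mM,
        consumed_volume_mL=consumed_volume_mL,
        weight_g=weight_g,
        intake_gkg=intake,
        active_responses=counts["active_poke"],
        inactive_responses=counts["inactive_poke"],
        licks=counts["lick"],
        reinforcers=counts["sipper_extend"],
    )
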