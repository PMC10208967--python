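"""Synthetic operant-drinking cohorts with known latent phenotypes.

The generator emulates the behavioral structure the phenotyping analysis
assumes: a cohort of mice run through fixed-ratio (FR 10) operant
alcohol self-administration with timed (10 s) sipper-access windows,
lick-by-lick consumption, a pre-binge epoch with limited between-subject
variance, a two-bottle-choice binge epoch, and a post-binge phenotyping
epoch where individual differences widen.  Each subject carries a latent
phenotype (Low / High / Compulsive Drinker) that shapes its post-binge
intake propensity and its sensitivity to quinine adulteration:
Compulsive subjects retain most of their intake at every tested quinine
concentration, while Low and High subjects are strongly suppressed.

Every session can be rendered either as a full millisecond-resolution
event stream (pokes, sipper extensions, individual licks with per-lick
volumes) or, for speed, as session-level summaries drawn from the same
latent intake model.  One root seed fully determines the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .events import (
    ETHANOL_DENSITY_G_PER_ML,
    EventRecord,
    SessionSummary,
    compute_intake_gkg,
    summarize_session,
)
from .phenotype import LABELS, IntakeTable, PreferenceResult, preference_ratio

__all__ = [
    "CohortConfig",
    "SessionSchedule",
    "LatentSubject",
    "SimulatedCohort",
    "ANALYTES",
    "REGIONS",
    "simulate_subject",
    "simulate_session",
    "simulate_two_bottle",
    "simulate_cohort",
]

#: Analyte panel quantified per brain region (amines, amino acids, metabolites).
ANALYTES = (
    "dopamine", "DOPAC", "HVA", "3-MT", "5-HT", "5-HIAA", "norepinephrine",
    "epinephrine", "glutamate", "glutamine", "GABA", "glycine",
    "aspartic acid", "serine", "taurine", "alanine", "histamine", "choline",
    "acetylcholine", "tyrosine", "tryptophan", "kynurenine", "adenosine",
)
REGIONS = ("mPFC", "dPAG")

# which (region, analyte) cells are coupled to which behavior metric
_COUPLED: dict[tuple[str, str], str] = {
    ("mPFC", "5-HT"): "alcohol",
    ("mPFC", "5-HIAA"): "alcohol",
    ("mPFC", "DOPAC"): "alcohol",
    ("dPAG", "5-HT"): "alcohol",
    ("dPAG", "5-HIAA"): "alcohol",
    ("dPAG", "dopamine"): "alcohol",
    ("dPAG", "DOPAC"): "alcohol",
    ("dPAG", "GABA"): "quinine",
    ("dPAG", "glutamate"): "quinine",
    ("dPAG", "glutamine"): "quinine",
    ("dPAG", "aspartic acid"): "quinine",
}


@dataclass
class SessionSchedule:
    """Operant schedule for one session type."""

    ratio: int = 10  # FR requirement (eligible active pokes per reinforcer)
    access_s: float = 10.0  # sipper extension per reinforcer
    duration_s: float = 3600.0
    lick_cap: int | None = None  # acquisition sessions terminate at 100 licks


@dataclass
class CohortConfig:
    """Parameterization of the synthetic cohort.

    Defaults mirror the reference study design: 41 subjects at Low/High/
    Compulsive proportions 19:5:17, one-hour FR-10 sessions with 10 s
    access, 15% (v/v) ethanol, pre-binge intake drawn from a common
    narrow distribution, and phenotype-dependent post-binge amplification
    and quinine-retention curves (Compulsive flattest).
    """

    n_subjects: int = 41
    phenotype_proportions: tuple[float, float, float] = (19 / 41, 5 / 41, 17 / 41)
    seed: int = 0
    sex: str = "male"
    weight_mean_g: float = 28.0
    weight_sd_g: float = 2.5
    ethanol_vv: float = 0.15
    schedule: SessionSchedule = field(default_factory=SessionSchedule)
    # latent intake model (g/kg per one-hour session)
    pre_binge_mean_gkg: float = 1.0
    pre_binge_sd_gkg: float = 0.10
    post_binge_mean_gkg: dict[str, float] = field(
        default_factory=lambda: {"Low": 0.9, "High": 1.9, "Compulsive": 1.9}
    )
    post_binge_sd_gkg: dict[str, float] = field(
        default_factory=lambda: {"Low": 0.18, "High": 0.25, "Compulsive": 0.25}
    )
    # quinine retention: fraction of intake kept at concentration c (mM),
    # retention(c) = floor + (1 - floor) / (1 + exp(slope * (c - c50)))
    quinine_retention: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Low": (0.08, 0.35, 8.0),  # (floor, c50 mM, slope /mM)
            "High": (0.08, 0.40, 8.0),
            "Compulsive": (0.80, 0.50, 3.0),
        }
    )
    quinine_sensitivity_sd: float = 0.10  # subject-level jitter on suppression depth
    session_noise_cv: float = 0.12  # multiplicative session-to-session noise
    quinine_concentrations_mM: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    n_alcohol_sessions: int = 3
    n_quinine_sessions: int = 4
    # event-level processes
    lick_volume_uL: float = 1.5
    lick_volume_cv: float = 0.20
    licks_per_window: float = 40.0  # planning value for poke-rate targeting
    inactive_rate_per_min: float = 0.3
    seek_rate_per_min: float = 1.2  # active-poke rate with no consumption drive
    # two-bottle choice epoch
    binge_rate_mL_per_h: float = 0.6
    binge_total_cv: float = 0.2
    binge_preference_ab: tuple[float, float] = (14.0, 4.0)
    # analyte table
    n_analyte_subjects: int = 15
    analyte_coupling: float = 0.8
    analyte_noise_sd: float = 0.4


@dataclass
class LatentSubject:
    """Ground-truth traits of one simulated subject."""

    subject_id: str
    true_phenotype: str
    weight_g: float
    pre_binge_gkg: float
    post_binge_gkg: float
    retention_floor: float
    retention_c50: float
    retention_slope: float
    vigor: float

    def retention(self, quinine_mM: float) -> float:
        """Fraction of unpunished intake retained at a quinine concentration."""
        f, c50, k = self.retention_floor, self.retention_c50, self.retention_slope
        return f + (1.0 - f) / (1.0 + np.exp(k * (quinine_mM - c50)))


def simulate_subject(
    cfg: CohortConfig, rng: np.random.Generator, subject_id: str = "s000"
) -> LatentSubject:
    """Draw one subject's latent traits from the cohort configuration."""
    p = np.asarray(cfg.phenotype_proportions, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("phenotype_proportions must sum to 1")
    phenotype = LABELS[rng.choice(3, p=p)]
    weight = float(np.clip(rng.normal(cfg.weight_mean_g, cfg.weight_sd_g), 18.0, 40.0))
    pre = float(max(0.2, rng.normal(cfg.pre_binge_mean_gkg, cfg.pre_binge_sd_gkg)))
    post = float(
        max(0.1, rng.normal(cfg.post_binge_mean_gkg[phenotype], cfg.post_binge_sd_gkg[phenotype]))
    )
    floor, c50, slope = cfg.quinine_retention[phenotype]
    # subject-level jitter scales the suppression depth (1 - retention) so the
    # phenotype ordering of the curves is preserved at the tested concentrations
    sens = float(np.clip(rng.normal(1.0, cfg.quinine_sensitivity_sd), 0.7, 1.3))
    floor_eff = float(np.clip(1.0 - sens * (1.0 - floor), 0.01, 0.99))
    vigor = float(np.clip(rng.lognormal(0.0, 0.25), 0.4, 2.5))
    return LatentSubject(
        subject_id=subject_id,
        true_phenotype=phenotype,
        weight_g=weight,
        pre_binge_gkg=pre,
        post_binge_gkg=post,
        retention_floor=floor_eff,
        retention_c50=c50,
        retention_slope=slope,
        vigor=vigor,
    )


def _target_intake_gkg(
    subj: LatentSubject,
    epoch: str,
    condition: str,
    quinine_mM: float,
    rng: np.random.Generator,
    cfg: CohortConfig,
) -> float:
    """Latent session intake: propensity x quinine retention x session noise."""
    if condition in ("dry", "water_choice"):
        return 0.0
    base = subj.pre_binge_gkg if epoch in ("acquisition", "pre_binge") else subj.post_binge_gkg
    if condition == "alcohol_quinine":
        base *= subj.retention(quinine_mM)
    noise = rng.lognormal(0.0, cfg.session_noise_cv)
    return float(base * noise)


def _generate_window_licks(
    start: float,
    end: float,
    budget: int,
    rng: np.random.Generator,
) -> list[float]:
    """Burst-structured lick times inside one access window."""
    times: list[float] = []
    t = start + 0.1 + rng.exponential(0.3)
    while t < end and len(times) < budget:
        burst = 1 + rng.poisson(10)
        for _ in range(burst):
            if t >= end or len(times) >= budget:
                break
            times.append(t)
            t += max(0.05, rng.normal(0.12, 0.03))
        t += 0.3 + rng.exponential(0.8)
    return times


def simulate_session(
    subj: LatentSubject,
    schedule: SessionSchedule,
    condition: str,
    quinine_mM: float,
    rng: np.random.Generator,
    *,
    epoch: str = "phenotyping",
    session_index: int = 1,
    cfg: CohortConfig | None = None,
) -> tuple[EventRecord, SessionSummary]:
    """Render one full event-level session for a latent subject.

    Active and inactive pokes are Poisson processes (rates scaled by the
    subject's drive and vigor); every ``ratio``-th active poke made outside
    an open access window extends the sipper for ``access_s``; licks occur
    only inside windows, in bursts, each carrying an independent per-lick
    volume; the subject stops licking when its latent volume target is
    consumed.  Sessions terminate at ``duration_s`` or when cumulative
    licks reach ``lick_cap``, whichever comes first.
    """
    cfg = cfg or CohortConfig()
    duration = schedule.duration_s
    target_gkg = _target_intake_gkg(subj, epoch, condition, quinine_mM, rng, cfg)
    weight_today = float(subj.weight_g * (1.0 + rng.normal(0.0, 0.01)))
    mean_lick_mL = cfg.lick_volume_uL / 1000.0
    if target_gkg > 0:
        target_mL = target_gkg * (weight_today / 1000.0) / (
            cfg.ethanol_vv * ETHANOL_DENSITY_G_PER_ML
        )
        budget = max(1, int(round(target_mL / mean_lick_mL)))
    else:
        budget = 0

    # poke rate targeted to earn enough access windows for the lick budget
    windows_needed = int(np.ceil(budget / cfg.licks_per_window)) if budget else 0
    drive_rate = windows_needed * 1.3 * schedule.ratio / duration  # per second
    seek_rate = cfg.seek_rate_per_min / 60.0 * subj.vigor
    active_rate = max(drive_rate, seek_rate)

    n_active = rng.poisson(active_rate * duration)
    active_t = np.sort(rng.uniform(0.0, duration, n_active))
    inactive_rate = cfg.inactive_rate_per_min / 60.0 * np.sqrt(subj.vigor)
    inactive_t = np.sort(rng.uniform(0.0, duration, rng.poisson(inactive_rate * duration)))

    events: list[tuple[float, str, int]] = [(float(t), "inactive_poke", 0) for t in inactive_t]
    lick_volumes: list[float] = []
    eligible = 0
    window_end = -1.0
    remaining = budget
    total_licks = 0
    cap = schedule.lick_cap
    cap_time: float | None = None

    for t in active_t:
        t = float(t)
        if cap_time is not None and t > cap_time:
            break
        events.append((t, "active_poke", 0))
        if t <= window_end + 1e-3:  # poke during access: logged, not ratio-eligible
            continue
        eligible += 1
        if eligible % schedule.ratio == 0:
            w_start, w_end = t, min(t + schedule.access_s, duration)
            events.append((w_start, "sipper_extend", 1))
            if condition in ("dry", "water_choice"):
                lick_budget_here = 0
            else:
                lick_budget_here = remaining
                if cap is not None:
                    lick_budget_here = min(lick_budget_here, cap - total_licks)
            licks = _generate_window_licks(w_start, w_end, lick_budget_here, rng)
            for lt in licks:
                events.append((float(lt), "lick", 2))
                vol = max(0.2e-3, rng.normal(mean_lick_mL, cfg.lick_volume_cv * mean_lick_mL))
                lick_volumes.append(vol)
            total_licks += len(licks)
            remaining = max(0, remaining - len(licks))
            if cap is not None and total_licks >= cap:
                cap_time = licks[-1] if licks else w_start
                events.append((float(cap_time), "sipper_retract", 3))
                window_end = cap_time
                break
            events.append((w_end, "sipper_retract", 3))
            window_end = w_end

    end_time = duration if cap_time is None else float(np.ceil(cap_time * 1000.0) / 1000.0)
    # millisecond timestamps; drop anything recorded past a cap-triggered end
    final = sorted(
        ((round(t, 3), kind, pri) for t, kind, pri in events if t <= end_time),
        key=lambda e: (e[0], e[2]),
    )
    rec = EventRecord(
        subject_id=subj.subject_id,
        session_id=f"{epoch}_{session_index:02d}",
        events=[(t, kind) for t, kind, _ in final],
        duration_s=end_time,
    )
    consumed = float(sum(lick_volumes)) if condition in ("alcohol_only", "alcohol_quinine") else 0.0
    summary = summarize_session(
        rec,
        epoch=epoch,
        condition=condition,
        session_index=session_index,
        consumed_volume_mL=consumed,
        weight_g=weight_today,
        quinine_mM=quinine_mM,
        ethanol_vv=cfg.ethanol_vv,
    )
    return rec, summary


def simulate_two_bottle(
    subj: LatentSubject,
    access_h: float,
    rng: np.random.Generator,
    cfg: CohortConfig | None = None,
) -> PreferenceResult:
    """One two-bottle-choice access period (alcohol vs water).

    Total fluid intake is linear in access time and, by construction,
    independent of phenotype; preference for alcohol is high (Beta-
    distributed around ~0.78).
    """
    cfg = cfg or CohortConfig()
    if access_h < 0:
        raise ValueError("access_h must be non-negative")
    if access_h == 0:
        return PreferenceResult(subj.subject_id, 0.0, 0.0, float("nan"), 0.0)
    total = access_h * cfg.binge_rate_mL_per_h * rng.lognormal(0.0, cfg.binge_total_cv)
    pref = rng.beta(*cfg.binge_preference_ab)
    alcohol_mL = total * pref
    water_mL = total * (1.0 - pref)
    intake = compute_intake_gkg(alcohol_mL, cfg.ethanol_vv, subj.weight_g)
    return PreferenceResult(
        subj.subject_id, alcohol_mL, water_mL, preference_ratio(alcohol_mL, water_mL), intake
    )


def _summary_without_events(
    subj: LatentSubject,
    schedule: SessionSchedule,
    condition: str,
    quinine_mM: float,
    rng: np.random.Generator,
    epoch: str,
    session_index: int,
    cfg: CohortConfig,
) -> SessionSummary:
    """Session summary drawn from the same latent intake model, no events.

    Counts are plausible but approximate (licks from volume / mean lick
    volume); intake follows the identical latent target distribution as
    the event-level path, so phenotyping behaves the same.
    """
    target_gkg = _target_intake_gkg(subj, epoch, condition, quinine_mM, rng, cfg)
    weight_today = float(subj.weight_g * (1.0 + rng.normal(0.0, 0.01)))
    mean_lick_mL = cfg.lick_volume_uL / 1000.0
    if target_gkg > 0:
        volume = target_gkg * (weight_today / 1000.0) / (
            cfg.ethanol_vv * ETHANOL_DENSITY_G_PER_ML
        )
        licks = max(1, int(round(volume / mean_lick_mL)))
    else:
        volume, licks = 0.0, 0
    reinforcers = int(np.ceil(licks / cfg.licks_per_window)) if licks else max(
        1, rng.poisson(2)
    )
    active = reinforcers * schedule.ratio + rng.poisson(5)
    inactive = rng.poisson(cfg.inactive_rate_per_min * schedule.duration_s / 60.0)
    intake = (
        compute_intake_gkg(volume, cfg.ethanol_vv, weight_today)
        if condition in ("alcohol_only", "alcohol_quinine")
        else 0.0
    )
    return SessionSummary(
        subject_id=subj.subject_id,
        session_index=session_index,
        epoch=epoch,
        condition=condition,
        quinine_mM=quinine_mM,
        consumed_volume_mL=volume,
        weight_g=weight_today,
        intake_gkg=intake,
        active_responses=int(active),
        inactive_responses=int(inactive),
        licks=int(licks),
        reinforcers=int(reinforcers),
    )


@dataclass
class SimulatedCohort:
    """Full synthetic dataset plus the latent ground truth that produced it."""

    config: CohortConfig
    subjects: list[LatentSubject]
    sessions: pd.DataFrame
    preference: pd.DataFrame
    events: list[EventRecord] | None = None
    analytes: pd.DataFrame | None = None

    @property
    def truth(self) -> dict[str, str]:
        return {s.subject_id: s.true_phenotype for s in self.subjects}

    def intake_table(self, epoch: str = "phenotyping") -> IntakeTable:
        return IntakeTable.from_sessions(self.sessions, epoch=epoch)

    def events_frame(self) -> pd.DataFrame:
        if self.events is None:
            raise ValueError("cohort was simulated without event-level data")
        rows = [
            (r.subject_id, r.session_id, t, kind)
            for r in self.events
            for t, kind in r.events
        ]
        return pd.DataFrame(rows, columns=["subject", "session", "time_s", "kind"])

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sessions.to_csv(out / "sessions.csv", index=False)
        self.preference.to_csv(out / "preference.csv", index=False)
        if self.events is not None:
            self.events_frame().to_csv(out / "events.csv", index=False)
        if self.analytes is not None:
            self.analytes.to_csv(out / "analytes.csv", index=False)
        truth = {
            "phenotypes": self.truth,
            "latents": [asdict(s) for s in self.subjects],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _phenotyping_like_epoch(
    name: str,
    subjects: list[LatentSubject],
    cfg: CohortConfig,
    seed_seq_key: int,
    include_events: bool,
) -> tuple[list[EventRecord], list[SessionSummary]]:
    """3 alcohol-only + 4 graded-quinine one-hour FR sessions per subject."""
    records: list[EventRecord] = []
    summaries: list[SessionSummary] = []
    conditions = [("alcohol_only", 0.0)] * cfg.n_alcohol_sessions + [
        ("alcohol_quinine", c) for c in cfg.quinine_concentrations_mM[: cfg.n_quinine_sessions]
    ]
    for i, subj in enumerate(subjects):
        for s_idx, (condition, quinine) in enumerate(conditions, start=1):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(seed_seq_key, i, s_idx))
            )
            if include_events:
                rec, summ = simulate_session(
                    subj,
                    cfg.schedule,
                    condition,
                    quinine,
                    rng,
                    epoch=name,
                    session_index=s_idx,
                    cfg=cfg,
                )
                records.append(rec)
            else:
                summ = _summary_without_events(
                    subj, cfg.schedule, condition, quinine, rng, name, s_idx, cfg
                )
            summaries.append(summ)
    return records, summaries


def simulate_cohort(
    cfg: CohortConfig | None = None,
    include_events: bool = True,
    include_analytes: bool = True,
) -> SimulatedCohort:
    """Simulate the full study: pre-binge, binge, and phenotyping epochs.

    ``include_events=False`` skips the event-level rendering (the session
    summaries then come straight from the latent intake model), which is
    much faster and sufficient for phenotyping/stability experiments.
    """
    cfg = cfg or CohortConfig()
    width = max(3, len(str(cfg.n_subjects)))
    subjects = [
        simulate_subject(
            cfg,
            np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0, i))),
            subject_id=f"m{i:0{width}d}",
        )
        for i in range(cfg.n_subjects)
    ]

    all_events: list[EventRecord] = []
    all_summaries: list[SessionSummary] = []
    for key, epoch in ((1, "pre_binge"), (2, "phenotyping")):
        recs, summs = _phenotyping_like_epoch(epoch, subjects, cfg, key, include_events)
        all_events.extend(recs)
        all_summaries.extend(summs)

    # binge epoch: two weekly cycles of 2,2,2,2,4,0,0 hours of two-bottle access
    week = (2.0, 2.0, 2.0, 2.0, 4.0, 0.0, 0.0)
    pref_rows = []
    for i, subj in enumerate(subjects):
        for day, access_h in enumerate([*week, *week], start=1):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(3, i, day))
            )
            res = simulate_two_bottle(subj, access_h, rng, cfg)
            pref_rows.append(
                (
                    subj.subject_id,
                    day,
                    access_h,
                    res.alcohol_volume_mL,
                    res.water_volume_mL,
                    res.preference,
                    res.intake_gkg,
                )
            )
    preference = pd.DataFrame(
        pref_rows,
        columns=[
            "subject_id",
            "day",
            "access_h",
            "alcohol_volume_mL",
            "water_volume_mL",
            "preference",
            "intake_gkg",
        ],
    )

    sessions = pd.DataFrame([asdict(s) for s in all_summaries])
    analytes = _simulate_analytes(subjects, cfg) if include_analytes else None
    return SimulatedCohort(
        config=cfg,
        subjects=subjects,
        sessions=sessions,
        preference=preference,
        events=all_events if include_events else None,
        analytes=analytes,
    )


def _simulate_analytes(subjects: list[LatentSubject], cfg: CohortConfig) -> pd.DataFrame:
    """Protein-normalized analyte concentrations with monotone behavior coupling.

    Coupled cells (e.g. dPAG GABA/glutamate vs punished intake) carry a
    log-linear dependence on the subject's standardized latent drive with
    strength ``cfg.analyte_coupling``; coupling 0 yields a pure null table.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(4,)))
    n = min(cfg.n_analyte_subjects, len(subjects))
    chosen_idx = sorted(rng.choice(len(subjects), size=n, replace=False))
    chosen = [subjects[i] for i in chosen_idx]

    alc = np.array([s.post_binge_gkg for s in chosen])
    mean_ret = np.array(
        [np.mean([s.retention(c) for c in cfg.quinine_concentrations_mM]) for s in chosen]
    )
    quin = alc * mean_ret

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_by_metric = {"alcohol": z(alc), "quinine": z(quin)}
    rows = []
    for region in REGIONS:
        for a_idx, analyte in enumerate(ANALYTES):
            base = 10.0 ** (1.0 + (a_idx % 5) * 0.4)  # ng per mg protein, panel-typical spread
            metric = _COUPLED.get((region, analyte))
            zz = cfg.analyte_coupling * z_by_metric[metric] if metric else 0.0
            conc = base * np.exp(zz + rng.normal(0.0, cfg.analyte_noise_sd, size=n))
            for subj, c in zip(chosen, conc):
                rows.append((subj.subject_id, region, analyte, float(c)))
    return pd.DataFrame(rows, columns=["subject_id", "region", "analyte", "concentration"])
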