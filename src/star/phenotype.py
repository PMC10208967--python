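"""Low/High/Compulsive drinker phenotyping from group-normalized intake.

Two values are computed per subject and expressed as a percent of the
cohort mean: normalized intake over the alcohol-only sessions
(sessions 1-3 of the phenotyping epoch) and over the quinine-adulterated
sessions (sessions 4-7).  Classification thresholds sit at 100% of the
cohort mean:

* Compulsive Drinker  — alcohol+quinine > 100% (punishment-resistant intake)
* High Drinker        — alcohol > 100% and alcohol+quinine < 100%
* Low Drinker         — both below 100%

Both published rules use strict inequalities, so a score of exactly 100
is unassigned by a literal reading; here ties resolve downward (100 is
"not above average"), which keeps the label partition exhaustive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, SchemaError

__all__ = [
    "IntakeTable",
    "PhenotypeResult",
    "PreferenceResult",
    "LABELS",
    "normalize_scores",
    "classify_subject",
    "phenotype_cohort",
    "preference_ratio",
    "RECOMMENDED_MIN_N",
]

#: Phenotype labels, indexed by the integer codes used internally.
LABELS = ("Low", "High", "Compulsive")

#: Recommended minimum cohort size for stable phenotype assignment.
RECOMMENDED_MIN_N = 15


@dataclass
class IntakeTable:
    """Per-subject intake (g/kg) for the phenotyping session series.

    ``alcohol`` maps subject -> intakes over the alcohol-only sessions,
    ``quinine`` maps subject -> intakes over the alcohol+quinine sessions.
    Subjects missing either condition entirely are dropped with a warning
    when constructed via :meth:`from_sessions`.
    """

    alcohol: dict[str, np.ndarray] = field(default_factory=dict)
    quinine: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alcohol = {s: np.atleast_1d(np.asarray(v, float)) for s, v in self.alcohol.items()}
        self.quinine = {s: np.atleast_1d(np.asarray(v, float)) for s, v in self.quinine.items()}
        if set(self.alcohol) != set(self.quinine):
            raise SchemaError("alcohol and quinine tables must cover the same subjects")
        for name, d in (("alcohol", self.alcohol), ("quinine", self.quinine)):
            for s, v in d.items():
                if v.size == 0:
                    raise SchemaError(f"subject {s} has no {name} sessions")
                if np.any(v < 0) or np.any(~np.isfinite(v)):
                    raise SchemaError(f"subject {s} has invalid {name} intakes")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.alcohol)

    def __len__(self) -> int:
        return len(self.alcohol)

    def subject_means(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Subject IDs with per-subject mean intake in each condition."""
        subs = self.subjects
        a = np.array([self.alcohol[s].mean() for s in subs])
        q = np.array([self.quinine[s].mean() for s in subs])
        return subs, a, q

    def subset(self, subjects: Sequence[str]) -> "IntakeTable":
        return IntakeTable(
            alcohol={s: self.alcohol[s] for s in subjects},
            quinine={s: self.quinine[s] for s in subjects},
        )

    @classmethod
    def from_sessions(cls, summaries: pd.DataFrame, epoch: str = "phenotyping") -> "IntakeTable":
        """Build from a session-summary table (one row per subject-session).

        Sessions are mapped to conditions by the ``condition`` column, not by
        position, so truncated or non-standard designs reuse the same machinery.
        """
        required = {"subject_id", "epoch", "condition", "intake_gkg"}
        missing = required - set(summaries.columns)
        if missing:
            raise SchemaError(f"session summary table missing columns: {sorted(missing)}")
        df = summaries[summaries["epoch"] == epoch]
        alcohol: dict[str, np.ndarray] = {}
        quinine: dict[str, np.ndarray] = {}
        dropped = []
        for subject, grp in df.groupby("subject_id"):
            a = grp.loc[grp["condition"] == "alcohol_only", "intake_gkg"].to_numpy()
            q = grp.loc[grp["condition"] == "alcohol_quinine", "intake_gkg"].to_numpy()
            if a.size == 0 or q.size == 0:
                dropped.append(str(subject))
                continue
            alcohol[str(subject)] = a
            quinine[str(subject)] = q
        if dropped:
            warnings.warn(
                f"excluded {len(dropped)} subject(s) missing a condition: {dropped}",
                stacklevel=2,
            )
        return cls(alcohol=alcohol, quinine=quinine)


@dataclass
class PhenotypeResult:
    subject_id: str
    alcohol_pct: float
    quinine_pct: float
    label: str


@dataclass
class PreferenceResult:
    subject_id: str
    alcohol_volume_mL: float
    water_volume_mL: float
    preference: float
    intake_gkg: float


def _pct_of_mean(values: np.ndarray) -> np.ndarray:
    m = values.mean()
    if m <= 0:
        raise DegenerateCohortError("cohort mean intake is zero; normalization undefined")
    return values / m * 100.0


def normalize_scores(table: IntakeTable) -> pd.DataFrame:
    """Percent-of-cohort-mean scores for each subject and condition.

    Each subject's per-condition mean is divided by the mean of those
    subject means across the cohort, times 100; each score column
    therefore averages exactly 100 across subjects.
    """
    if len(table) < 2:
        raise DegenerateCohortError("normalization needs at least 2 subjects")
    subs, a, q = table.subject_means()
    return pd.DataFrame(
        {
            "subject_id": subs,
            "alcohol_pct": _pct_of_mean(a),
            "quinine_pct": _pct_of_mean(q),
        }
    )


def label_codes(alcohol_pct: np.ndarray, quinine_pct: np.ndarray) -> np.ndarray:
    """Vectorized classification to integer codes (0=Low, 1=High, 2=Compulsive).

    Compulsive is checked first: the punished-intake rule carries no
    alcohol-score condition.  Scores of exactly 100 fall to the less
    severe branch.
    """
    a = np.asarray(alcohol_pct, float)
    q = np.asarray(quinine_pct, float)
    if np.any(a < 0) or np.any(q < 0) or np.any(~np.isfinite(a)) or np.any(~np.isfinite(q)):
        raise ValueError("scores must be finite and non-negative")
    codes = np.zeros(a.shape, dtype=np.int8)
    codes[a > 100.0] = 1
    codes[q > 100.0] = 2
    return codes


def classify_subject(alcohol_pct: float, quinine_pct: float) -> str:
    """Phenotype label for one subject's normalized scores."""
    return LABELS[int(label_codes(np.array([alcohol_pct]), np.array([quinine_pct]))[0])]


def phenotype_cohort(table: IntakeTable, min_n: int = RECOMMENDED_MIN_N) -> pd.DataFrame:
    """Normalize and classify every subject in the cohort.

    Returns a frame with columns ``subject_id, alcohol_pct, quinine_pct,
    label`` plus the recommended scatter coordinates (``x`` = quinine_pct,
    ``y`` = alcohol_pct).  Cohorts smaller than ``min_n`` trigger a warning:
    group normalization is unstable at small n.
    """
    if len(table) < min_n:
        warnings.warn(
            f"cohort size {len(table)} is below the recommended minimum of "
            f"{min_n} subjects; phenotype assignments may be unstable",
            stacklevel=2,
        )
    scores = normalize_scores(table)
    codes = label_codes(scores["alcohol_pct"].to_numpy(), scores["quinine_pct"].to_numpy())
    scores["label"] = [LABELS[c] for c in codes]
    scores["x"] = scores["quinine_pct"]
    scores["y"] = scores["alcohol_pct"]
    return scores


def preference_ratio(alcohol_mL: float, water_mL: float) -> float:
    """Two-bottle alcohol preference: alcohol / (alcohol + water).

    NaN when nothing was consumed from either bottle.
    """
    if alcohol_mL < 0 or water_mL < 0:
        raise ValueError("volumes must be non-negative")
    total = alcohol_mL + water_mL
    if total == 0:
        return float("nan")
    return alcohol_mL / total
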