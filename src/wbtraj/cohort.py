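"""Longitudinal cohort data model, CSV I/O, inclusion filtering and
missing-data views.

The cohort holds per-participant assessment records of life satisfaction
(LS, Satisfaction with Life sum, 5-35), affect balance (AB, PANAS positive
minus negative sum, -40..40) and depression symptoms (CES-D sum, 0-60),
plus weekly usage records (days-per-week of exercise use and an adherence
indicator).  Day 0 is each participant's own pretest; all days are
non-negative integers relative to it.

Missing values are empty CSV cells; no imputation is performed anywhere —
each analysis builds its own complete-case (pairwise-deletion) view.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCORE_RANGES",
    "CESD_CUTOFF",
    "StudyDesign",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "ConfigError",
    "default_designs",
    "load_designs",
    "read_cohort",
    "write_cohort",
    "eligibility_filter",
    "flag_depression",
    "pairwise_view",
]

#: legal closed score ranges for each outcome (scale-sum construction)
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "ls": (5.0, 35.0),
    "ab": (-40.0, 40.0),
    "cesd": (0.0, 60.0),
}

#: preclinical criterion for elevated depression risk on the CES-D
CESD_CUTOFF: int = 16

ASSESSMENT_COLUMNS = ["participant_id", "sample_id", "day", "ls", "ab", "cesd"]
USAGE_COLUMNS = ["participant_id", "sample_id", "day", "n_assigned", "freq_sum", "adhered"]


class CohortFormatError(ValueError):
    """A CSV file does not have the expected header/structure."""


class CohortValidationError(ValueError):
    """A record violates a score range or uniqueness invariant."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class StudyDesign:
    """Planned assessment schedule for one study sample.

    Parameters
    ----------
    sample_id
        Identifier the records refer to.
    lsab_days
        Planned LS/AB assessment days (strictly increasing, starting at 0).
    posttest_day
        The day trajectories are centered at (the central-most observation).
    window
        Closed modeled interval ``[t_lo, t_hi]`` in days, pretest through
        the 3-month follow-up; endpoints must be planned days.
    usage_days
        Planned usage-assessment days (all > 0).
    n_assigned_by_condition
        Map from condition name to number of assigned exercises (0-6).
    """

    sample_id: str
    lsab_days: tuple[int, ...]
    posttest_day: int
    window: tuple[int, int]
    usage_days: tuple[int, ...] = ()
    n_assigned_by_condition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.lsab_days)
        object.__setattr__(self, "lsab_days", days)
        object.__setattr__(self, "usage_days", tuple(int(d) for d in self.usage_days))
        object.__setattr__(self, "window", (int(self.window[0]), int(self.window[1])))
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError(f"{self.sample_id}: lsab_days must be strictly increasing")
        if days[0] != 0:
            raise ConfigError(f"{self.sample_id}: first planned day must be 0 (pretest)")
        if self.posttest_day not in days:
            raise ConfigError(f"{self.sample_id}: posttest_day must be a planned day")
        if self.window[0] != days[0] or self.window[1] not in days:
            raise ConfigError(f"{self.sample_id}: window endpoints must be planned days")
        if any(d <= 0 for d in self.usage_days):
            raise ConfigError(f"{self.sample_id}: usage days must be > 0")
        for cond, n in self.n_assigned_by_condition.items():
            if not 0 <= int(n) <= 6:
                raise ConfigError(f"{self.sample_id}: condition {cond!r} assigns {n} exercises")

    @property
    def t_lo(self) -> int:
        return self.window[0]

    @property
    def t_hi(self) -> int:
        return self.window[1]

    def days_in_window(self) -> tuple[int, ...]:
        return tuple(d for d in self.lsab_days if self.t_lo <= d <= self.t_hi)


def default_designs() -> dict[str, StudyDesign]:
    """The two default study designs.

    Sample 1: one-week single-exercise interventions, LS/AB at days
    0/7/37/97, posttest day 7.  Sample 2: 0-6 week multi-exercise
    interventions with weekly usage assessments, LS/AB at days
    0/42/72/132, posttest day 42.
    """
    s1 = StudyDesign(
        sample_id="s1",
        lsab_days=(0, 7, 37, 97),
        posttest_day=7,
        window=(0, 97),
        usage_days=(7, 37, 97),
        n_assigned_by_condition={"one_week": 1},
    )
    s2 = StudyDesign(
        sample_id="s2",
        lsab_days=(0, 42, 72, 132),
        posttest_day=42,
        window=(0, 132),
        usage_days=(14, 21, 28, 35, 42, 72, 132),
        n_assigned_by_condition={"0w": 0, "2w": 2, "4w": 4, "6w": 6},
    )
    return {"s1": s1, "s2": s2}


def load_designs(path: str | Path) -> dict[str, StudyDesign]:
    """Load study designs from a YAML or JSON file.

    The file maps sample ids to StudyDesign fields, e.g.::

        s1:
          lsab_days: [0, 7, 37, 97]
          posttest_day: 7
          window: [0, 97]
          usage_days: [7, 37, 97]
          n_assigned_by_condition: {one_week: 1}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: designs file must map sample ids to design fields")
    designs: dict[str, StudyDesign] = {}
    for sample_id, fields in raw.items():
        designs[sample_id] = StudyDesign(
            sample_id=sample_id,
            lsab_days=tuple(fields["lsab_days"]),
            posttest_day=int(fields["posttest_day"]),
            window=tuple(fields["window"]),
            usage_days=tuple(fields.get("usage_days", ())),
            n_assigned_by_condition=dict(fields.get("n_assigned_by_condition", {})),
        )
    return designs


@dataclass
class Cohort:
    """A validated longitudinal cohort.

    ``assessments`` has columns participant_id, sample_id, day, ls, ab,
    cesd (floats with NaN for missing); ``usage`` has participant_id,
    sample_id, day, n_assigned, freq_sum, adhered.  ``truth_labels`` maps
    participant_id to the generating archetype for synthetic cohorts.
    """

    designs: dict[str, StudyDesign]
    assessments: pd.DataFrame
    usage: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=USAGE_COLUMNS))
    truth_labels: pd.Series | None = None

    def participants(self) -> list[str]:
        ids: set[str] = set(self.assessments["participant_id"])
        ids.update(self.usage["participant_id"])
        if self.truth_labels is not None:
            ids.update(self.truth_labels.index)
        return sorted(ids)

    def design_of(self, sample_id: str) -> StudyDesign:
        try:
            return self.designs[sample_id]
        except KeyError:
            raise CohortValidationError(f"unknown sample_id {sample_id!r}") from None

    def sample_of(self) -> pd.Series:
        """participant_id -> sample_id, from whichever table mentions them."""
        frames = [self.assessments[["participant_id", "sample_id"]],
                  self.usage[["participant_id", "sample_id"]]]
        both = pd.concat(frames, ignore_index=True).drop_duplicates("participant_id")
        return both.set_index("participant_id")["sample_id"]


def _validate_assessments(df: pd.DataFrame, designs: Mapping[str, StudyDesign]) -> None:
    unknown = set(df["sample_id"]) - set(designs)
    if unknown:
        row = int(df.index[df["sample_id"].isin(unknown)][0]) + 2
        raise CohortValidationError(f"row {row}: unknown sample_id {sorted(unknown)[0]!r}")
    if (df["day"] < 0).any():
        row = int(df.index[df["day"] < 0][0]) + 2
        raise CohortValidationError(f"row {row}: negative day")
    for col, (lo, hi) in SCORE_RANGES.items():
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise CohortValidationError(
                f"row {row}: {col}={vals[bad].iloc[0]:g} outside [{lo:g}, {hi:g}]"
            )
    dup = df.duplicated(subset=["participant_id", "day"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise CohortValidationError(f"row {row}: duplicate (participant, day) record")


def _validate_usage(df: pd.DataFrame) -> None:
    if (df["day"] <= 0).any():
        row = int(df.index[df["day"] <= 0][0]) + 2
        raise CohortValidationError(f"row {row}: usage day must be > 0")
    bad = (df["freq_sum"] < 0) | (df["freq_sum"] > 7 * df["n_assigned"])
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise CohortValidationError(f"row {row}: freq_sum outside [0, 7*n_assigned]")
    if not df["adhered"].isin([0, 1]).all():
        row = int(df.index[~df["adhered"].isin([0, 1])][0]) + 2
        raise CohortValidationError(f"row {row}: adhered must be 0 or 1")


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str, "sample_id": str})
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: empty file, header required") from None
    if list(df.columns) != list(columns):
        raise CohortFormatError(
            f"{path}: expected header {','.join(columns)}, got {','.join(map(str, df.columns))}"
        )
    return df


def read_cohort(
    assessments_path: str | Path,
    designs: Mapping[str, StudyDesign],
    usage_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> Cohort:
    """Read and validate a cohort from CSV.

    Raises :class:`CohortFormatError` for a wrong header and
    :class:`CohortValidationError` naming the first offending row and
    field for out-of-range values.
    """
    adf = _read_csv(assessments_path, ASSESSMENT_COLUMNS)
    adf["day"] = adf["day"].astype(int)
    for col in ("ls", "ab", "cesd"):
        adf[col] = pd.to_numeric(adf[col], errors="coerce").astype(float)
    _validate_assessments(adf, designs)

    if usage_path is not None:
        udf = _read_csv(usage_path, USAGE_COLUMNS)
        for col in ("day", "n_assigned", "freq_sum", "adhered"):
            udf[col] = udf[col].astype(int)
        _validate_usage(udf)
    else:
        udf = pd.DataFrame(columns=USAGE_COLUMNS)

    truth = None
    if truth_path is not None:
        tdf = _read_csv(truth_path, ["participant_id", "archetype"])
        truth = tdf.set_index("participant_id")["archetype"]

    return Cohort(designs=dict(designs), assessments=adf, usage=udf, truth_labels=truth)


def _fmt_score(v: float) -> str:
    if pd.isna(v):
        return ""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_cohort(
    cohort: Cohort,
    assessments_path: str | Path,
    usage_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> None:
    """Write a cohort back to CSV (round-trip stable: integers stay
    integers, missing values become empty cells)."""
    adf = cohort.assessments.copy()
    for col in ("ls", "ab", "cesd"):
        adf[col] = adf[col].map(_fmt_score)
    adf.to_csv(assessments_path, index=False)
    if usage_path is not None:
        cohort.usage.to_csv(usage_path, index=False)
    if truth_path is not None and cohort.truth_labels is not None:
        cohort.truth_labels.rename("archetype").rename_axis("participant_id").to_csv(truth_path)


def eligibility_filter(
    cohort: Cohort,
    min_points: int = 4,
    within_window: bool = True,
) -> tuple[set[str], set[str]]:
    """Partition participants by the inclusion rule: at least ``min_points``
    non-missing observations in *both* LS and AB.

    With ``within_window`` (the default) only observations inside the
    participant's design window [t_lo, t_hi] are counted; otherwise all
    recorded days count.  Returns ``(included, excluded)``, a disjoint
    partition of all participants.
    """
    if min_points < 2:
        raise ConfigError("min_points must be >= 2 (cannot fit any trajectory below that)")
    everyone = set(cohort.participants())
    df = cohort.assessments
    if within_window and len(df):
        lo = df["sample_id"].map(lambda s: cohort.design_of(s).t_lo)
        hi = df["sample_id"].map(lambda s: cohort.design_of(s).t_hi)
        df = df[(df["day"] >= lo) & (df["day"] <= hi)]
    counts = df.groupby("participant_id")[["ls", "ab"]].count()
    ok = counts[(counts["ls"] >= min_points) & (counts["ab"] >= min_points)]
    included = set(ok.index)
    return included, everyone - included


def flag_depression(cesd):
    """Elevated-depression-risk flag: CES-D score of 16 or above.

    Accepts a scalar (returns ``True``/``False``/``None`` for missing) or
    an array-like (returns a pandas nullable-boolean Series with missing
    propagated, never coerced to False).
    """
    if np.isscalar(cesd) or cesd is None or (isinstance(cesd, float) and np.isnan(cesd)):
        if cesd is None or (isinstance(cesd, (int, float)) and pd.isna(cesd)):
            return None
        if not SCORE_RANGES["cesd"][0] <= float(cesd) <= SCORE_RANGES["cesd"][1]:
            raise CohortValidationError(f"cesd={cesd} outside [0, 60]")
        return bool(float(cesd) >= CESD_CUTOFF)
    s = pd.Series(cesd, dtype=float)
    out = pd.Series(pd.NA, index=s.index, dtype="boolean")
    out[s.notna()] = s[s.notna()] >= CESD_CUTOFF
    return out


def pairwise_view(cohort: Cohort, variables: Iterable[str], day: int | None = None) -> pd.DataFrame:
    """Complete-case view for a specific analysis (pairwise deletion).

    Keeps the rows (optionally restricted to ``day``) where *all* requested
    variables are non-missing; other variables' missingness is ignored, so
    each analysis drops only what it needs.
    """
    variables = list(variables)
    unknown = set(variables) - set(SCORE_RANGES)
    if unknown:
        raise ConfigError(f"unknown variable(s) {sorted(unknown)}; choose from ls, ab, cesd")
    df = cohort.assessments
    if day is not None:
        df = df[df["day"] == day]
    return df.dropna(subset=variables).reset_index(drop=True)
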