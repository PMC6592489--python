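"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates the latent structure the trajectory analysis
assumes: four trajectory archetypes (nondistressed, lasting benefit,
hedonic adaptation, residual) with piecewise-linear mean curves over the
assessment schedule, a shared person-level well-being factor loading
positively on LS and AB and negatively on CES-D (which induces the
strong observed cross-outcome correlations), baseline-dependent
attrition concentrated on the first post-baseline gap, and a usage
process in which, among the two "benefit" archetypes, frequency of use
and adherence follow the configured logistic law for lasting benefit
versus hedonic adaptation (sampled by Bayes inversion of that law, so a
downstream logistic fit recovers the configured slopes).

Scores are drawn around the archetype curves, rounded to integers (scale
sums are integers) and clipped into their legal ranges.  The generator
is a pure function of (config, designs): per-participant RNG substreams
are derived by counter, so identical seeds give byte-identical CSVs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    ASSESSMENT_COLUMNS,
    SCORE_RANGES,
    USAGE_COLUMNS,
    Cohort,
    ConfigError,
    StudyDesign,
    default_designs,
)

__all__ = [
    "ArchetypeSpec",
    "AttritionParams",
    "CohortConfig",
    "default_archetypes",
    "default_config",
    "archetype_mean",
    "attrition_sample",
    "usage_sample",
    "generate_cohort",
]

ARCHETYPES = ("nondistressed", "lasting_benefit", "hedonic_adaptation", "residual")

#: CES-D levels reported for baseline-distress subgroups: nondistressed
#: mean 7.93 (SD 5.85), distressed mean 26.74 (SD 10.58)
NONDISTRESSED_CESD = 7.93
DISTRESSED_CESD = 26.74


@dataclass(frozen=True)
class ArchetypeSpec:
    """Mean curves and noise levels for one latent trajectory archetype.

    Anchor values are aligned with a design's four planned LS/AB days
    (baseline, posttest, mid-window, window end) and interpolated
    piecewise-linearly between them; no functional form beyond the
    qualitative shape is assumed.
    """

    label: str
    ls_anchors: tuple[float, float, float, float]
    ab_anchors: tuple[float, float, float, float]
    cesd_anchors: tuple[float, float, float, float]
    within_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ls": 1.0, "ab": 1.75, "cesd": 2.0}
    )
    baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"ls": 4.9, "ab": 5.4, "cesd": 2.0}
    )

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.within_sd.values()):
            raise ConfigError("within-person SDs must be >= 0")
        if any(sd < 0 for sd in self.baseline_sd.values()):
            raise ConfigError("baseline SDs must be >= 0")


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """Default archetype curves.

    The nondistressed group is flat and high in LS/AB with low CES-D;
    the three distressed archetypes start low (CES-D at the distressed
    baseline mean 26.74) and then rise-and-hold (lasting benefit),
    rise-and-return (hedonic adaptation), or dip without an early benefit
    (residual).  Levels are free parameters chosen to sit inside the
    observed pooled baseline means/SDs.
    """
    return (
        ArchetypeSpec(
            label="nondistressed",
            ls_anchors=(27.0, 27.0, 27.0, 27.0),
            ab_anchors=(22.0, 22.0, 22.0, 22.0),
            cesd_anchors=(NONDISTRESSED_CESD,) * 4,
        ),
        ArchetypeSpec(
            label="lasting_benefit",
            ls_anchors=(17.0, 19.0, 25.0, 25.0),
            ab_anchors=(5.0, 9.0, 18.0, 18.0),
            cesd_anchors=(DISTRESSED_CESD, 23.0, 15.0, 14.0),
        ),
        ArchetypeSpec(
            label="hedonic_adaptation",
            ls_anchors=(17.0, 19.0, 25.0, 17.0),
            ab_anchors=(5.0, 9.0, 18.0, 5.0),
            cesd_anchors=(DISTRESSED_CESD, 23.0, 15.0, DISTRESSED_CESD),
        ),
        ArchetypeSpec(
            label="residual",
            ls_anchors=(18.0, 16.0, 13.0, 16.0),
            ab_anchors=(6.0, 2.0, -3.0, 2.0),
            cesd_anchors=(DISTRESSED_CESD, 29.0, 32.0, 29.0),
        ),
    )


@dataclass(frozen=True)
class AttritionParams:
    """Discrete dropout hazard over the post-baseline assessment days.

    ``base_hazards`` apply to a person of average baseline well-being at
    each post-baseline LS/AB day in order (largest first: most attrition
    happens between the first two assessments); the log-odds of dropping
    at each day decrease by ``wellbeing_slope`` per SD of baseline
    well-being, so excluded participants average lower LS/AB and higher
    CES-D than completers.
    """

    base_hazards: tuple[float, ...] = (0.45, 0.12, 0.10)
    wellbeing_slope: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Generative truth for a synthetic cohort."""

    n_per_sample: Mapping[str, int] = field(
        default_factory=lambda: {"s1": 912, "s2": 1318}
    )
    mixture_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "nondistressed": 0.528,
            "lasting_benefit": 0.180,
            "hedonic_adaptation": 0.142,
            "residual": 0.150,
        }
    )
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    #: loadings of the shared standard-normal distress factor (enters LS
    #: and AB positively, CES-D negatively)
    factor_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"ls": 2.6, "ab": 3.0, "cesd": 6.0}
    )
    #: loadings of a second person factor shared by LS and AB only (the
    #: hedonic-level variance depression does not explain); keeps the
    #: LS-AB correlation below the CES-D pairs while still positive
    hedonic_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"ls": 1.0, "ab": 3.5}
    )
    attrition: AttritionParams = field(default_factory=AttritionParams)
    #: true logistic coefficients for lasting benefit vs hedonic adaptation
    #: on the (z-scored freq, adherence, centered time) scale
    usage_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.47,
            "freq": -0.20,
            "adh": 0.11,
            "time": 0.0,
            "freq:adh": 0.65,
            "freq:time": 0.01,
            "adh:time": 0.0,
            "freq:adh:time": 0.0,
        }
    )
    #: day value subtracted when time enters the usage logistic law
    usage_time_center: float = 28.36
    adherence_rate: float = 0.6
    freq_mean_per_exercise: float = 3.5
    freq_sd_per_exercise: float = 1.5
    #: intended pooled correlations (cesd-ls, cesd-ab, ls-ab); metadata
    #: recording what the loadings were calibrated against
    target_correlations: tuple[float, float, float] = (-0.70, -0.75, 0.62)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mixture_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights sum to {total!r}, not 1")
        if any(n < 0 for n in self.n_per_sample.values()):
            raise ConfigError("n_per_sample must be >= 0")
        labels = [a.label for a in self.archetypes]
        if len(set(labels)) != len(labels):
            raise ConfigError("archetype labels must be unique")
        if set(self.mixture_weights) != set(labels):
            raise ConfigError("mixture weights must cover exactly the archetype labels")

    def archetype(self, label: str) -> ArchetypeSpec:
        for a in self.archetypes:
            if a.label == label:
                return a
        raise ConfigError(f"unknown archetype {label!r}")


def default_config(**overrides) -> CohortConfig:
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


def archetype_mean(
    label: str,
    day: int | float,
    design: StudyDesign,
    archetypes: Sequence[ArchetypeSpec] | None = None,
) -> tuple[float, float, float]:
    """Piecewise-linear archetype means (LS, AB, CES-D) at ``day``.

    Anchor values sit at the design's planned in-window LS/AB days and
    are linearly interpolated between them.
    """
    if not design.t_lo <= day <= design.t_hi:
        raise ConfigError(f"day {day} outside modeled window {design.window}")
    archetypes = archetypes if archetypes is not None else default_archetypes()
    spec = next((a for a in archetypes if a.label == label), None)
    if spec is None:
        raise ConfigError(f"unknown archetype {label!r}")
    days = np.asarray(design.days_in_window(), dtype=float)
    if len(days) != len(spec.ls_anchors):
        # denser schedules: spread the four anchors evenly over the window
        days = np.linspace(design.t_lo, design.t_hi, len(spec.ls_anchors))
    return (
        float(np.interp(day, days, spec.ls_anchors)),
        float(np.interp(day, days, spec.ab_anchors)),
        float(np.interp(day, days, spec.cesd_anchors)),
    )


# population-scale constants used to standardise baseline well-being for
# the attrition hazard (pooled baseline means/SDs of the emulated cohort)
_BASELINE_NORMS = {"ls": (21.9, 8.2), "ab": (14.9, 12.5), "cesd": (15.4, 12.0)}


def _wellbeing_z(ls: float, ab: float, cesd: float) -> float:
    z_ls = (ls - _BASELINE_NORMS["ls"][0]) / _BASELINE_NORMS["ls"][1]
    z_ab = (ab - _BASELINE_NORMS["ab"][0]) / _BASELINE_NORMS["ab"][1]
    z_cesd = (cesd - _BASELINE_NORMS["cesd"][0]) / _BASELINE_NORMS["cesd"][1]
    return (z_ls + z_ab - z_cesd) / 3.0


def attrition_sample(
    baseline_ls: float,
    baseline_ab: float,
    baseline_cesd: float,
    rng: np.random.Generator,
    design: StudyDesign,
    params: AttritionParams | None = None,
) -> int:
    """Draw the participant's last observed day.

    A discrete hazard acts at each post-baseline LS/AB day; its log-odds
    fall with baseline well-being, and the first gap carries the largest
    hazard.  Returns the last day with any records (the baseline day if
    the participant drops immediately).
    """
    params = params or AttritionParams()
    post_days = [d for d in design.lsab_days if d > design.t_lo]
    w = _wellbeing_z(baseline_ls, baseline_ab, baseline_cesd)
    last = design.t_lo
    for j, day in enumerate(post_days):
        base = params.base_hazards[min(j, len(params.base_hazards) - 1)]
        base = min(max(base, 1e-9), 1 - 1e-9)
        logit = math.log(base / (1 - base)) - params.wellbeing_slope * w
        hazard = 1.0 / (1.0 + math.exp(-logit))
        if rng.random() < hazard:
            return last
        last = day
    return last


def _linear_predictor(effects: Mapping[str, float], f: float, a: float, tc: float) -> float:
    return (
        effects.get("intercept", 0.0)
        + effects.get("freq", 0.0) * f
        + effects.get("adh", 0.0) * a
        + effects.get("time", 0.0) * tc
        + effects.get("freq:adh", 0.0) * f * a
        + effects.get("freq:time", 0.0) * f * tc
        + effects.get("adh:time", 0.0) * a * tc
        + effects.get("freq:adh:time", 0.0) * f * a * tc
    )


def usage_sample(
    label: str,
    day: int,
    n_assigned: int,
    rng: np.random.Generator,
    config: CohortConfig,
) -> tuple[int, int] | None:
    """Draw one usage record ``(freq_sum, adhered)`` for a participant.

    For the lasting-benefit and hedonic-adaptation archetypes the latent
    (z-scaled) frequency and the adherence indicator are sampled from
    label-conditional distributions obtained by Bayes inversion of the
    configured logistic law, so the conditional log-odds of lasting
    benefit given (freq, adh, centered time) reproduce the configured
    slopes (the intercept absorbs the mixture normalisation).  Other
    archetypes get exchangeable usage.  Returns ``None`` when no
    exercises are assigned (record suppressed).
    """
    if n_assigned <= 0:
        return None
    tc = day - config.usage_time_center
    if label in ("lasting_benefit", "hedonic_adaptation"):
        want = 1.0 if label == "lasting_benefit" else 0.0
        for _ in range(1000):
            f = rng.normal()
            a = 1.0 if rng.random() < config.adherence_rate else 0.0
            p = 1.0 / (1.0 + math.exp(-_linear_predictor(config.usage_effects, f, a, tc)))
            accept = p if want else 1.0 - p
            if rng.random() < accept:
                break
        else:  # pragma: no cover - pathological configs only
            f, a = rng.normal(), float(rng.random() < config.adherence_rate)
    else:
        f = rng.normal()
        a = 1.0 if rng.random() < config.adherence_rate else 0.0
    mean = config.freq_mean_per_exercise * n_assigned
    sd = config.freq_sd_per_exercise * n_assigned
    freq = int(round(mean + sd * f))
    freq = max(0, min(7 * n_assigned, freq))
    return freq, int(a)


def _clip_round(value: float, outcome: str) -> int:
    lo, hi = SCORE_RANGES[outcome]
    return int(min(max(round(value), lo), hi))


def generate_cohort(
    config: CohortConfig | None = None,
    designs: Mapping[str, StudyDesign] | None = None,
) -> Cohort:
    """Generate a synthetic cohort with truth labels.

    Deterministic given (config, designs): participant substreams are
    seeded by (config.seed, sample index, participant index).
    """
    config = config or CohortConfig()
    designs = dict(designs) if designs is not None else default_designs()
    labels = sorted(config.mixture_weights)
    weights = np.array([config.mixture_weights[l] for l in labels])
    weights = weights / weights.sum()

    assess_rows: list[tuple] = []
    usage_rows: list[tuple] = []
    truth: dict[str, str] = {}
    for s_idx, (sample_id, design) in enumerate(sorted(designs.items())):
        n = int(config.n_per_sample.get(sample_id, 0))
        conditions = sorted(design.n_assigned_by_condition) or ["default"]
        anchor_days = np.asarray(design.days_in_window(), dtype=float)
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), s_idx, i])
            )
            pid = f"{sample_id}-{i:05d}"
            label = labels[int(rng.choice(len(labels), p=weights))]
            truth[pid] = label
            spec = config.archetype(label)
            cond = conditions[int(rng.integers(len(conditions)))]
            n_assigned = int(design.n_assigned_by_condition.get(cond, 1))
            z = rng.normal()
            h = rng.normal()
            icept = {o: rng.normal(0.0, spec.baseline_sd[o]) for o in ("ls", "ab", "cesd")}
            sign = {"ls": 1.0, "ab": 1.0, "cesd": -1.0}
            values: dict[int, dict[str, int]] = {}
            for day in design.days_in_window():
                ls_m, ab_m, cesd_m = archetype_mean(label, day, design, config.archetypes)
                mean = {"ls": ls_m, "ab": ab_m, "cesd": cesd_m}
                values[day] = {
                    o: _clip_round(
                        mean[o]
                        + sign[o] * config.factor_loadings[o] * z
                        + config.hedonic_loadings.get(o, 0.0) * h
                        + icept[o]
                        + rng.normal(0.0, spec.within_sd[o]),
                        o,
                    )
                    for o in ("ls", "ab", "cesd")
                }
            base = values[design.t_lo]
            last_day = attrition_sample(
                base["ls"], base["ab"], base["cesd"], rng, design, config.attrition
            )
            for day in design.days_in_window():
                if day > last_day:
                    continue
                v = values[day]
                assess_rows.append((pid, sample_id, day, v["ls"], v["ab"], v["cesd"]))
            for day in design.usage_days:
                if day > last_day or day > design.t_hi:
                    continue
                drawn = usage_sample(label, day, n_assigned, rng, config)
                if drawn is not None:
                    usage_rows.append((pid, sample_id, day, n_assigned, drawn[0], drawn[1]))

    assessments = pd.DataFrame(assess_rows, columns=ASSESSMENT_COLUMNS)
    if len(assessments):
        assessments[["ls", "ab", "cesd"]] = assessments[["ls", "ab", "cesd"]].astype(float)
        assessments["day"] = assessments["day"].astype(int)
    usage = pd.DataFrame(usage_rows, columns=USAGE_COLUMNS)
    truth_series = pd.Series(truth, name="archetype")
    truth_series.index.name = "participant_id"
    return Cohort(
        designs=designs,
        assessments=assessments,
        usage=usage,
        truth_labels=truth_series,
    )
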