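"""Per-participant polynomial trajectories of well-being (pipeline Step 1).

Each participant's LS and AB series over the modeled window (pretest
through the 3-month follow-up) is summarised by an ordinary-least-squares
polynomial in centered time ``u = day - posttest_day``, with degree two
less than the number of observations, so the fit is precise but
unsaturated.  The LS and AB polynomials together form the participant's
3-D (LS x AB x time) trajectory that the shape clustering consumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfigError, StudyDesign

__all__ = [
    "PolyTrajectory",
    "Trajectory3D",
    "trajectory_degree",
    "fit_poly",
    "build_trajectory",
    "fit_cohort",
    "derivative",
    "evaluate",
    "trajectories_to_frame",
]

logger = logging.getLogger(__name__)

#: saturation guard: never exceed this polynomial degree
MAX_DEGREE = 4


@dataclass(frozen=True)
class PolyTrajectory:
    """A polynomial ``y(u) = c0 + c1*u + ... + cm*u**m`` in centered time
    ``u = day - center``, valid over a closed day window."""

    coefficients: tuple[float, ...]
    center: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        coef = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "window", (int(self.window[0]), int(self.window[1])))
        if len(coef) < 2:
            raise ConfigError("polynomial degree must be >= 1 (need at least c0, c1)")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, day) -> float | np.ndarray:
        return evaluate(self, day)


@dataclass(frozen=True)
class Trajectory3D:
    """A participant's paired LS and AB polynomials over a shared window."""

    participant_id: str
    sample_id: str
    ls_poly: PolyTrajectory
    ab_poly: PolyTrajectory

    def __post_init__(self) -> None:
        if self.ls_poly.center != self.ab_poly.center:
            raise ConfigError("LS and AB polynomials must share their center")
        if self.ls_poly.window != self.ab_poly.window:
            raise ConfigError("LS and AB polynomials must share their window")

    @property
    def window(self) -> tuple[int, int]:
        return self.ls_poly.window

    @property
    def center(self) -> int:
        return self.ls_poly.center


def trajectory_degree(n_obs: int, max_degree: int = MAX_DEGREE) -> int:
    """Polynomial degree for ``n_obs`` observations: two less than the
    number of observations (capped at ``max_degree`` to stay unsaturated
    on denser schedules)."""
    if n_obs < 3:
        raise ConfigError(f"need at least 3 observations for a degree-1 fit, got {n_obs}")
    return max(1, min(n_obs - 2, max_degree))


def fit_poly(
    days: Sequence[int],
    values: Sequence[float],
    center: int,
    degree: int,
    window: tuple[int, int] | None = None,
) -> PolyTrajectory:
    """Ordinary least squares on the centered monomial basis
    ``[1, u, u^2, ..., u^degree]``.

    When ``len(days) == degree + 1`` this interpolates the data exactly.
    Duplicate days make the design rank deficient and raise.
    """
    days_arr = np.asarray(days, dtype=float)
    vals = np.asarray(values, dtype=float)
    if days_arr.ndim != 1 or days_arr.shape != vals.shape:
        raise ConfigError("days and values must be 1-D and equally long")
    if len(np.unique(days_arr)) != len(days_arr):
        raise ConfigError("duplicate days make the polynomial fit rank deficient")
    if len(days_arr) < degree + 1:
        raise ConfigError(f"{len(days_arr)} observations cannot identify degree {degree}")
    u = days_arr - center
    X = np.vander(u, N=degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(X, vals, rcond=None)
    if rank < degree + 1:
        raise ConfigError("rank-deficient design matrix in polynomial fit")
    if window is None:
        window = (int(days_arr.min()), int(days_arr.max()))
    return PolyTrajectory(coefficients=tuple(coef), center=int(center), window=window)


def build_trajectory(records: pd.DataFrame, design: StudyDesign) -> Trajectory3D | None:
    """Fit one participant's LS and AB polynomials from their assessment
    records, restricted to the design window.

    Each outcome gets its own degree from its own non-missing in-window
    count; both polynomials are centered at the design's posttest day.
    Returns ``None`` (with a logged reason) if either outcome has fewer
    than 3 in-window points.
    """
    pid = str(records["participant_id"].iloc[0])
    in_win = records[(records["day"] >= design.t_lo) & (records["day"] <= design.t_hi)]
    polys: dict[str, PolyTrajectory] = {}
    for outcome in ("ls", "ab"):
        obs = in_win.dropna(subset=[outcome])
        if len(obs) < 3:
            logger.info("skipping %s: only %d in-window %s points", pid, len(obs), outcome)
            return None
        polys[outcome] = fit_poly(
            obs["day"].to_numpy(),
            obs[outcome].to_numpy(),
            center=design.posttest_day,
            degree=trajectory_degree(len(obs)),
            window=design.window,
        )
    return Trajectory3D(
        participant_id=pid,
        sample_id=design.sample_id,
        ls_poly=polys["ls"],
        ab_poly=polys["ab"],
    )


def fit_cohort(
    cohort: Cohort,
    participants: Iterable[str] | None = None,
) -> tuple[list[Trajectory3D], dict[str, str]]:
    """Fit trajectories for every (included) participant in the cohort.

    Returns the fitted trajectories and a map of skipped participants to
    the reason they could not be fitted.
    """
    keep = set(participants) if participants is not None else None
    trajectories: list[Trajectory3D] = []
    skipped: dict[str, str] = {}
    for (pid, sample_id), rec in cohort.assessments.groupby(
        ["participant_id", "sample_id"], sort=True
    ):
        if keep is not None and pid not in keep:
            continue
        design = cohort.design_of(sample_id)
        traj = build_trajectory(rec, design)
        if traj is None:
            skipped[str(pid)] = "fewer than 3 in-window points in LS or AB"
        else:
            trajectories.append(traj)
    return trajectories, skipped


def derivative(poly: PolyTrajectory) -> PolyTrajectory:
    """Polynomial derivative (power rule); center and window preserved.

    The derivative of a degree-1 polynomial is the constant ``(c1,)``:
    the one case where a degree-0 tuple is allowed, bypassing the
    degree >= 1 constructor invariant.
    """
    c = np.asarray(poly.coefficients)
    dc = c[1:] * np.arange(1, len(c))
    if len(dc) == 0:
        dc = np.array([0.0])
    if len(dc) == 1:
        out = PolyTrajectory.__new__(PolyTrajectory)
        object.__setattr__(out, "coefficients", (float(dc[0]),))
        object.__setattr__(out, "center", poly.center)
        object.__setattr__(out, "window", poly.window)
        return out
    return PolyTrajectory(coefficients=tuple(dc), center=poly.center, window=poly.window)


def evaluate(poly: PolyTrajectory, day) -> float | np.ndarray:
    """Evaluate at ``u = day - center`` (Horner).  Extrapolation outside
    the window is allowed but logged at debug level."""
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < poly.window[0]) or np.any(day_arr > poly.window[1]):
        logger.debug("evaluating polynomial outside its window %s", poly.window)
    u = day_arr - poly.center
    val = np.polynomial.polynomial.polyval(u, poly.coefficients)
    return float(val) if np.isscalar(day) or day_arr.ndim == 0 else val


def trajectories_to_frame(trajectories: Iterable[Trajectory3D]) -> pd.DataFrame:
    """Flat export: one row per participant x outcome with coefficients
    c0..c4 (blank for unused degrees)."""
    rows = []
    for t in trajectories:
        for outcome, poly in (("ls", t.ls_poly), ("ab", t.ab_poly)):
            row = {
                "participant_id": t.participant_id,
                "sample_id": t.sample_id,
                "outcome": outcome,
                "center": poly.center,
                "degree": poly.degree,
            }
            for i in range(MAX_DEGREE + 1):
                row[f"c{i}"] = (
                    poly.coefficients[i] if i < len(poly.coefficients) else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
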