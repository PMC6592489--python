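"""Shared fixtures: small synthetic cohorts and toy trajectory builders."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import wbtraj as w
from wbtraj.trajectories import PolyTrajectory, Trajectory3D


@pytest.fixture(scope="session")
def designs():
    return w.default_designs()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-sample synthetic cohort shared by read-only tests."""
    cfg = dataclasses.replace(
        w.CohortConfig(), n_per_sample={"s1": 150, "s2": 150}, seed=3
    )
    return w.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """An n=5000 cohort at default conditions for calibration checks."""
    cfg = dataclasses.replace(
        w.CohortConfig(), n_per_sample={"s1": 2000, "s2": 3000}, seed=11
    )
    return w.generate_cohort(cfg)


@pytest.fixture
def make_traj(designs):
    """Build a Trajectory3D directly from polynomial coefficients."""

    def _make(ls_coef, ab_coef, pid="p", sample="s1", center=None, window=None):
        d = designs[sample]
        center = d.posttest_day if center is None else center
        window = d.window if window is None else window
        return Trajectory3D(
            participant_id=pid,
            sample_id=sample,
            ls_poly=PolyTrajectory(tuple(ls_coef), center=center, window=window),
            ab_poly=PolyTrajectory(tuple(ab_coef), center=center, window=window),
        )

    return _make


@pytest.fixture
def make_cohort(designs):
    """Build a Cohort from explicit (pid, sample, day, ls, ab, cesd) rows."""

    def _make(rows, usage_rows=None, truth=None):
        adf = pd.DataFrame(
            rows, columns=["participant_id", "sample_id", "day", "ls", "ab", "cesd"]
        )
        adf[["ls", "ab", "cesd"]] = adf[["ls", "ab", "cesd"]].astype(float)
        udf = pd.DataFrame(
            usage_rows or [],
            columns=["participant_id", "sample_id", "day", "n_assigned", "freq_sum", "adhered"],
        )
        t = None
        if truth is not None:
            t = pd.Series(truth, name="archetype")
            t.index.name = "participant_id"
        return w.Cohort(designs=dict(designs), assessments=adf, usage=udf, truth_labels=t)

    return _make
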