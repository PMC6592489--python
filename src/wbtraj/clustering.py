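"""Curve-shape clustering of well-being trajectories (pipeline Step 2).

A modified K-means groups participants by *how* their well-being changes
rather than by its level: the distance between two trajectories is the
integral, over the modeled window, of the Euclidean norm of the
difference between their derivative functions in the LS and AB
dimensions,

    D(A, B) = int_{t_lo}^{t_hi} sqrt( (LS_A'(t) - LS_B'(t))^2
                                    + (AB_A'(t) - AB_B'(t))^2 ) dt .

Intercepts never enter, so D is a pseudometric on curve shapes: adding
any constant to either curve leaves every distance unchanged.  The
integrand (the square root of a polynomial) has no closed form in
general, so the integral is computed with fixed-node Gauss-Legendre
quadrature, which keeps distances deterministic and fast.

Prototypes are function-valued centroids: the coefficient-wise mean of
their members' polynomials with the intercept forced to zero.  Because
the mean of coefficients does not exactly minimise this integral
distance, a descent guard keeps the previous prototypes (and stops the
restart) whenever an update would increase the objective, so reported
objectives are always monotone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfigError, StudyDesign
from .trajectories import PolyTrajectory, Trajectory3D, derivative

__all__ = [
    "DEFAULT_NODES",
    "ARCHETYPE_LABELS",
    "Prototype",
    "ClusterSolution",
    "ScreeTable",
    "shape_distance",
    "assign_step",
    "update_step",
    "kmeans_shape",
    "scree_select",
    "label_clusters",
    "apply_display_intercept",
]

logger = logging.getLogger(__name__)

DEFAULT_NODES = 64

ARCHETYPE_LABELS = ("nondistressed", "lasting_benefit", "hedonic_adaptation", "residual")


@dataclass(frozen=True)
class Prototype:
    """Function-valued cluster centroid with intercepts fixed to zero.

    ``display_intercepts`` are optional (LS, AB) anchors used only for
    plotting/export; they never affect distances.
    """

    k: int
    ls_poly: PolyTrajectory
    ab_poly: PolyTrajectory
    display_intercepts: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if abs(self.ls_poly.coefficients[0]) > 1e-12 or abs(self.ab_poly.coefficients[0]) > 1e-12:
            raise ConfigError("prototype polynomials must have zero intercept")

    @property
    def window(self) -> tuple[int, int]:
        return self.ls_poly.window


@dataclass
class ClusterSolution:
    """Output of one K-means run: assignments, prototypes and the total
    shape-distance objective ``W = sum_i D(traj_i, proto_{a(i)})``."""

    K: int
    participant_ids: list[str]
    assignments: dict[str, int]
    prototypes: list[Prototype]
    objective: float
    n_iter: int
    seed: int
    restarts: int
    converged: bool
    objective_trace: list[float]

    def labels_array(self) -> np.ndarray:
        return np.array([self.assignments[p] for p in self.participant_ids])


@dataclass
class ScreeTable:
    """Objective-vs-K table for elbow (scree) selection of K."""

    table: pd.DataFrame  # columns: K, objective, n_restarts, selected
    selected_K: int | None
    solutions: dict[int, ClusterSolution] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# quadrature machinery


def _quad_nodes(window: tuple[int, int], n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights mapped onto [t_lo, t_hi]."""
    t_lo, t_hi = window
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (t_hi - t_lo)
    return half * x + 0.5 * (t_hi + t_lo), half * w


def _deriv_at(poly: PolyTrajectory, days: np.ndarray) -> np.ndarray:
    dpoly = derivative(poly)
    return np.polynomial.polynomial.polyval(days - dpoly.center, dpoly.coefficients)


def _pair_distance(a_ls, a_ab, b_ls, b_ab, days, weights) -> float:
    dl = _deriv_at(a_ls, days) - _deriv_at(b_ls, days)
    da = _deriv_at(a_ab, days) - _deriv_at(b_ab, days)
    return float(np.sum(weights * np.hypot(dl, da)))


def shape_distance(
    a: Trajectory3D | Prototype,
    b: Trajectory3D | Prototype,
    n_nodes: int = DEFAULT_NODES,
    normalize: bool = False,
) -> float:
    """Derivative-based integral distance between two trajectory shapes.

    Both objects must share the same window.  The result is invariant to
    both curves' intercepts and is a pseudometric (symmetric,
    non-negative, zero on identical shapes, triangle inequality).
    ``normalize`` divides by the window length (a mean rather than an
    integral), useful only when comparing distances across designs with
    different windows; clustering is within-sample, so it is off by
    default.
    """
    if tuple(a.window) != tuple(b.window):
        raise ConfigError(f"window mismatch: {a.window} vs {b.window}")
    days, weights = _quad_nodes(tuple(a.window), n_nodes)
    d = _pair_distance(a.ls_poly, a.ab_poly, b.ls_poly, b.ab_poly, days, weights)
    if normalize:
        d /= a.window[1] - a.window[0]
    return d


# ---------------------------------------------------------------------------
# vectorised engine: every trajectory/prototype is represented by its
# derivative values at the shared quadrature nodes (distance only sees
# derivatives, and coefficient averaging commutes with evaluation).


class _NodeSpace:
    def __init__(self, trajectories: Sequence[Trajectory3D], n_nodes: int) -> None:
        if not trajectories:
            raise ConfigError("no trajectories to cluster")
        windows = {tuple(t.window) for t in trajectories}
        if len(windows) > 1:
            raise ConfigError(f"trajectories span different windows: {sorted(windows)}")
        self.window = windows.pop()
        self.days, self.weights = _quad_nodes(self.window, n_nodes)
        self.ids = [t.participant_id for t in trajectories]
        self.sample_id = trajectories[0].sample_id
        self.center = trajectories[0].center
        self.L = np.array([_deriv_at(t.ls_poly, self.days) for t in trajectories])
        self.A = np.array([_deriv_at(t.ab_poly, self.days) for t in trajectories])
        self.max_len = max(
            max(len(t.ls_poly.coefficients), len(t.ab_poly.coefficients)) for t in trajectories
        )
        self.C_ls = np.array([self._pad(t.ls_poly.coefficients) for t in trajectories])
        self.C_ab = np.array([self._pad(t.ab_poly.coefficients) for t in trajectories])

    def _pad(self, coef: tuple[float, ...]) -> np.ndarray:
        out = np.zeros(self.max_len)
        out[: len(coef)] = coef
        return out

    @property
    def n(self) -> int:
        return len(self.ids)

    def distances(self, proto_L: np.ndarray, proto_A: np.ndarray) -> np.ndarray:
        """(n, K) matrix of integral shape distances to each prototype."""
        dl = self.L[:, None, :] - proto_L[None, :, :]
        da = self.A[:, None, :] - proto_A[None, :, :]
        return np.hypot(dl, da) @ self.weights

    def mean_coeffs(self, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c_ls = self.C_ls[members].mean(axis=0)
        c_ab = self.C_ab[members].mean(axis=0)
        c_ls[0] = 0.0
        c_ab[0] = 0.0
        return c_ls, c_ab

    def node_values_from_coeffs(self, c_ls: np.ndarray, c_ab: np.ndarray):
        u = self.days - self.center
        d_ls = np.polynomial.polynomial.polyder(c_ls)
        d_ab = np.polynomial.polynomial.polyder(c_ab)
        return (
            np.polynomial.polynomial.polyval(u, d_ls),
            np.polynomial.polynomial.polyval(u, d_ab),
        )

    def prototype(self, k: int, c_ls: np.ndarray, c_ab: np.ndarray) -> Prototype:
        def trim(c: np.ndarray) -> tuple[float, ...]:
            nz = np.nonzero(np.abs(c) > 0)[0]
            upto = max(2, (nz.max() + 1) if len(nz) else 2)
            return tuple(c[:upto])

        return Prototype(
            k=k,
            ls_poly=PolyTrajectory(trim(c_ls), center=self.center, window=self.window),
            ab_poly=PolyTrajectory(trim(c_ab), center=self.center, window=self.window),
        )


def assign_step(
    trajectories: Sequence[Trajectory3D],
    prototypes: Sequence[Prototype],
    n_nodes: int = DEFAULT_NODES,
) -> np.ndarray:
    """Assign every trajectory to its nearest prototype (ties go to the
    lowest cluster index)."""
    if not prototypes:
        raise ConfigError("need at least one prototype")
    space = _NodeSpace(trajectories, n_nodes)
    pL = np.array([_deriv_at(p.ls_poly, space.days) for p in prototypes])
    pA = np.array([_deriv_at(p.ab_poly, space.days) for p in prototypes])
    return space.distances(pL, pA).argmin(axis=1)


def update_step(
    trajectories: Sequence[Trajectory3D],
    assignments: np.ndarray,
    K: int,
    n_nodes: int = DEFAULT_NODES,
) -> list[Prototype]:
    """Recompute each prototype as the coefficient-wise mean of its
    members (zero-padded to the max member degree, intercept forced to
    zero).  An empty cluster is reseeded to the trajectory farthest from
    its currently assigned prototype."""
    space = _NodeSpace(trajectories, n_nodes)
    assignments = np.asarray(assignments)
    coeffs: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(K):
        members = np.where(assignments == k)[0]
        if len(members):
            coeffs.append(space.mean_coeffs(members))
        else:
            coeffs.append((None, None))  # type: ignore[arg-type]
    # reseed empties against the non-empty prototypes
    empty = [k for k in range(K) if coeffs[k][0] is None]
    if empty:
        pL = np.array(
            [space.node_values_from_coeffs(*c)[0] if c[0] is not None else np.zeros_like(space.days) for c in coeffs]
        )
        pA = np.array(
            [space.node_values_from_coeffs(*c)[1] if c[0] is not None else np.zeros_like(space.days) for c in coeffs]
        )
        D = space.distances(pL, pA)
        own = D[np.arange(space.n), assignments]
        used: set[int] = set()
        for k in empty:
            order = np.argsort(-own)
            pick = next(int(i) for i in order if int(i) not in used)
            used.add(pick)
            c_ls = space.C_ls[pick].copy()
            c_ab = space.C_ab[pick].copy()
            c_ls[0] = 0.0
            c_ab[0] = 0.0
            coeffs[k] = (c_ls, c_ab)
    return [space.prototype(k, *coeffs[k]) for k in range(K)]


def _run_restart(
    space: _NodeSpace,
    K: int,
    init_idx: np.ndarray,
    max_iter: int,
    tol: float,
):
    """One K-means restart in node space.  Returns (assign, W, coeff
    prototypes, trace, n_iter, converged)."""
    c_ls = space.C_ls[init_idx].copy()
    c_ab = space.C_ab[init_idx].copy()
    c_ls[:, 0] = 0.0
    c_ab[:, 0] = 0.0
    pL = space.L[init_idx].copy()
    pA = space.A[init_idx].copy()

    prev_assign: np.ndarray | None = None
    prev_W = np.inf
    prev_state = (pL, pA, c_ls, c_ab)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        D = space.distances(pL, pA)
        assign = D.argmin(axis=1)
        W = float(D[np.arange(space.n), assign].sum())
        # descent guard: an update that increased the objective is undone
        if W > prev_W + 1e-12:
            assign, W = prev_assign, prev_W  # type: ignore[assignment]
            pL, pA, c_ls, c_ab = prev_state
            converged = True
            break
        trace.append(W)
        if prev_assign is not None and (
            np.array_equal(assign, prev_assign) or prev_W - W < tol
        ):
            converged = True
            break
        prev_assign, prev_W = assign, W
        prev_state = (pL, pA, c_ls, c_ab)
        # update step: coefficient means, empty clusters reseeded to the
        # trajectory farthest from its current prototype
        new_c_ls = np.zeros_like(c_ls)
        new_c_ab = np.zeros_like(c_ab)
        empty: list[int] = []
        for k in range(K):
            members = np.where(assign == k)[0]
            if len(members):
                new_c_ls[k], new_c_ab[k] = space.mean_coeffs(members)
            else:
                empty.append(k)
        if empty:
            own = D[np.arange(space.n), assign]
            order = np.argsort(-own)
            used: set[int] = set()
            for k in empty:
                pick = next(int(i) for i in order if int(i) not in used)
                used.add(pick)
                new_c_ls[k] = space.C_ls[pick]
                new_c_ab[k] = space.C_ab[pick]
                new_c_ls[k, 0] = 0.0
                new_c_ab[k, 0] = 0.0
        c_ls, c_ab = new_c_ls, new_c_ab
        for k in range(K):
            pL[k], pA[k] = space.node_values_from_coeffs(c_ls[k], c_ab[k])
    return assign, W, (c_ls, c_ab), trace, n_iter, converged


def kmeans_shape(
    trajectories: Sequence[Trajectory3D],
    K: int,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_nodes: int = DEFAULT_NODES,
) -> ClusterSolution:
    """Modified K-means on trajectory shape.

    Each restart initialises the K prototypes as distinct randomly chosen
    participant trajectories (intercepts zeroed), then alternates
    assignment (nearest prototype under the integral shape distance) and
    update (coefficient mean) until assignments stop changing, the
    objective improvement falls below ``tol``, or ``max_iter`` is hit.
    The restart with the smallest objective wins.  Deterministic given
    ``seed``.
    """
    space = _NodeSpace(trajectories, n_nodes)
    if not 1 <= K <= space.n:
        raise ConfigError(f"K={K} must be in [1, {space.n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        init_idx = rng.choice(space.n, size=K, replace=False)
        result = _run_restart(space, K, init_idx, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
    assign, W, (c_ls, c_ab), trace, n_iter, converged = best
    prototypes = [space.prototype(k, c_ls[k], c_ab[k]) for k in range(K)]
    return ClusterSolution(
        K=K,
        participant_ids=list(space.ids),
        assignments={pid: int(k) for pid, k in zip(space.ids, assign)},
        prototypes=prototypes,
        objective=W,
        n_iter=n_iter,
        seed=seed,
        restarts=restarts,
        converged=converged,
        objective_trace=trace,
    )


def scree_select(
    trajectories: Sequence[Trajectory3D],
    k_range: Iterable[int] = range(1, 11),
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_nodes: int = DEFAULT_NODES,
    method: str = "chord",
) -> ScreeTable:
    """Run K-means over a range of K and pick the scree elbow.

    ``method='chord'`` (default) selects the interior K whose objective
    lies farthest below the chord joining the first and last points of
    the W(K) curve — the point where the decline levels off, which is
    what reading a scree plot by eye does.  ``method='second_difference'``
    instead maximises ``W(K-1) - 2 W(K) + W(K+1)``; on objectives whose
    drops decay geometrically that curvature is dominated by the very
    first split, so it is not the default.  The full table is kept so
    solutions around the elbow can be compared descriptively.
    """
    if method not in ("chord", "second_difference"):
        raise ConfigError("method must be 'chord' or 'second_difference'")
    ks = sorted(set(int(k) for k in k_range))
    solutions: dict[int, ClusterSolution] = {}
    for k in ks:
        solutions[k] = kmeans_shape(
            trajectories, k, seed=seed + k, restarts=restarts,
            max_iter=max_iter, tol=tol, n_nodes=n_nodes,
        )
    W = {k: solutions[k].objective for k in ks}
    selected = None
    interior = [k for k in ks if (k - 1) in W and (k + 1) in W]
    if interior:
        if method == "second_difference":
            curvature = {k: W[k - 1] - 2 * W[k] + W[k + 1] for k in interior}
            selected = max(interior, key=lambda k: (curvature[k], -k))
        else:
            k0, k1 = ks[0], ks[-1]
            slope = (W[k1] - W[k0]) / (k1 - k0) if k1 > k0 else 0.0
            gap = {k: (W[k0] + slope * (k - k0)) - W[k] for k in interior}
            selected = max(interior, key=lambda k: (gap[k], -k))
    table = pd.DataFrame(
        {
            "K": ks,
            "objective": [W[k] for k in ks],
            "n_restarts": restarts,
            "selected": [k == selected for k in ks],
        }
    )
    return ScreeTable(table=table, selected_K=selected, solutions=solutions)


# ---------------------------------------------------------------------------
# interpretation


def _observed_cluster_means(
    solution: ClusterSolution,
    cohort: Cohort,
    design: StudyDesign,
    outcome: str,
    day: int,
) -> np.ndarray:
    df = cohort.assessments
    df = df[(df["sample_id"] == design.sample_id) & (df["day"] == day)].dropna(subset=[outcome])
    means = np.full(solution.K, np.nan)
    member = df["participant_id"].map(solution.assignments)
    df = df[member.notna()]
    member = member[member.notna()].astype(int)
    for k in range(solution.K):
        vals = df.loc[member == k, outcome]
        if len(vals):
            means[k] = vals.mean()
    return means


def _mid_day(design: StudyDesign) -> int:
    days = np.array(design.days_in_window())
    midpoint = 0.5 * (design.t_lo + design.t_hi)
    inner = days[(days != design.t_lo) & (days != design.t_hi)]
    cand = inner if len(inner) else days
    return int(cand[np.argmin(np.abs(cand - midpoint))])


def _shape_label(l0: float, lmid: float, lend: float, is_max_baseline: bool, delta: float) -> str:
    if is_max_baseline and abs(lend - l0) <= delta:
        return "nondistressed"
    if lmid - l0 > delta and lend - l0 > delta:
        return "lasting_benefit"
    if lmid - l0 > delta and abs(lend - l0) <= delta:
        return "hedonic_adaptation"
    return "residual"


def label_clusters(
    solution: ClusterSolution,
    cohort: Cohort,
    design: StudyDesign,
    delta: float = 2.0,
    ab_delta: float | None = None,
) -> tuple[dict[str, str], dict[int, str]]:
    """Name the K=4 clusters from their members' observed means.

    Per cluster the member mean LS at baseline (L0), mid-window (Lmid)
    and window end (Lend) drives the rule: *nondistressed* iff L0 is the
    cross-cluster maximum and the curve is stable (|Lend-L0| <= delta);
    *lasting_benefit* iff the mid-window rise exceeds delta and persists;
    *hedonic_adaptation* iff the rise exceeds delta but the end returns
    to baseline; otherwise *residual*.  The same rule on AB (with
    ``ab_delta``, default delta scaled by the AB/LS range ratio 8/3) must
    agree, else the cluster falls back to residual with a warning.

    For K != 4 no names are assigned (indices only).

    Returns ``(participant -> label, cluster index -> label)``.
    """
    if solution.K != 4:
        logger.warning("cluster naming is defined for K=4 only; got K=%d", solution.K)
        by_cluster = {k: f"cluster_{k}" for k in range(solution.K)}
        return (
            {p: by_cluster[k] for p, k in solution.assignments.items()},
            by_cluster,
        )
    if ab_delta is None:
        ab_delta = delta * 8.0 / 3.0
    mid = _mid_day(design)
    ls0 = _observed_cluster_means(solution, cohort, design, "ls", design.t_lo)
    lsm = _observed_cluster_means(solution, cohort, design, "ls", mid)
    lse = _observed_cluster_means(solution, cohort, design, "ls", design.t_hi)
    ab0 = _observed_cluster_means(solution, cohort, design, "ab", design.t_lo)
    abm = _observed_cluster_means(solution, cohort, design, "ab", mid)
    abe = _observed_cluster_means(solution, cohort, design, "ab", design.t_hi)
    by_cluster: dict[int, str] = {}
    for k in range(4):
        ls_label = _shape_label(ls0[k], lsm[k], lse[k], k == int(np.nanargmax(ls0)), delta)
        ab_label = _shape_label(ab0[k], abm[k], abe[k], k == int(np.nanargmax(ab0)), ab_delta)
        if ls_label != ab_label:
            logger.warning(
                "cluster %d: LS rule says %s but AB rule says %s; falling back to residual",
                k, ls_label, ab_label,
            )
            by_cluster[k] = "residual"
        else:
            by_cluster[k] = ls_label
    by_participant = {p: by_cluster[k] for p, k in solution.assignments.items()}
    return by_participant, by_cluster


def apply_display_intercept(
    prototype: Prototype,
    member_ids: Iterable[str],
    cohort: Cohort,
) -> Prototype:
    """Anchor a prototype for plotting: set display intercepts so the
    curve passes through the member mean observed (LS, AB) at the
    centering day.  Distances are untouched (intercept invariance)."""
    member_ids = set(member_ids)
    center = prototype.ls_poly.center
    df = cohort.assessments
    df = df[(df["day"] == center) & df["participant_id"].isin(member_ids)]
    if not len(df):
        logger.warning("prototype %d has no member observations at day %d; anchoring at 0",
                       prototype.k, center)
        return replace(prototype, display_intercepts=(0.0, 0.0))
    return replace(
        prototype,
        display_intercepts=(float(df["ls"].mean()), float(df["ab"].mean())),
    )
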