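"""End-to-end orchestration: simulate/load -> filter -> fit -> cluster ->
infer -> usage-model, with reproducible, manifest-logged artifacts.

Each sample is clustered and analysed separately (distances are never
taken across samples); correlations, the attrition comparison and the
usage GLM pool observations afterwards.  Re-running with an identical
config and seed reproduces byte-identical CSV/JSON artifacts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, inference, trajectories, usage as usage_models
from .cohort import (
    Cohort,
    ConfigError,
    StudyDesign,
    default_designs,
    eligibility_filter,
    load_designs,
    pairwise_view,
    read_cohort,
    write_cohort,
)
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "load_run_config", "run_pipeline", "EPOCHS"]

logger = logging.getLogger(__name__)

#: pooled cross-sample assessment epochs, by day-since-pretest
EPOCHS: dict[str, tuple[int, ...]] = {
    "early": (0, 7),
    "middle": (37, 42),
    "late": (72, 97, 132),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``synthetic`` (a :class:`CohortConfig`) or
    ``assessments_path`` must be supplied.
    """

    outdir: str | Path = "wbtraj_run"
    synthetic: CohortConfig | None = None
    assessments_path: str | Path | None = None
    usage_path: str | Path | None = None
    truth_path: str | Path | None = None
    designs_path: str | Path | None = None
    seed: int = 0
    k: int | None = None
    k_range: tuple[int, int] = (1, 10)
    restarts: int = 20
    max_iter: int = 100
    quad_nodes: int = clustering.DEFAULT_NODES
    label_delta: float = 2.0
    min_points: int = 4
    selection: str = "aic"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.assessments_path is None):
            raise ConfigError(
                "supply exactly one of a synthetic config or an assessments CSV path"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML/JSON.  A ``synthetic:`` block mirrors
    CohortConfig fields; a ``data:`` block gives input CSV paths."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    kwargs: dict = {k: v for k, v in raw.items() if k not in ("synthetic", "data")}
    if "k_range" in kwargs:
        kwargs["k_range"] = tuple(kwargs["k_range"])
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        kwargs["synthetic"] = dataclasses.replace(CohortConfig(), **syn)
    if "data" in raw and raw["data"] is not None:
        d = raw["data"]
        kwargs["assessments_path"] = d.get("assessments")
        kwargs["usage_path"] = d.get("usage")
        kwargs["truth_path"] = d.get("truth")
        kwargs["designs_path"] = d.get("designs")
    return RunConfig(**kwargs)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.integer, np.floating)):
            return str(o)
        if isinstance(o, tuple):
            return list(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _anova_frame(tables: list[tuple[str, str, inference.AnovaTable]]) -> pd.DataFrame:
    frames = []
    for scope, outcome, tab in tables:
        df = tab.table.copy()
        df.insert(0, "outcome", outcome)
        df.insert(0, "scope", scope)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts plus a manifest to
    ``config.outdir``.  Returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": stages,
    }
    try:
        manifest["versions"]["wbtraj"] = pkg_version("wbtraj")
    except PackageNotFoundError:  # pragma: no cover
        manifest["versions"]["wbtraj"] = "unknown"

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                info = fn() or {}
            except Exception as exc:
                (outdir / "manifest.json").write_text(
                    json.dumps({**manifest, "failed_stage": name, "error": str(exc)},
                               indent=2, default=str)
                )
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3),
                           **info})
            return info
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        if config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            designs = (
                load_designs(config.designs_path) if config.designs_path else default_designs()
            )
            cohort = generate_cohort(syn, designs)
            write_cohort(cohort, outdir / "assessments.csv", outdir / "usage.csv",
                         outdir / "truth_labels.csv")
        else:
            designs = (
                load_designs(config.designs_path) if config.designs_path else default_designs()
            )
            cohort = read_cohort(config.assessments_path, designs,
                                 config.usage_path, config.truth_path)
        state["cohort"] = cohort
        return {"participants": len(cohort.participants()),
                "assessment_rows": len(cohort.assessments),
                "usage_rows": len(cohort.usage)}

    @stage("filter")
    def _filter():
        cohort: Cohort = state["cohort"]
        included, excluded = eligibility_filter(cohort, min_points=config.min_points)
        state["included"], state["excluded"] = included, excluded
        pd.DataFrame(
            sorted([(p, "included") for p in included] + [(p, "excluded") for p in excluded]),
            columns=["participant_id", "status"],
        ).to_csv(outdir / "eligibility.csv", index=False)
        return {"included": len(included), "excluded": len(excluded),
                "rule": f">={config.min_points} points in both LS and AB"}

    @stage("fit")
    def _fit():
        cohort: Cohort = state["cohort"]
        trajs, skipped = trajectories.fit_cohort(cohort, state["included"])
        state["trajectories"] = trajs
        trajectories.trajectories_to_frame(trajs).to_csv(
            outdir / "trajectories.csv", index=False
        )
        return {"fitted": len(trajs), "skipped": len(skipped),
                "skip_reasons": sorted(set(skipped.values()))}

    @stage("cluster")
    def _cluster():
        cohort: Cohort = state["cohort"]
        solutions: dict[str, clustering.ClusterSolution] = {}
        scree_rows = []
        for sample_id, design in sorted(cohort.designs.items()):
            trajs = [t for t in state["trajectories"] if t.sample_id == sample_id]
            if not trajs:
                continue
            if config.k is not None:
                sol = clustering.kmeans_shape(
                    trajs, config.k, seed=config.seed, restarts=config.restarts,
                    max_iter=config.max_iter, n_nodes=config.quad_nodes,
                )
            else:
                lo, hi = config.k_range
                scree = clustering.scree_select(
                    trajs, range(lo, min(hi, len(trajs)) + 1), seed=config.seed,
                    restarts=config.restarts, max_iter=config.max_iter,
                    n_nodes=config.quad_nodes,
                )
                df = scree.table.copy()
                df.insert(0, "sample_id", sample_id)
                scree_rows.append(df)
                pick = scree.selected_K if scree.selected_K in scree.solutions else max(scree.solutions)
                sol = scree.solutions[pick]
            solutions[sample_id] = sol
        if scree_rows:
            pd.concat(scree_rows, ignore_index=True).to_csv(
                outdir / "scree.csv", index=False
            )
        state["solutions"] = solutions
        return {"samples": sorted(solutions),
                "K": {s: sol.K for s, sol in solutions.items()},
                "objective": {s: round(sol.objective, 6) for s, sol in solutions.items()}}

    @stage("label")
    def _label():
        cohort: Cohort = state["cohort"]
        labels: dict[str, str] = {}
        rows = []
        proto_export: dict[str, list] = {}
        for sample_id, sol in state["solutions"].items():
            design = cohort.design_of(sample_id)
            by_p, by_k = clustering.label_clusters(
                sol, cohort, design, delta=config.label_delta
            )
            labels.update(by_p)
            for pid, k in sol.assignments.items():
                rows.append((pid, sample_id, k, by_k[k]))
            protos = []
            for proto in sol.prototypes:
                members = [p for p, k in sol.assignments.items() if k == proto.k]
                anchored = clustering.apply_display_intercept(proto, members, cohort)
                protos.append({
                    "k": proto.k,
                    "label": by_k[proto.k],
                    "ls_coefficients": list(anchored.ls_poly.coefficients),
                    "ab_coefficients": list(anchored.ab_poly.coefficients),
                    "center": anchored.ls_poly.center,
                    "window": list(anchored.ls_poly.window),
                    "display_intercepts": list(anchored.display_intercepts),
                })
            proto_export[sample_id] = protos
        state["labels"] = labels
        pd.DataFrame(rows, columns=["participant_id", "sample_id", "cluster_index",
                                    "cluster_label"]).sort_values(
            "participant_id"
        ).to_csv(outdir / "clusters.csv", index=False)
        (outdir / "prototypes.json").write_text(json.dumps(proto_export, indent=2))
        counts = pd.Series(labels).value_counts().to_dict()
        return {"labels": counts}

    @stage("infer")
    def _infer():
        cohort: Cohort = state["cohort"]
        labels = state["labels"]
        anovas: list[tuple[str, str, inference.AnovaTable]] = []
        posthoc_frames = []
        for sample_id, sol in state["solutions"].items():
            design = cohort.design_of(sample_id)
            days = design.days_in_window()
            sample_view = cohort.assessments[cohort.assessments["sample_id"] == sample_id]
            for outcome in ("ls", "ab"):
                try:
                    anovas.append(
                        (sample_id, outcome,
                         inference.mixed_anova_4x4(sample_view, labels, days, outcome))
                    )
                except ConfigError as exc:
                    logger.warning("mixed ANOVA skipped for %s/%s: %s",
                                   sample_id, outcome, exc)
                    continue
                n_groups = len(set(labels[p] for p in sol.assignments))
                family = len(days) * n_groups * (n_groups - 1) // 2
                for day in days:
                    ph = inference.posthoc_pairwise(
                        sample_view, labels, day, family_size=family, outcome=outcome
                    )
                    df = ph.table.copy()
                    df.insert(0, "outcome", outcome)
                    df.insert(0, "sample_id", sample_id)
                    posthoc_frames.append(df)
        for epoch, days in EPOCHS.items():
            view = cohort.assessments[cohort.assessments["day"].isin(days)]
            if not len(view) or view["sample_id"].nunique() < 2:
                continue
            for outcome in ("ls", "ab"):
                try:
                    anovas.append(
                        (f"epoch:{epoch}", outcome,
                         inference.cross_sample_anova(view, labels, outcome))
                    )
                except ConfigError as exc:
                    logger.warning("cross-sample ANOVA skipped for %s/%s: %s",
                                   epoch, outcome, exc)
        if anovas:
            _anova_frame(anovas).to_csv(outdir / "anova.csv", index=False)
        if posthoc_frames:
            pd.concat(posthoc_frames, ignore_index=True).to_csv(
                outdir / "posthoc.csv", index=False
            )
        corr_rows = []
        for a, b in (("cesd", "ls"), ("cesd", "ab"), ("ls", "ab")):
            view = pairwise_view(cohort, [a, b])
            res = inference.pearson_corr(view[a], view[b])
            corr_rows.append({"pair": f"{a}-{b}", "r": res.r, "ci_low": res.ci_low,
                              "ci_high": res.ci_high, "p": res.p, "n": res.n})
        pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)
        report = inference.attrition_compare(cohort, state["included"], state["excluded"])
        report.outcomes.assign(chi2=report.chi2, chi2_df=report.chi2_df,
                               chi2_p=report.chi2_p).to_csv(
            outdir / "comparisons.csv", index=False
        )
        return {"anovas": len(anovas), "correlations": len(corr_rows),
                "attrition_chi2": round(report.chi2, 3)}

    @stage("usage_model")
    def _usage_model():
        cohort: Cohort = state["cohort"]
        data = usage_models.build_usage_data(cohort, state["labels"])
        result = usage_models.backward_select(
            data, criterion=config.selection, alpha=config.alpha
        )
        null_fit = usage_models.fit_binomial_glm(data, terms=())
        r2 = usage_models.pseudo_r2(result.chosen, null_fit)
        summary = {
            "n": result.chosen.n,
            "selection": config.selection,
            "removed": result.removed,
            "terms": list(result.chosen.terms),
            "b": result.chosen.b.round(6).to_dict(),
            "se": result.chosen.se.round(6).to_dict(),
            "z": result.chosen.z.round(4).to_dict(),
            "p": result.chosen.p.round(6).to_dict(),
            "beta_std": result.chosen.beta_std.round(6).to_dict(),
            "loglik": result.chosen.loglik,
            "aic": usage_models.aic(result.chosen),
            "deviance": result.chosen.deviance,
            "pseudo_r2": dataclasses.asdict(r2),
        }
        (outdir / "usage_model.json").write_text(json.dumps(summary, indent=2))
        comp_rows = []
        for i, fit in enumerate(result.fits):
            comp_rows.append({
                "model": i, "terms": "+".join(fit.terms) or "intercept",
                "df": fit.k, "loglik": round(fit.loglik, 4),
                "aic": round(usage_models.aic(fit), 4),
                "deviance": round(fit.deviance, 4),
                "chi2_vs_previous": round(result.comparisons[i - 1].chi2, 4) if i else np.nan,
                "p_vs_previous": round(result.comparisons[i - 1].p, 6) if i else np.nan,
            })
        pd.DataFrame(comp_rows).to_csv(outdir / "model_comparison.csv", index=False)
        return {"chosen_terms": list(result.chosen.terms), "n_obs": result.chosen.n}

    @stage("report")
    def _report():
        counts = {
            "participants": len(state["cohort"].participants()),
            "included": len(state["included"]),
            "fitted": len(state["trajectories"]),
            "clustered": sum(len(s.assignments.values()) for s in state["solutions"].values()),
        }
        return counts

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
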