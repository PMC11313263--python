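"""End-to-end study-arm pipeline.

One call runs a full arm — synthesise cohort, trim to the requested
extent, register, build the shape atlas, extract shape vectors, cluster
(correlation + WPGMA by default), cross-tabulate clusters against
surgical groups with a chi-squared test, and compare whole-aorta
morphometrics across clusters with Kruskal–Wallis and Dunn tests.
Every stage's outputs land as open CSV/JSON files and everything is
deterministic given the cohort seed.

The pre- and post-operative arms are independent cohorts (different
patients), so nothing here pretends they are paired; cross-arm
comparison is limited to cluster-label agreement (adjusted Rand index)
between the ascending and whole-aorta trims of the *same* cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import clustering as cl
from . import morphometrics as morpho
from . import ssm
from . import stats as st
from .errors import InvalidParameterError
from .synthetic import (
    CohortConfig,
    GroupSpec,
    ShapePopulation,
    preop_cohort,
    postop_cohort,
    sample_population,
    trim_population,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_arms", "load_run_config"]

log = logging.getLogger(__name__)

_MORPHO_METRICS = ("centreline_length_mm", "tortuosity",
                   "sa_v_ratio_per_mm", "asc_desc_ratio")


@dataclass(frozen=True)
class RunConfig:
    """One study arm: cohort recipe + extent + analysis settings."""

    cohort: CohortConfig
    phase: str = "pre"                 # "pre" | "post" (bookkeeping label)
    extent: str = "ascending"          # "ascending" | "whole"
    kernel: ssm.KernelParams | None = None
    mode_threshold: float = 0.7
    metric: str = "correlation"
    linkage: str = "mcquitty"
    cut_height: float | None = 1.0
    cut_k: int | None = None
    dunn_adjustment: str = "none"
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise InvalidParameterError("phase must be 'pre' or 'post'")
        if self.extent not in ("ascending", "whole"):
            raise InvalidParameterError("extent must be 'ascending' or 'whole'")
        if (self.cut_height is None) == (self.cut_k is None):
            raise InvalidParameterError("set exactly one of cut_height / cut_k")


@dataclass
class RunReport:
    """In-memory results of one arm plus the manifest of files written."""

    config: RunConfig
    population: ShapePopulation
    atlas: ssm.ShapeAtlas
    dendrogram: cl.Dendrogram
    assignment: cl.ClusterAssignment
    contingency: cl.ContingencyTable
    chi2: st.TestResult | None
    profiles: pd.DataFrame
    kw_dunn: pd.DataFrame
    summary: dict
    files: list[str] = field(default_factory=list)


def _cluster_stats(profiles: pd.DataFrame, adjustment: str) -> pd.DataFrame:
    """Kruskal–Wallis + Dunn contrasts per morphometric, across clusters."""
    rows = []
    clusters = sorted(profiles["cluster"].unique())
    names = [str(c) for c in clusters]
    for metric in _MORPHO_METRICS:
        samples = [profiles.loc[profiles["cluster"] == c, metric].to_numpy()
                   for c in clusters]
        if len(samples) >= 2:
            kw = st.kruskal_wallis(samples)
            rows.append({"metric": metric, "test": "kruskal_wallis", "pair": "",
                         "statistic": kw.statistic, "df": kw.df, "p": kw.p})
            for res in st.dunn_pairwise(samples, adjustment, names):
                rows.append({"metric": metric, "test": res.method,
                             "pair": f"{res.pair[0]}-{res.pair[1]}",
                             "statistic": res.statistic, "df": "", "p": res.p})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one arm end to end; see module docstring for the stages.

    Raises from the failing stage with the stage named; if an output
    directory is set, partial outputs stay on disk next to a FAILED
    marker naming the stage.
    """
    out = Path(config.output_dir) if config.output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        cohort = config.cohort
        population = sample_population(cohort)
        n = population.n_subjects
        log.info("generated %d subjects (seed=%d)", n, cohort.seed)

        stage = "trim"
        if config.extent == "ascending":
            cut = population.ground_truth[0].params.asc_fraction
            analysed = trim_population(population, cut)
        else:
            analysed = population

        stage = "register"
        registered = ssm.barycentre_register(analysed)

        stage = "atlas"
        atlas = ssm.compute_atlas(registered, config.kernel)
        n_modes = ssm.n_modes_for(atlas, config.mode_threshold)
        truth0 = population.ground_truth[0]
        landmarks = np.array([0.04 * truth0.params.asc_fraction + 0.02,
                              truth0.params.mid_asc_fraction,
                              0.93 * truth0.params.asc_fraction])
        if config.extent == "ascending":
            # template centreline re-extracted from the trimmed template grid
            na, nc = atlas.grid_shape
            tmpl_cl = morpho.extract_centreline(atlas.template.reshape(na, nc, 3))
            tmpl_landmarks = np.array([0.06, 0.5, 0.93])
        else:
            na, nc = atlas.grid_shape
            tmpl_cl = morpho.extract_centreline(atlas.template.reshape(na, nc, 3))
            tmpl_landmarks = landmarks
        diameters = ssm.template_diameters(atlas, tmpl_cl, tmpl_landmarks)

        stage = "shape_vectors"
        vectors = ssm.shape_vectors(registered)

        stage = "cluster"
        D = cl.dissimilarity_matrix(vectors, config.metric)
        dendro = cl.agglomerate(
            D, config.linkage,
            leaf_labels=population.covariates["subject_id"].tolist(),
        )
        if config.cut_k is not None:
            assignment = cl.cut_to_k(dendro, config.cut_k)
        else:
            assignment = cl.cut_at_height(dendro, config.cut_height)

        stage = "contingency"
        table = cl.cluster_contingency(
            assignment, population.group_labels,
            group_order=list(cohort.groups.keys()),
        )
        if assignment.k < 2:
            log.warning("single cluster at this cut: chi-squared test skipped")
            chi2 = None
        else:
            chi2 = st.pearson_chi_squared(table)

        stage = "morphometrics"
        profiles = morpho.population_profiles(population, assignment.labels)

        stage = "cluster_stats"
        kw_dunn = _cluster_stats(profiles, config.dunn_adjustment)

        stage = "report"
        majority = {
            g: cl.majority_cluster_fraction(assignment, population.group_labels, g)
            for g in cohort.groups
        }
        inertia = atlas.cumulative_inertia_curve
        summary = {
            "phase": config.phase,
            "extent": config.extent,
            "seed": cohort.seed,
            "n_subjects": n,
            "group_sizes": {g: int(s.n_subjects) for g, s in cohort.groups.items()},
            "n_modes_for_threshold": int(n_modes),
            "mode_threshold": config.mode_threshold,
            "cumulative_inertia_first4": [round(float(x), 6) for x in inertia[:4]],
            "template_diameters_mm": [round(float(d), 4) for d in diameters],
            "metric": config.metric,
            "linkage": config.linkage,
            "cut": {"kind": assignment.cut_kind, "value": assignment.cut},
            "n_clusters": int(assignment.k),
            "cluster_sizes": np.bincount(assignment.labels)[1:].tolist(),
            "chi2": None if chi2 is None else {
                "statistic": round(chi2.statistic, 6),
                "df": chi2.df, "p": round(chi2.p, 8),
            },
            "majority_cluster_fraction": {k: round(v, 6) for k, v in majority.items()},
            "mode1_size_abs_r": round(_mode1_size_corr(atlas, registered), 6),
        }
        report = RunReport(config, population, atlas, dendro, assignment,
                           table, chi2, profiles, kw_dunn, summary)
        if out is not None:
            _write_outputs(report, out)
        return report
    except Exception:
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %r", stage)
        raise


def _mode1_size_corr(atlas: ssm.ShapeAtlas, population: ShapePopulation) -> float:
    areas = np.array([population.subject_area(i)
                      for i in range(population.n_subjects)])
    if np.std(atlas.scores[:, 0]) == 0 or np.std(areas) == 0:
        return 0.0
    return float(abs(np.corrcoef(atlas.scores[:, 0], areas)[0, 1]))


def _write_outputs(report: RunReport, out: Path) -> None:
    cov = report.population.covariates
    cov.to_csv(out / "manifest.csv", index=False)
    report.atlas.save(out / "atlas")
    scatter = pd.DataFrame({
        "subject_id": cov["subject_id"],
        "group": cov["group"],
        "mode_1": report.atlas.scores[:, 0],
        "mode_2": report.atlas.scores[:, 1] if report.atlas.n_modes > 1 else 0.0,
    })
    scatter.to_csv(out / "scatter.csv", index=False)
    merges = pd.DataFrame(
        [(i + 1, a, b, h, s) for i, (a, b, h, s) in enumerate(report.dendrogram.merges)],
        columns=["step", "cluster_a", "cluster_b", "height", "size"],
    )
    merges.to_csv(out / "merges.csv", index=False)
    (out / "dendrogram.nwk").write_text(cl.to_newick(report.dendrogram) + "\n")
    pd.DataFrame({
        "subject_id": cov["subject_id"],
        "cluster": report.assignment.labels,
    }).to_csv(out / "labels.csv", index=False)
    report.contingency.to_frame().to_csv(out / "contingency.csv")
    (out / "chi2.json").write_text(json.dumps(
        report.summary["chi2"], indent=2, sort_keys=True) + "\n")
    report.profiles.to_csv(out / "profiles.csv", index=False)
    report.kw_dunn.to_csv(out / "kw_dunn.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True) + "\n"
    )
    report.files = sorted(p.name for p in out.iterdir())


def compare_arms(report_a: RunReport, report_b: RunReport) -> dict:
    """Cluster-label agreement between two trims of the same cohort.

    Cross-tabulates the two label vectors and reports the adjusted Rand
    index: 1 for identical partitions, ~0 for independent ones.
    """
    ids_a = report_a.population.covariates["subject_id"].tolist()
    ids_b = report_b.population.covariates["subject_id"].tolist()
    if ids_a != ids_b:
        raise InvalidParameterError("arms analysed different subject sets")
    la, lb = report_a.assignment.labels, report_b.assignment.labels
    cross = pd.crosstab(pd.Series(la, name=report_a.config.extent),
                        pd.Series(lb, name=report_b.config.extent))
    return {
        "adjusted_rand_index": float(adjusted_rand_score(la, lb)),
        "cross_tabulation": cross.to_numpy().tolist(),
        "n_clusters_a": int(report_a.assignment.k),
        "n_clusters_b": int(report_b.assignment.k),
    }


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Recognised keys: ``phase``, ``extent``, ``seed``, ``cohort`` (either
    the name of a default — ``preop``/``postop`` — or a mapping of group
    specs), ``clustering`` (metric/linkage/cut_height/cut_k), ``ssm``
    (lambda_v/lambda_w/mode_threshold), ``stats`` (dunn_adjustment),
    ``output_dir``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))
    cohort_spec = raw.get("cohort", "preop")
    if cohort_spec in ("preop", "pre"):
        cohort = preop_cohort(seed=seed)
    elif cohort_spec in ("postop", "post"):
        cohort = postop_cohort(seed=seed)
    elif isinstance(cohort_spec, dict):
        groups = {name: GroupSpec(**spec) for name, spec in cohort_spec.items()}
        cohort = CohortConfig(groups=groups, seed=seed)
    else:
        raise InvalidParameterError(f"unrecognised cohort spec {cohort_spec!r}")
    clus = raw.get("clustering", {})
    ssm_cfg = raw.get("ssm", {})
    kernel = None
    if "lambda_w" in ssm_cfg:
        kernel = ssm.KernelParams(
            stiffness_lambda_V=float(ssm_cfg.get("lambda_v", ssm_cfg["lambda_w"])),
            resolution_lambda_W=float(ssm_cfg["lambda_w"]),
        )
    cut_k = clus.get("cut_k")
    cut_height = clus.get("cut_height", None if cut_k is not None else 1.0)
    return RunConfig(
        cohort=cohort,
        phase=raw.get("phase", "pre"),
        extent=raw.get("extent", "ascending"),
        kernel=kernel,
        mode_threshold=float(ssm_cfg.get("mode_threshold", 0.7)),
        metric=clus.get("metric", "correlation"),
        linkage=clus.get("linkage", "mcquitty"),
        cut_height=cut_height,
        cut_k=cut_k,
        dunn_adjustment=raw.get("stats", {}).get("dunn_adjustment", "none"),
        output_dir=raw.get("output_dir"),
    )
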