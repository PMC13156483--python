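"""Config-driven orchestration: simulate -> measure -> stats -> shape -> report.

A run is described by a YAML config (see :class:`RunConfig`), executes
deterministically given its seeds, and writes CSV tables plus a JSON manifest
to the output directory. Stages can also be run individually from each
other's CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CohortTable, read_landmark_csv, write_landmark_csv, write_results_table
from .measure import (classify_asymmetry, compute_panel, default_panel,
                      eruption_score, panel_frame, penetrance_summary)
from .procrustes import GeneralizedProcrustes, ShapePCA, mirror_outline
from .rrpp import ShapeMANCOVA, reduce_model
from .simulate import CohortSpec, generate_cohort, generate_cusp_table
from .stats import compare_groups

log = logging.getLogger("craniomorph")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one input source.

    ``cohort`` holds CohortSpec overrides for synthetic input; ``input_csv``
    points at an existing long-format landmark CSV instead.
    """

    cohort: dict[str, Any] | None = None
    input_csv: str | None = None
    q: float = 5.0                      # FDR Q, percent
    alpha: float = 0.05
    stringent_alpha: float = 0.01
    fdr_procedure: str = "two-stage"
    iterations: int = 10_000            # permutation iterations for shape stats
    retention_threshold: float = 0.10
    seed: int = 0
    allow_cross_experimental: bool = False
    out_dir: str = "craniomorph_out"

    def validate(self) -> list[str]:
        problems = []
        if (self.cohort is None) == (self.input_csv is None):
            problems.append("exactly one input source required: 'cohort' or 'input_csv'")
        if not 0 < self.q < 100:
            problems.append(f"q must be in (0, 100), got {self.q}")
        for name in ("alpha", "stringent_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                problems.append(f"{name} must be in (0, 1), got {v}")
        if self.fdr_procedure not in ("two-stage", "bh"):
            problems.append(f"unknown fdr_procedure {self.fdr_procedure!r}")
        if self.iterations < 1:
            problems.append("iterations must be >= 1")
        if not 0 < self.retention_threshold < 1:
            problems.append(f"retention_threshold must be in (0, 1), got "
                            f"{self.retention_threshold}")
        if self.cohort is not None:
            try:
                spec = self.cohort_spec()
            except (TypeError, ValueError, KeyError) as exc:
                problems.append(f"invalid cohort spec: {exc}")
            else:
                from .measure import default_panel as _panel
                known = {d.name for d in _panel()}
                bad = [m for (_, m) in spec.effect_map if m not in known]
                if bad:
                    problems.append(f"effect map references unknown measurements: {bad}")
        return problems

    def cohort_spec(self) -> CohortSpec:
        params = dict(self.cohort or {})
        if "effect_map" in params and isinstance(params["effect_map"], dict):
            # YAML writes tuple keys as "genotype/measurement" strings
            fixed = {}
            for key, v in params["effect_map"].items():
                if isinstance(key, str):
                    g, m = key.split("/", 1)
                    fixed[(g, m)] = float(v)
                else:
                    fixed[tuple(key)] = float(v)
            params["effect_map"] = fixed
        if "asymmetry" in params:
            params["asymmetry"] = {g: (float(p), (float(lo), float(hi)))
                                   for g, (p, (lo, hi)) in
                                   ((g, (v[0], tuple(v[1]))) for g, v in
                                    params["asymmetry"].items())}
        params.setdefault("seed", self.seed)
        return CohortSpec(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> tuple[bool, list[str]]:
    """Load and check a config file; returns (valid, list of problems)."""
    try:
        config = RunConfig.from_yaml(path)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        return False, [str(exc)]
    problems = config.validate()
    return not problems, problems


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write outputs; returns the manifest dict."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # -- stage: input ------------------------------------------------------
    log.info("stage simulate/load")
    cusp_table = None
    truth = None
    if config.cohort is not None:
        spec = config.cohort_spec()
        cohort, truth = generate_cohort(spec)
        cusp_table = generate_cusp_table(spec, truth)
        write_landmark_csv(cohort, out / "landmarks.csv")
        write_results_table(truth.frame(), out / "ground_truth.csv")
        write_results_table(cusp_table, out / "cusp_states.csv")
    else:
        cohort = read_landmark_csv(config.input_csv)
    manifest["stages"]["input"] = {"n_configurations": len(cohort.configurations),
                                   "n_specimens": len(cohort.specimen_ids())}

    # -- stage: measure ----------------------------------------------------
    log.info("stage measure")
    panel = panel_frame(compute_panel(cohort, default_panel()))
    write_results_table(panel, out / "panel.csv")
    deviations = (panel[panel["measurement"] == "snout_deviation"]
                  .set_index("specimen_id")["raw"].to_dict())
    genotypes = {s: cohort.genotype_of(s) for s in cohort.specimen_ids()}
    control_ids = [s for s, g in genotypes.items() if g == "control"]
    grades = classify_asymmetry(deviations, control_ids, genotypes)
    write_results_table(grades, out / "asymmetry_grades.csv")
    write_results_table(penetrance_summary(grades), out / "asymmetry_penetrance.csv")
    if cusp_table is not None:
        write_results_table(eruption_score(cusp_table, genotypes),
                            out / "eruption_summary.csv")
    manifest["stages"]["measure"] = {"n_panel_rows": len(panel)}

    # -- stage: stats ------------------------------------------------------
    log.info("stage stats")
    comparisons = compare_groups(
        panel, q=config.q, stringent_alpha=config.stringent_alpha,
        fdr_procedure=config.fdr_procedure,
        allow_cross_experimental=config.allow_cross_experimental)
    write_results_table(comparisons, out / "group_comparisons.csv")
    manifest["stages"]["stats"] = {"n_comparisons": len(comparisons)}

    # -- stage: shape ------------------------------------------------------
    log.info("stage shape")
    shape_manifest = run_shape_stage(cohort, out, iterations=config.iterations,
                                     seed=config.seed, alpha=config.alpha,
                                     retention_threshold=config.retention_threshold)
    manifest["stages"]["shape"] = shape_manifest

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def run_shape_stage(cohort: CohortTable, out: Path, *, iterations: int = 10_000,
                    seed: int = 0, alpha: float = 0.05,
                    retention_threshold: float = 0.10) -> dict[str, Any]:
    """GPA + shape PCA + MANCOVA + pairwise tests on the process outlines.

    Right-side outlines are mirrored before superimposition; log mandible
    centroid size (mean of the specimen's two 3D hemimandibles) is the
    protected covariate.
    """
    outlines = []
    rows = []
    mand_rcs: dict[str, list[float]] = {}
    from .measure import root_centroid_size

    for c in cohort.select(structure="mandible"):
        mand_rcs.setdefault(c.specimen_id, []).append(root_centroid_size(c))
    for c in cohort.select(structure="outline"):
        cfg = mirror_outline(c) if c.side == "right" else c
        outlines.append(cfg)
        rows.append({"specimen_id": c.specimen_id, "side": c.side,
                     "genotype": c.genotype, "sex": c.sex,
                     "log_size": float(np.log(np.mean(mand_rcs[c.specimen_id])))})
    if len(outlines) < 3:
        return {"skipped": "fewer than 3 outlines"}
    design = pd.DataFrame(rows)
    fit = GeneralizedProcrustes(outlines).fit()
    model = ShapePCA(fit, retention_threshold=retention_threshold).fit()
    pca_table = pd.DataFrame({
        "axis": [f"PC{i + 1}" for i in range(model.n_axes)],
        "variance_pct": model.variance_pct,
        "retained": [i in set(model.retained.tolist()) for i in range(model.n_axes)],
    })
    write_results_table(pca_table, out / "shape_pca.csv")
    scores = model.retained_scores()
    if scores.shape[1] == 0:
        scores = model.scores[:, :1]

    terms = ["genotype", "sex", "side", "log_size",
             "genotype:sex", "genotype:side", "sex:side"]
    covariates = ["log_size"]
    if design["log_size"].nunique() == 1:
        log.warning("no centroid-size variation; dropping the size covariate")
        terms.remove("log_size")
        covariates = []
    single_level = [t for t in ("sex", "side") if design[t].nunique() == 1]
    if single_level:
        terms = [t for t in terms
                 if not any(s in t.split(":") for s in single_level)]
    # Drop terms the realized design cannot estimate (e.g. an empty
    # genotype x sex cell) before reduction rather than failing the run.
    from .rrpp import CollinearDesignError, build_design, _check_collinear

    while True:
        try:
            x, spans = build_design(design, terms, covariates)
            _check_collinear(x, spans)
            break
        except CollinearDesignError as exc:
            # interactions first; then a covariate that genotype/sex fully
            # determine (e.g. log size in a deterministic synthetic cohort)
            aliased = [t for t in exc.aliased if ":" in t] or \
                [t for t in exc.aliased if t in covariates]
            if not aliased:
                raise
            covariates = [c for c in covariates if c not in aliased]
            log.warning("dropping aliased terms from initial shape model: %s", aliased)
            terms = [t for t in terms if t not in aliased]
    final_terms, final_fit = reduce_model(
        scores, design, terms, covariates=covariates, protected=covariates,
        alpha=alpha, iterations=iterations, seed=seed)
    final_fit.table.to_csv(out / "shape_mancova.csv")
    (out / "shape_model_terms.txt").write_text(
        "\n".join(final_terms) + "\n", encoding="utf-8")

    if "genotype" in final_terms:
        pw = final_fit.model.pairwise_means("genotype", iterations=iterations, seed=seed)
        write_results_table(pw, out / "shape_pairwise_means.csv")
    slope_terms = [t for t in final_terms if t != "genotype:log_size"]
    slope_terms = list(dict.fromkeys(
        [t for t in slope_terms if t in ("genotype", "log_size")]))
    if "genotype" in slope_terms and "log_size" in slope_terms:
        slope_model = ShapeMANCOVA(scores, design,
                                   ["genotype", "log_size", "genotype:log_size"],
                                   covariates=["log_size"])
        slopes = slope_model.pairwise_slopes("genotype", "log_size",
                                             iterations=iterations, seed=seed)
        write_results_table(slopes, out / "shape_pairwise_slopes.csv")
    return {"n_outlines": len(outlines),
            "n_retained_axes": int(len(model.retained)),
            "final_terms": final_terms}
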