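"""End-to-end analysis: data -> trajectories -> vulnerability -> effect sizes.

Stage order mirrors the study's analysis plan: (1) load or simulate the
cohort and baseline battery; (2) scan group-based trajectory models on the
observed (available-case) pain data and select by BIC; (3) hard-assign
subjects to trajectories; (4) z-standardize the baseline battery and build
the composite vulnerability score; (5) compare the composite between the
persistent- and transient-pain groups with a pooled-SD d and CI; (6) repeat
(2)-(5) on LOCF-completed data as a sensitivity analysis.

A run is fully determined by (config, seed): the report serializes to
byte-identical JSON across repeats.  The generator's latent-group truth is
never read by the pipeline; recovery metrics live in the test suite only.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort_io import (
    EndpointMatrix,
    LongCohort,
    locf_impute,
    read_cohort,
    read_endpoints,
)
from .effects import cohens_d_from_samples
from .gbtm import select_model
from .synthetic import GeneratorConfig, generate
from .vulnerability import composite, standardize

__all__ = ["GBTMOptions", "InputPaths", "PipelineConfig", "PipelineError", "run", "sensitivity_locf"]

log = logging.getLogger("trajvuln")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and any partial results."""

    def __init__(self, stage: str, cause: Exception, partial: dict | None = None):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial or {}


class GBTMOptions(BaseModel):
    k_range: tuple[int, ...] = (1, 2, 3)
    order_range: tuple[int, ...] = (1, 2, 3)
    censored: bool = True
    n_starts: int = Field(default=20, ge=1)
    tol: float = Field(default=1e-8, gt=0)
    max_iter: int = Field(default=500, ge=1)


class InputPaths(BaseModel):
    cohort: str
    endpoints: str
    registry: str | None = None  # None -> packaged default battery registry


class PipelineConfig(BaseModel):
    """One config drives the whole run; exactly one data source is allowed."""

    inputs: InputPaths | None = None
    generator: GeneratorConfig | None = None
    gbtm: GBTMOptions = GBTMOptions()
    completeness_threshold: float = Field(default=0.5, ge=0, le=1)
    confidence_level: float = Field(default=0.95, gt=0, lt=1)
    seed: int
    group_labels: tuple[str, str] = ("TP", "PP")
    output_dir: str | None = None

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.inputs is None) == (self.generator is None):
            raise ValueError("exactly one of inputs / generator must be set")
        return self


def _jsonable(obj: Any) -> Any:
    """Make a report JSON-serializable and deterministic (NaN -> None)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def report_json(report: dict) -> str:
    return json.dumps(_jsonable(report), sort_keys=True, indent=1)


def _load(config: PipelineConfig) -> tuple[LongCohort, EndpointMatrix]:
    if config.generator is not None:
        cohort, endpoints, _truth = generate(config.generator)
        return cohort, endpoints
    paths = config.inputs
    if paths.registry is None:
        from .instruments import default_registry

        registry = default_registry()
    else:
        registry = paths.registry
    return read_cohort(paths.cohort), read_endpoints(paths.endpoints, registry)


def _analyse(
    cohort: LongCohort,
    endpoints: EndpointMatrix,
    config: PipelineConfig,
    seed: int,
) -> tuple[dict, dict]:
    """Stages 2-5 on one cohort; returns (report section, artifacts)."""
    opts = config.gbtm
    sel = select_model(
        cohort,
        K_range=opts.k_range,
        order_range=opts.order_range,
        censored=opts.censored,
        n_starts=opts.n_starts,
        seed=seed,
        tol=opts.tol,
        max_iter=opts.max_iter,
    )
    model, assign, diag = sel.model, sel.assignment, sel.diagnostics
    K = model.K
    labels = (
        list(config.group_labels) if K == 2 else [f"G{j}" for j in range(K)]
    )
    hard = assign.assigned
    sizes = {labels[j]: int((hard == j).sum()) for j in range(K)}
    n_assigned = int(len(hard))

    zm = standardize(endpoints)
    comp = composite(zm, config.completeness_threshold)

    warnings_: list[str] = []
    effect: dict | None = None
    group_summaries: dict | None = None
    if K >= 2:
        # lowest- vs highest-mean trajectory: transient first, so a more
        # vulnerable persistent group gives a negative d
        scores = comp.scores
        lo_subj = [s for s, g in zip(assign.subjects, hard) if g == 0]
        hi_subj = [s for s, g in zip(assign.subjects, hard) if g == K - 1]
        x1 = scores.reindex(lo_subj).dropna().values
        x2 = scores.reindex(hi_subj).dropna().values
        if len(x1) >= 2 and len(x2) >= 2:
            res = cohens_d_from_samples(x1, x2, level=config.confidence_level)
            effect = res.to_dict()
            s = res.summary
            group_summaries = {
                labels[0]: {"n": s.n1, "mean": s.m1, "sd": s.s1},
                labels[-1]: {"n": s.n2, "mean": s.m2, "sd": s.s2},
            }
        else:
            warnings_.append("too few scored subjects per trajectory for a comparison")
    else:
        warnings_.append(
            "single trajectory selected; composite comparison skipped (needs >= 2 groups)"
        )

    section = {
        "model": model.to_dict(),
        "diagnostics": diag.to_dict(),
        "trajectory_labels": labels,
        "trajectory_sizes": sizes,
        "trajectory_proportions": {
            lab: sizes[lab] / n_assigned for lab in labels
        },
        "composite_group_summaries": group_summaries,
        "composite_effect": effect,
        "warnings": warnings_,
        "scan": sel.scan.to_dict(orient="records"),
    }
    artifacts = {"selection": sel, "zmatrix": zm, "composite": comp}
    return section, artifacts


def _per_endpoint_effects(zm, assign, labels, level) -> pd.DataFrame:
    """One row per endpoint: d and CI between extreme trajectories on z scores."""
    hard = assign.assigned
    K = hard.max() + 1
    lo = [s for s, g in zip(assign.subjects, hard) if g == 0]
    hi = [s for s, g in zip(assign.subjects, hard) if g == K - 1]
    rows = []
    for e in zm.z.columns:
        x1 = zm.z[e].reindex(lo).dropna().values
        x2 = zm.z[e].reindex(hi).dropna().values
        if len(x1) < 2 or len(x2) < 2:
            continue
        r = cohens_d_from_samples(x1, x2, level=level)
        rows.append({"endpoint": e, **r.to_dict()})
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis and (optionally) persist a run directory."""
    t0 = time.perf_counter()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    partial: dict = {}

    stage = "load"
    try:
        log.info("stage=%s", stage)
        cohort, endpoints = _load(config)
        partial["n_subjects"] = cohort.n_subjects

        stage = "primary_analysis"
        log.info("stage=%s n=%d", stage, cohort.n_subjects)
        primary, artifacts = _analyse(cohort, endpoints, config, seed=config.seed)
        partial["primary"] = primary

        stage = "locf_sensitivity"
        log.info("stage=%s", stage)
        locf_cohort = locf_impute(cohort)
        locf_section, locf_artifacts = _analyse(
            locf_cohort, endpoints, config, seed=config.seed
        )
        partial["locf"] = locf_section
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        if outdir:
            (outdir / "partial.json").write_text(report_json(partial), encoding="utf-8")
        raise PipelineError(stage, exc, partial) from exc

    report = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "n_subjects": cohort.n_subjects,
        "primary": primary,
        "locf": locf_section,
    }

    if outdir:
        (outdir / "report.json").write_text(report_json(report), encoding="utf-8")
        sel = artifacts["selection"]
        (outdir / "model.json").write_text(
            json.dumps(_jsonable(sel.model.to_dict()), sort_keys=True, indent=1),
            encoding="utf-8",
        )
        sel.assignment.to_frame().to_csv(outdir / "assignment.csv", index=False)
        artifacts["zmatrix"].z.to_csv(outdir / "zmatrix.csv", na_rep="")
        eff = _per_endpoint_effects(
            artifacts["zmatrix"], sel.assignment,
            primary["trajectory_labels"], config.confidence_level,
        )
        eff.to_csv(outdir / "effects.csv", index=False)
        with open(outdir / "log.txt", "a", encoding="utf-8") as fh:
            fh.write(f"run completed in {time.perf_counter() - t0:.2f}s\n")
    return report


def sensitivity_locf(config: PipelineConfig, primary_report: dict) -> dict:
    """Side-by-side complete/available-case vs LOCF effect sizes and their gap.

    ``run`` already performs the LOCF pass; this helper condenses the two
    effect estimates from a finished report (or re-runs if handed a config
    whose report lacks the LOCF section).
    """
    if "locf" not in primary_report:
        primary_report = run(config)
    p = primary_report["primary"].get("composite_effect")
    l = primary_report["locf"].get("composite_effect")
    out = {"primary": p, "locf": l, "delta_d": None}
    if p and l and p.get("d") is not None and l.get("d") is not None:
        out["delta_d"] = l["d"] - p["d"]
    return out
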