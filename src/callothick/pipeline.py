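"""End-to-end study replica: simulate -> demographics -> pointwise scan ->
region aggregation -> per-region Johnson-Neyman -> per-region PLSC ->
FDR across regions -> symptom-level JN follow-up.

Every stage writes its outputs as CSV into the run directory, together
with a JSON manifest recording the configuration, seeds and package
version, so any stage can be rerun from the intermediate tables with
identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demographics import demographics
from .moderation import (
    WITELSON_REGIONS,
    aggregate_regions,
    crossover_age,
    fit_moderation,
    jn_boundaries,
    pointwise_scan,
)
from .plsc import (
    behavior_scores,
    bootstrap_ratios,
    build_inputs,
    fdr_across_regions,
    fit,
    permutation_test,
    symptom_jn,
)
from .simulate import SyntheticCohortConfig, simulate_cohort, write_tables

log = logging.getLogger("callothick")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(
    out_dir: str | Path,
    config: SyntheticCohortConfig | None = None,
    cohort: pd.DataFrame | None = None,
    profiles: pd.DataFrame | None = None,
    symptoms: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the full analysis and write results + manifest to ``out_dir``.

    Either a :class:`SyntheticCohortConfig` (simulated inputs) or the three
    tables (cohort, profiles, symptoms) must be provided.  Returns the run
    report as a dict (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config is not None:
        cohort, profiles, symptoms, truth = _simulate(config)
        write_tables(out, cohort, profiles, symptoms)
    else:
        truth = None
        if cohort is None or profiles is None:
            raise PipelineError("inputs", "need a config or cohort + profiles tables")

    node_cols = [c for c in profiles.columns if c.startswith("node_")]
    prof = profiles[node_cols]

    demo = _demographics(cohort)
    demo.to_frame().to_csv(out / "demographics.csv", index=False)

    group01 = (cohort["group"] == "patient").astype(int).to_numpy()
    age = cohort["age"].to_numpy()
    covs = cohort[["sex", "education", "tiv"]]
    scan = _scan(prof, group01, age, covs, alpha)
    scan.to_csv(out / "pointwise_scan.csv")

    regions = _regions(prof)
    regions.to_csv(out / "region_means.csv", index=False)

    age_range = (float(age.min()), float(age.max()))
    region_jn = _region_jn(regions, group01, age, covs, alpha, age_range)
    pd.DataFrame(region_jn).to_csv(out / "region_jn.csv", index=False)

    plsc_report = None
    if symptoms is not None:
        plsc_report = _plsc(
            cohort, regions, symptoms, alpha, n_perm, n_boot, seed, age_range, out
        )
    report = {
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "n_perm": n_perm,
        "n_boot": n_boot,
        "config": asdict(config) if config is not None else None,
        "n_subjects": int(len(cohort)),
        "significant_nodes": [
            int(c.split("_")[1]) for c in scan.index[scan["significant"]]
        ],
        "region_jn": region_jn,
        "plsc": plsc_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": asdict(config) if config is not None else None,
        "stages": [
            "simulate" if config is not None else "load",
            "demographics",
            "pointwise_scan",
            "aggregate_regions",
            "region_jn",
            "plsc" if symptoms is not None else None,
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return report


@_stage("simulate")
def _simulate(config):
    return simulate_cohort(config)


@_stage("demographics")
def _demographics(cohort):
    return demographics(cohort)


@_stage("pointwise_scan")
def _scan(prof, group01, age, covs, alpha):
    return pointwise_scan(prof, group01, age, covariates=covs, alpha=alpha)


@_stage("aggregate_regions")
def _regions(prof):
    return aggregate_regions(prof)


@_stage("region_jn")
def _region_jn(regions, group01, age, covs, alpha, age_range):
    rows = []
    for reg in WITELSON_REGIONS:
        mfit = fit_moderation(
            regions[reg.region_id], group01, age, covariates=covs
        )
        sol = jn_boundaries(mfit, alpha=alpha, moderator_range=age_range)
        rows.append(
            {
                "region": reg.region_id,
                "b_group": mfit.b1,
                "b_interaction": mfit.b3,
                "crossover_age": crossover_age(mfit),
                "boundaries": ";".join(f"{b:.2f}" for b in sol.boundaries),
                "pattern": ";".join(
                    f"{lo:.1f}-{hi:.1f}:{lab}" for lo, hi, lab in sol.intervals
                ),
            }
        )
    return rows


@_stage("plsc")
def _plsc(cohort, regions, symptoms, alpha, n_perm, n_boot, seed, age_range, out):
    pat_mask = cohort["group"] == "patient"
    pat = cohort[pat_mask].reset_index(drop=True)
    reg_pat = regions[pat_mask.to_numpy()].reset_index(drop=True)
    sym = symptoms.set_index("subject_id").loc[pat["subject_id"]].reset_index()
    report = {}
    lv1_p = []
    for i, reg in enumerate(WITELSON_REGIONS):
        inputs = build_inputs(reg_pat[reg.region_id], pat["age"], sym.drop(columns="subject_id"))
        model = fit(inputs)
        p = permutation_test(inputs, n_perm=n_perm, seed=seed + 1000 + i)
        bsr = bootstrap_ratios(inputs, n_boot=n_boot, seed=seed + 2000 + i)
        scores = behavior_scores(inputs.Y, model.V)
        mfit, jn = symptom_jn(
            scores[:, 0],
            inputs.X["thickness"],
            pat["age"].to_numpy()[inputs.kept],
            moderator_range=age_range,
        )
        lv1_p.append(p[0])
        sal = pd.DataFrame(model.V, index=model.y_names, columns=["LV1", "LV2", "LV3"])
        sal["bsr_LV1"] = bsr["bsr_v"][:, 0]
        sal.to_csv(out / f"plsc_region_{reg.region_id}_saliences.csv")
        report[reg.region_id] = {
            "singular_values": model.S.tolist(),
            "perm_p": p.tolist(),
            "lv1_jn_boundaries": jn.boundaries,
            "lv1_jn_pattern": [[lo, hi, lab] for lo, hi, lab in jn.intervals],
        }
    q = fdr_across_regions(lv1_p)
    for reg, qv in zip(WITELSON_REGIONS, q):
        report[reg.region_id]["lv1_q_across_regions"] = float(qv)
    return report
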