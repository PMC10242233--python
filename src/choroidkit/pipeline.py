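"""End-to-end pipeline: simulate -> quantify -> analyze.

``run_pipeline`` generates a synthetic cohort and image phantoms, pushes
the phantoms through the quantification stages, runs the full biomarker
analysis on the cohort, and writes every artifact plus a manifest with
the seed, config hash and file hashes.  Re-running with the same config
reproduces byte-identical numeric outputs (timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .angio import EnfaceAngiogram, FDConfig, quantify_angiogram
from .io import (RunConfig, save_angio_sidecar, save_bscan_sidecar,
                 save_cohort_csv, save_image, save_mask, sha256_file)
from .nomogram import build_nomogram, render_nomogram, score_subject
from .quant import (BinarizationConfig, BScanImage, ChoroidSegmentation,
                    quantify_bscan)
from .stats import (MODEL1_PREDICTORS, MODEL2_PREDICTORS, compare_groups,
                    compute_idi, delong_compare, dichotomize_by_median,
                    fit_linear_model, fit_logistic_and_roc,
                    screen_univariable)
from .synthetic import (AngioPhantomSpec, BScanPhantomSpec, CohortGenParams,
                        generate_bscan_phantom, generate_cc_phantom,
                        generate_cohort)

__all__ = ["ROC_MODEL_SETS", "analyze_cohort", "run_pipeline"]

log = logging.getLogger("choroidkit")

#: The seven discrimination models compared for slow-progression prediction.
ROC_MODEL_SETS: dict[str, tuple[str, ...]] = {
    "cvi0": ("cvi0_pct",),
    "d_la": ("d_la_mm2",),
    "d_sfct": ("d_sfct_um",),
    "cvi0+d_la": ("cvi0_pct", "d_la_mm2"),
    "cvi0+d_la+age+sex": ("cvi0_pct", "d_la_mm2", "age_years", "sex"),
    "cvi0+d_sfct": ("cvi0_pct", "d_sfct_um"),
    "cvi0+d_sfct+age+sex": ("cvi0_pct", "d_sfct_um", "age_years", "sex"),
}

#: Paired model comparisons reported (new vs reference).
_DELONG_PAIRS = [
    ("cvi0+d_la", "cvi0"),
    ("cvi0+d_sfct", "cvi0"),
    ("cvi0+d_la+age+sex", "cvi0+d_la"),
    ("cvi0+d_sfct+age+sex", "cvi0+d_sfct"),
]

_NOMOGRAM_MODEL = "cvi0+d_sfct+age+sex"


def analyze_cohort(table: pd.DataFrame, outdir: str | Path | None = None) -> dict:
    """Run the complete biomarker analysis on a cohort table.

    Returns a result bundle (screening, group comparisons, the two linear
    models, ROC/DeLong/IDI across the model ladder, and the nomogram);
    when ``outdir`` is given, also writes the corresponding CSV/JSON
    artifacts and the rendered nomogram.
    """
    median, labels = dichotomize_by_median(table["d_al_annualized_mm_yr"])

    screen = screen_univariable(table)
    groups = compare_groups(table, labels)
    model1 = fit_linear_model(table, MODEL1_PREDICTORS, model_label="model1")
    model2 = fit_linear_model(table, MODEL2_PREDICTORS, model_label="model2")

    rocs = {name: fit_logistic_and_roc(table, preds, labels, name)
            for name, preds in ROC_MODEL_SETS.items()}
    delong = {}
    idi = {}
    for new, ref in _DELONG_PAIRS:
        d_auc, p = delong_compare(rocs[new], rocs[ref])
        delong[f"{new} vs {ref}"] = {"delta_auc": d_auc, "p": p}
        res = compute_idi(rocs[new].scores, rocs[ref].scores, labels)
        idi[f"{new} vs {ref}"] = dataclasses.asdict(res)

    nomo_roc = rocs[_NOMOGRAM_MODEL]
    ranges = {}
    for pred in ROC_MODEL_SETS[_NOMOGRAM_MODEL]:
        if pred == "sex":
            ranges[pred] = (0.0, 1.0)
        else:
            ranges[pred] = (float(table[pred].min()), float(table[pred].max()))
    nomogram = build_nomogram(nomo_roc.model, ranges)

    bundle = {
        "median_elongation": median,
        "labels": labels,
        "screening": screen,
        "group_comparisons": groups,
        "model1": model1,
        "model2": model2,
        "roc": rocs,
        "delong": delong,
        "idi": idi,
        "nomogram": nomogram,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([dataclasses.asdict(s) for s in screen]).to_csv(
            outdir / "screening.csv", index=False
        )
        pd.DataFrame([{
            "variable": g.variable, "test": g.test, "p": g.p,
            "slow": json.dumps(g.group_a), "fast": json.dumps(g.group_b),
        } for g in groups]).to_csv(outdir / "group_comparisons.csv",
                                   index=False)
        models_json = {
            "median_elongation_mm_yr": median,
            "model1": dataclasses.asdict(model1),
            "model2": dataclasses.asdict(model2),
            "roc": {
                name: {"auc": r.auc, "ci": [r.ci_low, r.ci_high],
                       "predictors": list(ROC_MODEL_SETS[name])}
                for name, r in rocs.items()
            },
            "delong": delong,
            "idi": idi,
        }
        (outdir / "models.json").write_text(json.dumps(models_json, indent=1))
        roc_rows = []
        for name, r in rocs.items():
            for f, t in zip(r.fpr, r.tpr):
                roc_rows.append({"model": name, "fpr": f, "tpr": t})
        pd.DataFrame(roc_rows).to_csv(outdir / "roc_points.csv", index=False)
        (outdir / "nomogram.json").write_text(
            json.dumps(nomogram.to_dict(), indent=1)
        )
        render_nomogram(nomogram, str(outdir / "nomogram.png"))
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline described by ``config``.

    Stages: (1) simulate a cohort, (2) simulate B-scan and angiogram
    phantoms and quantify them, (3) analyze the cohort.  All artifacts are
    written under ``config.outdir`` together with ``manifest.json``
    (versions, seed, config hash, per-file hashes, record counts); stage
    failures are recorded in the manifest before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "choroidkit",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": {},
        "files": {},
    }
    config.save(outdir / "config.json")

    def _finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}
        log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)

    try:
        # 1. cohort ---------------------------------------------------------
        t0 = time.perf_counter()
        params = CohortGenParams(seed=config.seed, **config.cohort)
        table, truth = generate_cohort(params)
        save_cohort_csv(outdir / "cohort.csv", table)
        (outdir / "cohort_truth.json").write_text(json.dumps(truth, indent=1))
        _finish_stage("simulate_cohort", t0, n_subjects=len(table))

        # 2. phantoms -------------------------------------------------------
        t0 = time.perf_counter()
        phantom_dir = outdir / "phantoms"
        phantom_dir.mkdir(exist_ok=True)
        bin_cfg = BinarizationConfig(**config.binarization)
        fd_cfg = FDConfig(**config.flow_deficit)
        rows = []
        for i in range(config.n_bscan_phantoms):
            spec = BScanPhantomSpec(seed=config.seed * 1000 + i,
                                    **config.bscan_phantom)
            img, tr = generate_bscan_phantom(spec)
            bscan = BScanImage(img, spec.lateral_scale, spec.axial_scale,
                               tr.fovea_column)
            seg = ChoroidSegmentation(tr.boundary_upper, tr.boundary_lower)
            stem = phantom_dir / f"bscan_{i:02d}"
            save_image(f"{stem}.tiff", img)
            save_bscan_sidecar(f"{stem}.json", bscan, seg)
            save_mask(f"{stem}_lumen_truth.png", tr.lumen_mask)
            metrics, lumen, _ = quantify_bscan(bscan, seg, bin_cfg)
            save_mask(f"{stem}_lumen.png", lumen)
            rows.append({"phantom": f"bscan_{i:02d}",
                         **{f"true_{k}": v for k, v in tr.true_metrics.items()},
                         **{f"measured_{k}": v
                            for k, v in metrics.to_dict().items()}})
        for i in range(config.n_cc_phantoms):
            spec = AngioPhantomSpec(seed=config.seed * 1000 + 500 + i,
                                    **config.cc_phantom)
            img, tr = generate_cc_phantom(spec)
            angio = EnfaceAngiogram(img, spec.scale, tr.center)
            stem = phantom_dir / f"cc_{i:02d}"
            save_image(f"{stem}.tiff", img)
            save_angio_sidecar(f"{stem}.json", angio)
            save_mask(f"{stem}_deficit_truth.png", tr.deficit_mask)
            result, mask = quantify_angiogram(angio, fd_cfg)
            save_mask(f"{stem}_deficit.png", mask)
            rows.append({"phantom": f"cc_{i:02d}",
                         **{f"true_{k}": v for k, v in tr.true_metrics.items()},
                         **{f"measured_{k}": v
                            for k, v in result.to_dict().items()}})
        pd.DataFrame(rows).to_csv(outdir / "phantom_metrics.csv", index=False)
        _finish_stage("simulate_and_quantify_phantoms", t0,
                      n_bscan=config.n_bscan_phantoms,
                      n_cc=config.n_cc_phantoms)

        # 3. analysis -------------------------------------------------------
        t0 = time.perf_counter()
        bundle = analyze_cohort(table, outdir / "analysis")
        _finish_stage("analyze", t0,
                      n_roc_models=len(bundle["roc"]))
    except Exception as exc:
        manifest["stages"]["failed"] = {"status": "error", "error": repr(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(outdir))] = sha256_file(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    bundle["cohort"] = table
    bundle["cohort_truth"] = truth
    bundle["phantom_metrics"] = pd.DataFrame(rows)
    bundle["manifest"] = manifest
    return bundle
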