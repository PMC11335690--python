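"""End-to-end demo runs (simulate -> markers -> stats) and input validation.

``run_demo`` exercises every stage of the toolkit on synthetic data: it
builds structural and diffusion phantoms, estimates ePVS burden and the
ALPS index against their analytic ground truths, generates a synthetic
cohort and runs the full statistics battery, then writes a metrics JSON, a
markdown report (watermarked as synthetic throughout) and a run manifest.
Runs are byte-reproducible given the config seed.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import stats as st
from .alps import compute_alps_index, make_alps_rois
from .cohort import CohortGenSpec, make_synthetic_cohort
from .config import RunConfig, RunManifest
from .dki import extract_diffusivity_maps, fit_dki_lls
from .epvs import (
    FrangiParams,
    SegmentationParams,
    calibrate_threshold,
    compute_epc,
    fit_structureness_c,
    normalize_intensity,
    region_fill,
    segment_epvs,
)
from .io import read_cohort_table, read_gradient_table, read_volume, resample_labels, resample_volume
from .phantoms import (
    StructuralPhantomSpec,
    make_alps_tensor_field,
    make_dwi_phantom,
    make_structural_phantom,
)

__all__ = ["run_demo", "validate_inputs"]


def _epvs_for_phantom(phantom, h_wm, frangi_params, working=0.7):
    """Resample -> normalize -> EPC (region-conditioned) -> Frangi -> segment.

    ``frangi_params`` should carry a *fixed* structureness c so the
    threshold ``h_wm`` is comparable across phantoms.
    """
    target = (working,) * 3
    t1r = resample_volume(phantom.t1w, target)
    t2r = resample_volume(phantom.t2w, target)
    labr = resample_labels(phantom.labels, target)
    wm = labr.region_mask("WM")
    epc = compute_epc(normalize_intensity(t1r, wm), normalize_intensity(t2r, wm))
    from .epvs import frangi_vesselness

    vness = frangi_vesselness(region_fill(epc, wm), frangi_params, region_mask=wm)
    res = segment_epvs(vness, wm, SegmentationParams(h=h_wm), region="WM")
    return res, vness, wm


def run_demo(config: RunConfig | None = None) -> dict:
    """Run the full synthetic demonstration pipeline; returns the metrics dict."""
    cfg = config or RunConfig()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = RunManifest()
    manifest.log_stage("config", json.loads(cfg.to_json()))
    metrics: dict = {"seed": cfg.seed}

    if cfg.run_imaging:
        # calibrate the structureness scale and WM threshold once on a
        # noise-free phantom, then hold both fixed across subjects
        calib_spec = StructuralPhantomSpec(
            shape=cfg.structural_shape,
            spacing=cfg.structural_spacing,
            noise_sigma=(0.0, 0.0),
            seed=cfg.seed,
        )
        calib = make_structural_phantom(calib_spec)
        target = (0.7,) * 3
        t1r = resample_volume(calib.t1w, target)
        t2r = resample_volume(calib.t2w, target)
        labr = resample_labels(calib.labels, target)
        wm0 = labr.region_mask("WM")
        epc0 = region_fill(
            compute_epc(normalize_intensity(t1r, wm0), normalize_intensity(t2r, wm0)), wm0
        )
        frangi_params = FrangiParams(c=fit_structureness_c(epc0, region_mask=wm0))
        _, vness, wm = _epvs_for_phantom(calib, h_wm=0.0, frangi_params=frangi_params)
        h_wm = calibrate_threshold(vness, wm, calib.true_burden["WM"])
        manifest.log_stage(
            "calibrate_threshold",
            {"h_wm": h_wm, "frangi_c": list(frangi_params.c)},
            {"vesselness": vness.data},
        )

        epvs_rows = []
        for k in range(cfg.n_imaging_subjects):
            spec = StructuralPhantomSpec(
                shape=cfg.structural_shape,
                spacing=cfg.structural_spacing,
                seed=cfg.seed * 1000 + k + 1,
            )
            ph = make_structural_phantom(spec)
            res, _, _ = _epvs_for_phantom(ph, h_wm, frangi_params)
            epvs_rows.append(
                {
                    "subject": k,
                    "true_wm_burden_pct": round(ph.true_burden["WM"], 6),
                    "est_wm_burden_pct": round(res.burden_pct, 6),
                    "n_clusters": res.n_clusters,
                }
            )
        metrics["epvs"] = {"h_wm_calibrated": h_wm, "subjects": epvs_rows}
        manifest.log_stage("epvs_subjects", {"n": cfg.n_imaging_subjects})

        alps_rows = []
        rng = np.random.default_rng(cfg.seed + 7)
        for k in range(cfg.n_imaging_subjects):
            dxx = rng.uniform(1.1e-3, 1.5e-3)
            spec = make_alps_tensor_field(
                dxx_proj=dxx, dyy_proj=0.9e-3, dzz_proj=1.6e-3,
                dxx_assoc=dxx, dyy_assoc=1.6e-3, dzz_assoc=0.9e-3,
                snr=cfg.dwi_snr, noise_model="rician", seed=cfg.seed * 1000 + 500 + k,
            )
            dwi, _ = make_dwi_phantom(spec)
            tf = fit_dki_lls(dwi, spec.gtab, mask=spec.labels > 0,
                             spacing=(spec.spacing,) * 3)
            dxx_m, dyy_m, dzz_m = extract_diffusivity_maps(tf)
            rois = make_alps_rois(spec.shape, (spec.spacing,) * 3, spec.roi_centers)
            res = compute_alps_index(dxx_m, dyy_m, dzz_m, rois, fit_mask=tf.mask,
                                     fit_method=tf.fit_method)
            alps_rows.append(
                {
                    "subject": k,
                    "true_alps": round(spec.alps_truth, 6),
                    "est_alps": round(res.alps_index, 6),
                }
            )
        metrics["alps"] = {"subjects": alps_rows}
        manifest.log_stage("alps_subjects", {"n": cfg.n_imaging_subjects})

    if cfg.run_stats:
        cohort = make_synthetic_cohort(
            CohortGenSpec(n_control=cfg.n_control, n_mtbi=cfg.n_mtbi, seed=cfg.seed + 11)
        )
        metrics["stats"] = run_stats_battery(cohort, seed=cfg.seed + 13)
        manifest.log_stage("stats", {"n_control": cfg.n_control, "n_mtbi": cfg.n_mtbi})

    out_json = os.path.join(cfg.out_dir, "metrics.json")
    with open(out_json, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    manifest.save(os.path.join(cfg.out_dir, "manifest.json"))
    _write_report(metrics, os.path.join(cfg.out_dir, "report.md"))
    return metrics


def run_stats_battery(cohort, seed: int = 0) -> dict:
    """Group tests, age correlations, adjusted associations, longitudinal
    models and the two prediction models, on a cohort table."""
    out: dict = {}
    ctrl = cohort[cohort["visit"] == "control"]
    d14 = cohort[cohort["visit"] == "14Day"]
    d6m = cohort[cohort["visit"] == "6-12Mon"]

    groups = {}
    for var in ("wm_epvs", "bg_epvs", "alps_index", "rpq_total", "n_symptoms", "psqi"):
        res = st.welch_t_test(ctrl[var], d14[var])
        groups[var] = {"t": round(res.statistic, 6), "p": round(res.p_value, 6)}
    groups["_family_fdr_p"] = [round(float(q), 6) for q in st.fdr_adjust([g["p"] for g in groups.values()])]
    out["group_control_vs_mtbi14"] = groups

    age = {}
    for var in ("wm_epvs", "alps_index"):
        r_ctrl = st.pearson_correlation(ctrl["age"], ctrl[var])
        r_14 = st.pearson_correlation(d14["age"], d14[var])
        age[var] = {
            "control_r": round(r_ctrl.statistic, 6), "control_p": round(r_ctrl.p_value, 6),
            "mtbi14_r": round(r_14.statistic, 6), "mtbi14_p": round(r_14.p_value, 6),
        }
    out["age_correlations"] = age

    assoc = st.adjusted_association(
        d14["n_symptoms"], d14["wm_epvs"], covariates=[d14["age"], d14["sex"]]
    )
    out["symptom_association"] = {
        "slope": round(assoc.estimate, 6),
        "partial_r": round(assoc.extra["partial_r"], 6),
        "p": round(assoc.p_value, 6),
    }

    mtbi_long = cohort[cohort["group"] == "mTBI"]
    lmm = st.fit_lmm_visit(mtbi_long, "bg_epvs")
    visit_key = [k for k in lmm if k.startswith("visit_")][0]
    out["lmm_bg_visit_effect"] = {
        "estimate": round(lmm[visit_key].estimate, 6),
        "p": round(lmm[visit_key].p_value, 6),
    }

    ratio = st.ratio_change_correlation(mtbi_long, "alps_index", "psqi")
    out["alps_psqi_ratio"] = {
        "r": round(ratio.statistic, 6),
        "p": round(ratio.p_value, 6),
        "n_pairs": ratio.extra["n_pairs"],
    }

    pred = d14.merge(
        d6m[["subject_id", "memory_problem"]].rename(columns={"memory_problem": "memory_6mon"}),
        on="subject_id",
    )
    basic = ["age", "sex", "education", "gcs", "ct_or_mri_positive"]
    markers = basic + ["wm_epvs", "bg_epvs", "alps_index"]
    fit1, sel1, _ = st.stepwise_logistic(pred, basic, "memory_6mon")
    fit2, sel2, _ = st.stepwise_logistic(pred, markers, "memory_6mon")

    def scores(fit, sel):
        import statsmodels.api as sm

        X = sm.add_constant(pred[sel].to_numpy(dtype=float)) if sel else np.ones((len(pred), 1))
        return fit.predict(X)

    s1, s2 = scores(fit1, sel1), scores(fit2, sel2)
    y = pred["memory_6mon"].to_numpy()
    roc1, roc2 = st.roc_auc(s1, y), st.roc_auc(s2, y)
    cmp_res = st.compare_auc_bootstrap(s2, s1, y, n_boot=2000, seed=seed)
    out["prediction"] = {
        "model1_selected": sel1,
        "model2_selected": sel2,
        "model2_coefficients": {
            name: round(float(v), 6)
            for name, v in zip(["intercept"] + sel2, np.asarray(fit2.params))
        },
        "auc_model1": round(roc1.auc, 6),
        "auc_model2": round(roc2.auc, 6),
        "delta_auc": round(roc2.auc - roc1.auc, 6),
        "bootstrap_p": round(cmp_res.p_value, 6),
    }
    return out


def _write_report(metrics: dict, path: str) -> None:
    lines = [
        "# glymkit demo report",
        "",
        "**All data in this report are SYNTHETIC** (phantoms and a simulated",
        "cohort); no human data were used.",
        "",
    ]
    if "epvs" in metrics:
        lines += ["## ePVS burden (phantoms)", "",
                  "| subject | true WM burden (%) | estimated (%) | clusters |",
                  "|---|---|---|---|"]
        for r in metrics["epvs"]["subjects"]:
            lines.append(
                f"| {r['subject']} | {r['true_wm_burden_pct']:.3f} | "
                f"{r['est_wm_burden_pct']:.3f} | {r['n_clusters']} |"
            )
        lines.append("")
    if "alps" in metrics:
        lines += ["## ALPS index (phantoms)", "",
                  "| subject | true ALPS | estimated |", "|---|---|---|"]
        for r in metrics["alps"]["subjects"]:
            lines.append(f"| {r['subject']} | {r['true_alps']:.3f} | {r['est_alps']:.3f} |")
        lines.append("")
    if "stats" in metrics:
        s = metrics["stats"]
        lines += ["## Cohort statistics (synthetic)", "",
                  f"- age vs WM-ePVS (control): r = {s['age_correlations']['wm_epvs']['control_r']:.3f}",
                  f"- age vs ALPS (control): r = {s['age_correlations']['alps_index']['control_r']:.3f}",
                  f"- symptom count vs WM-ePVS (mTBI 14Day, adjusted): "
                  f"partial r = {s['symptom_association']['partial_r']:.3f}, "
                  f"p = {s['symptom_association']['p']:.4g}",
                  f"- ALPS ratio vs PSQI ratio: r = {s['alps_psqi_ratio']['r']:.3f}",
                  f"- memory prediction: AUC basic = {s['prediction']['auc_model1']:.3f}, "
                  f"with markers = {s['prediction']['auc_model2']:.3f} "
                  f"(bootstrap p = {s['prediction']['bootstrap_p']:.4g})",
                  ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def validate_inputs(
    t1w: str | None = None,
    t2w: str | None = None,
    labels: str | None = None,
    bval: str | None = None,
    bvec: str | None = None,
    cohort: str | None = None,
) -> dict:
    """Run enumerated sanity checks on pipeline inputs.

    Returns ``{"passed": bool, "checks": [{"name", "passed", "detail"}, ...]}``.
    """
    checks: list[dict] = []

    def record(name: str, fn) -> None:
        try:
            detail = fn()
            checks.append({"name": name, "passed": True, "detail": detail or "ok"})
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            checks.append({"name": name, "passed": False, "detail": str(exc)})

    vols = {}
    for name, path in (("t1w", t1w), ("t2w", t2w), ("labels", labels)):
        if path is not None:
            record(f"read_{name}", lambda p=path, n=name: vols.__setitem__(n, read_volume(p)))
    if "t1w" in vols and "t2w" in vols:
        record(
            "t1w_t2w_same_grid",
            lambda: None
            if vols["t1w"].same_grid(vols["t2w"])
            else (_ for _ in ()).throw(ValueError(
                f"grid mismatch: {vols['t1w'].shape} vs {vols['t2w'].shape}")),
        )
    if bval is not None and bvec is not None:
        record("gradient_table", lambda: f"{len(read_gradient_table(bval, bvec))} entries")
    if cohort is not None:
        record("cohort_schema", lambda: f"{len(read_cohort_table(cohort))} rows")
    return {"passed": all(c["passed"] for c in checks), "checks": checks}
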