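"""End-to-end orchestration: study quantification and cohort reporting."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hbsquant import cohortstats, io, outcomes, planar, volumetry
from hbsquant import function as fn
from hbsquant.config import PipelineConfig

__all__ = ["quantify_study", "run_quantify", "run_report"]


def quantify_study(
    stack_ant: planar.FrameStack,
    stack_post: planar.FrameStack,
    rois: planar.ROISet,
    spect: np.ndarray,
    flr_voi: np.ndarray,
    liver_voi: np.ndarray,
    height_cm: float,
    weight_kg: float,
    config: PipelineConfig | None = None,
) -> dict:
    """Compute all functional indices for one study, in memory.

    Wires the clinically standard modes: TL-F from the pixel-pixel
    geometric-mean stack, TL-U from ROI-ROI geometric-mean curves,
    FLR-C from the SPECT VOIs, then the FLR-F and HIBA-index scores.
    """
    config = config or PipelineConfig()
    window = fn.EkmanWindow(config.window_start_s, config.window_end_s)
    bsa = fn.bsa_dubois(height_cm, weight_kg)

    gstack = planar.gmean_pixel(stack_ant, stack_post, config.mirror_posterior)

    def curves(stack_or_mode: str):
        if stack_or_mode == "pixel":
            liver = planar.extract_tac(gstack, rois.liver, "liver")
            blood = planar.extract_tac(gstack, rois.bloodpool, "bloodpool")
            fov = planar.extract_tac(gstack, rois.fov, "fov")
        else:
            # ROI-ROI: per-view sums combined by geometric mean; posterior
            # ROIs are the mirrored anterior masks.
            post_frames = stack_post.frames[:, :, ::-1] if config.mirror_posterior else stack_post.frames
            post = planar.FrameStack("posterior", post_frames, stack_post.frame_mid_times)
            liver = planar.gmean_roi(
                planar.extract_tac(stack_ant, rois.liver, "liver"),
                planar.extract_tac(post, rois.liver, "liver"),
            )
            blood = planar.gmean_roi(
                planar.extract_tac(stack_ant, rois.bloodpool, "bloodpool"),
                planar.extract_tac(post, rois.bloodpool, "bloodpool"),
            )
            fov = planar.gmean_roi(
                planar.extract_tac(stack_ant, rois.fov, "fov"),
                planar.extract_tac(post, rois.fov, "fov"),
            )
        return liver, blood, fov

    liver_px, blood_px, fov_px = curves(config.tl_f_gmean_mode)
    liver_roi, _, fov_roi = curves(config.tl_u_gmean_mode)

    tl_f = fn.tl_f_ekman(liver_px, blood_px, fov_px, window, estimator=config.tl_f_estimator)
    tl_u = fn.tl_u(liver_roi, fov_roi, window, mode=config.tl_u_definition)
    flr_c = fn.flr_c(spect, flr_voi, liver_voi)
    indices = fn.FunctionalIndices.compute(tl_f, tl_u, flr_c, bsa)
    return {
        "tl_f": indices.tl_f,
        "tl_u": indices.tl_u,
        "flr_c": indices.flr_c,
        "bsa": indices.bsa,
        "flr_f": indices.flr_f,
        "hiba_i": indices.hiba_i,
        "estimator": config.tl_f_estimator,
        "window_s": [config.window_start_s, config.window_end_s],
        "config_hash": config.config_hash(),
    }


def run_quantify(study_dir: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Quantify one on-disk study directory into a one-row indices table.

    Expects ``anterior.nii``/``posterior.nii`` with JSON sidecars,
    ``liver_roi.nii``/``bloodpool_roi.nii`` planar masks,
    ``spect.nii`` with ``flr_voi.nii``/``liver_voi.nii``, and a
    ``subject.json`` carrying height_cm / weight_kg / study_id.
    """
    config = config or PipelineConfig()
    d = Path(study_dir)
    subject_path = d / "subject.json"
    if not subject_path.exists():
        raise FileNotFoundError(f"subject metadata not found: {subject_path}")
    subject = json.loads(subject_path.read_text())
    for key in ("height_cm", "weight_kg"):
        if key not in subject:
            raise ValueError(f"subject.json is missing field {key!r}")

    stack_ant = io.load_frame_stack(d / "anterior.nii")
    stack_post = io.load_frame_stack(d / "posterior.nii")
    rois = planar.ROISet(
        liver=io.load_mask(d / "liver_roi.nii"),
        bloodpool=io.load_mask(d / "bloodpool_roi.nii"),
    )
    spect = io.load_volume(d / "spect.nii")
    flr_voi = io.load_mask(d / "flr_voi.nii")
    liver_voi = io.load_mask(d / "liver_voi.nii")

    row = quantify_study(
        stack_ant, stack_post, rois, spect, flr_voi, liver_voi,
        subject["height_cm"], subject["weight_kg"], config,
    )
    row["study_id"] = subject.get("study_id", d.name)
    row["window_s"] = f"{config.window_start_s:g}-{config.window_end_s:g}"
    row["non_default_window"] = (config.window_start_s, config.window_end_s) != (150.0, 350.0)
    cols = [
        "study_id", "tl_f", "tl_u", "flr_c", "bsa", "flr_f", "hiba_i",
        "estimator", "window_s", "non_default_window", "config_hash",
    ]
    return pd.DataFrame([row])[cols]


def run_report(
    cohort: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    roc_plot: bool = False,
) -> dict:
    """Cohort report: outcome grading, summary stats, diagnostic table.

    Grades each patient from day-5 labs and flags, summarises the
    functional indices by outcome group (median/IQR), builds the
    endpoint x index diagnostic-accuracy table, and states the
    suggested safe reference band for remnant function.  Deterministic:
    the same cohort and config give byte-identical outputs.
    """
    config = config or PipelineConfig()
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    required = {
        "flr_f", "hiba_i", "inr_pod5", "bilirubin_umol_l_pod5", "pt_pct_pod5",
        "deviation_noninvasive", "invasive_procedure",
    }
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")

    cohort = cohort.copy()
    grades, fifties = [], []
    for _, r in cohort.iterrows():
        course = outcomes.PostopCourse.single_day(
            pod=5,
            bilirubin_umol_l=r["bilirubin_umol_l_pod5"],
            inr=r["inr_pod5"],
            pt_pct=r["pt_pct_pod5"],
            any_deviation_noninvasive=bool(r["deviation_noninvasive"]),
            invasive_procedure=bool(r["invasive_procedure"]),
        )
        grades.append(
            outcomes.isgls_grade(
                course, config.inr_upper_normal, config.bilirubin_upper_normal_umol
            )
        )
        fifties.append(outcomes.fifty_fifty(course))
    cohort["isgls_grade"] = grades
    cohort["fifty_fifty"] = fifties

    summary = {}
    for index in ("flr_f", "hiba_i"):
        summary[index] = {}
        for group, mask in (
            ("no_phlf", cohort["isgls_grade"] == "none"),
            ("grade_A", cohort["isgls_grade"] == "A"),
            ("grade_B", cohort["isgls_grade"] == "B"),
        ):
            if mask.any():
                med, q1, q3 = cohortstats.median_iqr(cohort.loc[mask, index].to_numpy())
                summary[index][group] = {"median": med, "iqr": [q1, q3], "n": int(mask.sum())}

    table = cohortstats.build_table5(cohort)
    report = {
        "n_patients": int(len(cohort)),
        "grade_counts": {g: int((cohort["isgls_grade"] == g).sum()) for g in ("none", "A", "B", "C")},
        "fifty_fifty_count": int(cohort["fifty_fifty"].sum()),
        "summary": summary,
        "diagnostics": table.to_dict(orient="records"),
        "reference_band": {
            "flr_f_pct_min_m2": list(fn.FLR_F_REFERENCE_RANGE),
            "hiba_i_pct": list(fn.HIBA_I_REFERENCE_RANGE),
        },
        "config_hash": config.config_hash(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(outdir / "cohort_graded.csv", index=False)
        table.to_csv(outdir / "diagnostic_table.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if roc_plot:
            _write_roc_plot(cohort, outdir / "roc.png", config)
    return report


def _write_roc_plot(cohort: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    labels = cohort["isgls_grade"].isin(["A", "B"]).to_numpy()
    for index in ("flr_f", "hiba_i"):
        r = cohortstats.roc(cohort[index].to_numpy(float), labels, config.low_is_positive)
        ax.plot(r["fpr"], r["tpr"], label=f"{index} (AUC {r['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
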