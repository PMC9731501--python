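"""Pipeline orchestration: per-subject runs, provenance, QC and reliability.

A subject/visit run executes: DWI preprocessing (realignment, b-vector
rotation, brain masking, WLS tensor fit, FA) -> T1 segmentation and
boundary-based b0->T1 registration -> nonlinear T1->template registration ->
one-step back-projection chain -> anatomy-restricted tract and boundary
segmentation -> ROI metric extraction.  Outputs live under
``<out>/<subject>/<visit>/{dwi,anat,xfm,masks,metrics,qc}``; all volumes are
NIfTI, all tables CSV, transforms in the plain-text/NIfTI formats of the
transforms module.  Every run writes a resolved-config copy and a
provenance log (config hash, seed, software version, stage timings), and a
completed run is not recomputed unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dwi import (
    GradientTable,
    average_b0,
    brain_mask_from_b0,
    fa_from_tensor,
    fit_tensor_wls,
    realign_volumes,
    rotate_bvecs,
)
from .image import (
    BinaryMask,
    Volume,
    load_volume,
    resample,
    save_volume,
    threshold_binarize,
)
from .metrics import (
    bootstrap_icc,
    cov_table,
    exclude_tracts,
    icc_consistency,
    pairwise_visit_correlation,
    roi_stats,
    tukey_nonadditivity,
)
from .register import bbr_refine, build_native_chain, nonlinear_to_template, rigid_prealign
from .segment import (
    ROIAtlas,
    make_wm_mask,
    segment_tissues,
    segment_tract,
    segment_wm_boundary,
    split_boundary,
    tract_boundary,
)

log = logging.getLogger("diffseg")

STAGES = ("preprocess", "register", "segment", "metrics")


def _tissue_feature(vol: Volume, tissues=None, wm_weight: float = 0.8) -> Volume:
    """Normalized intensity plus weighted WM posterior, for registration."""
    if tissues is None:
        mask = brain_mask_from_b0(vol, frac=0.15)
        tissues = segment_tissues(vol, mask)
    fg = vol.data[vol.data > 0]
    hi = np.percentile(fg, 99.5) if fg.size else 1.0
    data = np.clip(vol.data / max(hi, 1e-12), 0.0, 1.2) + wm_weight * tissues.wm.data
    return Volume(data, vol.affine.copy())


@dataclass
class RunConfig:
    """Resolved configuration of a subject/visit run."""

    dwi: str = ""
    bvals: str = ""
    bvecs: str = ""
    t1: str = ""
    template: str = ""
    atlas: str = ""
    labels: str = ""
    out_dir: str = "out"
    subject: str = "sub-01"
    visit: str = "visit-1"
    wm_threshold: float = 0.8
    tract_threshold: float = 0.8
    csf_threshold: float = 0.8
    pre_erode: int = 1
    wm_erode: int = 1
    both_erosions: bool = True     # also emit the conservative 2-erosion table
    cov_cutoff: float = 5.0
    n_boot: int = 10000
    bin_width: float = 0.02
    seed: int = 0
    force: bool = False
    fieldmap: str | None = None    # reserved; not implemented
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        for name in ("wm_threshold", "tract_threshold", "csf_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.pre_erode < 0 or self.wm_erode < 0:
            raise ValueError("erosion counts must be >= 0")
        if self.fieldmap:
            raise NotImplementedError(
                "field-map-based distortion correction is not implemented; "
                "deformable registration to T1 stands in for it"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    """In-memory bundle of everything a subject run produces."""

    config: RunConfig
    fa: Volume = None
    b0: Volume = None
    brain_mask: BinaryMask = None
    t1_in_dwi: Volume = None
    wm_mask: BinaryMask = None
    csf_mask: BinaryMask = None
    bbr: object = None             # pull-back T1 world -> b0 world
    warp: object = None            # pull-back template world -> T1 world
    chain: object = None           # pull-back b0 world -> template world
    tract_masks: dict = field(default_factory=dict)        # (code, wm_erode) -> mask
    empty_flags: dict = field(default_factory=dict)
    boundaries: object = None
    tract_boundaries: dict = field(default_factory=dict)
    metrics: pd.DataFrame = None
    histograms: pd.DataFrame = None
    motions: list = None
    timings: dict = field(default_factory=dict)


def process_subject(
    dwi: Volume,
    gtab: GradientTable,
    t1: Volume,
    template: Volume,
    atlas: ROIAtlas,
    config: RunConfig | None = None,
) -> SubjectResult:
    """Run the in-memory pipeline on already-loaded inputs.

    ``config.stages`` selects a prefix of the workflow: processing stops
    after the last requested stage (earlier stages always run, since each
    stage consumes its predecessors' outputs).
    """
    config = config or RunConfig()
    res = SubjectResult(config=config)
    missing = [c for c in config.stages if c not in STAGES]
    if missing:
        raise ValueError(f"unknown stages: {missing}")
    last_stage = max(STAGES.index(s) for s in config.stages)

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    dwi_re, motions = realign_volumes(dwi, gtab)
    gtab_rot = rotate_bvecs(gtab, motions)
    res.motions = motions
    res.b0 = average_b0(dwi_re, gtab_rot)
    res.brain_mask = brain_mask_from_b0(res.b0)
    tensor = fit_tensor_wls(dwi_re, gtab_rot, res.brain_mask)
    res.fa = fa_from_tensor(tensor)
    res.timings["preprocess"] = time.perf_counter() - t0
    if last_stage < STAGES.index("register"):
        return res

    # --- register ---------------------------------------------------------
    t0 = time.perf_counter()
    t1_mask = brain_mask_from_b0(t1, frac=0.15)  # T1 assumed brain-extracted
    tissues_t1 = segment_tissues(t1, t1_mask)
    # the BBR surface is the 0.5 posterior isocontour (maximum-likelihood
    # boundary, unbiased under symmetric blur); the 0.8 cut is for ROI
    # restriction, not surface definition
    wm_t1 = make_wm_mask(tissues_t1.wm, 0.5)
    pre = rigid_prealign(res.b0, t1)
    res.bbr = bbr_refine(res.b0, t1, wm_t1, pre)
    if res.bbr.failed:
        log.warning("BBR fell back to the pre-alignment transform")
    # tissue-enhanced feature images for the nonlinear stage: adding the WM
    # posterior to the normalized T1 sharpens exactly the surfaces the
    # back-projected ROIs depend on (same construction on both sides)
    res.warp = nonlinear_to_template(
        _tissue_feature(t1, tissues_t1), _tissue_feature(template)
    )
    res.chain, inv_bbr = build_native_chain(res.warp, res.bbr)
    res.t1_in_dwi = resample(t1, inv_bbr, res.b0)
    res.timings["register"] = time.perf_counter() - t0
    if last_stage < STAGES.index("segment"):
        return res

    # --- segment ----------------------------------------------------------
    t0 = time.perf_counter()
    tissues = segment_tissues(res.t1_in_dwi, res.brain_mask)
    res.wm_mask = make_wm_mask(tissues.wm, config.wm_threshold)
    res.csf_mask = threshold_binarize(tissues.csf, config.csf_threshold)
    erosions = (
        sorted({config.wm_erode, 2}) if config.both_erosions else [config.wm_erode]
    )
    for code in atlas.codes:
        for we in erosions:
            mask, empty = segment_tract(
                atlas, code, res.chain, res.wm_mask,
                reference=res.b0,
                pre_erode=config.pre_erode, wm_erode=we,
                tract_threshold=config.tract_threshold,
            )
            res.tract_masks[(code, we)] = mask
            res.empty_flags[(code, we)] = empty
            if empty:
                log.warning(
                    "empty tract mask: %s (wm_erode=%d)", atlas.names[code], we
                )
    wm_boundary = segment_wm_boundary(res.wm_mask)
    res.boundaries = split_boundary(wm_boundary, res.csf_mask)
    for code in atlas.codes:
        tmask = res.tract_masks[(code, config.wm_erode)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res.tract_boundaries[code] = tract_boundary(tmask, res.boundaries)
    res.timings["segment"] = time.perf_counter() - t0
    if last_stage < STAGES.index("metrics"):
        return res

    # --- metrics ----------------------------------------------------------
    t0 = time.perf_counter()
    rows, hists = [], []
    for (code, we), mask in sorted(res.tract_masks.items()):
        m = roi_stats(
            res.fa, mask, bin_width=config.bin_width,
            subject=config.subject, visit=config.visit,
            tract=atlas.names[code],
        )
        row = m.as_row()
        row["wm_erode"] = we
        rows.append(row)
        if we == config.wm_erode:
            h = m.hist_rows()
            h.insert(0, "subject", config.subject)
            h.insert(1, "visit", config.visit)
            hists.append(h)
    extra = {
        "wm_map": res.wm_mask,
        "wm_boundary": res.boundaries.whole_wm_boundary,
        "wm_csf_boundary": res.boundaries.wm_csf_boundary,
        "wm_gm_boundary": res.boundaries.wm_gm_boundary,
    }
    for name, mask in extra.items():
        m = roi_stats(
            res.fa, mask, bin_width=config.bin_width,
            subject=config.subject, visit=config.visit, tract=name,
        )
        row = m.as_row()
        row["wm_erode"] = config.wm_erode
        rows.append(row)
    res.metrics = pd.DataFrame(rows)
    res.histograms = (
        pd.concat(hists, ignore_index=True) if hists else pd.DataFrame()
    )
    res.timings["metrics"] = time.perf_counter() - t0
    return res


# ---------------------------------------------------------------------------
# on-disk runs
# ---------------------------------------------------------------------------

def _visit_dir(config: RunConfig) -> Path:
    return Path(config.out_dir) / config.subject / config.visit


def run_subject(config: RunConfig, qc: bool = True) -> SubjectResult:
    """Load inputs from the configured paths, run the pipeline, write outputs.

    A completed run (matching config hash) is skipped unless ``force``;
    empty tract masks are warnings, never failures.  On a hard stage failure
    partial outputs remain on disk next to a machine-readable error report.
    """
    vdir = _visit_dir(config)
    marker = vdir / ".done"
    if marker.exists() and not config.force:
        if marker.read_text().strip() == config.config_hash():
            log.info("run already complete: %s", vdir)
            return None

    dwi = load_volume(config.dwi)
    gtab = GradientTable.load(config.bvals, config.bvecs)
    t1 = load_volume(config.t1)
    template = load_volume(config.template)
    atlas = ROIAtlas(load_volume(config.atlas), ROIAtlas.load_table(config.labels))

    for sub in ("dwi", "anat", "xfm", "masks", "metrics", "qc"):
        (vdir / sub).mkdir(parents=True, exist_ok=True)
    try:
        res = process_subject(dwi, gtab, t1, template, atlas, config)
    except Exception as exc:  # keep partial outputs + machine-readable report
        (vdir / "error.json").write_text(
            json.dumps({"error": type(exc).__name__, "message": str(exc)})
        )
        raise

    save_volume(res.b0, vdir / "dwi" / "b0.nii.gz")
    save_volume(res.fa, vdir / "dwi" / "fa.nii.gz")
    save_volume(res.brain_mask, vdir / "dwi" / "brain_mask.nii.gz")
    if res.bbr is not None:
        save_volume(res.t1_in_dwi, vdir / "anat" / "t1_in_dwi.nii.gz")
        res.bbr.save(vdir / "xfm" / "bbr_t1_to_b0.mat")
        res.warp.save(
            vdir / "xfm" / "warp_template_to_t1.nii.gz",
            vdir / "xfm" / "warp_affine.mat",
        )
        res.chain.save_manifest(
            vdir / "xfm" / "chain_template_to_native.yaml",
            ["bbr_t1_to_b0.mat (inverted)", "warp_template_to_t1.nii.gz (inverted)"],
        )
    sid = config.subject
    if res.wm_mask is not None:
        save_volume(res.wm_mask, vdir / "masks" / f"{sid}_wm_map.nii.gz")
        save_volume(
            res.boundaries.whole_wm_boundary,
            vdir / "masks" / f"{sid}_wm_boundary.nii.gz",
        )
        save_volume(
            res.boundaries.wm_csf_boundary, vdir / "masks" / f"{sid}_wm_csf.nii.gz"
        )
        save_volume(
            res.boundaries.wm_gm_boundary, vdir / "masks" / f"{sid}_wm_gm.nii.gz"
        )
        for (code, we), mask in res.tract_masks.items():
            if we == config.wm_erode:
                save_volume(
                    mask, vdir / "masks" / f"{sid}_{atlas.names[code]}_mask.nii.gz"
                )
    if res.metrics is not None:
        res.metrics.to_csv(vdir / "metrics" / "roi_metrics.csv", index=False)
        res.histograms.to_csv(vdir / "metrics" / "fa_histograms.csv", index=False)

    if qc and res.boundaries is not None:
        try:
            _qc_overlay(res, atlas, vdir / "qc" / "overlay.png")
        except Exception as exc:  # QC must never fail a run
            log.warning("QC overlay failed: %s", exc)

    prov = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "timings_s": {k: round(v, 2) for k, v in res.timings.items()},
        "empty_tracts": [
            f"{atlas.names[c]}(wm_erode={w})"
            for (c, w), e in res.empty_flags.items() if e
        ],
    }
    with open(vdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(prov, fh)
    with open(vdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    marker.write_text(config.config_hash())
    return res


def _qc_overlay(res: SubjectResult, atlas: ROIAtlas, path) -> None:
    """Static QC export: FA slice with WM-boundary contour and tract overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = res.fa.shape3[2] // 2
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].imshow(res.fa.data[:, :, z].T, cmap="gray", origin="lower")
    axes[0].set_title("FA")
    axes[1].imshow(res.t1_in_dwi.data[:, :, z].T, cmap="gray", origin="lower")
    axes[1].contour(
        res.boundaries.whole_wm_boundary.data[:, :, z].T, levels=[0.5], colors="r",
        linewidths=0.8,
    )
    axes[1].set_title("T1 in DWI + WM boundary")
    axes[2].imshow(res.fa.data[:, :, z].T, cmap="gray", origin="lower")
    overlay = np.zeros(res.fa.shape3[:2])
    for (code, we), mask in res.tract_masks.items():
        if we == res.config.wm_erode:
            overlay = np.maximum(overlay, code * mask.data[:, :, z])
    axes[2].imshow(
        np.ma.masked_equal(overlay.T, 0), cmap="tab10", origin="lower", alpha=0.6
    )
    axes[2].set_title("tract masks")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# reliability report
# ---------------------------------------------------------------------------

def run_reliability(
    metrics_frames: list[pd.DataFrame] | pd.DataFrame,
    config: RunConfig | None = None,
    out_dir=None,
) -> dict:
    """Full test-retest reliability report from multi-visit ROI metrics.

    Expects tidy metric rows (subject, visit, tract, mean_fa, n_voxels,
    wm_erode) covering >=2 visits with consistent tract sets.  Produces
    per-tract COV for both erosion conditions, the exclusion list, ICC(3,1)
    (tracts x subject-visit raters) with parametric and bootstrap CIs,
    pairwise visit correlations for FA and voxel counts, and Tukey's
    non-additivity test on the first visit's tracts x subjects table (when
    at least 3 subjects are present).
    """
    config = config or RunConfig()
    df = (
        pd.concat(metrics_frames, ignore_index=True)
        if isinstance(metrics_frames, list)
        else metrics_frames.copy()
    )
    if "wm_erode" not in df.columns:
        df["wm_erode"] = config.wm_erode
    # naming consistency is checked before empty-mask rows are dropped: a
    # tract that legitimately segmented empty on one visit is still named
    tract_sets = df.groupby("visit")["tract"].apply(lambda s: frozenset(s))
    if len(set(tract_sets)) > 1:
        base = set.intersection(*[set(s) for s in tract_sets])
        mism = {
            v: sorted(set(s) - base) for v, s in tract_sets.items()
            if set(s) != base
        }
        raise ValueError(f"inconsistent tract sets across visits: {mism}")
    if "undefined" in df.columns:
        df = df[~df["undefined"].astype(bool)]
    if df["visit"].nunique() < 2:
        raise ValueError("reliability needs >=2 visits")

    e1 = df[df["wm_erode"] == 1]
    e2 = df[df["wm_erode"] == 2]
    cov1, sum1 = cov_table(e1)
    report: dict = {"cov_erode1": cov1, "cov_summary_erode1": sum1}
    merged = cov1.rename(columns={"mean_cov": "cov_erode1"})[["tract", "cov_erode1"]]
    if len(e2):
        cov2, sum2 = cov_table(e2)
        report["cov_erode2"] = cov2
        report["cov_summary_erode2"] = sum2
        merged = merged.merge(
            cov2.rename(columns={"mean_cov": "cov_erode2"})[["tract", "cov_erode2"]],
            on="tract", how="outer",
        )
    kept, excluded = exclude_tracts(merged, cutoff=config.cov_cutoff)
    report["kept"], report["excluded"] = kept, excluded
    report["cov_conditions"] = merged

    # ICC: tracts as targets, subject x visit as raters
    wide = e1.pivot_table(
        index="tract", columns=["subject", "visit"], values="mean_fa"
    ).dropna(axis=0)
    if wide.shape[0] >= 2 and wide.shape[1] >= 2:
        report["icc"] = icc_consistency(wide.to_numpy())
        report["icc_boot"] = bootstrap_icc(
            wide.to_numpy(), n_boot=config.n_boot, seed=config.seed
        )
    report["pairwise_fa"] = pairwise_visit_correlation(e1, "mean_fa")
    report["pairwise_voxels"] = pairwise_visit_correlation(e1, "n_voxels")

    first_visit = sorted(e1["visit"].unique())[0]
    t1_table = e1[e1["visit"] == first_visit].pivot_table(
        index="tract", columns="subject", values="mean_fa"
    ).dropna(axis=0)
    if t1_table.shape[0] >= 3 and t1_table.shape[1] >= 3:
        report["tukey"] = tukey_nonadditivity(t1_table.to_numpy())

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        merged.to_csv(out / "cov_by_tract.csv", index=False)
        pd.DataFrame({"tract": kept}).to_csv(out / "kept_tracts.csv", index=False)
        pd.DataFrame({"tract": excluded}).to_csv(
            out / "excluded_tracts.csv", index=False
        )
        report["pairwise_fa"].to_csv(out / "pairwise_fa.csv", index=False)
        report["pairwise_voxels"].to_csv(out / "pairwise_voxels.csv", index=False)
        scalars = {}
        if "icc" in report:
            icc = report["icc"]
            scalars.update(
                icc=icc["icc"], icc_F=icc["F"],
                icc_ci_lower=icc["ci"][0], icc_ci_upper=icc["ci"][1],
                icc_boot_lower=report["icc_boot"]["ci"][0],
                icc_boot_upper=report["icc_boot"]["ci"][1],
            )
        if "tukey" in report:
            scalars.update(
                tukey_F=report["tukey"]["F"], tukey_p=report["tukey"]["p"]
            )
        scalars["grand_mean_cov"] = report["cov_summary_erode1"]["grand_mean_cov"]
        scalars["grand_sd_cov"] = report["cov_summary_erode1"]["grand_sd_cov"]
        pd.DataFrame([scalars]).to_csv(out / "reliability_summary.csv", index=False)
    return report
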