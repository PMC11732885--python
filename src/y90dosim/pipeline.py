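"""End-to-end orchestration: phantom -> segmentation -> dosimetry -> statistics.

A single :class:`RunConfig` drives the whole chain and a single top-level
seed feeds deterministic substreams to every stochastic stage, so identical
configs produce identical reports (timestamps are excluded from the config
hash).  Artifacts are written as NIfTI (grids, masks), CSV (cohort) and JSON
(report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, pearson_corr
from .cohort import CohortConfig, simulate_cohort
from .dosimetry import PhysicsConstants, calibrate, compartment_summary, dose_map
from .grids import VoxelGrid, save_mask
from .outcomes import fit_cox_tad, fit_dose_response_logistic, km_curve, multivariable_select
from .phantom import Lesion, LesionSpec, Phantom, PhantomConfig, generate_phantom, simulate_misregistration
from .segmentation import (
    CompartmentSet,
    ThresholdSpec,
    derive_compartments,
    lesion_diameter,
    threshold_segment,
)

log = logging.getLogger("y90dosim")

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "segment_threshold_method",
    "preset_matched",
    "preset_misregistered",
    "preset_threshold_infeasible",
]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    physics: PhysicsConstants = field(default_factory=PhysicsConstants)
    tumor_threshold: float = 0.30      # isocontour fraction for tumor VOIs
    perfused_threshold: float = 0.10   # isocontour fraction for perfused volume
    box_margin_voxels: int = 3         # padding of the user box around each VOI
    maa_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # pre-count misregistration
    seed: int = 0

    def __post_init__(self) -> None:
        # Propagate the top-level seed into per-stage substreams.
        ss = np.random.SeedSequence(self.seed)
        s_ph, s_co = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
        self.phantom = dataclasses.replace(self.phantom, seed=s_ph)
        self.cohort = dataclasses.replace(self.cohort, seed=s_co)

    def to_dict(self) -> dict:
        def _clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items() if not callable(v)}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        d = _clean(self)
        d["cohort"].pop("covariate_generators", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable result of a run plus the in-memory objects."""

    report: dict
    phantom: Phantom
    compartments: dict[str, CompartmentSet]
    cohort: pd.DataFrame


def _bounding_box(mask: np.ndarray, margin: int, shape) -> tuple:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, shape)
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))


def segment_threshold_method(
    counts: VoxelGrid,
    phantom: Phantom,
    tumor_threshold: float = 0.30,
    perfused_threshold: float = 0.10,
    box_margin_voxels: int = 3,
) -> CompartmentSet:
    """Activity-isocontour counterpart of the anatomic compartments.

    The perfused volume is re-segmented as a low isocontour inside a box
    around the true perfused region (clipped to the liver); each tumor is
    re-segmented as a high isocontour inside a box around its anatomic mask
    (clipped to the threshold perfused volume), with the diameter recomputed
    from the resulting mask.  Tumors whose box contains no signal yield an
    empty isocontour and are skipped with a log message — the
    threshold-infeasible situation.
    """
    shape = counts.shape
    perf_box = _bounding_box(phantom.perfused, box_margin_voxels, shape)
    perf_mask = threshold_segment(
        counts,
        ThresholdSpec(perf_box, perfused_threshold, clip=phantom.whole_liver),
    )
    lesions: list[Lesion] = []
    for les in phantom.lesions:
        box = _bounding_box(les.mask, box_margin_voxels, shape)
        m = threshold_segment(counts, ThresholdSpec(box, tumor_threshold, clip=perf_mask))
        if not m.any():
            log.warning("threshold segmentation infeasible for lesion %s", les.id)
            continue
        lesions.append(Lesion(les.id, m, lesion_diameter(m, counts.spacing_mm)))
    return derive_compartments(phantom.whole_liver, perf_mask, lesions, "maa_threshold")


def run_pipeline(config: RunConfig, outdir: str | None = None) -> RunReport:
    """Execute every stage and assemble the report.

    Any stage failure raises with the stage name prefixed; artifacts written
    before a failure are left as partial output (flagged in the exception).
    """
    stage = "phantom"
    try:
        phantom = generate_phantom(config.phantom)
        pre = phantom.pre_counts
        if any(s != 0 for s in config.maa_shift_mm):
            pre = simulate_misregistration(pre, config.maa_shift_mm)

        stage = "segmentation"
        comps_anat = derive_compartments(
            phantom.whole_liver, phantom.perfused, phantom.lesions, "anatomic"
        )
        comps_thresh = segment_threshold_method(
            pre,
            phantom,
            config.tumor_threshold,
            config.perfused_threshold,
            config.box_margin_voxels,
        )

        stage = "dosimetry"
        activity = config.phantom.administered_activity_GBq
        reports = {}
        for comps in (comps_anat, comps_thresh):
            cal = calibrate(pre, comps.perfused, activity)
            dmap = dose_map(pre, cal, config.physics, timepoint="pre")
            reports[f"pre_{comps.method}"] = compartment_summary(dmap, comps)
        # Post-treatment dosimetry uses the anatomic compartments.
        cal_post = calibrate(phantom.post_activity, comps_anat.perfused, activity)
        dmap_post = dose_map(phantom.post_activity, cal_post, config.physics, timepoint="post")
        reports["post_anatomic"] = compartment_summary(dmap_post, comps_anat)

        stage = "cohort"
        cohort = simulate_cohort(config.cohort)

        stage = "statistics"
        stats: dict = {}
        n = len(cohort)
        from .outcomes import orr_with_ci

        for flag in ("response_mrecist", "response_recist11"):
            rate, ci = orr_with_ci(int(cohort[flag].sum()), n)
            stats[f"orr_{flag}"] = {"rate_pct": rate, "ci95_pct": list(ci)}
        for dose_col in ("tad_anat_gy", "tad_thresh_gy"):
            tag = "anat" if "anat" in dose_col else "thresh"
            stats[f"tcp_mrecist_{tag}"] = fit_dose_response_logistic(
                cohort, dose_col, "response_mrecist"
            ).to_dict()
            stats[f"cox_os_{tag}"] = fit_cox_tad(cohort, dose_col).to_dict()
        stats["ntcp_tox"] = fit_dose_response_logistic(
            cohort, "ntad_perfused_gy", "tox_grade3plus"
        ).to_dict()
        stats["km_os"] = km_curve(cohort).to_dict()
        sel = multivariable_select(
            cohort,
            candidates=["age_years", "sex_male", "cirrhosis", "bclc_c"],
        )
        stats["multivariable_tox"] = {
            "forced": sel.forced_term,
            "selected": sel.selected,
            "trail": sel.trail,
        }
        ba = bland_altman(cohort["tad_anat_gy"], cohort["tad_post_gy"])
        stats["bland_altman_tad"] = ba.to_dict()
        stats["pearson_tad"] = pearson_corr(cohort["tad_anat_gy"], cohort["tad_post_gy"])

        report = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "dose_reports": {k: v.to_dict() for k, v in reports.items()},
            "statistics": stats,
        }

        if outdir is not None:
            stage = "write"
            os.makedirs(outdir, exist_ok=True)
            pre.to_nifti(os.path.join(outdir, "pre_counts.nii.gz"))
            phantom.post_activity.to_nifti(os.path.join(outdir, "post_activity.nii.gz"))
            for name, m in comps_anat.as_dict().items():
                save_mask(m, pre, os.path.join(outdir, f"mask_{name}.nii.gz"))
            cohort.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
            with open(os.path.join(outdir, "report.json"), "w") as fh:
                json.dump(report, fh, indent=2)

        return RunReport(report, phantom, {"anatomic": comps_anat, "maa_threshold": comps_thresh}, cohort)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Scenario presets: the three qualitative imaging situations.
# ---------------------------------------------------------------------------


def _single_lesion_phantom(tumor_to_normal: float, seed: int = 0) -> PhantomConfig:
    cfg = PhantomConfig(seed=seed)
    extent = tuple((n - 1) * cfg.spacing_mm for n in cfg.shape)
    center = tuple(e / 2 for e in extent)
    perf_center = tuple(c + o for c, o in zip(center, cfg.perfused_offset_mm))
    cfg.lesions = [LesionSpec(perf_center, 4.0, "T1")]
    cfg.tumor_to_normal = tumor_to_normal
    return cfg


def preset_matched(seed: int = 0) -> RunConfig:
    """Well-matched case: hypervascular tumor, focal uptake, no misregistration."""
    return RunConfig(phantom=_single_lesion_phantom(8.0, seed), seed=seed)


def preset_misregistered(seed: int = 0, shift_mm: float = 16.0) -> RunConfig:
    """Misaligned case: the count map is shifted against the anatomic masks."""
    return RunConfig(
        phantom=_single_lesion_phantom(8.0, seed),
        maa_shift_mm=(shift_mm, 0.0, 0.0),
        seed=seed,
    )


def preset_threshold_infeasible(seed: int = 0) -> RunConfig:
    """No focal uptake (T/N = 1): the isocontour cannot delineate the tumor."""
    return RunConfig(phantom=_single_lesion_phantom(1.0, seed), seed=seed)
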