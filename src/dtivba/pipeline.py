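"""End-to-end runs: phantom generation and the full analysis, reproducibly.

A run is a pure function of its configuration plus seed: ``run_phantom``
writes a cohort (per-subject 4D DWI NIfTI with FSL bval/bvec, a subject
manifest CSV, ground-truth masks and the resolved config), and
``run_analysis`` executes mask -> tensor fit -> scalar maps -> global/ROI
tables -> voxel-based analysis -> multi-template consensus, emitting CSV
tables, NIfTI stat maps and a JSON run summary with provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gradients import default_scheme
from .io import read_dwi, read_manifest, read_volume, write_dwi, write_manifest, write_volume
from .mask import compute_brain_mask, compute_idwi
from .phantom import default_spec, focal_effect_spec, generate_cohort, null_spec
from .stats import two_sample_compare
from .summary import (
    behavior_correlation_table,
    compare_cohort,
    roi_comparison_table,
    summarize_subject,
)
from .tensor import METRIC_NAMES, fit_tensors, scalar_maps
from .vba import (
    build_stack,
    estimate_affine,
    multi_template_consensus,
    voxelwise_correlation,
    voxelwise_group_test,
)

log = logging.getLogger("dtivba")

__all__ = ["RunConfig", "run_phantom", "run_analysis"]


@dataclass
class RunConfig:
    # phantom
    seed: int = 0
    n_per_group: int = 10
    n_directions: int = 30
    b_value: float = 3000.0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spec_kind: str = "default"  # default | focal | null
    delta_fa: float = 0.03  # focal spec only
    noise_model: str = "rician"
    # masking
    threshold_fraction: float = 0.05
    closing_radius: int = 1
    opening_radius: int = 1
    # tensor fit
    fit_method: str = "ols"
    # global analysis
    wm_threshold: float = 0.20
    # vba
    smooth_kernel: int = 3
    smooth_sigma: float = 1.0
    alpha: float = 0.01
    consensus_fraction: float = 1.0
    registration: str = "identity"  # identity | affine
    max_templates: int | None = 5
    run_vba: bool = True
    vba_metrics: tuple[str, ...] = ("fa", "adc", "linearity", "planarity", "sphericity")
    vba_scores: tuple[str, ...] = ("head_turn",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.vba_metrics = tuple(cfg.vba_metrics)
        cfg.vba_scores = tuple(cfg.vba_scores)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _spec_from_config(cfg: RunConfig):
    if cfg.spec_kind == "default":
        return default_spec(cfg.grid_shape)
    if cfg.spec_kind == "focal":
        return focal_effect_spec(cfg.delta_fa, cfg.grid_shape)
    if cfg.spec_kind == "null":
        return null_spec(cfg.grid_shape)
    raise ValueError(f"unknown spec_kind {cfg.spec_kind!r}")


def run_phantom(cfg: RunConfig, out_dir) -> Path:
    """Generate a cohort on disk; returns the cohort directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _spec_from_config(cfg)
    scheme = default_scheme(cfg.n_directions, cfg.b_value)
    log.info("generating cohort: %d/%d subjects, %d directions, seed %d",
             cfg.n_per_group, cfg.n_per_group, cfg.n_directions, cfg.seed)
    cohort = generate_cohort(
        spec, cfg.n_per_group, scheme, seed=cfg.seed, noise_model=cfg.noise_model
    )
    vs = spec.voxel_size
    for s in cohort.subjects:
        sid = s.record.subject_id
        write_dwi(s.dwi, out / f"sub-{sid}_dwi.nii.gz", out / f"sub-{sid}.bval",
                  out / f"sub-{sid}.bvec")
    write_manifest(cohort.records, out / "manifest.csv")
    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)
    write_volume(spec.brain_mask.astype(np.uint8), vs, gt / "brain_mask.nii.gz", np.uint8)
    write_volume(spec.wm_mask.astype(np.uint8), vs, gt / "wm_mask.nii.gz", np.uint8)
    write_volume(
        spec.effect_region_mask.astype(np.uint8), vs, gt / "effect_region_mask.nii.gz", np.uint8
    )
    with open(gt / "couplings.json", "w") as fh:
        json.dump(_jsonable(cohort.achieved_correlations), fh, indent=2)
    cfg.to_yaml(out / "config.yaml")
    return out


def run_analysis(cfg: RunConfig, cohort_dir, out_dir, roi_labels_path=None) -> dict:
    """Full analysis of a cohort directory; returns the run summary dict."""
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_manifest(cohort_dir / "manifest.csv")
    by_id = {r.subject_id: r for r in records}

    roi_labels = None
    if roi_labels_path is not None:
        roi_labels = read_volume(roi_labels_path)[0].astype(int)

    # stage 1-3: mask, fit, maps, per-subject summaries
    summaries, all_maps, all_masks, failures = [], {}, {}, []
    counts = {}
    for rec in records:
        sid = rec.subject_id
        try:
            dwi = read_dwi(
                cohort_dir / f"sub-{sid}_dwi.nii.gz",
                cohort_dir / f"sub-{sid}.bval",
                cohort_dir / f"sub-{sid}.bvec",
            )
            idwi = compute_idwi(dwi)
            brain = compute_brain_mask(
                idwi, dwi.voxel_size, cfg.threshold_fraction, cfg.closing_radius,
                cfg.opening_radius,
            )
            tf = fit_tensors(dwi, brain, method=cfg.fit_method)
            maps = scalar_maps(tf)
            counts[sid] = {
                "brain_voxels": brain.n_voxels,
                "valid_fit_voxels": int((brain.mask & maps.valid_mask).sum()),
                "clamped_eigenvalues": tf.n_clamped,
            }
            summaries.append(
                summarize_subject(maps, brain, rec, roi_labels=roi_labels)
            )
            all_maps[sid], all_masks[sid] = maps, brain
        except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
            failures.append(sid)
            raise RuntimeError(f"[subject {sid}] tensor pipeline failed: {exc}") from exc

    voxel_size = next(iter(all_masks.values())).voxel_size

    # stage 4: global tables
    table_global = compare_cohort(summaries, records, cfg.wm_threshold)
    table_global.to_csv(out / "table_global.csv", index=False)
    table_corr = behavior_correlation_table(summaries, records, cfg.wm_threshold)
    table_corr.to_csv(out / "table_behavior_correlations.csv", index=False)
    if roi_labels is not None:
        roi_comparison_table(summaries, records).to_csv(out / "table_rois.csv", index=False)

    # behavior table (descriptives + test per score), table-1 shaped
    rows = []
    for name in records[0].scores:
        xs = [r.scores.get(name, np.nan) for r in records if r.group == "control"]
        ys = [r.scores.get(name, np.nan) for r in records if r.group == "IUGR"]
        xs = np.asarray(xs, float)[np.isfinite(xs)]
        ys = np.asarray(ys, float)[np.isfinite(ys)]
        if xs.size >= 3 and ys.size >= 3:
            res = two_sample_compare(xs, ys)
            rows.append({"item": name, "statistic": res.statistic, "p": res.p_value,
                         "method": res.method, "n_control": xs.size, "n_IUGR": ys.size})
    pd.DataFrame(rows).to_csv(out / "table_behavior.csv", index=False)

    # stage 5: VBA with multi-template consensus
    ids = [r.subject_id for r in records]
    groups = [r.group for r in records]
    templates = list(range(len(ids))) if cfg.run_vba else []
    if cfg.max_templates is not None:
        templates = templates[: cfg.max_templates]
    fa_maps = [all_maps[s].fa for s in ids]
    brain_masks = [all_masks[s].mask for s in ids]

    vba_summary: dict = {}
    consensus_dir = out / "vba"
    if cfg.run_vba:
        consensus_dir.mkdir(exist_ok=True)
    per_metric_results: dict[str, list] = {m: [] for m in cfg.vba_metrics}
    corr_results: dict[str, list] = {s: [] for s in cfg.vba_scores}
    for t in templates:
        if cfg.registration == "affine":
            transforms = [
                None if i == t else estimate_affine(fa_maps[i], fa_maps[t], voxel_size,
                                                    seed=1000 + 31 * t + i)
                for i in range(len(ids))
            ]
        else:
            transforms = None
        for metric in cfg.vba_metrics:
            stack = build_stack(
                [all_maps[s][metric] for s in ids], brain_masks, ids, t, voxel_size,
                transforms, cfg.smooth_sigma, cfg.smooth_kernel,
            )
            per_metric_results[metric].append(voxelwise_group_test(stack, groups))
        for score in cfg.vba_scores:
            stack = build_stack(fa_maps, brain_masks, ids, t, voxel_size, transforms,
                                cfg.smooth_sigma, cfg.smooth_kernel)
            scores = [by_id[s].scores.get(score, np.nan) for s in ids]
            corr_results[score].append(voxelwise_correlation(stack, scores))

    for metric, results in per_metric_results.items():
        if not results:
            continue
        ref = results[0]
        for name, vol in (("t", ref.statistic), ("p", ref.p),
                          ("sig01", ref.sig01.astype(np.uint8)),
                          ("sig05", ref.sig05.astype(np.uint8))):
            write_volume(np.nan_to_num(vol), voxel_size,
                         consensus_dir / f"{metric}_template0_{name}.nii.gz")
        if len(results) >= 2:
            cons, support = multi_template_consensus(results, cfg.alpha, cfg.consensus_fraction)
        else:
            cons = ref.sig01 if cfg.alpha == 0.01 else ref.sig05
            support = cons.astype(int)
        write_volume(cons.astype(np.uint8), voxel_size,
                     consensus_dir / f"{metric}_consensus_sig.nii.gz", np.uint8)
        write_volume(support.astype(np.uint8), voxel_size,
                     consensus_dir / f"{metric}_consensus_support.nii.gz", np.uint8)
        vba_summary[metric] = {
            "significant_voxels_template0": int(ref.sig01.sum() if cfg.alpha == 0.01
                                                else ref.sig05.sum()),
            "consensus_voxels": int(cons.sum()),
            "direction_control_gt_iugr": int(((cons) & (ref.direction > 0)).sum()),
        }
    for score, results in corr_results.items():
        if not results:
            continue
        ref = results[0]
        write_volume(np.nan_to_num(ref.statistic), voxel_size,
                     consensus_dir / f"rho_{score}_template0.nii.gz")
        write_volume(ref.extra["display_mask"].astype(np.uint8), voxel_size,
                     consensus_dir / f"rho_{score}_display_gt0.2.nii.gz", np.uint8)
        if len(results) >= 2:
            cons, _ = multi_template_consensus(results, cfg.alpha, cfg.consensus_fraction)
        else:
            cons = ref.sig01 if cfg.alpha == 0.01 else ref.sig05
        vba_summary[f"rho_{score}"] = {
            "significant_voxels_template0": int(ref.sig01.sum() if cfg.alpha == 0.01
                                                else ref.sig05.sum()),
            "consensus_voxels": int(cons.sum()),
        }

    summary = {
        "version": __version__,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "n_subjects": len(ids),
        "templates_used": len(templates),
        "registration": cfg.registration,
        "subject_counts": counts,
        "failed_subjects": failures,
        "group_means": {
            g: {
                m: float(np.mean([s.whole_brain[m] for s, r in zip(summaries, records)
                                  if r.group == g]))
                for m in METRIC_NAMES
            }
            for g in ("control", "IUGR")
        },
        "vba": vba_summary,
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    cfg.to_yaml(out / "config.yaml")
    return summary
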