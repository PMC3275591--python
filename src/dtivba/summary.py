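"""Global, WM-threshold and ROI summaries, and group comparison tables.

Per subject: whole-brain means of the seven diffusion metrics, the same
means inside FA-threshold white-matter masks over a threshold sweep
(default 0.05 to 0.40 in steps of 0.05), per-ROI means when a label map is
supplied, brain volume and the brain-volume/birth-weight ratio (mm^3/g).
Across subjects: a gated two-sample comparison per measure (the shape of a
global-analysis table) and a Spearman correlation table of diffusion
metrics against every neurobehavioral item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import SCORE_REGISTRY, SubjectRecord, check_same_grid
from .mask import BrainMask
from .stats import describe, spearman, two_sample_compare
from .tensor import METRIC_NAMES, ScalarMapSet, wm_mask_from_fa

__all__ = [
    "SubjectSummary",
    "DEFAULT_WM_THRESHOLDS",
    "summarize_subject",
    "compare_cohort",
    "behavior_correlation_table",
    "resample_labels",
]

DEFAULT_WM_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.401, 0.05), 2))

#: metrics reported in the behavior-correlation table
CORRELATION_METRICS = ("fa", "adc", "axial_diffusivity", "radial_diffusivity")


@dataclass
class SubjectSummary:
    subject_id: str
    brain_volume_mm3: float
    volume_weight_ratio: float | None  # mm^3 / g, None when weight unknown
    whole_brain: dict[str, float]  # metric -> mean
    wm: dict[float, dict[str, float]]  # threshold -> metric -> mean
    rois: dict[int, dict[str, float]] = field(default_factory=dict)
    n_valid_voxels: int = 0


def resample_labels(labels: np.ndarray, affine: np.ndarray, out_shape) -> np.ndarray:
    """Apply a voxel-space affine to an integer label map (nearest neighbour).

    ``affine`` is a 4x4 pull transform: output voxel x maps to input voxel
    ``A[:3, :3] @ x + A[:3, 3]``.
    """
    A = np.asarray(affine, dtype=float)
    return ndimage.affine_transform(
        np.asarray(labels), A[:3, :3], A[:3, 3], output_shape=tuple(out_shape), order=0
    )


def summarize_subject(
    maps: ScalarMapSet,
    brain: BrainMask,
    record: SubjectRecord | None = None,
    wm_thresholds=DEFAULT_WM_THRESHOLDS,
    roi_labels: np.ndarray | None = None,
) -> SubjectSummary:
    """Mask-restricted means of every metric for one subject.

    All means are over ``brain AND valid-fit`` voxels; WM means additionally
    condition on FA above each threshold in the sweep.  ROI label maps must
    already be on the subject grid (use :func:`resample_labels` first when a
    transform is needed).
    """
    check_same_grid(maps.fa.shape, brain.mask.shape, "scalar maps")
    analysis = brain.mask & maps.valid_mask
    whole = {m: float(maps[m][analysis].mean()) for m in METRIC_NAMES}
    wm: dict[float, dict[str, float]] = {}
    for thr in wm_thresholds:
        wm_mask = wm_mask_from_fa(maps.fa, brain, float(thr)).mask & maps.valid_mask
        if wm_mask.any():
            wm[float(thr)] = {m: float(maps[m][wm_mask].mean()) for m in METRIC_NAMES}
        else:
            wm[float(thr)] = {m: float("nan") for m in METRIC_NAMES}
    rois: dict[int, dict[str, float]] = {}
    if roi_labels is not None:
        check_same_grid(maps.fa.shape, roi_labels.shape, "ROI label map")
        for label in np.unique(roi_labels):
            if label == 0:
                continue
            sel = (roi_labels == label) & analysis
            if sel.any():
                rois[int(label)] = {m: float(maps[m][sel].mean()) for m in METRIC_NAMES}
    ratio = None
    if record is not None and np.isfinite(record.birth_weight) and record.birth_weight > 0:
        ratio = brain.volume_mm3 / record.birth_weight
    return SubjectSummary(
        subject_id=record.subject_id if record is not None else "",
        brain_volume_mm3=brain.volume_mm3,
        volume_weight_ratio=ratio,
        whole_brain=whole,
        wm=wm,
        rois=rois,
        n_valid_voxels=int(analysis.sum()),
    )


def _split_groups(
    summaries: list[SubjectSummary], records: list[SubjectRecord]
) -> tuple[list[SubjectSummary], list[SubjectSummary]]:
    by_id = {r.subject_id: r for r in records}
    ctrl = [s for s in summaries if by_id[s.subject_id].group == "control"]
    iugr = [s for s in summaries if by_id[s.subject_id].group == "IUGR"]
    if len(ctrl) < 2 or len(iugr) < 2:
        raise ValueError("need at least 2 subjects per group")
    return ctrl, iugr


def _row(measure, mask_name, xs, ys) -> dict:
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    n_x, n_y = int(np.isfinite(xs).sum()), int(np.isfinite(ys).sum())
    if n_x >= 3 and n_y >= 3:
        res = two_sample_compare(xs, ys)
        statistic, p, method = res.statistic, res.p_value, res.method
    else:
        # descriptives are still reported; the test needs 3 finite values
        # per group (tiny cohorts, or WM means undefined for some subjects)
        statistic, p, method = float("nan"), float("nan"), "insufficient_n"
    return {
        "measure": measure,
        "mask": mask_name,
        "control": describe(xs),
        "IUGR": describe(ys),
        "statistic": statistic,
        "p": p,
        "method": method,
        "n_control": n_x,
        "n_IUGR": n_y,
    }


def compare_cohort(
    summaries: list[SubjectSummary],
    records: list[SubjectRecord],
    wm_threshold: float = 0.20,
) -> pd.DataFrame:
    """Group-comparison table: volumes, whole-brain and WM-mask metrics.

    One row per measure with group descriptives (mean (sd) or median (IQR)
    according to the normality gate), the test statistic, the two-sided p
    and the method actually used.
    """
    ctrl, iugr = _split_groups(summaries, records)
    by_id = {r.subject_id: r for r in records}
    rows = [
        _row(
            "brain_volume_mm3",
            "brain",
            [s.brain_volume_mm3 for s in ctrl],
            [s.brain_volume_mm3 for s in iugr],
        ),
        _row(
            "birth_weight_g",
            "-",
            [by_id[s.subject_id].birth_weight for s in ctrl],
            [by_id[s.subject_id].birth_weight for s in iugr],
        ),
    ]
    if all(s.volume_weight_ratio is not None for s in ctrl + iugr):
        rows.append(
            _row(
                "volume_weight_ratio_mm3_per_g",
                "-",
                [s.volume_weight_ratio for s in ctrl],
                [s.volume_weight_ratio for s in iugr],
            )
        )
    for metric in METRIC_NAMES:
        rows.append(
            _row(
                metric,
                "whole_brain",
                [s.whole_brain[metric] for s in ctrl],
                [s.whole_brain[metric] for s in iugr],
            )
        )
    for metric in METRIC_NAMES:
        rows.append(
            _row(
                metric,
                f"wm_fa>{wm_threshold:g}",
                [s.wm[wm_threshold][metric] for s in ctrl],
                [s.wm[wm_threshold][metric] for s in iugr],
            )
        )
    return pd.DataFrame(rows)


def roi_comparison_table(
    summaries: list[SubjectSummary], records: list[SubjectRecord]
) -> pd.DataFrame:
    """Per-ROI, per-metric group comparison (requires ROI means present)."""
    ctrl, iugr = _split_groups(summaries, records)
    labels = sorted({k for s in summaries for k in s.rois})
    rows = []
    for label in labels:
        for metric in METRIC_NAMES:
            xs = [s.rois[label][metric] for s in ctrl if label in s.rois]
            ys = [s.rois[label][metric] for s in iugr if label in s.rois]
            if len(xs) >= 3 and len(ys) >= 3:
                row = _row(metric, f"roi_{label}", xs, ys)
                row["roi"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def behavior_correlation_table(
    summaries: list[SubjectSummary],
    records: list[SubjectRecord],
    wm_threshold: float = 0.20,
    metrics=CORRELATION_METRICS,
) -> pd.DataFrame:
    """Spearman correlations of each behavioral item with the diffusion means.

    Rows: score x metric x mask (whole brain and the FA > ``wm_threshold``
    WM mask).  Missing scores are dropped pairwise; an undefined correlation
    (constant score) is reported with NaN rho and a note rather than an
    error.
    """
    by_id = {r.subject_id: r for r in records}
    rows = []
    for score in SCORE_REGISTRY:
        svals = np.array(
            [by_id[s.subject_id].scores.get(score, np.nan) for s in summaries], dtype=float
        )
        if np.isfinite(svals).sum() < 4:
            continue
        for mask_name in ("whole_brain", f"wm_fa>{wm_threshold:g}"):
            for metric in metrics:
                if mask_name == "whole_brain":
                    mvals = np.array([s.whole_brain[metric] for s in summaries])
                else:
                    mvals = np.array([s.wm[wm_threshold][metric] for s in summaries])
                keep = np.isfinite(svals) & np.isfinite(mvals)
                if keep.sum() < 4:
                    continue
                res = spearman(svals[keep], mvals[keep])
                rows.append(
                    {
                        "score": score,
                        "metric": metric,
                        "mask": mask_name,
                        "rho": res.statistic,
                        "p": res.p_value,
                        "n": int(keep.sum()),
                        "note": res.note or "",
                    }
                )
    return pd.DataFrame(rows)
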