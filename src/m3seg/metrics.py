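"""Evaluation metrics: Dice similarity (DSC), 95th-percentile Hausdorff
surface distance (HD95) and intersection-over-union (IOU).

DSC and IOU measure regional overlap between a predicted binary mask P and
the ground truth G; HD95 measures boundary agreement in millimetres. A
voxel is a boundary voxel if it is foreground with at least one background
face-neighbour (volume edges count as background); distances are exact
Euclidean distances on the spacing-scaled grid, and HD95 is the 95th
percentile of the pooled union of the two directed boundary-distance sets.

HD95 is undefined when either mask is empty; such cases are flagged and
excluded from means (with the exclusion count reported) rather than
imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["dsc", "iou", "hd95", "evaluate_case", "MetricReport"]


def _check_pair(p: np.ndarray, g: np.ndarray):
    p = np.asarray(p).astype(bool)
    g = np.asarray(g).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return p, g


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient in percent: ``2|P∩G| / (|P|+|G|) * 100``.

    Both masks empty counts as perfect agreement (100)."""
    p, g = _check_pair(pred, truth)
    total = p.sum() + g.sum()
    if total == 0:
        return 100.0
    return 200.0 * np.logical_and(p, g).sum() / total


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union ``|P∩G| / |P∪G|`` (both empty -> 1)."""
    p, g = _check_pair(pred, truth)
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def _boundary(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)  # face connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def _directed_surface_distances(a: np.ndarray, b: np.ndarray,
                                spacing) -> np.ndarray:
    """Distances from each boundary voxel of ``a`` to the boundary of ``b``."""
    bb = _boundary(b)
    dt = ndimage.distance_transform_edt(~bb, sampling=spacing)
    return dt[_boundary(a)]


def hd95(pred: np.ndarray, truth: np.ndarray, spacing=None) -> float:
    """95th percentile of pooled bidirectional boundary distances, in mm.

    Returns ``nan`` (undefined) when either mask is empty.
    """
    p, g = _check_pair(pred, truth)
    if spacing is None:
        spacing = (1.0,) * p.ndim
    if len(spacing) != p.ndim:
        raise ValueError(f"spacing has {len(spacing)} entries for a {p.ndim}-D mask")
    if p.sum() == 0 or g.sum() == 0:
        return float("nan")
    d_pg = _directed_surface_distances(p, g, spacing)
    d_gp = _directed_surface_distances(g, p, spacing)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


@dataclass
class MetricReport:
    """Per-class and mean metrics for one case (or a pooled dataset)."""

    case_id: str
    spacing: tuple
    per_class: dict = field(default_factory=dict)  # label -> {dsc, hd95, iou}
    hd95_undefined: int = 0

    @property
    def mean_dsc(self) -> float:
        vals = [m["dsc"] for m in self.per_class.values()]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_iou(self) -> float:
        vals = [m["iou"] for m in self.per_class.values()]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_hd95(self) -> float:
        vals = [m["hd95"] for m in self.per_class.values() if np.isfinite(m["hd95"])]
        return float(np.mean(vals)) if vals else float("nan")

    def rows(self):
        for label, m in sorted(self.per_class.items()):
            yield {"case": self.case_id, "label": label, **m}

    def summary(self) -> dict:
        return {
            "case": self.case_id,
            "mean_dsc": self.mean_dsc,
            "mean_hd95": self.mean_hd95,
            "mean_iou": self.mean_iou,
            "hd95_undefined": self.hd95_undefined,
        }

    def to_json(self) -> str:
        return json.dumps({"summary": self.summary(), "per_class": self.per_class})


def evaluate_case(pred: np.ndarray, truth: np.ndarray, num_classes: int,
                  spacing=None, case_id: str = "case") -> MetricReport:
    """Per-foreground-class DSC/HD95/IOU between integer label masks.

    Classes absent from *both* masks are skipped; empty-mask HD95 values
    are recorded as ``nan`` and counted in ``hd95_undefined``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    report = MetricReport(case_id=case_id, spacing=tuple(spacing))
    for label in range(1, num_classes):
        p = pred == label
        g = truth == label
        if not p.any() and not g.any():
            continue
        h = hd95(p, g, spacing)
        if not np.isfinite(h):
            report.hd95_undefined += 1
        report.per_class[label] = {"dsc": dsc(p, g), "hd95": h, "iou": iou(p, g)}
    return report
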