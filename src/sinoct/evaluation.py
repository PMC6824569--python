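"""Image- and sinogram-quality metrics and batch reports.

PSNR is ``10 * log10(MAX(G)^2 / MSE)`` with ``MAX(G)`` the per-image maximum
of the ground truth; aPSNR is the arithmetic mean over an ensemble.  Image
PSNR is evaluated inside the reconstruction support circle only (the blank
corner regions carry no signal).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = ["MetricsReport", "apsnr", "evaluate_suite", "psnr", "support_mask"]

STAGES = ("corrupted_sinogram", "restored_sinogram", "fbp_image", "dlfbp_image")


def psnr(ground_truth: np.ndarray, test: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio of ``test`` against ``ground_truth``, dB.

    Returns ``inf`` for identical inputs.  ``mask`` optionally restricts the
    MSE (not the peak) to a region of interest.
    """
    g = np.asarray(ground_truth, dtype=np.float64)
    k = np.asarray(test, dtype=np.float64)
    if g.shape != k.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {k.shape}")
    if not np.any(g):
        raise ValueError("ground truth is identically zero; PSNR undefined")
    diff2 = (g - k) ** 2
    mse = float(diff2[mask].mean()) if mask is not None else float(diff2.mean())
    if mse == 0.0:
        return math.inf
    peak = float(np.abs(g).max())
    return 10.0 * math.log10(peak * peak / mse)


def apsnr(values: Sequence[float]) -> float:
    """Arithmetic mean of a non-empty list of finite PSNR values."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("apsnr of an empty list is undefined")
    if not np.all(np.isfinite(vals)):
        raise ValueError("apsnr requires finite entries")
    return float(vals.mean())


def support_mask(grid_size: int) -> np.ndarray:
    """Boolean mask of the inscribed reconstruction circle."""
    c = (grid_size - 1) / 2.0
    x = np.arange(grid_size) - c
    xx, yy = np.meshgrid(x, x)
    return xx * xx + yy * yy <= (grid_size / 2.0) ** 2


@dataclass
class ReportRow:
    case: str
    stage: str
    psnrs: List[float]

    @property
    def apsnr(self) -> float:
        return apsnr(self.psnrs)


@dataclass
class MetricsReport:
    rows: List[ReportRow] = field(default_factory=list)

    def add(self, case: str, stage: str, psnrs: Sequence[float]) -> None:
        self.rows.append(ReportRow(case=case, stage=stage, psnrs=list(psnrs)))

    def row(self, case: str, stage: str) -> ReportRow:
        for r in self.rows:
            if r.case == case and r.stage == stage:
                return r
        raise KeyError(f"no report row for case={case!r} stage={stage!r}")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case", "stage", "n", "apsnr_db", "psnr_db_list"])
            for r in self.rows:
                writer.writerow(
                    [
                        r.case,
                        r.stage,
                        len(r.psnrs),
                        f"{r.apsnr:.6f}",
                        ";".join(f"{v:.6f}" for v in r.psnrs),
                    ]
                )


def evaluate_suite(
    test_items: Sequence[dict],
    nets: Dict[str, object],
    geometry,
    out_size: int,
    train_labels: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Score trained networks over a held-out test set.

    ``test_items`` are dicts with keys ``label``, ``phantom_image`` (2-D
    array), ``complete`` (Sinogram) and per-condition incomplete sinograms
    under ``incomplete[<case>]``.  ``nets`` maps case label to a trained
    network.  Sinogram-stage PSNR is measured against the complete sinogram,
    image-stage PSNR against the ground-truth phantom inside the support
    circle.
    """
    from sinoct.fbp import fbp_reconstruct
    from sinoct.geometry import embed_incomplete
    from sinoct.training import dlfbp_infer, make_corrupted

    labels = [item["label"] for item in test_items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate test item labels")
    if train_labels is not None:
        overlap = set(labels) & set(train_labels)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)}")
    mask = support_mask(out_size)
    report = MetricsReport()
    for case, net in nets.items():
        per_stage: Dict[str, List[float]] = {s: [] for s in STAGES}
        for item in test_items:
            truth = np.asarray(item["phantom_image"], dtype=np.float64)
            complete = item["complete"]
            incomplete = item["incomplete"][case]
            corrupted = make_corrupted(incomplete, geometry, out_size)
            fbp_img = fbp_reconstruct(embed_incomplete(incomplete), geometry, out_size)
            dl_img, restored = dlfbp_infer(incomplete, net, geometry, out_size)
            per_stage["corrupted_sinogram"].append(
                psnr(complete.values, corrupted.values)
            )
            per_stage["restored_sinogram"].append(
                psnr(complete.values, restored.values)
            )
            per_stage["fbp_image"].append(psnr(truth, fbp_img.values, mask=mask))
            per_stage["dlfbp_image"].append(psnr(truth, dl_img.values, mask=mask))
        for stage in STAGES:
            report.add(case, stage, per_stage[stage])
    return report
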