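"""End-to-end orchestration of the five-stage segmentation pipeline.

Per frame: curvature smoothing + z-interpolation -> per-plane seed detection
and region growing -> center-slice detection and nucleus assembly.  After
all frames are segmented, a second pass applies bi-directional prediction
(needs the future frame) and transient flagging, then the pairwise
merge/delete filter.  The growth-rule radius ``r`` for each frame is the
largest nucleus radius accepted in all previous frames (configured fallback
for the first frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import ErrorReport, evaluate_series
from .filtering import filter_frame
from .io import NUCLEUS_COLUMNS, TimeLapseStack, empty_nucleus_table, write_nucleus_table
from .nuclei import Nucleus, assign_slices, find_center_slices
from .preprocess import preprocess_frame
from .segment2d import GrowthParams, _safe_otsu, find_seeds, segment_plane

logger = logging.getLogger(__name__)


@dataclass
class FrameSegmentation:
    """Segmentation result for one frame, with stage bookkeeping."""

    t: int
    nuclei: list[Nucleus]
    n_seeds: int
    n_slices: int
    n_centers: int


@dataclass
class PipelineResult:
    table: pd.DataFrame  # final nucleus table, all frames
    transients: pd.DataFrame  # removed single-frame nuclei (side log)
    stage_counts: pd.DataFrame
    report: ErrorReport | None = None


def nuclei_to_table(nuclei: list[Nucleus], t: int) -> pd.DataFrame:
    rows = [
        {
            "nucleus_id": n.id,
            "t": t,
            "x_um": n.x_um,
            "y_um": n.y_um,
            "z_um": n.z_um,
            "radius_um": n.radius_um,
            "volume_um3": n.volume_um3,
            "mean_gray": n.mean_gray,
            "n_slices": n.n_slices,
            "provenance": n.provenance,
        }
        for n in nuclei
    ]
    if not rows:
        return empty_nucleus_table()
    return pd.DataFrame(rows, columns=NUCLEUS_COLUMNS)


def segment_frame(
    frame: np.ndarray, config: PipelineConfig, r_max_um: float, t: int = 0
) -> FrameSegmentation:
    """Stages 1-3 on a single (z, y, x) frame."""
    volume = preprocess_frame(frame, config.preprocess)
    dz_eff = config.spacing.dz / 2.0 if config.preprocess.interpolate else config.spacing.dz
    thr = config.segment.background_threshold
    if thr is None:
        thr = _safe_otsu(volume)
    params = replace(config.segment, r_max_um=r_max_um, background_threshold=thr)
    dx, dy = config.spacing.dx, config.spacing.dy
    all_slices = []
    n_seeds = 0
    for z in range(volume.shape[0]):
        plane = volume[z]
        n_seeds += len(find_seeds(plane, params, z=z))
        all_slices.extend(segment_plane(plane, params, dx, dy, z=z))
    centers = find_center_slices(volume, all_slices, rule=config.center_rule)
    nuclei = assign_slices(centers, all_slices, r_max_um, dz_eff)
    logger.info(
        "frame %d: %d seeds, %d slices, %d centers -> %d nuclei",
        t, n_seeds, len(all_slices), len(centers), len(nuclei),
    )
    return FrameSegmentation(t, nuclei, n_seeds, len(all_slices), len(centers))


def segment_series(
    stack: TimeLapseStack, config: PipelineConfig
) -> list[FrameSegmentation]:
    """Stages 1-3 on every frame, threading the history-based growth radius.

    The growth radius for frame t is the largest nucleus radius accepted in
    frames 0..t-1, floored at the configured prior: radius estimates from
    thresholded slices run below the true radius, and letting the cap track
    them unfloored shrinks the growth conditions frame over frame, making
    volumes of the same nucleus inconsistent across time.
    """
    segmentations: list[FrameSegmentation] = []
    r_floor = config.segment.r_max_um
    r_max = r_floor
    r_history: list[float] = []
    for t in range(stack.n_frames):
        seg = segment_frame(stack.frame(t), config, r_max, t=t)
        segmentations.append(seg)
        r_history.extend(n.radius_um for n in seg.nuclei)
        if r_history:
            r_max = max(r_floor, max(r_history))
    return segmentations


def postprocess_series(
    segmentations: list[FrameSegmentation],
    config: PipelineConfig,
    ground_truth: pd.DataFrame | None = None,
    temporal: bool = True,
) -> PipelineResult:
    """Stages 4-5 (and scoring) on already-segmented frames.

    The pairwise merge/delete filter runs twice: once per frame before the
    temporal pass, to consolidate detections of one nucleus that noise split
    into fragments (the dissimilarity score assumes whole-nucleus volumes),
    and once after prediction for the final cleanup.
    """
    tables = {s.t: nuclei_to_table(s.nuclei, s.t) for s in segmentations}
    n_raw = {t: len(tab) for t, tab in tables.items()}
    for t in tables:
        tables[t] = filter_frame(tables[t], config.filter)
    n_before = {t: len(tab) for t, tab in tables.items()}
    n_frames = len(segmentations)
    n_predicted = {t: 0 for t in tables}
    n_transient = {t: 0 for t in tables}
    transients_frames = []
    if temporal and n_frames >= 3:
        for t in range(1, n_frames - 1):
            augmented = tables[t]
            augmented = _predict(tables[t - 1], augmented, tables[t + 1], config)
            n_predicted[t] = len(augmented) - len(tables[t])
            tables[t] = augmented
        from .temporal import flag_single_frame

        for t in range(1, n_frames - 1):
            kept, trans = flag_single_frame(tables[t - 1], tables[t], tables[t + 1], config.predict)
            n_transient[t] = len(trans)
            tables[t] = kept
            if len(trans):
                transients_frames.append(trans)

    # ---- stage 5: pairwise merge/delete filter
    n_final = {}
    for t in tables:
        before = len(tables[t])
        tables[t] = filter_frame(tables[t], config.filter)
        n_final[t] = len(tables[t])
        logger.info(
            "frame %d: %d before filter -> %d final (%d removed)",
            t, before, n_final[t], before - n_final[t],
        )

    table = pd.concat([tables[t] for t in sorted(tables)], ignore_index=True)
    transients = (
        pd.concat(transients_frames, ignore_index=True)
        if transients_frames
        else empty_nucleus_table()
    )
    stage_counts = pd.DataFrame(
        [
            {
                "t": s.t,
                "n_seeds": s.n_seeds,
                "n_slices": s.n_slices,
                "n_centers": s.n_centers,
                "n_raw": n_raw[s.t],
                "n_nuclei": n_before[s.t],
                "n_predicted": n_predicted[s.t],
                "n_transient": n_transient[s.t],
                "n_final": n_final[s.t],
            }
            for s in segmentations
        ]
    )
    report = None
    if ground_truth is not None:
        report = evaluate_series(table, ground_truth, config.evaluate)
    return PipelineResult(table, transients, stage_counts, report)


def run_pipeline(
    stack: TimeLapseStack,
    config: PipelineConfig | None = None,
    ground_truth: pd.DataFrame | None = None,
    temporal: bool = True,
) -> PipelineResult:
    """Run all five stages on a time-lapse stack.

    ``temporal=False`` skips prediction and transient flagging (useful for
    ablation studies of the bi-directional pass).
    """
    config = config or PipelineConfig()
    if (config.spacing.dx, config.spacing.dy, config.spacing.dz) != (
        stack.spacing.dx,
        stack.spacing.dy,
        stack.spacing.dz,
    ):
        config = replace(config, spacing=stack.spacing)
    segmentations = segment_series(stack, config)
    return postprocess_series(segmentations, config, ground_truth, temporal)


def _predict(prev, cur, nxt, config: PipelineConfig):
    from .temporal import predict_missing

    return predict_missing(prev, cur, nxt, config.predict)


def save_run(result: PipelineResult, config: PipelineConfig, out_dir) -> None:
    """Write tables, stage counts, report and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nucleus_table(result.table, out / "nuclei.csv")
    for t, sub in result.table.groupby("t"):
        write_nucleus_table(sub.reset_index(drop=True), out / f"nuclei-t{int(t):03d}.csv")
    if len(result.transients):
        write_nucleus_table(result.transients, out / "transients.csv")
    result.stage_counts.to_csv(out / "stage_counts.csv", index=False)
    if result.report is not None:
        result.report.per_frame.to_csv(out / "error_report.csv", index=False)
        (out / "error_report.txt").write_text(result.report.summary() + "\n")
    config.to_yaml(out / "config.resolved.yaml")
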