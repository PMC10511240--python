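"""Cell/nucleus segmentation and nuclear:cytosolic ratio quantification.

The readout is the per-cell ratio I_N/I_C of background-subtracted mean
reporter fluorescence in the nucleus over the cytosol — a proxy for
transcription-factor nuclear localization.  Segmentation is a deterministic
classical pipeline (smoothing, Otsu threshold, distance-transform
watershed) on the bright-field-like channel; nuclei come from a nuclear
marker channel thresholded per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

__all__ = [
    "CellRecord",
    "segment_cells",
    "segment_nuclei",
    "measure_nc_ratio",
    "evaluate_segmentation",
    "summarize_population",
    "records_to_frame",
]


@dataclass
class CellRecord:
    """Per-cell measurement: areas, mean intensities, and their ratio."""

    cell_id: int
    cell_area_px: int
    nucleus_area_px: int
    i_n: float
    i_c: float
    ratio: float
    border_touching: bool = False
    flags: tuple[str, ...] = ()

    @property
    def excluded(self) -> bool:
        return self.border_touching or bool(self.flags)


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "cell_area_px": r.cell_area_px,
                "nucleus_area_px": r.nucleus_area_px,
                "i_n": r.i_n,
                "i_c": r.i_c,
                "ratio": r.ratio,
                "border_touching": r.border_touching,
                "flags": ";".join(r.flags),
            }
            for r in records
        ]
    )


def segment_cells(
    brightfield: np.ndarray,
    smooth_sigma: float = 1.5,
    min_area: int = 60,
    max_area: int = 3000,
    rim_recovery_px: float = 2.0,
    min_marker_distance: int = 7,
) -> np.ndarray:
    """Label candidate cells on a bright-field-like channel.

    Smoothing -> Otsu threshold (cells' interiors brighter than background)
    -> hole filling -> distance-transform watershed to split touching cells
    -> label expansion by ``rim_recovery_px`` to recover the dark cell rim
    excluded by the threshold -> size filter.

    A constant image yields zero labels rather than an error.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.size == 0:
        raise ValueError("empty field")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    try:
        thr = filters.threshold_otsu(smoothed)
    except ValueError:
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > thr
    mask = morphology.remove_small_objects(mask, max_size=max(min_area // 4, 8))
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = feature.peak_local_max(
        distance, min_distance=min_marker_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(ndi.binary_dilation(markers > 0, iterations=2))
    labels = segmentation.watershed(-distance, markers, mask=mask)

    if rim_recovery_px > 0:
        labels = segmentation.expand_labels(labels, distance=rim_recovery_px)

    # size filter after rim recovery
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def border_touching_ids(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    return set(np.unique(edge[edge > 0]).tolist())


def segment_nuclei(
    nuclear_channel: np.ndarray,
    cell_labels: np.ndarray,
    min_nucleus_area: int = 4,
    max_area_fraction: float = 0.6,
) -> tuple[np.ndarray, dict[int, tuple[str, ...]]]:
    """Delimit one nucleus per cell from the nuclear-marker channel.

    Each cell's pixels are thresholded independently (Otsu).  The largest
    connected component above threshold is kept as the nucleus; cells whose
    candidate nucleus is smaller than ``min_nucleus_area`` or larger than
    ``max_area_fraction`` of the cell are flagged ``nucleus_free``; cells
    with a second substantial component are flagged ``multinucleate`` (the
    larger one is kept).

    Returns a nucleus label image sharing ids with ``cell_labels`` and a
    per-cell flag mapping.  No exceptions: problems become flags.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    nucleus_labels = np.zeros_like(cell_labels)
    flags: dict[int, tuple[str, ...]] = {}

    for region in measure.regionprops(cell_labels):
        cid = region.label
        inside = cell_labels == cid
        vals = img[inside]
        cell_flags: list[str] = []
        if np.ptp(vals) == 0:
            flags[cid] = ("nucleus_free",)
            continue
        thr = filters.threshold_otsu(vals)
        fg = inside & (img > thr)
        comp, n = ndi.label(fg)
        if n == 0:
            flags[cid] = ("nucleus_free",)
            continue
        sizes = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        area = int(sizes[best - 1])
        if area < min_nucleus_area or area > max_area_fraction * region.area:
            flags[cid] = ("nucleus_free",)
            continue
        if n > 1 and np.sort(sizes)[-2] >= min_nucleus_area:
            cell_flags.append("multinucleate")
        nucleus_labels[comp == best] = cid
        flags[cid] = tuple(cell_flags)
    return nucleus_labels, flags


def measure_nc_ratio(
    reporter: np.ndarray,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    cell_flags: dict[int, tuple[str, ...]] | None = None,
    guard_px: int = 1,
    nucleus_erode_px: int = 1,
) -> list[CellRecord]:
    """Per-cell I_N/I_C from the reporter channel.

    Background (the median reporter intensity outside all cells) is
    subtracted from both means.  The cytosol is the cell minus the nucleus
    dilated by ``guard_px`` (a guard ring limiting nuclear bleed-through);
    symmetrically, I_N is measured over the nucleus eroded by
    ``nucleus_erode_px`` so the blurred nuclear boundary contaminates
    neither mean (erosion falls back to the full nucleus when it would
    empty it).  Border-touching cells, nucleus-free cells and cells with
    non-positive cytosolic signal are flagged; flagged records are
    excluded from population statistics but still returned.
    """
    img = np.asarray(reporter, dtype=float)
    if img.shape != cell_labels.shape or img.shape != nucleus_labels.shape:
        raise ValueError("reporter and masks must share shape")
    cell_flags = cell_flags or {}

    outside = cell_labels == 0
    background = float(np.median(img[outside])) if outside.any() else 0.0

    border = border_touching_ids(cell_labels)
    guard = (
        morphology.dilation(nucleus_labels, morphology.disk(guard_px))
        if guard_px > 0
        else nucleus_labels
    )

    records: list[CellRecord] = []
    for region in measure.regionprops(cell_labels):
        cid = region.label
        cell = cell_labels == cid
        nucleus = nucleus_labels == cid
        flags = list(cell_flags.get(cid, ()))
        if not nucleus.any() and "nucleus_free" not in flags:
            flags.append("nucleus_free")
        cytosol = cell & (guard != cid) & (nucleus_labels == 0)
        core = nucleus
        if nucleus_erode_px > 0 and nucleus.any():
            eroded = ndi.binary_erosion(nucleus, iterations=nucleus_erode_px)
            if eroded.any():
                core = eroded
        i_n = float(img[core].mean()) - background if core.any() else np.nan
        i_c = float(img[cytosol].mean()) - background if cytosol.any() else np.nan
        if np.isfinite(i_c) and i_c <= 0 and "nucleus_free" not in flags:
            flags.append("nonpositive_cytosol")
        ratio = i_n / i_c if np.isfinite(i_n) and np.isfinite(i_c) and i_c > 0 else np.nan
        records.append(
            CellRecord(
                cell_id=cid,
                cell_area_px=int(region.area),
                nucleus_area_px=int(nucleus.sum()),
                i_n=i_n,
                i_c=i_c,
                ratio=ratio,
                border_touching=cid in border,
                flags=tuple(flags),
            )
        )
    return records


def evaluate_segmentation(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    iou_threshold: float = 0.5,
) -> tuple[float, pd.DataFrame]:
    """Detection fraction of ground-truth cells by greedy IoU matching.

    Predicted and truth labels are matched one-to-one in order of
    descending IoU; a truth cell counts as detected when its match reaches
    ``iou_threshold``.  Returns (fraction detected, per-truth-cell table).
    """
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("masks must share shape")
    truth_ids = np.unique(truth_labels[truth_labels > 0])
    if truth_ids.size == 0:
        return 1.0, pd.DataFrame(columns=["truth_id", "pred_id", "iou", "detected"])

    # joint histogram of overlapping label pairs
    both = (pred_labels > 0) & (truth_labels > 0)
    pairs, counts = np.unique(
        np.stack([truth_labels[both], pred_labels[both]]), axis=1, return_counts=True
    )
    truth_areas = {int(r): int((truth_labels == r).sum()) for r in truth_ids}
    pred_ids = np.unique(pred_labels[pred_labels > 0])
    pred_areas = {int(p): int((pred_labels == p).sum()) for p in pred_ids}

    candidates = []
    for (tid, pid), inter in zip(pairs.T, counts):
        union = truth_areas[int(tid)] + pred_areas[int(pid)] - int(inter)
        candidates.append((int(inter) / union, int(tid), int(pid)))
    candidates.sort(reverse=True)

    matched_truth: dict[int, tuple[int, float]] = {}
    used_pred: set[int] = set()
    for iou, tid, pid in candidates:
        if tid in matched_truth or pid in used_pred:
            continue
        matched_truth[tid] = (pid, iou)
        used_pred.add(pid)

    rows = []
    n_detected = 0
    for tid in truth_ids:
        pid, iou = matched_truth.get(int(tid), (0, 0.0))
        detected = iou >= iou_threshold
        n_detected += int(detected)
        rows.append({"truth_id": int(tid), "pred_id": pid, "iou": iou, "detected": detected})
    return n_detected / truth_ids.size, pd.DataFrame(rows)


def summarize_population(
    records: list[CellRecord] | pd.DataFrame,
    group_keys: list[str] | None = None,
    expected_n: tuple[int, int] = (100, 200),
) -> pd.DataFrame:
    """Per-condition mean/sd/n of I_N/I_C over included (unflagged) cells.

    Warns when a condition's cell count falls outside ``expected_n`` (the
    usual per-condition sampling depth), as a soft QC check.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "excluded" not in df.columns:
            df["excluded"] = df.get("border_touching", False) | (
                df.get("flags", "").astype(str).str.len() > 0
            )
    else:
        df = records_to_frame(records)
        df["excluded"] = [r.excluded for r in records]
    df = df[~df["excluded"] & np.isfinite(df["ratio"])]
    if df.empty:
        raise ValueError("no included cell records to summarize")

    if not group_keys:
        df = df.assign(_all="all")
        group_keys = ["_all"]
    out = (
        df.groupby(group_keys)["ratio"]
        .agg(mean_ratio="mean", sd_ratio=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    for _, row in out.iterrows():
        if not expected_n[0] <= row["n"] <= expected_n[1]:
            warnings.warn(
                f"condition {tuple(row[k] for k in group_keys)}: n={row['n']} cells "
                f"outside the expected {expected_n[0]}-{expected_n[1]} range",
                stacklevel=2,
            )
    return out.drop(columns=["_all"], errors="ignore")
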