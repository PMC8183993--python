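"""Nucleus-seeded cell segmentation and per-cell intensity measurement.

The quantification scheme mirrors the standard high-content-screening
primary/secondary/tertiary object hierarchy: nuclei are detected in the
DNA-stain channel and used as seeds; each seed is expanded outward through
the OPP channel by intensity-guided geodesic propagation to form the
whole-cell (secondary) object; subtracting the nucleus yields the cytoplasm
(tertiary) object, over which the mean OPP intensity — the per-cell
translation readout — is measured.

Propagation assigns every candidate pixel to the seed with minimal
cumulative geodesic cost, where a step between 4-adjacent pixels ``p, q``
costs ``sqrt((I(p) - I(q))**2 + lambda_reg)``: for large intensity contrast
the cost follows image structure, while ``lambda_reg`` regularizes toward
plain spatial distance. Expansion is limited to ``max_distance`` steps and
to pixels brighter than a background threshold, so cells never claim empty
plate surface.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

__all__ = [
    "FieldImage",
    "LabelMap",
    "CellRecord",
    "segment_nuclei",
    "propagate_cells",
    "subtract_nucleus",
    "measure_cells",
    "segment_field",
    "cells_to_dataframe",
]


@dataclass
class FieldImage:
    """Two-channel field: DNA stain and click-labeled OPP.

    Both channels are 2D nonnegative intensity grids of identical shape,
    0-based row-major.
    """

    nuclei_channel: np.ndarray
    opp_channel: np.ndarray

    def __post_init__(self):
        self.nuclei_channel = np.asarray(self.nuclei_channel, dtype=float)
        self.opp_channel = np.asarray(self.opp_channel, dtype=float)
        if self.nuclei_channel.shape != self.opp_channel.shape:
            raise ValueError("channel shapes differ")
        if self.nuclei_channel.ndim != 2:
            raise ValueError("channels must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_channel.shape


@dataclass
class LabelMap:
    """Integer pixel labeling; 0 is background.

    kind is one of {"nucleus", "cell", "cytoplasm"}. For kind="cell" every
    region contains its seed nucleus entirely under the same label; for
    kind="cytoplasm" the map equals the cell map with nucleus pixels zeroed.
    """

    labels: np.ndarray
    kind: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.kind not in ("nucleus", "cell", "cytoplasm"):
            raise ValueError(f"unknown LabelMap kind {self.kind!r}")

    @property
    def max_label(self) -> int:
        return int(self.labels.max(initial=0))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellRecord:
    """Per-cell areas (pixels) and mean OPP intensities over the three masks.

    Invariants: cell_area = nucleus_area + cytoplasm_area, and the
    area-weighted nucleus/cytoplasm means recompose the total mean.
    ``mean_opp_cytoplasm`` is NaN with ``cytoplasm_empty`` set when the cell
    never expanded past its nucleus. Border-touching cells are flagged via
    ``on_border`` (their cytoplasm is truncated by the field of view) and
    excluded from well summaries downstream, never silently dropped here.
    """

    cell_id: int
    nucleus_area: int
    cell_area: int
    cytoplasm_area: int
    mean_opp_total: float
    mean_opp_cytoplasm: float
    mean_opp_nucleus: float
    on_border: bool = False
    cytoplasm_empty: bool = False


def segment_nuclei(nuclei_channel: np.ndarray, min_area: int = 20, max_area: int = 2000,
                   sigma: float = 1.0) -> LabelMap:
    """Detect nuclei: Gaussian smoothing, global Otsu threshold, 8-connected
    components, size gating to [min_area, max_area] pixels, labels renumbered
    1..K in raster-scan order of each component's first pixel.

    A constant image yields zero nuclei; NaN pixels are an error.
    """
    img = np.asarray(nuclei_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei_channel must be 2D")
    if not np.isfinite(img).all():
        raise ValueError("nuclei_channel contains NaN/inf pixels")
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    smoothed = filters.gaussian(img, sigma=sigma, preserve_range=True) if sigma > 0 else img
    if smoothed.max() == smoothed.min():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="nucleus")
    thr = filters.threshold_otsu(smoothed)
    lbl = measure.label(smoothed > thr, connectivity=2)
    areas = np.bincount(lbl.ravel())
    keep = np.zeros(areas.size, dtype=bool)
    keep[1:] = (areas[1:] >= min_area) & (areas[1:] <= max_area)
    lbl[~keep[lbl]] = 0
    # renumber surviving labels by first occurrence in scan order
    flat = lbl.ravel()
    order = flat[np.sort(np.unique(flat, return_index=True)[1])]
    remap = np.zeros(areas.size, dtype=np.int32)
    nxt = 0
    for lab in order:
        if lab > 0:
            nxt += 1
            remap[lab] = nxt
    return LabelMap(remap[lbl], kind="nucleus")


def propagate_cells(nuclei: LabelMap, opp_channel: np.ndarray, lambda_reg: float = 0.05,
                    max_distance: int = 40, threshold: float | None = None,
                    threshold_floor: float = 0.0) -> LabelMap:
    """Expand nucleus seeds into whole-cell objects by geodesic propagation.

    All seed pixels start simultaneously at cost 0 with their nucleus label;
    a best-first (Dijkstra) expansion assigns each reachable pixel the label
    of the seed with minimal cumulative cost, with step cost
    ``sqrt((I(p) - I(q))**2 + lambda_reg)`` between 4-adjacent pixels. Ties
    are resolved by (cost, label, scan order), so the result is deterministic.
    Expansion is restricted to pixels whose OPP intensity strictly exceeds
    ``threshold`` (Otsu on the OPP channel if None, clamped from below to
    ``threshold_floor``) and stops once the minimum-cost path reaching a
    pixel has used ``max_distance`` steps. Seed pixels always keep their own
    labels regardless of intensity.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    if max_distance < 0:
        raise ValueError("max_distance must be nonnegative")
    if nuclei.kind != "nucleus":
        raise ValueError("seeds must be a nucleus LabelMap")
    img = np.asarray(opp_channel, dtype=float)
    seeds = nuclei.labels
    if seeds.shape != img.shape:
        raise ValueError("nuclei and opp_channel dimensions differ")
    labels = np.where(seeds > 0, seeds, 0).astype(np.int64)
    if labels.max(initial=0) == 0:
        return LabelMap(labels, kind="cell")
    if threshold is None:
        thr = filters.threshold_otsu(img) if img.max() > img.min() else np.inf
        thr = max(thr, threshold_floor)
    else:
        thr = threshold
    h, w = img.shape
    flat_img = img.ravel()
    flat_labels = labels.ravel()
    in_mask = (flat_img > thr) | (flat_labels > 0)
    finalized = np.zeros(h * w, dtype=bool)
    steps = np.full(h * w, -1, dtype=np.int32)

    heap: list[tuple[float, int, int, int]] = []  # (cost, label, pixel, steps)
    seed_pix = np.flatnonzero(flat_labels > 0)
    for p in seed_pix:
        heap.append((0.0, int(flat_labels[p]), int(p), 0))
    heapq.heapify(heap)

    while heap:
        cost, lab, p, s = heapq.heappop(heap)
        if finalized[p]:
            continue
        if flat_labels[p] != 0 and flat_labels[p] != lab:
            continue  # seed pixel of another nucleus; never overwritten
        finalized[p] = True
        flat_labels[p] = lab
        steps[p] = s
        if s >= max_distance:
            continue
        ip = flat_img[p]
        y, x = divmod(p, w)
        for q in ((p - w) if y > 0 else -1, (p + w) if y < h - 1 else -1,
                  (p - 1) if x > 0 else -1, (p + 1) if x < w - 1 else -1):
            if q < 0 or finalized[q] or not in_mask[q]:
                continue
            d = ip - flat_img[q]
            heapq.heappush(heap, (cost + np.sqrt(d * d + lambda_reg), lab, int(q), s + 1))

    return LabelMap(flat_labels.reshape(h, w).astype(np.int32), kind="cell")


def subtract_nucleus(cells: LabelMap, nuclei: LabelMap) -> LabelMap:
    """Tertiary object: cytoplasm(p) = cell(p) where nucleus(p) = 0, else 0."""
    if cells.kind != "cell" or nuclei.kind != "nucleus":
        raise ValueError("expected a cell map and a nucleus map")
    if cells.labels.shape != nuclei.labels.shape:
        raise ValueError("label map dimensions differ")
    cell_ids = set(cells.label_ids().tolist())
    nuc_ids = set(nuclei.label_ids().tolist())
    if not cell_ids <= nuc_ids:
        raise ValueError(f"cell labels without a matching nucleus: {sorted(cell_ids - nuc_ids)}")
    cyto = np.where(nuclei.labels == 0, cells.labels, 0)
    return LabelMap(cyto.astype(cells.labels.dtype), kind="cytoplasm")


def _label_stats(labels: np.ndarray, img: np.ndarray, n: int):
    """Per-label pixel count and intensity sum via bincount (label 0 dropped)."""
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n + 1)[1:n + 1]
    total = np.bincount(flat, weights=img.ravel(), minlength=n + 1)[1:n + 1]
    return area, total


def measure_cells(field: FieldImage, nuclei: LabelMap, cells: LabelMap,
                  cytoplasm: LabelMap) -> list[CellRecord]:
    """Measure per-cell OPP means over the nucleus, cell and cytoplasm masks.

    Cells whose region touches the image border are flagged ``on_border``;
    cells with an empty cytoplasm keep their record with the cytoplasm mean
    NaN-flagged.
    """
    for lm, kind in ((nuclei, "nucleus"), (cells, "cell"), (cytoplasm, "cytoplasm")):
        if lm.kind != kind:
            raise ValueError(f"expected a {kind} map")
        if lm.labels.shape != field.shape:
            raise ValueError("label map does not match field dimensions")
    n = cells.max_label
    if n == 0:
        return []
    opp = field.opp_channel
    nuc_area, nuc_sum = _label_stats(nuclei.labels, opp, n)
    cell_area, cell_sum = _label_stats(cells.labels, opp, n)
    cyto_area, cyto_sum = _label_stats(cytoplasm.labels, opp, n)
    border = np.zeros(n + 1, dtype=bool)
    for edge in (cells.labels[0], cells.labels[-1], cells.labels[:, 0], cells.labels[:, -1]):
        border[np.unique(edge)] = True
    records = []
    for i in range(n):
        if cell_area[i] == 0:
            continue  # label absent from this field (e.g. filtered upstream)
        empty = cyto_area[i] == 0
        records.append(CellRecord(
            cell_id=i + 1,
            nucleus_area=int(nuc_area[i]),
            cell_area=int(cell_area[i]),
            cytoplasm_area=int(cyto_area[i]),
            mean_opp_total=cell_sum[i] / cell_area[i],
            mean_opp_cytoplasm=np.nan if empty else cyto_sum[i] / cyto_area[i],
            mean_opp_nucleus=nuc_sum[i] / nuc_area[i] if nuc_area[i] else np.nan,
            on_border=bool(border[i + 1]),
            cytoplasm_empty=bool(empty),
        ))
    return records


def segment_field(field: FieldImage, min_area: int = 20, max_area: int = 2000,
                  sigma: float = 1.0, lambda_reg: float = 0.05, max_distance: int = 40,
                  threshold: float | None = None) -> tuple[list[CellRecord], LabelMap, LabelMap, LabelMap]:
    """Full per-field pipeline: nuclei -> cells -> cytoplasm -> measurements."""
    nuclei = segment_nuclei(field.nuclei_channel, min_area=min_area, max_area=max_area,
                            sigma=sigma)
    cells = propagate_cells(nuclei, field.opp_channel, lambda_reg=lambda_reg,
                            max_distance=max_distance, threshold=threshold)
    cyto = subtract_nucleus(cells, nuclei)
    return measure_cells(field, nuclei, cells, cyto), nuclei, cells, cyto


def cells_to_dataframe(records: list[CellRecord], plate_id: str = "", well: str = "",
                       field_idx: int = 0) -> pd.DataFrame:
    cols = ["cell_id", "nucleus_area", "cell_area", "cytoplasm_area", "mean_opp_total",
            "mean_opp_cytoplasm", "mean_opp_nucleus", "on_border", "cytoplasm_empty"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.insert(0, "field", field_idx)
    df.insert(0, "well", well)
    df.insert(0, "plate_id", plate_id)
    return df
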