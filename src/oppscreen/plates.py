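"""Well summaries, per-plate percent-of-control normalization, triplicate merging.

Each well's two readouts are the mean cytoplasmic OPP intensity of its
included cells and the nuclei count (the viability proxy). Every readout is
normalized to the mean of the vehicle (DMSO) wells on the same plate, which
removes any well-independent multiplicative plate factor exactly; compound
values are then averaged over the triplicate plates with a coefficient of
variation reported per compound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlateError", "WellSummary", "summarize_well", "summarize_wells",
           "normalize_plate", "normalize_screen", "aggregate_replicates"]


class PlateError(ValueError):
    """A plate cannot be normalized (e.g. no usable DMSO wells)."""


@dataclass
class WellSummary:
    """Per-well screen readouts pooled over the well's imaging fields."""

    plate_id: str
    well: str
    mean_cyto_opp: float
    nuclei_count: int
    n_fields: int
    flag: str = ""


def summarize_well(cell_records: pd.DataFrame, method: str = "pooled") -> WellSummary:
    """Aggregate the cell records of all fields of one well.

    Included cells are those not on a field border and with a defined
    cytoplasm mean. ``method='pooled'`` averages over cells (each cell
    weighted equally, the default); ``method='field_mean'`` averages the
    per-field means instead. Empty wells are flagged, never fatal.
    """
    if method not in ("pooled", "field_mean"):
        raise ValueError(f"unknown method {method!r}")
    if len(cell_records) == 0:
        return WellSummary("", "", np.nan, 0, 0, flag="empty")
    plate_id = str(cell_records["plate_id"].iloc[0])
    well = str(cell_records["well"].iloc[0])
    n_fields = int(cell_records["field"].nunique())
    inc = cell_records[~cell_records["on_border"].astype(bool)
                       & ~cell_records["cytoplasm_empty"].astype(bool)]
    count = len(inc)
    if count == 0:
        return WellSummary(plate_id, well, np.nan, 0, n_fields, flag="empty")
    if method == "pooled":
        mean = float(inc["mean_opp_cytoplasm"].mean())
    else:
        mean = float(inc.groupby("field")["mean_opp_cytoplasm"].mean().mean())
    return WellSummary(plate_id, well, mean, count, n_fields)


def summarize_wells(cell_records: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Vector version of :func:`summarize_well` over a multi-well record table."""
    rows = [summarize_well(g, method=method).__dict__
            for _, g in cell_records.groupby(["plate_id", "well"], sort=True)]
    return pd.DataFrame(rows, columns=["plate_id", "well", "mean_cyto_opp",
                                       "nuclei_count", "n_fields", "flag"])


def _dmso_reference(plate_wells: pd.DataFrame, plate_map: pd.DataFrame, plate_id) -> tuple[float, float]:
    pm = plate_map[(plate_map["plate_id"] == plate_id) & (plate_map["role"] == "dmso")]
    ref = plate_wells[plate_wells["well"].isin(pm["well"])]
    ref = ref[(ref["nuclei_count"] > 0) & ref["mean_cyto_opp"].notna()]
    if len(ref) < 2:
        raise PlateError(f"plate {plate_id}: need >= 2 usable DMSO wells, found {len(ref)}")
    return float(ref["mean_cyto_opp"].mean()), float(ref["nuclei_count"].mean())


def normalize_plate(well_summaries: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate's wells to its DMSO mean (percent-of-control).

    opp_norm = mean_cyto_opp / mean(DMSO mean_cyto_opp); viability_norm
    likewise on nuclei_count. DMSO wells are included in their own reference
    mean, so per plate the DMSO opp_norm values average exactly 1. Wells
    flagged empty propagate as missing (NaN), never as zero signal.
    """
    plate_ids = well_summaries["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateError(f"normalize_plate expects a single plate, got {list(plate_ids)}")
    pid = plate_ids[0]
    opp_ref, via_ref = _dmso_reference(well_summaries, plate_map, pid)
    out = well_summaries[["plate_id", "well"]].copy()
    usable = (well_summaries["nuclei_count"] > 0) & well_summaries["mean_cyto_opp"].notna()
    out["opp_norm"] = np.where(usable, well_summaries["mean_cyto_opp"] / opp_ref, np.nan)
    out["viability_norm"] = np.where(usable, well_summaries["nuclei_count"] / via_ref, np.nan)
    out["flag"] = np.where(usable, "", "empty")
    return out


def normalize_screen(well_summaries: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_plate` per plate and concatenate."""
    parts = [normalize_plate(g, plate_map)
             for _, g in well_summaries.groupby("plate_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


def _cv_percent(values: np.ndarray) -> float:
    """100 * sample SD (n-1 denominator) / mean over replicate values."""
    mean = values.mean()
    if mean == 0:
        return np.nan
    return 100.0 * values.std(ddof=1) / mean


def aggregate_replicates(normalized: pd.DataFrame, plate_map: pd.DataFrame,
                         n_replicates: int | None = None) -> pd.DataFrame:
    """Merge the triplicate plates into one score per compound.

    Each compound must appear once per plate on every replicate plate;
    compounds with missing or flagged replicates are excluded from hit
    calling with reason ``incomplete_triplicate``. Means are simple averages
    of the per-plate normalized values and CVs use the sample SD.
    The result is invariant to plate ordering.
    """
    n_plates = n_replicates or normalized["plate_id"].nunique()
    cmp_map = plate_map[plate_map["role"] == "compound"][["plate_id", "well", "compound_id"]]
    merged = normalized.merge(cmp_map, on=["plate_id", "well"], how="inner")
    rows = []
    for cid, g in merged.groupby("compound_id", sort=True):
        g = g.sort_values("plate_id")
        complete = (len(g) == n_plates
                    and g["plate_id"].nunique() == n_plates
                    and g["opp_norm"].notna().all()
                    and g["viability_norm"].notna().all())
        row = {"compound_id": cid, "n_replicates": int(g["opp_norm"].notna().sum())}
        for i, (_, r) in enumerate(g.iterrows(), start=1):
            row[f"opp_norm_{i}"] = r["opp_norm"]
            row[f"viability_norm_{i}"] = r["viability_norm"]
            row[f"plate_{i}"] = r["plate_id"]
        if complete:
            opp = g["opp_norm"].to_numpy(float)
            via = g["viability_norm"].to_numpy(float)
            row.update(mean_opp_norm=float(opp.mean()), mean_viability_norm=float(via.mean()),
                       cv_opp=_cv_percent(opp), cv_viability=_cv_percent(via),
                       excluded=False, exclusion_reason="")
        else:
            row.update(mean_opp_norm=np.nan, mean_viability_norm=np.nan,
                       cv_opp=np.nan, cv_viability=np.nan,
                       excluded=True, exclusion_reason="incomplete_triplicate")
        rows.append(row)
    cols = ["compound_id", "n_replicates"]
    for i in range(1, n_plates + 1):
        cols += [f"plate_{i}", f"opp_norm_{i}", f"viability_norm_{i}"]
    cols += ["mean_opp_norm", "mean_viability_norm", "cv_opp", "cv_viability",
             "excluded", "exclusion_reason"]
    return pd.DataFrame(rows).reindex(columns=cols)
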