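"""File-format helpers: 16-bit TIFF channels, plate-map / well-table CSVs, GMT gene sets.

Column dictionaries
-------------------
plate map CSV : plate_id, well (A01..P24), role {compound|dmso|torin|chx},
                compound_id (empty for controls), dose_uM
well table CSV: plate_id, well, mean_cyto_opp, nuclei_count, n_fields, flag
image files   : ``{plate}_{well}_f{field}_{channel}.tif`` with channel in
                {nuclei, opp}, one 16-bit grayscale TIFF per channel per field
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd
import tifffile

PLATEMAP_COLUMNS = ["plate_id", "well", "role", "compound_id", "dose_uM"]
WELLTABLE_COLUMNS = ["plate_id", "well", "mean_cyto_opp", "nuclei_count", "n_fields", "flag"]

_IMAGE_RE = re.compile(r"^(?P<plate>[^_]+)_(?P<well>[A-P]\d{2})_f(?P<field>\d+)_(?P<channel>nuclei|opp)\.tif$")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01' style address."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def read_platemap(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str, "compound_id": str})
    missing = set(PLATEMAP_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return df


def write_platemap(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def read_well_table(path: str | os.PathLike) -> pd.DataFrame:
    # round_trip parsing so a write/read cycle is bit-exact (determinism
    # guarantees depend on it)
    return pd.read_csv(path, dtype={"plate_id": str, "well": str},
                       float_precision="round_trip")


def write_well_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def image_filename(plate_id: str, well: str, field: int, channel: str) -> str:
    return f"{plate_id}_{well}_f{field}_{channel}.tif"


def write_field_tiff(directory: str | os.PathLike, plate_id: str, well: str, field: int,
                     nuclei: np.ndarray, opp: np.ndarray) -> None:
    for channel, img in (("nuclei", nuclei), ("opp", opp)):
        arr = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        tifffile.imwrite(os.path.join(directory, image_filename(plate_id, well, field, channel)), arr)


def read_field_tiff(directory: str | os.PathLike, plate_id: str, well: str, field: int):
    """Return (nuclei_channel, opp_channel) as float arrays."""
    out = []
    for channel in ("nuclei", "opp"):
        path = os.path.join(directory, image_filename(plate_id, well, field, channel))
        out.append(tifffile.imread(path).astype(float))
    return tuple(out)


def list_fields(directory: str | os.PathLike):
    """Scan a directory for field images; yield (plate_id, well, field) triples
    that have both channels present, sorted."""
    seen: dict[tuple, set] = {}
    for name in sorted(os.listdir(directory)):
        m = _IMAGE_RE.match(name)
        if m:
            key = (m["plate"], m["well"], int(m["field"]))
            seen.setdefault(key, set()).add(m["channel"])
    return [k for k, ch in sorted(seen.items()) if ch == {"nuclei", "opp"}]


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets from GMT (tab-separated: name, description, members...).

    Duplicate member genes within a set are dropped, preserving order.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            seen: set[str] = set()
            members = [g for g in genes if g and not (g in seen or seen.add(g))]
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
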