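"""Model/results objects for the tabular analysis stages.

:class:`TranslationScreen` is built from a per-well readout table plus a
plate map and, on :meth:`~TranslationScreen.fit`, runs per-plate DMSO
normalization, triplicate aggregation and four-criterion hit calling,
returning a :class:`ScreenResults` carrying the normalized wells, compound
scores, vehicle-well statistics, hit calls and QC diagnostics.

:class:`ProteomicsExperiment` wraps the 3-vs-3 protein quantification
table; its :class:`ProteomicsResults` exposes the differential table, the
ranked list and preRanked enrichment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from . import plates, proteomics as _prot
from .hits import DmsoStats, HitThresholds, call_hits, compute_dmso_stats
from .segmentation import cells_to_dataframe, segment_field

__all__ = ["TranslationScreen", "ScreenResults", "ProteomicsExperiment", "ProteomicsResults"]


class TranslationScreen:
    """A translation screen: per-well readouts plus the plate layout.

    Parameters
    ----------
    well_table : DataFrame with columns plate_id, well, mean_cyto_opp,
        nuclei_count (the two screen readouts per well).
    plate_map : DataFrame with plate_id, well, role, compound_id.
    """

    def __init__(self, well_table: pd.DataFrame, plate_map: pd.DataFrame):
        need = {"plate_id", "well", "mean_cyto_opp", "nuclei_count"}
        if not need <= set(well_table.columns):
            raise ValueError(f"well_table missing columns {sorted(need - set(well_table.columns))}")
        self.well_table = well_table.copy()
        self.plate_map = plate_map.copy()
        self.n_plates = int(well_table["plate_id"].nunique())

    @classmethod
    def from_csv(cls, well_table_path, plate_map_path) -> "TranslationScreen":
        return cls(_io.read_well_table(well_table_path), _io.read_platemap(plate_map_path))

    @classmethod
    def from_cell_records(cls, cell_records: pd.DataFrame, plate_map: pd.DataFrame,
                          method: str = "pooled") -> "TranslationScreen":
        """Build the well table from per-cell segmentation records."""
        return cls(plates.summarize_wells(cell_records, method=method), plate_map)

    @classmethod
    def from_images(cls, image_dir, plate_map: pd.DataFrame, method: str = "pooled",
                    **segment_kwargs) -> "TranslationScreen":
        """Segment every two-channel field found in ``image_dir`` and build
        the well table from the resulting cell records."""
        frames = []
        for plate_id, well, fld in _io.list_fields(image_dir):
            nuc, opp = _io.read_field_tiff(image_dir, plate_id, well, fld)
            from .segmentation import FieldImage
            records, *_ = segment_field(FieldImage(nuc, opp), **segment_kwargs)
            frames.append(cells_to_dataframe(records, plate_id, well, fld))
        if not frames:
            raise ValueError(f"no field images found in {image_dir}")
        return cls.from_cell_records(pd.concat(frames, ignore_index=True), plate_map,
                                     method=method)

    def fit(self, thresholds: HitThresholds | None = None) -> "ScreenResults":
        """Normalize, aggregate triplicates, and call hits."""
        thresholds = thresholds or HitThresholds()
        normalized = plates.normalize_screen(self.well_table, self.plate_map)
        dmso = compute_dmso_stats(normalized, self.plate_map)
        scores = plates.aggregate_replicates(normalized, self.plate_map,
                                             n_replicates=self.n_plates)
        calls = call_hits(scores, dmso, thresholds)
        return ScreenResults(self, normalized, dmso, scores, calls, thresholds)


@dataclass
class ScreenResults:
    """Fitted screen: normalized wells, compound scores, hit calls, QC."""

    model: TranslationScreen
    normalized_wells: pd.DataFrame
    dmso_stats: DmsoStats
    compound_scores: pd.DataFrame
    hit_calls: pd.DataFrame
    thresholds: HitThresholds

    @property
    def hit_counts(self) -> pd.Series:
        return (self.hit_calls["class"]
                .value_counts()
                .reindex(["up", "down", "null", "excluded"], fill_value=0))

    def hits(self, direction: str | None = None) -> pd.DataFrame:
        calls = self.hit_calls
        if direction is None:
            return calls[calls["class"].isin(["up", "down"])]
        return calls[calls["class"] == direction]

    def qc(self) -> pd.DataFrame:
        """Per-plate QC: DMSO CV and normalized control levels.

        ``chx_separation`` is the gap between the DMSO mean and the CHX-like
        control mean in units of the plate's DMSO SD — the dynamic range the
        3-SD hit threshold lives in.
        """
        pm, nw = self.model.plate_map, self.normalized_wells
        rows = []
        for pid, g in nw.groupby("plate_id", sort=True):
            mean_d, sd_d = self.dmso_stats.plate(pid)
            row = {"plate_id": pid, "dmso_mean": mean_d, "dmso_sd": sd_d,
                   "dmso_cv_percent": 100.0 * sd_d / mean_d if mean_d else np.nan}
            for role in ("torin", "chx"):
                wells = pm[(pm["plate_id"] == pid) & (pm["role"] == role)]["well"]
                vals = g[g["well"].isin(wells)]["opp_norm"].dropna()
                row[f"{role}_opp_norm"] = float(vals.mean()) if len(vals) else np.nan
            row["chx_separation"] = ((mean_d - row["chx_opp_norm"]) / sd_d
                                     if sd_d and np.isfinite(row["chx_opp_norm"]) else np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        counts = self.hit_counts
        qc = self.qc()
        lines = [
            "Translation screen results",
            "=" * 60,
            f"Plates: {self.model.n_plates}    Wells: {len(self.model.well_table)}"
            f"    Compounds scored: {len(self.compound_scores)}",
            f"Thresholds: k_sd={self.thresholds.k_sd}, "
            f"max_toxicity={self.thresholds.max_toxicity}, max_cv={self.thresholds.max_cv}%",
            "-" * 60,
            f"Up-regulators:   {counts['up']:5d}",
            f"Down-regulators: {counts['down']:5d}",
            f"Null:            {counts['null']:5d}",
            f"Excluded:        {counts['excluded']:5d}",
            "-" * 60,
            "Per-plate QC (DMSO CV %, CHX separation in DMSO SDs):",
        ]
        for _, r in qc.iterrows():
            lines.append(f"  {r['plate_id']}: DMSO CV {r['dmso_cv_percent']:.2f}%"
                         f"   CHX sep {r['chx_separation']:.1f} SD"
                         if np.isfinite(r["chx_separation"]) else
                         f"  {r['plate_id']}: DMSO CV {r['dmso_cv_percent']:.2f}%")
        return "\n".join(lines)

    def plot_distribution(self, ax=None):
        """Ranked scatter of triplicate-mean normalized OPP per compound,
        colored by hit class (the classic screen waterfall)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.hit_calls.sort_values("mean_opp_norm", ignore_index=True)
        colors = {"up": "tab:green", "down": "tab:orange", "null": "0.6", "excluded": "0.85"}
        for cls, g in df.groupby("class"):
            ax.scatter(g.index, g["mean_opp_norm"], s=8, label=cls,
                       color=colors.get(cls, "k"))
        m, s = self.dmso_stats.pooled_mean, self.dmso_stats.pooled_sd
        for y in (m, m + self.thresholds.k_sd * s, m - self.thresholds.k_sd * s):
            ax.axhline(y, color="k", lw=0.5, ls="--")
        ax.set_xlabel("compound rank")
        ax.set_ylabel("OPP signal (fraction of DMSO)")
        ax.legend(fontsize=8)
        return ax

    def to_csv(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.normalized_wells.to_csv(os.path.join(out_dir, "normalized_wells.csv"), index=False)
        self.compound_scores.to_csv(os.path.join(out_dir, "compound_scores.csv"), index=False)
        self.hit_calls.to_csv(os.path.join(out_dir, "hit_calls.csv"), index=False)
        self.dmso_stats.per_plate.to_csv(os.path.join(out_dir, "dmso_stats.csv"), index=False)
        self.qc().to_csv(os.path.join(out_dir, "qc.csv"), index=False)


class ProteomicsExperiment:
    """A 3-vs-3 protein quantification experiment (log2 intensities)."""

    def __init__(self, table: pd.DataFrame, treated_cols: list[str] | None = None,
                 control_cols: list[str] | None = None):
        if "protein_id" not in table.columns:
            raise ValueError("table needs a protein_id column")
        self.table = table.copy()
        self.treated_cols = treated_cols
        self.control_cols = control_cols

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ProteomicsExperiment":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, p_thr: float = 0.05, lfc_thr: float = 0.3) -> "ProteomicsResults":
        res = _prot.differential_proteins(self.table, p_thr=p_thr, lfc_thr=lfc_thr,
                                          treated_cols=self.treated_cols,
                                          control_cols=self.control_cols)
        return ProteomicsResults(self, res, p_thr, lfc_thr)


@dataclass
class ProteomicsResults:
    model: ProteomicsExperiment
    results: pd.DataFrame
    p_thr: float
    lfc_thr: float

    @property
    def regulated(self) -> pd.DataFrame:
        return self.results[self.results["regulated"]]

    @property
    def n_regulated(self) -> int:
        return int(self.results["regulated"].sum())

    def ranked(self) -> pd.DataFrame:
        return _prot.rank_proteins(self.results)

    def gsea(self, gene_sets: dict[str, list[str]], **kwargs) -> pd.DataFrame:
        return _prot.gsea_preranked(self.ranked(), gene_sets, **kwargs)

    def summary(self) -> str:
        r = self.results
        up = int(((r["regulated"]) & (r["log2fc"] > 0)).sum())
        down = self.n_regulated - up
        return "\n".join([
            "Differential protein abundance (Welch t-test, BH adjustment)",
            "=" * 60,
            f"Proteins tested: {len(r)}",
            f"Regulated (p < {self.p_thr}, |log2FC| > {self.lfc_thr}): "
            f"{self.n_regulated}  ({up} up, {down} down)",
            f"q-value range among regulated: "
            f"[{self.regulated['q_value'].min():.3g}, {self.regulated['q_value'].max():.3g}]"
            if self.n_regulated else "q-value range among regulated: n/a",
        ])

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        r = self.results
        neglog = -np.log10(np.clip(r["p_value"], 1e-300, None))
        ax.scatter(r["log2fc"], neglog, s=6,
                   c=np.where(r["regulated"], "tab:red", "0.7"))
        ax.axhline(-np.log10(self.p_thr), color="k", lw=0.5, ls="--")
        for x in (-self.lfc_thr, self.lfc_thr):
            ax.axvline(x, color="k", lw=0.5, ls="--")
        ax.set_xlabel("log2 fold change (treated - control)")
        ax.set_ylabel("-log10 p")
        return ax
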