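"""Ground-truthed synthetic screen data.

Emulates the statistical structure of an OPP (o-propargyl-puromycin)
translation screen in 384-well plates: vehicle (DMSO) wells, positive-control
wells with strongly reduced protein synthesis (CHX-like, near-total shutdown)
or intermediate reduction (Torin-like mTOR inhibition), planted up-/
down-regulator compounds with configurable effect sizes, planted toxicity
(reduced cell counts), and plate-to-plate / well-to-well multiplicative
level shifts that the per-plate DMSO normalization must remove.

Two output modes share the same underlying per-well draws:

* ``fast`` — emits the well-level table directly (mean cytoplasmic OPP
  intensity and nuclei count per well), bypassing image rendering;
* ``images`` — additionally renders two-channel fields (nuclei stain,
  OPP label) as disk nuclei with annular cytoplasms, so the segmentation
  stage can be exercised against per-cell ground truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawn keys ``(plate, well, field)``, so any
subset of the screen is reproducible in isolation and a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .segmentation import FieldImage

__all__ = [
    "ConfigError",
    "PlantedCompound",
    "SyntheticScreenConfig",
    "GroundTruth",
    "ScreenData",
    "CellSpec",
    "FieldSpec",
    "render_field",
    "generate_screen",
    "generate_proteomics",
    "generate_dose_response",
]


class ConfigError(ValueError):
    """Invalid synthetic-screen configuration."""


@dataclass(frozen=True)
class PlantedCompound:
    """A library compound with a planted effect.

    Parameters
    ----------
    effect : multiplicative factor on cytoplasmic OPP intensity (1.0 = null,
        <1 down-regulator, >1 up-regulator).
    toxicity : multiplicative factor on cell count (1.0 = none).
    replicate_noise_cv : CV of the per-plate multiplicative replicate noise.
    """

    compound_id: str
    effect: float = 1.0
    toxicity: float = 1.0
    replicate_noise_cv: float = 0.0

    def __post_init__(self):
        if not self.effect > 0:
            raise ConfigError(f"{self.compound_id}: effect must be > 0")
        if not (0 < self.toxicity <= 1):
            raise ConfigError(f"{self.compound_id}: toxicity must be in (0, 1]")
        if self.replicate_noise_cv < 0:
            raise ConfigError(f"{self.compound_id}: replicate_noise_cv must be >= 0")

    @property
    def true_class(self) -> str:
        if self.effect > 1:
            return "up"
        if self.effect < 1:
            return "down"
        return "null"


def _default_controls(n_rows: int, n_cols: int):
    """Default layout: DMSO fills the next-to-last column, Torin-like the top
    half and CHX-like the bottom half of the last column."""
    dmso = [_io.well_name(r, n_cols - 2) for r in range(n_rows)]
    torin = [_io.well_name(r, n_cols - 1) for r in range(n_rows // 2)]
    chx = [_io.well_name(r, n_cols - 1) for r in range(n_rows // 2, n_rows)]
    return dmso, torin, chx


@dataclass
class SyntheticScreenConfig:
    """Parameters of a synthetic screen.

    Intensities are 16-bit camera units; radii and sizes are pixels. The
    noise model is additive Gaussian on both channels (``noise_sd``) plus
    log-normal multiplicative level shifts per plate (``plate_effect_cv``)
    and per well (``well_effect_cv``). Replicate plates share an identical
    layout.
    """

    n_plates: int = 3
    n_rows: int = 16
    n_cols: int = 24
    fields_per_well: int = 4
    image_size: int = 192
    cells_per_well: float = 120.0
    compounds: list[PlantedCompound] = field(default_factory=list)
    dmso_wells: list[str] | None = None
    torin_wells: list[str] | None = None
    chx_wells: list[str] | None = None
    baseline_opp: float = 2000.0
    nucleus_radius: float = 5.0
    nucleus_radius_sd: float = 0.8
    cyto_expansion: float = 2.0           # cell radius = cyto_expansion * nucleus radius
    cell_intensity_cv: float = 0.10       # per-cell lognormal spread around the well mean
    nucleus_opp_fraction: float = 0.6     # OPP level inside the nucleus relative to cytoplasm
    nucleus_stain_intensity: float = 10000.0
    background: float = 100.0
    noise_sd: float = 40.0
    plate_effect_cv: float = 0.05
    well_effect_cv: float = 0.05
    torin_effect: float = 0.5
    chx_effect: float = 0.05
    compound_dose_uM: float = 10.0
    seed: int = 0

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * self.n_cols

    def __post_init__(self):
        if self.dmso_wells is None or self.torin_wells is None or self.chx_wells is None:
            d, t, c = _default_controls(self.n_rows, self.n_cols)
            if self.dmso_wells is None:
                self.dmso_wells = d
            if self.torin_wells is None:
                self.torin_wells = t
            if self.chx_wells is None:
                self.chx_wells = c
        self.validate()

    def validate(self) -> None:
        for name in ("n_plates", "n_rows", "n_cols", "fields_per_well", "image_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cells_per_well <= 0:
            raise ConfigError("cells_per_well must be positive")
        for name in ("baseline_opp", "noise_sd", "background", "nucleus_radius",
                     "nucleus_radius_sd", "plate_effect_cv", "well_effect_cv",
                     "torin_effect", "chx_effect"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.image_size < 8 * self.nucleus_radius:
            raise ConfigError("image_size must be at least 8 * nucleus_radius")
        roles = [("dmso", self.dmso_wells), ("torin", self.torin_wells), ("chx", self.chx_wells)]
        seen: dict[str, str] = {}
        for role, wells in roles:
            for w in wells:
                if w in seen:
                    raise ConfigError(f"well {w} assigned to both {seen[w]} and {role}")
                seen[w] = role
        all_wells = [_io.well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]
        unknown = set(seen) - set(all_wells)
        if unknown:
            raise ConfigError(f"control wells outside the plate: {sorted(unknown)}")
        free = [w for w in all_wells if w not in seen]
        if len(self.compounds) > len(free):
            raise ConfigError(
                f"{len(self.compounds)} compounds but only {len(free)} non-control wells")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate compound_id")

    def compound_wells(self) -> list[tuple[str, PlantedCompound]]:
        """Assign compounds to free wells in row-major scan order (identical
        on every replicate plate)."""
        controls = set(self.dmso_wells) | set(self.torin_wells) | set(self.chx_wells)
        free = [_io.well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)
                if _io.well_name(r, c) not in controls]
        return list(zip(free, self.compounds))


@dataclass
class GroundTruth:
    """Planted truth for a synthetic screen.

    compounds : per compound — true effect class (up/down/null), effect, toxicity
    wells     : per (plate, well) — role, true mean cytoplasmic intensity,
                true cell count
    cells     : per rendered cell (image mode only) — centroid, radii, true
                mean cytoplasmic intensity
    """

    compounds: pd.DataFrame
    wells: pd.DataFrame
    cells: pd.DataFrame | None = None


@dataclass
class ScreenData:
    """Bundle returned by :func:`generate_screen`."""

    plate_map: pd.DataFrame
    well_table: pd.DataFrame
    truth: GroundTruth
    images: dict[tuple[str, str, int], FieldImage] | None = None
    config: SyntheticScreenConfig | None = None


# ---------------------------------------------------------------------------
# field rendering

@dataclass(frozen=True)
class CellSpec:
    """Geometry and intensity of one rendered cell (pixel units; 0-based
    row-major centroid)."""

    y: float
    x: float
    r_nucleus: float
    r_cell: float
    intensity_cyto: float
    intensity_nucleus_opp: float
    intensity_nucleus_stain: float


@dataclass
class FieldSpec:
    image_size: int
    background: float
    noise_sd: float
    cells: list[CellSpec] = field(default_factory=list)


def _paint_disk(img: np.ndarray, y: float, x: float, r: float, value: float,
                inner_r: float = -1.0) -> None:
    n = img.shape[0]
    y0, y1 = max(0, int(y - r) - 1), min(n, int(y + r) + 2)
    x0, x1 = max(0, int(x - r) - 1), min(n, int(x + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    mask = d2 <= r * r
    if inner_r >= 0:
        mask &= d2 > inner_r * inner_r
    img[y0:y1, x0:x1][mask] = value


def render_field(spec: FieldSpec, seed: int | np.random.SeedSequence) -> tuple[FieldImage, float]:
    """Render one two-channel field.

    The nuclei channel holds disks of ``intensity_nucleus_stain`` on a flat
    background; the OPP channel holds annular cytoplasms of
    ``intensity_cyto`` with the nuclear interior at ``intensity_nucleus_opp``.
    Additive Gaussian noise of SD ``noise_sd`` is applied to both channels,
    and values are clipped to the 16-bit range [0, 65535].

    Returns the field and the fraction of pixels that were clipped.
    """
    n = spec.image_size
    for c in spec.cells:
        if not (0 <= c.y < n and 0 <= c.x < n):
            raise ValueError(f"cell centroid ({c.y}, {c.x}) outside {n}x{n} image")
    nuc = np.full((n, n), spec.background, dtype=float)
    opp = np.full((n, n), spec.background, dtype=float)
    for c in spec.cells:
        _paint_disk(opp, c.y, c.x, c.r_cell, c.intensity_cyto, inner_r=c.r_nucleus)
        _paint_disk(opp, c.y, c.x, c.r_nucleus, c.intensity_nucleus_opp)
        _paint_disk(nuc, c.y, c.x, c.r_nucleus, c.intensity_nucleus_stain)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        nuc += rng.normal(0.0, spec.noise_sd, size=nuc.shape)
        opp += rng.normal(0.0, spec.noise_sd, size=opp.shape)
    clipped = int(np.sum((nuc < 0) | (nuc > 65535)) + np.sum((opp < 0) | (opp > 65535)))
    np.clip(nuc, 0, 65535, out=nuc)
    np.clip(opp, 0, 65535, out=opp)
    return FieldImage(nuclei_channel=nuc, opp_channel=opp), clipped / (2 * n * n)


def _place_cells(rng: np.random.Generator, n_cells: int, cfg: SyntheticScreenConfig):
    """Rejection-sample non-overlapping cell positions away from the border.

    Returns (y, x, r_nuc, r_cell) per placed cell; fewer than ``n_cells`` are
    placed when the field saturates.
    """
    placed: list[tuple[float, float, float, float]] = []
    size = cfg.image_size
    attempts = 0
    max_attempts = 300 * max(n_cells, 1)
    while len(placed) < n_cells and attempts < max_attempts:
        attempts += 1
        r_nuc = float(np.clip(rng.normal(cfg.nucleus_radius, cfg.nucleus_radius_sd),
                              2.0, 3.0 * cfg.nucleus_radius))
        r_cell = cfg.cyto_expansion * r_nuc
        margin = r_cell + 2.0
        if 2 * margin >= size:
            break
        y = rng.uniform(margin, size - margin)
        x = rng.uniform(margin, size - margin)
        if all((y - py) ** 2 + (x - px) ** 2 > (r_cell + pr + 1.0) ** 2
               for py, px, _, pr in placed):
            placed.append((y, x, r_nuc, r_cell))
    return placed


# ---------------------------------------------------------------------------
# screen generation

def _well_roles(cfg: SyntheticScreenConfig):
    rows = []
    for w in cfg.dmso_wells:
        rows.append((w, "dmso", "", 0.0))
    for w in cfg.torin_wells:
        rows.append((w, "torin", "", 0.5))
    for w in cfg.chx_wells:
        rows.append((w, "chx", "", 0.0))
    for w, comp in cfg.compound_wells():
        rows.append((w, "compound", comp.compound_id, cfg.compound_dose_uM))
    rows.sort(key=lambda r: r[0])
    return rows


def generate_screen(config: SyntheticScreenConfig, mode: str = "fast",
                    image_dir: str | os.PathLike | None = None) -> ScreenData:
    """Generate a synthetic screen.

    ``mode='fast'`` emits the well-level table directly; ``mode='images'``
    also renders every field (held in memory, and written as 16-bit TIFFs if
    ``image_dir`` is given). Fast and image mode share the same per-well
    draws, so the rendered per-well mean intensities track the fast-mode
    values up to per-cell sampling spread.
    """
    if mode not in ("fast", "images"):
        raise ValueError(f"mode must be 'fast' or 'images', got {mode!r}")
    config.validate()
    by_id = {c.compound_id: c for c in config.compounds}
    role_rows = _well_roles(config)

    plate_ids = [f"P{p + 1}" for p in range(config.n_plates)]
    pm_rows = [(pid, w, role, cid, dose)
               for pid in plate_ids for (w, role, cid, dose) in role_rows]
    plate_map = pd.DataFrame(pm_rows, columns=_io.PLATEMAP_COLUMNS)

    role_effect = {"dmso": 1.0, "torin": config.torin_effect, "chx": config.chx_effect}
    well_index = {w: i for i, (w, _, _, _) in enumerate(role_rows)}

    well_rows = []
    truth_wells = []
    cell_rows = []
    images: dict[tuple[str, str, int], FieldImage] = {} if mode == "images" else None

    for p, pid in enumerate(plate_ids):
        plate_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, p)))
        plate_factor = float(np.exp(plate_rng.normal(0.0, config.plate_effect_cv)))
        for w, role, cid, _dose in role_rows:
            wi = well_index[w]
            wrng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(2, p, wi)))
            if role == "compound":
                comp = by_id[cid]
                effect, toxicity, rep_cv = comp.effect, comp.toxicity, comp.replicate_noise_cv
            else:
                effect, toxicity, rep_cv = role_effect[role], 1.0, 0.0
            rep_factor = float(np.exp(wrng.normal(0.0, rep_cv))) if rep_cv > 0 else 1.0
            well_factor = float(np.exp(wrng.normal(0.0, config.well_effect_cv))) \
                if config.well_effect_cv > 0 else 1.0
            true_mean = config.baseline_opp * effect * plate_factor * rep_factor * well_factor
            n_cells = int(wrng.poisson(config.cells_per_well * toxicity))
            truth_wells.append((pid, w, role, cid, true_mean, n_cells))
            if mode == "fast":
                well_rows.append((pid, w, true_mean, n_cells, config.fields_per_well,
                                  "empty" if n_cells == 0 else ""))
            else:
                per_field = wrng.multinomial(n_cells,
                                             [1.0 / config.fields_per_well] * config.fields_per_well)
                for f in range(config.fields_per_well):
                    frng = np.random.default_rng(
                        np.random.SeedSequence(config.seed, spawn_key=(3, p, wi, f)))
                    placed = _place_cells(frng, int(per_field[f]), config)
                    cells = []
                    for (y, x, r_nuc, r_cell) in placed:
                        ci = true_mean * float(np.exp(frng.normal(0.0, config.cell_intensity_cv))) \
                            if config.cell_intensity_cv > 0 else true_mean
                        cells.append(CellSpec(y, x, r_nuc, r_cell, ci,
                                              config.nucleus_opp_fraction * ci,
                                              config.nucleus_stain_intensity))
                        cell_rows.append((pid, w, f, y, x, r_nuc, r_cell, ci))
                    spec = FieldSpec(config.image_size, config.background, config.noise_sd, cells)
                    img, _clip = render_field(
                        spec, np.random.SeedSequence(config.seed, spawn_key=(4, p, wi, f)))
                    images[(pid, w, f)] = img
                    if image_dir is not None:
                        _io.write_field_tiff(image_dir, pid, w, f,
                                             img.nuclei_channel, img.opp_channel)

    comp_truth = pd.DataFrame(
        [(c.compound_id, c.true_class, c.effect, c.toxicity) for c in config.compounds],
        columns=["compound_id", "true_class", "effect", "toxicity"])
    wells_truth = pd.DataFrame(
        truth_wells, columns=["plate_id", "well", "role", "compound_id",
                              "true_mean_cyto", "n_cells"])
    cells_truth = None
    if mode == "images":
        cells_truth = pd.DataFrame(
            cell_rows, columns=["plate_id", "well", "field", "y", "x",
                                "r_nucleus", "r_cell", "cyto_intensity"])
    truth = GroundTruth(compounds=comp_truth, wells=wells_truth, cells=cells_truth)

    if mode == "fast":
        well_table = pd.DataFrame(well_rows, columns=_io.WELLTABLE_COLUMNS)
    else:
        well_table = wells_truth.rename(columns={"true_mean_cyto": "mean_cyto_opp",
                                                 "n_cells": "nuclei_count"})[
            ["plate_id", "well", "mean_cyto_opp", "nuclei_count"]].copy()
        well_table["n_fields"] = config.fields_per_well
        well_table["flag"] = np.where(well_table["nuclei_count"] == 0, "empty", "")
    return ScreenData(plate_map=plate_map, well_table=well_table, truth=truth,
                      images=images, config=config)


# ---------------------------------------------------------------------------
# proteomics and dose-response tables

def generate_proteomics(n_proteins: int, n_regulated: int, effect_log2fc: float = 0.5,
                        within_group_sd: float = 0.15, seed: int = 0,
                        base_mean: float = 25.0, base_sd: float = 2.0,
                        frac_up: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a 3-vs-3 protein quantification table (log2 intensities).

    Each protein gets a baseline log2 abundance ~ N(base_mean, base_sd);
    replicates scatter around the group mean with SD ``within_group_sd``.
    ``n_regulated`` randomly chosen proteins are shifted by ±``effect_log2fc``
    in the treated group (a ``frac_up`` fraction upward); null proteins share
    group means, so under the null the per-protein two-sample test is exact.

    Returns (table, truth) where the table has columns protein_id,
    treated_1..3, control_1..3 and truth carries the planted labels.
    """
    if n_regulated > n_proteins:
        raise ValueError("n_regulated must be <= n_proteins")
    if within_group_sd <= 0:
        raise ValueError("within_group_sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    base = rng.normal(base_mean, base_sd, size=n_proteins)
    reg_idx = rng.choice(n_proteins, size=n_regulated, replace=False)
    n_up = int(round(frac_up * n_regulated))
    shift = np.zeros(n_proteins)
    shift[reg_idx[:n_up]] = effect_log2fc
    shift[reg_idx[n_up:]] = -effect_log2fc
    treated = base[:, None] + shift[:, None] + rng.normal(0, within_group_sd, (n_proteins, 3))
    control = base[:, None] + rng.normal(0, within_group_sd, (n_proteins, 3))
    table = pd.DataFrame({"protein_id": ids})
    for j in range(3):
        table[f"treated_{j + 1}"] = treated[:, j]
    for j in range(3):
        table[f"control_{j + 1}"] = control[:, j]
    direction = np.where(shift > 0, "up", np.where(shift < 0, "down", "null"))
    truth = pd.DataFrame({"protein_id": ids, "regulated": shift != 0,
                          "direction": direction, "true_log2fc": shift})
    return table, truth


def generate_dose_response(compound_effects: dict[str, float], seed: int = 0,
                           doses: tuple[float, ...] = (1.0, 3.0, 10.0),
                           hill: float = 1.0, ec50: float = 3.0,
                           noise_sd: float = 0.02,
                           assays: tuple[str, ...] = ("OPP", "HPG"),
                           n_plates: int = 2) -> pd.DataFrame:
    """Planted dose-response records for the validation screen.

    ``compound_effects`` maps compound_id to the fractional response at
    saturating dose (e.g. 0.3 means the signal drops to 30% of DMSO). The
    response follows a Hill curve anchored at 1.0 for dose 0; both assays
    share the true curve, with independent additive noise per record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for cid, bottom in sorted(compound_effects.items()):
        for assay in assays:
            for plate in range(1, n_plates + 1):
                for dose in doses:
                    frac = dose ** hill / (ec50 ** hill + dose ** hill)
                    resp = 1.0 + (bottom - 1.0) * frac
                    if noise_sd > 0:
                        resp += rng.normal(0.0, noise_sd)
                    rows.append((cid, assay, plate, dose, max(resp, 0.0)))
    return pd.DataFrame(rows, columns=["compound_id", "assay", "replicate_plate",
                                       "dose_uM", "response"])
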