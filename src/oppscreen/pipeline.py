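"""End-to-end screen orchestration: images or well tables in, hit calls out.

Stages run segmentation -> plate analytics -> hit calling with per-stage
CSV outputs, structured logging and a JSON run report (hit counts by class,
per-plate DMSO CV, DMSO/CHX control separation). The effective configuration
is serialized into the output directory for provenance, and the tabular
stages can be re-run from the persisted well table without re-segmentation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import yaml

from . import io as _io
from .hits import HitThresholds
from .screen import ScreenResults, TranslationScreen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen"]


@dataclass
class RunConfig:
    """Run parameters; exactly one of ``well_table`` / ``image_dir`` is set.

    Segmentation parameters are pixels (sizes/distances) and intensity units
    (threshold); hit thresholds as in :class:`~oppscreen.hits.HitThresholds`.
    """

    plate_map: str
    out_dir: str
    well_table: str | None = None
    image_dir: str | None = None
    # segmentation
    min_area: int = 20
    max_area: int = 2000
    sigma: float = 1.0
    lambda_reg: float = 0.05
    max_distance: int = 40
    pooling: str = "pooled"
    # hit calling
    k_sd: float = 3.0
    max_toxicity: float = 0.30
    max_cv: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if (self.well_table is None) == (self.image_dir is None):
            raise ValueError("set exactly one of well_table / image_dir")
        if not os.path.exists(self.plate_map):
            raise FileNotFoundError(self.plate_map)
        for p in (self.well_table, self.image_dir):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)

    def thresholds(self) -> HitThresholds:
        return HitThresholds(k_sd=self.k_sd, max_toxicity=self.max_toxicity,
                             max_cv=self.max_cv)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_screen(config: RunConfig) -> ScreenResults:
    """Execute the screen pipeline and persist per-stage outputs.

    Writes well_summaries.csv, normalized_wells.csv, compound_scores.csv,
    hit_calls.csv, qc.csv, report.json and the effective config.yaml into
    ``config.out_dir``. Stage failures abort with the stage name attached.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    plate_map = _io.read_platemap(config.plate_map)

    stage = "segmentation"
    try:
        if config.image_dir is not None:
            logger.info("segmenting fields in %s", config.image_dir)
            model = TranslationScreen.from_images(
                config.image_dir, plate_map, method=config.pooling,
                min_area=config.min_area, max_area=config.max_area, sigma=config.sigma,
                lambda_reg=config.lambda_reg, max_distance=config.max_distance)
        else:
            logger.info("loading well table %s", config.well_table)
            model = TranslationScreen.from_csv(config.well_table, config.plate_map)
        _io.write_well_table(model.well_table,
                             os.path.join(config.out_dir, "well_summaries.csv"))
        stage = "plate_analytics/hit_calling"
        results = model.fit(config.thresholds())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    results.to_csv(config.out_dir)
    counts = results.hit_counts
    qc = results.qc()
    report = {
        "n_plates": model.n_plates,
        "n_wells": int(len(model.well_table)),
        "n_compounds": int(len(results.compound_scores)),
        "hit_counts": {k: int(v) for k, v in counts.items()},
        "qc": {
            "dmso_cv_percent": {str(r["plate_id"]): float(r["dmso_cv_percent"])
                                for _, r in qc.iterrows()},
            "chx_separation_sd": {str(r["plate_id"]): (float(r["chx_separation"])
                                                       if np.isfinite(r["chx_separation"])
                                                       else None)
                                  for _, r in qc.iterrows()},
        },
        "thresholds": dataclasses.asdict(config.thresholds()),
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("screen complete: %s", report["hit_counts"])
    return results
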