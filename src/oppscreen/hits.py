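"""Four-criterion hit calling against the vehicle-well distribution.

A compound is called an up- or down-regulator of translation only when all
four gates hold:

1. its triplicate-mean normalized OPP signal deviates from the DMSO average
   by more than ``k_sd`` standard deviations (pooled over the triplicate
   plates' DMSO wells);
2. viability (normalized nuclei count) drops by no more than
   ``max_toxicity`` — compounds exceeding the toxicity bound are excluded
   from the analysis outright, whatever their OPP effect;
3. the per-plate deviation exceeds ``k_sd`` plate-level DMSO SDs on all
   three plates with a consistent sign;
4. the replicate coefficient of variation is below ``max_cv`` percent for
   both the OPP signal and the nuclei count.

The SD scale for the per-plate flags is each plate's own DMSO SD, while the
mean-based criterion 1 uses the pooled DMSO distribution — robust to plate
effects in both cases because everything is computed after per-plate
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HitThresholds", "DmsoStats", "compute_dmso_stats", "call_hits"]


@dataclass(frozen=True)
class HitThresholds:
    """Gate parameters: SD multiplier, maximum tolerated toxicity fraction,
    maximum replicate CV in percent. All strictly positive."""

    k_sd: float = 3.0
    max_toxicity: float = 0.30
    max_cv: float = 20.0

    def __post_init__(self):
        for name in ("k_sd", "max_toxicity", "max_cv"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DmsoStats:
    """Mean and sample SD of DMSO opp_norm, per plate and pooled."""

    per_plate: pd.DataFrame  # plate_id, mean, sd, n
    pooled_mean: float
    pooled_sd: float
    n_total: int

    def plate(self, plate_id) -> tuple[float, float]:
        row = self.per_plate.loc[self.per_plate["plate_id"] == plate_id]
        if row.empty:
            raise KeyError(f"no DMSO stats for plate {plate_id}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


def compute_dmso_stats(normalized: pd.DataFrame, plate_map: pd.DataFrame) -> DmsoStats:
    """Per-plate and pooled mean/sample-SD of the DMSO wells' opp_norm."""
    dm = plate_map[plate_map["role"] == "dmso"][["plate_id", "well"]]
    vals = normalized.merge(dm, on=["plate_id", "well"], how="inner")
    vals = vals[vals["opp_norm"].notna()]
    rows = []
    for pid, g in vals.groupby("plate_id", sort=True):
        if len(g) < 2:
            raise ValueError(f"plate {pid}: need >= 2 DMSO wells to estimate the SD")
        rows.append({"plate_id": pid, "mean": g["opp_norm"].mean(),
                     "sd": g["opp_norm"].std(ddof=1), "n": len(g)})
    if not rows:
        raise ValueError("no DMSO wells found")
    pooled = vals["opp_norm"].to_numpy(float)
    return DmsoStats(per_plate=pd.DataFrame(rows),
                     pooled_mean=float(pooled.mean()),
                     pooled_sd=float(pooled.std(ddof=1)),
                     n_total=len(pooled))


def call_hits(scores: pd.DataFrame, dmso: DmsoStats,
              thresholds: HitThresholds = HitThresholds()) -> pd.DataFrame:
    """Classify each compound as up / down / null / excluded.

    ``scores`` is the output of :func:`oppscreen.plates.aggregate_replicates`.
    Output columns carry the class, the four criterion booleans
    (effect_3sd_mean, viability_ok, hit_all_plates, cv_ok) and an exclusion
    reason. All comparisons use strict inequalities at the thresholds.
    """
    k = thresholds.k_sd
    plate_cols = sorted(c for c in scores.columns if c.startswith("plate_"))
    n_plates = len(plate_cols)
    rows = []
    for _, s in scores.iterrows():
        row = {"compound_id": s["compound_id"],
               "mean_opp_norm": s.get("mean_opp_norm", np.nan),
               "mean_viability_norm": s.get("mean_viability_norm", np.nan),
               "cv_opp": s.get("cv_opp", np.nan), "cv_viability": s.get("cv_viability", np.nan),
               "effect_3sd_mean": False, "viability_ok": False,
               "hit_all_plates": False, "cv_ok": False}
        if bool(s.get("excluded", False)):
            row.update({"class": "excluded",
                        "exclusion_reason": s.get("exclusion_reason", "") or "incomplete_triplicate"})
            rows.append(row)
            continue

        # criterion 3: per-plate deviation beyond k plate-DMSO-SDs, same sign
        signs = []
        per_plate_hit = []
        for i in range(1, n_plates + 1):
            mean_i, sd_i = dmso.plate(s[f"plate_{i}"])
            dev = s[f"opp_norm_{i}"] - mean_i
            per_plate_hit.append(abs(dev) > k * sd_i)
            signs.append(np.sign(dev))
        hit_all = all(per_plate_hit) and len(set(signs)) == 1 and signs[0] != 0
        # criterion 1: triplicate mean beyond k pooled-DMSO-SDs
        mean_dev = s["mean_opp_norm"] - dmso.pooled_mean
        effect_mean = abs(mean_dev) > k * dmso.pooled_sd
        # criterion 2: toxicity gate
        viability_ok = s["mean_viability_norm"] >= 1.0 - thresholds.max_toxicity
        # criterion 4: replicate reproducibility, both readouts
        cv_ok = (s["cv_opp"] < thresholds.max_cv) and (s["cv_viability"] < thresholds.max_cv)

        row.update({"effect_3sd_mean": bool(effect_mean), "viability_ok": bool(viability_ok),
                    "hit_all_plates": bool(hit_all), "cv_ok": bool(cv_ok)})
        if not viability_ok:
            row.update({"class": "excluded", "exclusion_reason": "toxicity"})
        elif effect_mean and hit_all and not cv_ok:
            row.update({"class": "excluded", "exclusion_reason": "high_cv"})
        elif effect_mean and hit_all and cv_ok:
            row.update({"class": "up" if mean_dev > 0 else "down", "exclusion_reason": ""})
        else:
            row.update({"class": "null", "exclusion_reason": ""})
        rows.append(row)
    cols = ["compound_id", "class", "effect_3sd_mean", "viability_ok", "hit_all_plates",
            "cv_ok", "mean_opp_norm", "mean_viability_norm", "cv_opp", "cv_viability",
            "exclusion_reason"]
    return pd.DataFrame(rows).reindex(columns=cols)
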