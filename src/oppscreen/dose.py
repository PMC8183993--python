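"""Dose-response validation of primary-screen hits.

Each hit is re-tested at 1, 3 and 10 uM on two independent plates with two
orthogonal translation labels (OPP and HPG). A compound validates as a
down-regulator when, in every (assay, plate) series, the response at the top
dose drops by at least ``min_effect`` below vehicle and the responses are
non-increasing in dose within an additive tolerance ``mono_tol`` (mirrored
for up-regulators). The default requires both assays to pass; a lenient
mode accepts a compound when either assay passes on both plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ValidationCall", "evaluate_dose_response", "evaluate_dose_response_table"]

DOSES = (1.0, 3.0, 10.0)


@dataclass
class ValidationCall:
    compound_id: str
    validated: bool
    direction: str                      # "down" or "up" (the mode evaluated)
    complete: bool
    series_pass: dict = field(default_factory=dict)    # (assay, plate) -> bool
    assay_monotone: dict = field(default_factory=dict)  # assay -> all plates monotone
    top_dose_effect: dict = field(default_factory=dict)  # assay -> mean response at top dose


def _series_passes(responses: np.ndarray, min_effect: float, mono_tol: float,
                   direction: str) -> tuple[bool, bool]:
    """(passes, monotone) for one dose-ordered response series."""
    if direction == "down":
        monotone = bool(np.all(np.diff(responses) <= mono_tol))
        effect = responses[-1] <= 1.0 - min_effect
    else:
        monotone = bool(np.all(np.diff(responses) >= -mono_tol))
        effect = responses[-1] >= 1.0 + min_effect
    return bool(effect and monotone), monotone


def evaluate_dose_response(records: pd.DataFrame, min_effect: float = 0.25,
                           mono_tol: float = 0.05, direction: str = "down",
                           require_both_assays: bool = True,
                           doses: tuple[float, ...] = DOSES) -> ValidationCall:
    """Evaluate the validation rule for one compound's dose-response records.

    ``records`` needs columns assay, replicate_plate, dose_uM, response and a
    complete dose grid per (assay, plate); an incomplete grid flags the
    compound rather than raising.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    cid = str(records["compound_id"].iloc[0]) if "compound_id" in records and len(records) else ""
    series_pass: dict = {}
    monotone_by_assay: dict[str, list[bool]] = {}
    top_by_assay: dict[str, list[float]] = {}
    complete = True
    for (assay, plate), g in records.groupby(["assay", "replicate_plate"], sort=True):
        g = g.set_index("dose_uM")["response"]
        if not all(d in g.index for d in doses):
            complete = False
            continue
        resp = np.array([float(g.loc[d]) for d in doses])
        ok, mono = _series_passes(resp, min_effect, mono_tol, direction)
        series_pass[(assay, int(plate))] = ok
        monotone_by_assay.setdefault(assay, []).append(mono)
        top_by_assay.setdefault(assay, []).append(resp[-1])

    assays = sorted(top_by_assay)
    if not complete or not assays:
        return ValidationCall(cid, False, direction, False, series_pass,
                              {a: all(v) for a, v in monotone_by_assay.items()},
                              {a: float(np.mean(v)) for a, v in top_by_assay.items()})
    per_assay_ok = {a: all(ok for (aa, _), ok in series_pass.items() if aa == a)
                    for a in assays}
    validated = all(per_assay_ok.values()) if require_both_assays else any(per_assay_ok.values())
    return ValidationCall(cid, bool(validated), direction, True, series_pass,
                          {a: all(v) for a, v in monotone_by_assay.items()},
                          {a: float(np.mean(v)) for a, v in top_by_assay.items()})


def evaluate_dose_response_table(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-compound validation calls for a multi-compound record table."""
    rows = []
    for cid, g in records.groupby("compound_id", sort=True):
        call = evaluate_dose_response(g, **kwargs)
        rows.append({"compound_id": cid, "validated": call.validated,
                     "complete": call.complete,
                     "n_series_pass": sum(call.series_pass.values()),
                     "n_series": len(call.series_pass)})
    return pd.DataFrame(rows)
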