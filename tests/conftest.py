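"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the slowest, most direct
route (naive per-label Dijkstra, explicit BH recursion, running-sum loops)
so the package implementations are checked against code that shares nothing
with them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oppscreen.synthetic import PlantedCompound, SyntheticScreenConfig, generate_screen


# ---------------------------------------------------------------------------
# oracles

def dijkstra_oracle(seeds: np.ndarray, img: np.ndarray, lambda_reg: float,
                    threshold: float) -> np.ndarray:
    """Declarative multi-source shortest-path labeling (no step limit).

    For each seed label, relax the geodesic cost over mask pixels until a
    fixpoint (paths may not pass through other labels' seed pixels), then
    assign every pixel the label minimizing (cost, label).
    """
    h, w = img.shape
    mask = (img > threshold) | (seeds > 0)
    best_cost = np.full((h, w), np.inf)
    best_label = np.zeros((h, w), dtype=int)
    for lab in sorted(np.unique(seeds[seeds > 0])):
        allowed = mask & ~((seeds > 0) & (seeds != lab))
        cost = np.full((h, w), np.inf)
        cost[seeds == lab] = 0.0
        changed = True
        while changed:
            changed = False
            for y in range(h):
                for x in range(w):
                    if not allowed[y, x] or cost[y, x] == 0.0:
                        continue
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and allowed[ny, nx] \
                                and np.isfinite(cost[ny, nx]):
                            step = np.sqrt((img[ny, nx] - img[y, x]) ** 2 + lambda_reg)
                            if cost[ny, nx] + step < cost[y, x]:
                                cost[y, x] = cost[ny, nx] + step
                                changed = True
        better = cost < best_cost
        tie = (cost == best_cost) & np.isfinite(cost) & (best_label > lab)
        upd = better | tie
        best_cost[upd] = cost[upd]
        best_label[upd] = lab
    return best_label


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by direct definition: sort, p*m/rank, cumulative
    min from the largest rank down."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def running_sum_es(metric: np.ndarray, member: np.ndarray, weight_p: float):
    """Enrichment score by an explicit running-sum loop; returns the signed
    extremum (ties between the positive and negative extreme of equal
    magnitude resolved toward the positive one, matching the package)."""
    member = np.asarray(member, bool)
    n, k = len(metric), int(member.sum())
    w = np.abs(np.asarray(metric, float)) ** weight_p
    wsum = w[member].sum()
    run, hi, lo = 0.0, 0.0, 0.0
    for i in range(n):
        if member[i]:
            run += (w[i] / wsum) if wsum > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        hi = max(hi, run)
        lo = min(lo, run)
    return hi if hi >= -lo else lo


# ---------------------------------------------------------------------------
# fixtures

def planted_library(n_compounds: int = 200, n_down: int = 10, n_up: int = 10,
                    effect_down: float = 0.5, effect_up: float = 1.5,
                    toxicity: float = 1.0, rep_cv: float = 0.02):
    """A compound library with planted regulators at the head of the list."""
    comps = []
    for i in range(n_compounds):
        effect = 1.0
        if i < n_down:
            effect = effect_down
        elif i < n_down + n_up:
            effect = effect_up
        comps.append(PlantedCompound(f"C{i + 1:04d}", effect=effect,
                                     toxicity=toxicity, replicate_noise_cv=rep_cv))
    return comps


@pytest.fixture
def fast_screen():
    """A triplicate fast-mode screen with 10 down- and 10 up-regulators."""
    cfg = SyntheticScreenConfig(compounds=planted_library(), seed=11)
    return generate_screen(cfg, mode="fast")


@pytest.fixture
def null_screen():
    """A triplicate fast-mode screen with no planted effects."""
    cfg = SyntheticScreenConfig(compounds=planted_library(n_down=0, n_up=0), seed=5)
    return generate_screen(cfg, mode="fast")


@pytest.fixture
def tiny_image_config():
    """A small noiseless image-mode screen (one plate, 8 wells)."""
    return SyntheticScreenConfig(
        n_plates=1, n_rows=2, n_cols=4, fields_per_well=2, image_size=160,
        cells_per_well=40,
        compounds=[PlantedCompound("C0001", effect=0.5),
                   PlantedCompound("C0002"), PlantedCompound("C0003"),
                   PlantedCompound("C0004"), PlantedCompound("C0005")],
        dmso_wells=["A02", "A03"], torin_wells=["A04"], chx_wells=[],
        noise_sd=0.0, seed=7)
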