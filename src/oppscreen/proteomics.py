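"""Differential-protein filter and preRanked gene-set enrichment.

The pipeline starts at the quantified protein table (one row per protein,
log2 intensities for 3 treated and 3 control replicates). Differential
abundance uses a per-protein two-sided two-sample t-test on the log2
intensities with Benjamini-Hochberg adjustment across all tested proteins;
a protein is flagged *regulated* when its raw p-value is < 0.05 and
|log2FC| > 0.3, with the BH q-value reported alongside. The default test
pools the within-group variance (exact under the equal-variance model that
labeled-quantification replicates approximate, and exactly calibrated at
triplicate group sizes, where the Welch-Satterthwaite approximation runs
conservative); Welch's unequal-variance form is available via ``test``.

Enrichment follows the preRanked scheme with the weighted enrichment
statistic: proteins are ranked by descending log2 ratio, the running sum
increments at set members by |metric|^p normalized by the member-weight
total and decrements at non-members by 1/(N - N_set); the enrichment score
(ES) is the extremum of the running sum. Null ES values come from random
gene-label memberships with a fixed seed; NES divides ES by the mean
|null ES| of the same sign, and FDR q-values use the pooled sign-stratified
null.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["differential_proteins", "rank_proteins", "enrichment_score", "gsea_preranked"]


def _group_columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(prefix)]
    if len(cols) < 2:
        raise ValueError(f"need >= 2 replicate columns with prefix {prefix!r}, found {cols}")
    return cols


def differential_proteins(table: pd.DataFrame, p_thr: float = 0.05, lfc_thr: float = 0.3,
                          treated_cols: list[str] | None = None,
                          control_cols: list[str] | None = None,
                          test: str = "student") -> pd.DataFrame:
    """Per-protein two-sample t-test and regulated flag.

    ``table`` holds protein_id plus per-replicate log2 intensity columns
    (default prefixes ``treated_`` / ``control_``). Returns protein_id,
    log2fc (treated mean - control mean), two-sided p_value, BH q_value and
    the regulated flag (p < p_thr and |log2fc| > lfc_thr, both strict).
    ``test`` is ``"student"`` (pooled variance, default) or ``"welch"``;
    the choice is flagged in the output's ``attrs`` metadata.
    Proteins with zero variance in both groups and equal means get p = 1 by
    convention (logged); zero variance with unequal means gets p = 0.
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    treated_cols = treated_cols or _group_columns(table, "treated_")
    control_cols = control_cols or _group_columns(table, "control_")
    t = table[treated_cols].to_numpy(float)
    c = table[control_cols].to_numpy(float)
    if not (np.isfinite(t).all() and np.isfinite(c).all()):
        raise ValueError("protein table contains non-finite intensities")
    log2fc = t.mean(axis=1) - c.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant replicate triples trip scipy's precision-loss warning;
        # those p-values are overwritten by the conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(t, c, axis=1, equal_var=(test == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("t-test degenerate for %d proteins (zero within-group variance)",
                    int(degenerate.sum()))
        p[degenerate & (log2fc == 0)] = 1.0
        p[degenerate & (log2fc != 0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "protein_id": table["protein_id"].to_numpy(),
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "regulated": (p < p_thr) & (np.abs(log2fc) > lfc_thr),
    })
    out.attrs["test"] = test
    out.attrs["p_thr"], out.attrs["lfc_thr"] = p_thr, lfc_thr
    return out


def rank_proteins(results: pd.DataFrame) -> pd.DataFrame:
    """Rank proteins by descending log2fc, ties broken lexicographically by
    protein_id; the log2 ratio is carried as the ranking metric."""
    if not np.isfinite(results["log2fc"].to_numpy(float)).all():
        raise ValueError("log2fc must be finite for ranking")
    ranked = results.sort_values(["log2fc", "protein_id"],
                                 ascending=[False, True], kind="mergesort",
                                 ignore_index=True)
    ranked = ranked[["protein_id", "log2fc"]].rename(columns={"log2fc": "metric"})
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


# ---------------------------------------------------------------------------
# enrichment

def _es_from_positions(absw: np.ndarray, pos: np.ndarray, n_total: int) -> np.ndarray:
    """Signed ES for one or many memberships.

    absw : |metric|^p over the full ranked list (length N)
    pos  : (m, k) 0-based hit positions, sorted ascending along axis 1
    """
    pos = np.atleast_2d(pos)
    m, k = pos.shape
    n_miss = n_total - k
    if n_miss <= 0:
        raise ValueError("gene set must be a strict subset of the ranked universe")
    w = absw[pos]
    wsum = w.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if flat.any():  # all member metrics exactly zero: fall back to equal weights
        w[flat] = 1.0
        wsum[flat] = k
    cumw = np.cumsum(w, axis=1) / wsum
    i = np.arange(1, k + 1)
    top = cumw - (pos + 1 - i) / n_miss            # running sum at each hit
    prev = np.concatenate([np.zeros((m, 1)), cumw[:, :-1]], axis=1)
    bottom = prev - (pos - (i - 1)) / n_miss       # running sum just before each hit
    hi = top.max(axis=1)
    lo = np.minimum(bottom.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def enrichment_score(metric: np.ndarray, member: np.ndarray, weight_p: float = 1.0) -> float:
    """ES of one gene set against a ranked metric vector.

    ``metric`` must already be sorted descending; ``member`` is a boolean
    mask over the ranked list. ``weight_p=0`` recovers the classic
    Kolmogorov-Smirnov-style statistic; ``weight_p=1`` (default) weights
    hits by |metric|.
    """
    metric = np.asarray(metric, dtype=float)
    member = np.asarray(member, dtype=bool)
    pos = np.flatnonzero(member)
    if pos.size == 0:
        raise ValueError("empty gene set")
    absw = np.abs(metric) ** weight_p
    return float(_es_from_positions(absw, pos[None, :], metric.size)[0])


@dataclass
class _SetResult:
    gene_set_id: str
    size: int
    es: float
    nes: float
    p_value: float
    null_nes: np.ndarray


def _normalize(es_values: np.ndarray, null_es: np.ndarray):
    """Sign-stratified NES: divide by the mean |null ES| of the same sign."""
    pos_mean = np.abs(null_es[null_es >= 0]).mean() if (null_es >= 0).any() else np.nan
    neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
    scale = np.where(np.asarray(es_values) >= 0, pos_mean, neg_mean)
    return np.asarray(es_values) / scale


def gsea_preranked(ranked: pd.DataFrame, gene_sets: dict[str, list[str]],
                   weight_p: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 5, exhaustive: bool = False,
                   max_exhaustive: int = 200_000) -> pd.DataFrame:
    """preRanked enrichment of every gene set against a ranked protein list.

    ``ranked`` is the output of :func:`rank_proteins` (columns protein_id,
    metric, already sorted). Sets are intersected with the ranked universe;
    sets smaller than ``min_size`` after intersection are skipped (logged).
    The null is built from random memberships of matching size drawn with a
    fixed seed (``exhaustive=True`` enumerates all C(N, k) memberships when
    that count is at most ``max_exhaustive``). The permutation p-value is
    the fraction of same-sign null ES with |ES_null| >= |ES|; FDR q-values
    use the pooled sign-stratified null with a monotonicity cleanup.
    Deterministic for a fixed seed.
    """
    ids = ranked["protein_id"].to_numpy()
    metric = ranked["metric"].to_numpy(float)
    if not np.all(np.diff(metric) <= 0):
        raise ValueError("ranked list must be sorted by descending metric")
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    absw = np.abs(metric) ** weight_p
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    results: list[_SetResult] = []
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in index]
        if not members:
            logger.warning("gene set %s has empty intersection with the universe; skipped", name)
            continue
        k = len(members)
        if k < min_size:
            logger.info("gene set %s below min_size (%d < %d); skipped", name, k, min_size)
            continue
        if k >= n:
            logger.warning("gene set %s covers the whole universe; skipped", name)
            continue
        pos = np.sort(np.fromiter((index[g] for g in members), dtype=int))
        es = float(_es_from_positions(absw, pos[None, :], n)[0])
        if exhaustive:
            total = math.comb(n, k)
            if total > max_exhaustive:
                raise ValueError(f"exhaustive enumeration of C({n},{k})={total} "
                                 f"exceeds max_exhaustive={max_exhaustive}")
            null_pos = np.array(list(itertools.combinations(range(n), k)), dtype=int)
        else:
            null_pos = np.sort(
                np.array([rng.choice(n, size=k, replace=False) for _ in range(n_perm)]),
                axis=1)
        null_es = _es_from_positions(absw, null_pos, n)
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        p = float(np.mean(np.abs(null_es[same]) >= abs(es))) if n_same else 1.0
        nes = float(_normalize(np.array([es]), null_es)[0])
        null_nes = _normalize(null_es, null_es)
        results.append(_SetResult(name, k, es, nes, p, null_nes[np.isfinite(null_nes)]))

    if not results:
        return pd.DataFrame(columns=["gene_set_id", "size", "es", "nes", "p_value",
                                     "fdr_q", "n_perm", "seed"])

    nes_obs = np.array([r.nes for r in results])
    pool = np.concatenate([r.null_nes for r in results])
    fdr = np.full(len(results), np.nan)
    for sign in (1, -1):
        sel = np.flatnonzero((nes_obs >= 0) if sign > 0 else (nes_obs < 0))
        if sel.size == 0:
            continue
        pool_s = pool[pool >= 0] if sign > 0 else pool[pool < 0]
        for j in sel:
            v = nes_obs[j]
            if pool_s.size == 0 or not np.isfinite(v):
                fdr[j] = np.nan
                continue
            frac_null = np.mean(pool_s >= v) if sign > 0 else np.mean(pool_s <= v)
            frac_obs = np.mean(nes_obs[sel] >= v) if sign > 0 else np.mean(nes_obs[sel] <= v)
            fdr[j] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else np.nan
        # monotone cleanup: q non-increasing toward more extreme NES
        order = sel[np.argsort(-sign * nes_obs[sel])]       # most extreme first
        fdr[order] = np.fmin.accumulate(fdr[order][::-1])[::-1]

    out = pd.DataFrame({
        "gene_set_id": [r.gene_set_id for r in results],
        "size": [r.size for r in results],
        "es": [r.es for r in results],
        "nes": nes_obs,
        "p_value": [r.p_value for r in results],
        "fdr_q": fdr,
        "n_perm": [len(r.null_nes) for r in results],
        "seed": seed,
    })
    return out
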