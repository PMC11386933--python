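"""Rank-based gene-set enrichment (weighted Kolmogorov–Smirnov running sum).

Genes are ranked by the signal-to-noise statistic on log2 normalized
abundances, (mu_treated - mu_control) / (sd_treated + sd_control), with each
group sd floored at max(0.2 |mu|, 0.2). Walking the ranked list, set members
("hits") add |score|^weight / sum_hits |score|^weight and non-members
subtract 1/(n - n_hits); the enrichment score ES is the running-sum value of
maximal absolute deviation. A permutation null (random gene sets of matching
size by default, phenotype relabeling where the design allows) yields the
normalized score NES = ES / mean |null ES of the same sign|, an add-one
nominal p, and the standard positive/negative-side FDR q. Significance uses
the gates p < 0.05, |NES| > 1, FDR q < 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .diffexpr import PSEUDOCOUNT, normalize
from .errors import DomainError
from .io_formats import CountMatrix, GeneSetCollection

GATE_P = 0.05
GATE_ABS_NES = 1.0
GATE_FDR_Q = 0.25


@dataclass
class RankedList:
    """Gene ids ordered by score descending; ties broken by id."""

    gene_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise DomainError("gene_ids and scores lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DomainError("gene ids must be unique")


def signal_to_noise(
    matrix: CountMatrix, method: str = "cpm", pseudocount: float = PSEUDOCOUNT
) -> RankedList:
    """Signal-to-noise ranking of all features, treated vs control."""
    ctrl = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "control"]
    trt = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "treated"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise DomainError("signal-to-noise needs >= 2 samples per group")
    log_norm = np.log2(normalize(matrix, method=method) + pseudocount)
    scores = _s2n(log_norm, np.array(trt), np.array(ctrl))
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], matrix.feature_ids[i]))
    return RankedList(
        gene_ids=[matrix.feature_ids[i] for i in order], scores=scores[order]
    )


def _s2n(log_norm: np.ndarray, trt: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    mu_t = log_norm[:, trt].mean(axis=1)
    mu_c = log_norm[:, ctrl].mean(axis=1)
    sd_t = log_norm[:, trt].std(axis=1, ddof=1)
    sd_c = log_norm[:, ctrl].std(axis=1, ddof=1)
    sd_t = np.maximum(sd_t, np.maximum(0.2 * np.abs(mu_t), 0.2))
    sd_c = np.maximum(sd_c, np.maximum(0.2 * np.abs(mu_c), 0.2))
    return (mu_t - mu_c) / (sd_t + sd_c)


def enrichment_score(
    ranked: RankedList, set_ids, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Full running-sum walk; returns (es, running_sum, leading_edge)."""
    n = len(ranked.gene_ids)
    members = set(set_ids)
    hits = np.array([gid in members for gid in ranked.gene_ids])
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise DomainError("gene set must cover some but not all of the ranked list")
    w = np.abs(ranked.scores) ** weight
    hit_gain = np.where(hits, w, 0.0)
    total = hit_gain.sum()
    if total == 0:  # all member scores zero: fall back to unweighted steps
        hit_gain = hits.astype(float)
        total = float(n_hits)
    miss_loss = np.where(hits, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(hit_gain / total - miss_loss)
    # positive side wins ties of the two extreme deviations (tolerance keeps
    # exact ties stable under floating-point noise)
    max_pos, min_neg = float(running.max()), float(running.min())
    if max_pos >= -min_neg - 1e-9:
        extremum = int(np.argmax(running))
        es = max_pos
    else:
        extremum = int(np.argmin(running))
        es = min_neg
    if es >= 0:
        leading = [ranked.gene_ids[i] for i in range(extremum + 1) if hits[i]]
    else:
        leading = [ranked.gene_ids[i] for i in range(extremum, n) if hits[i]]
    return es, running, leading


def _es_from_hits(scores: np.ndarray, hit_idx: np.ndarray, weight: float) -> float:
    """ES evaluated only at hit boundaries (equivalent to the full walk)."""
    n = scores.size
    k = hit_idx.size
    w = np.abs(scores[hit_idx]) ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    p_hit = np.cumsum(w) / total
    miss = 1.0 / (n - k)
    ranks = np.arange(1, k + 1)
    after = p_hit - (hit_idx + 1 - ranks) * miss
    before = np.concatenate(([0.0], p_hit[:-1])) - (hit_idx - (ranks - 1)) * miss
    candidates = np.concatenate((after, before))
    max_pos = float(max(candidates.max(), 0.0))
    min_neg = float(min(candidates.min(), 0.0))
    return max_pos if max_pos >= -min_neg - 1e-9 else min_neg


def gsea_test(
    matrix: CountMatrix,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    perm_mode: str = "gene_set",
    rng_seed: int = 0,
    weight: float = 1.0,
    method: str = "cpm",
) -> pd.DataFrame:
    """Permutation GSEA over a collection; one row per testable gene set."""
    if n_perm < 100:
        raise DomainError("n_perm must be >= 100")
    if perm_mode not in ("gene_set", "phenotype"):
        raise DomainError(f"unknown perm_mode {perm_mode!r}")
    rng = np.random.default_rng(rng_seed)
    ranked = signal_to_noise(matrix, method=method)
    id_index = {gid: i for i, gid in enumerate(ranked.gene_ids)}
    n = len(ranked.gene_ids)

    testable = []
    for term, name, members in sets.sets:
        idx = np.array(sorted(id_index[m] for m in set(members) if m in id_index))
        if 0 < idx.size < n:
            testable.append((term, name, idx))
    if not testable:
        return _empty_gsea_frame()

    null_es = _null_es(
        matrix, ranked, testable, n_perm, perm_mode, weight, rng, method
    )

    rows = []
    obs_nes = []
    null_nes_pool = []
    for (term, name, idx), nulls in zip(testable, null_es):
        es, _, leading = enrichment_score(ranked, {ranked.gene_ids[i] for i in idx}, weight)
        pos = nulls[nulls >= 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        same = pos if es >= 0 else neg
        denom = mean_pos if es >= 0 else mean_neg
        if not np.isfinite(denom) or denom == 0:
            denom = np.abs(nulls).mean() or 1.0
        nes = es / denom
        n_extreme = int(np.sum(np.abs(same) >= abs(es))) if same.size else 0
        nominal_p = (1 + n_extreme) / (1 + same.size)
        # normalize the null the same way to build the FDR reference
        norm_null = np.where(
            nulls >= 0,
            nulls / (mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 1.0),
            nulls / (mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 1.0),
        )
        null_nes_pool.append(norm_null)
        obs_nes.append(nes)
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "es": es,
                "nes": nes,
                "nominal_p": nominal_p,
                "leading_edge": ",".join(leading),
                "set_size": int(idx.size),
            }
        )

    obs_nes_arr = np.array(obs_nes)
    pool = np.concatenate(null_nes_pool)
    for row, nes in zip(rows, obs_nes_arr):
        row["fdr_q"] = _fdr_q(nes, obs_nes_arr, pool)
        row["significant"] = bool(
            row["nominal_p"] < GATE_P
            and abs(nes) > GATE_ABS_NES
            and row["fdr_q"] < GATE_FDR_Q
        )
    df = pd.DataFrame(rows)
    cols = [
        "term_id", "term_name", "set_size", "es", "nes",
        "nominal_p", "fdr_q", "significant", "leading_edge",
    ]
    return df[cols].sort_values(["nominal_p", "term_id"], kind="mergesort").reset_index(drop=True)


def _null_es(matrix, ranked, testable, n_perm, perm_mode, weight, rng, method):
    scores = ranked.scores
    n = scores.size
    if perm_mode == "gene_set":
        # null depends only on set size: share permutations across equal sizes
        sizes = sorted({idx.size for _, _, idx in testable})
        null_by_size = {}
        for k in sizes:
            nulls = np.empty(n_perm)
            for p in range(n_perm):
                perm_idx = np.sort(rng.choice(n, size=k, replace=False))
                nulls[p] = _es_from_hits(scores, perm_idx, weight)
            null_by_size[k] = nulls
        return [null_by_size[idx.size] for _, _, idx in testable]

    # phenotype relabeling
    ctrl = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "control"]
    trt = [i for i, s in enumerate(matrix.sample_ids) if matrix.group_of[s] == "treated"]
    n_samples = len(matrix.sample_ids)
    n_relabel = _n_distinct_relabelings(n_samples, len(trt))
    if n_relabel < 20:
        raise DomainError(
            f"only {n_relabel} distinct phenotype relabelings; use perm_mode='gene_set'"
        )
    log_norm = np.log2(normalize(matrix, method=method) + PSEUDOCOUNT)
    nulls = np.empty((len(testable), n_perm))
    all_idx = np.arange(n_samples)
    for p in range(n_perm):
        perm = rng.permutation(all_idx)
        p_trt, p_ctrl = perm[: len(trt)], perm[len(trt):]
        perm_scores = _s2n(log_norm, p_trt, p_ctrl)
        order = np.lexsort((np.array(ranked.gene_ids), -perm_scores))
        # order is over the original ranked ordering of ids
        pos_of = np.empty(n, dtype=int)
        pos_of[order] = np.arange(n)
        sorted_scores = perm_scores[order]
        for j, (_, _, idx) in enumerate(testable):
            hit_idx = np.sort(pos_of[idx])
            nulls[j, p] = _es_from_hits(sorted_scores, hit_idx, weight)
    return list(nulls)


def _n_distinct_relabelings(n_samples: int, n_treated: int) -> int:
    from math import comb

    return comb(n_samples, n_treated)


def _fdr_q(nes: float, obs: np.ndarray, pool: np.ndarray) -> float:
    """Positive/negative-side normalized-null ratio FDR estimate."""
    if nes >= 0:
        null_side = pool[pool >= 0]
        obs_side = obs[obs >= 0]
        null_frac = np.mean(null_side >= nes) if null_side.size else 0.0
        obs_frac = np.mean(obs_side >= nes) if obs_side.size else 1.0
    else:
        null_side = pool[pool < 0]
        obs_side = obs[obs < 0]
        null_frac = np.mean(null_side <= nes) if null_side.size else 0.0
        obs_frac = np.mean(obs_side <= nes) if obs_side.size else 1.0
    if obs_frac == 0:
        return 0.0 if null_frac == 0 else 1.0
    return float(min(1.0, null_frac / obs_frac))


def _empty_gsea_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term_id", "term_name", "set_size", "es", "nes",
            "nominal_p", "fdr_q", "significant", "leading_edge",
        ]
    )
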