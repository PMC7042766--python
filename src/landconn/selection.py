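"""Spatially-thinned bootstrap replication, AICc ranking, and consensus.

Uneven sampling intensity can bias pairwise landscape-genetic models, so
individuals are resampled into many replicate sets whose members are all at
least ``min_dist`` apart (spatial thinning).  Within each replicate the
candidate models are ranked by AICc and given Akaike weights; across
replicates the per-model rank distributions are summarized and a single
consensus median ranking is found by branch and bound under the tau_x rank
correlation for tied rankings (Emond & Mason), i.e. the ranking minimizing
the total tau_x distance to all replicate rankings — a Kemeny-style optimum,
exact for small model sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ReplicateSet:
    replicate: int
    indices: np.ndarray     # individual indices, order of acceptance
    seed: int


def spatial_bootstrap(coords, min_dist_m: float, n_sets: int = 999,
                      seed: int = 0) -> list[ReplicateSet]:
    """Resample individuals into ``n_sets`` spatially thinned sets.

    Each set is grown by uniform random draws over all individuals; a draw is
    accepted only if it lies at least ``min_dist_m`` from every already
    accepted member (an individual is trivially rejected if redrawn, keeping
    members unique within a set).  Growth stops when no eligible individual
    remains, so every set is maximal and individuals isolated by more than
    ``min_dist_m`` from everyone else appear in every set.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if min_dist_m <= 0:
        raise ValueError("min_dist must be positive")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if not np.any(d[np.triu_indices(n, 1)] >= min_dist_m):
        warnings.warn("no pair satisfies the minimum distance; each set is a "
                      "single random individual")
        rng = np.random.default_rng(seed)
        return [ReplicateSet(r, np.array([rng.integers(n)]), seed)
                for r in range(n_sets)]
    rng = np.random.default_rng(seed)
    sets = []
    for r in range(n_sets):
        accepted: list[int] = []
        eligible = np.ones(n, dtype=bool)
        while eligible.any():
            i = int(rng.integers(n))
            if not eligible[i]:
                continue
            accepted.append(i)
            eligible &= d[i] >= min_dist_m   # also removes i (d[i,i]=0)
        sets.append(ReplicateSet(r, np.array(accepted, dtype=np.int64), seed))
    return sets


def replicate_sets_to_frame(sets: list[ReplicateSet], ids=None) -> pd.DataFrame:
    rows = []
    for s in sets:
        for i in s.indices:
            rows.append({"replicate": s.replicate,
                         "individual": ids[i] if ids is not None else int(i)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AICc ranking and Akaike weights

def rank_and_weight(aicc_matrix, model_names=None) -> dict:
    """Per-replicate ranks/weights and cross-replicate summaries.

    ``aicc_matrix`` is models × replicates.  Non-finite entries (failed fits)
    receive the worst rank and weight 0 within their replicate, with a logged
    count.  Returns a dict with "ranks" (models × replicates, ties = mean
    rank), "weights" (Akaike weights, summing to 1 per replicate) and
    "summary" (per-model average rank, mean AICc, ΔAICc, mean weight, and the
    percentage of replicates ranked 1st/2nd/3rd).
    """
    A = np.asarray(aicc_matrix, dtype=float)
    m, R = A.shape
    if model_names is None:
        model_names = [f"model{i+1}" for i in range(m)]
    n_failed = int((~np.isfinite(A)).sum())
    if n_failed:
        warnings.warn(f"{n_failed} failed fits assigned worst rank and "
                      "zero weight")
    ranks = np.empty_like(A)
    weights = np.zeros_like(A)
    for r in range(R):
        col = A[:, r]
        ok = np.isfinite(col)
        filled = np.where(ok, col, np.inf)
        ranks[:, r] = rankdata(filled, method="average")
        if ok.any():
            delta = col[ok] - col[ok].min()
            w = np.exp(-delta / 2.0)
            weights[ok, r] = w / w.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_aicc = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
    summary = pd.DataFrame({
        "model": model_names,
        "avg_rank": ranks.mean(axis=1),
        "mean_AICc": mean_aicc,
        "delta_AICc": mean_aicc - np.nanmin(mean_aicc),
        "mean_weight": weights.mean(axis=1),
        "pct_rank1": 100.0 * (ranks == 1).mean(axis=1),
        "pct_rank2": 100.0 * (ranks == 2).mean(axis=1),
        "pct_rank3": 100.0 * (ranks == 3).mean(axis=1),
    })
    return {"ranks": ranks, "weights": weights, "summary": summary,
            "model_names": list(model_names), "n_failed": n_failed}


# ---------------------------------------------------------------------------
# Consensus median ranking (tau_x, branch and bound)

def _score_matrix(rank_matrix: np.ndarray) -> np.ndarray:
    """Combined Emond–Mason score matrix C over replicates.

    For each replicate ranking r, b_ij = 1 if r_i <= r_j (i ranked ahead of
    or tied with j), −1 otherwise; C sums b over replicates.
    """
    R = np.asarray(rank_matrix, dtype=float)
    m = R.shape[0]
    C = np.zeros((m, m))
    for r in range(R.shape[1]):
        col = R[:, r]
        b = np.where(col[:, None] <= col[None, :], 1.0, -1.0)
        np.fill_diagonal(b, 0.0)
        C += b
    return C


def _objective_from_ranking(ranking: np.ndarray, C: np.ndarray) -> float:
    """Total tau_x agreement of a (possibly tied) candidate ranking with the
    replicate set: sum over ordered pairs of a_ij * C_ij."""
    a = np.where(ranking[:, None] <= ranking[None, :], 1.0, -1.0)
    np.fill_diagonal(a, 0.0)
    return float((a * C).sum())


def _buckets_to_ranking(buckets: list[list[int]], m: int) -> np.ndarray:
    out = np.zeros(m)
    pos = 1
    for b in buckets:
        rank = pos + (len(b) - 1) / 2.0
        for i in b:
            out[i] = rank
        pos += len(b)
    return out


def consensus_median_ranking(rank_matrix, max_models: int = 12):
    """Exact consensus median ranking by branch and bound.

    ``rank_matrix`` is models × replicates of (possibly tied) ranks.  The
    search enumerates ordered partitions of the models (ties allowed in the
    output), pruning with an upper bound that credits every undecided pair
    with its best achievable pairwise agreement.  Returns (ranking, total
    tau_x agreement); the ranking uses mean ranks for tied groups.
    """
    R = np.asarray(rank_matrix, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    m = R.shape[0]
    if m > max_models:
        raise ValueError(f"{m} models exceeds the exact-search cap "
                         f"({max_models}); reduce the model set or raise "
                         "max_models")
    C = _score_matrix(R)
    # per unordered pair, the best achievable contribution
    pair_max = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            pair_max[i, j] = max(C[i, j] - C[j, i],
                                 C[j, i] - C[i, j],
                                 C[i, j] + C[j, i])

    best = {"score": -np.inf, "buckets": None}

    def bound(fixed_score, placed, remaining):
        # placed items are strictly ahead of every remaining item (new
        # buckets only ever open behind), so those pairs are decided; pairs
        # among remaining items get their best achievable contribution
        ub = fixed_score
        rem = list(remaining)
        for j in rem:
            for i in placed:
                ub += C[i, j] - C[j, i]
        for ii, i in enumerate(rem):
            for j in rem[ii + 1:]:
                a, b = (i, j) if i < j else (j, i)
                ub += pair_max[a, b]
        return ub

    def recurse(buckets, placed, remaining, fixed_score):
        if not remaining:
            if fixed_score > best["score"]:
                best["score"] = fixed_score
                best["buckets"] = [list(b) for b in buckets]
            return
        if bound(fixed_score, placed, remaining) <= best["score"]:
            return
        rem = sorted(remaining)
        for pick in _nonempty_subsets(rem):
            # contribution of the new bucket against placed items and within
            add = 0.0
            for i in pick:
                for j in placed:
                    add += C[j, i] - C[i, j]      # placed ahead of i
            picks = list(pick)
            for ii, i in enumerate(picks):
                for j in picks[ii + 1:]:
                    add += C[i, j] + C[j, i]      # tied within the bucket
            recurse(buckets + [picks], placed + picks,
                    remaining - set(pick), fixed_score + add)

    recurse([], [], set(range(m)), 0.0)
    ranking = _buckets_to_ranking(best["buckets"], m)
    return ranking, best["score"]


def _nonempty_subsets(items):
    m = len(items)
    for mask in range(1, 1 << m):
        yield tuple(items[k] for k in range(m) if mask >> k & 1)


def exhaustive_consensus(rank_matrix):
    """Brute-force consensus over all ordered partitions (reference
    implementation for small m; used to validate the branch and bound)."""
    R = np.asarray(rank_matrix, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    m = R.shape[0]
    C = _score_matrix(R)
    best_score, best_ranking = -np.inf, None
    for buckets in _ordered_partitions(list(range(m))):
        ranking = _buckets_to_ranking(buckets, m)
        s = _objective_from_ranking(ranking, C)
        if s > best_score:
            best_score, best_ranking = s, ranking
    return best_ranking, best_score


def _ordered_partitions(items):
    if not items:
        yield []
        return
    rest = set(items)
    for first in _nonempty_subsets(sorted(rest)):
        remaining = sorted(rest - set(first))
        for tail in _ordered_partitions(remaining):
            yield [list(first)] + tail


def ranking_table(aicc_matrix, model_names=None,
                  max_models: int = 12) -> pd.DataFrame:
    """Full model-selection table: consensus rank plus rank/weight summaries,
    sorted by consensus rank."""
    rw = rank_and_weight(aicc_matrix, model_names)
    cons, _ = consensus_median_ranking(rw["ranks"], max_models=max_models)
    tbl = rw["summary"].copy()
    tbl.insert(1, "consensus_rank", cons)
    return tbl.sort_values("consensus_rank").reset_index(drop=True)
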